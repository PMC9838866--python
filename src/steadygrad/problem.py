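"""Estimation problems: conditions, measurements and the shared container.

A problem couples a compiled model with a set of experimental conditions,
a measurement table and the parameter metadata (scales and bounds).  Steady
state measurements are marked with an infinite time; a condition with such
rows requires post-equilibration, and a condition with pre-equilibration
inputs starts its time course from the steady state under those inputs.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .conservation import reduce_model
from .model import ModelFunctions, ParameterSet, ReactionNetwork, compile_model

STEADY_STATE_TIME = math.inf

__all__ = [
    "STEADY_STATE_TIME",
    "ExperimentCondition",
    "MeasurementTable",
    "ConditionData",
    "Problem",
]


@dataclasses.dataclass
class ExperimentCondition:
    """Constant inputs of one experiment, with optional pre-equilibration inputs."""

    id: str
    u: np.ndarray
    u_pre: np.ndarray | None = None
    requires_postequilibration: bool = False  # set from the measurement table

    def __post_init__(self) -> None:
        self.u = np.atleast_1d(np.asarray(self.u, dtype=float))
        if self.u_pre is not None:
            self.u_pre = np.atleast_1d(np.asarray(self.u_pre, dtype=float))

    @property
    def requires_preequilibration(self) -> bool:
        return self.u_pre is not None


@dataclasses.dataclass
class ConditionData:
    """Measurements of one condition, split into time-course and steady-state."""

    times: np.ndarray  # sorted unique finite measurement times
    tc_time_index: np.ndarray  # per row: index into times
    tc_obs_index: np.ndarray
    tc_value: np.ndarray
    tc_sigma: np.ndarray
    ss_obs_index: np.ndarray
    ss_value: np.ndarray
    ss_sigma: np.ndarray

    @property
    def has_timecourse(self) -> bool:
        return self.times.size > 0

    @property
    def has_steady_state(self) -> bool:
        return self.ss_value.size > 0


class MeasurementTable:
    """Measurement rows (condition, observable, time, value, sigma).

    ``time == inf`` marks a steady-state measurement.  Rows are sorted by
    (condition, time) on construction; sigmas must be positive and finite.
    """

    COLUMNS = ["condition_id", "observable_id", "time", "value", "sigma"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"measurement table is missing columns {missing}")
        df = df[self.COLUMNS].copy()
        df["time"] = df["time"].astype(float)
        df["value"] = df["value"].astype(float)
        df["sigma"] = df["sigma"].astype(float)
        if (df["sigma"] <= 0).any() or not np.isfinite(df["sigma"]).all():
            bad = df.index[(df["sigma"] <= 0) | ~np.isfinite(df["sigma"])][0]
            raise ValueError(f"measurement row {bad}: sigma must be positive and finite")
        if df["time"].isna().any() or (df["time"] < 0).any():
            raise ValueError("measurement times must be nonnegative (inf marks steady state)")
        if not np.isfinite(df["value"]).all():
            raise ValueError("measurement values must be finite")
        self.df = df.sort_values(["condition_id", "time"], kind="stable").reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "MeasurementTable":
        return cls(pd.DataFrame(list(records), columns=cls.COLUMNS))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def condition_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["condition_id"]))

    def for_condition(self, condition_id: str, observable_ids) -> ConditionData:
        obs_index = {name: i for i, name in enumerate(observable_ids)}
        sub = self.df[self.df["condition_id"] == condition_id]
        unknown = [o for o in sub["observable_id"] if o not in obs_index]
        if unknown:
            raise KeyError(
                f"measurement for condition '{condition_id}' references unknown "
                f"observable '{unknown[0]}'"
            )
        tc = sub[np.isfinite(sub["time"])]
        ss = sub[~np.isfinite(sub["time"])]
        times = np.unique(tc["time"].to_numpy())
        t_pos = {t: i for i, t in enumerate(times)}
        return ConditionData(
            times=times,
            tc_time_index=np.array([t_pos[t] for t in tc["time"]], dtype=int),
            tc_obs_index=np.array([obs_index[o] for o in tc["observable_id"]], dtype=int),
            tc_value=tc["value"].to_numpy(),
            tc_sigma=tc["sigma"].to_numpy(),
            ss_obs_index=np.array([obs_index[o] for o in ss["observable_id"]], dtype=int),
            ss_value=ss["value"].to_numpy(),
            ss_sigma=ss["sigma"].to_numpy(),
        )


class Problem:
    """A full estimation problem (model + conditions + data + parameters)."""

    def __init__(
        self,
        network: ReactionNetwork,
        conditions: list[ExperimentCondition],
        measurements: MeasurementTable,
        parameters: ParameterSet,
        model: ModelFunctions | None = None,
    ):
        self.network = network
        self.model = model if model is not None else compile_model(network)
        self.conditions = list(conditions)
        self.measurements = measurements
        self.parameters = parameters
        self._cache: dict[str, ConditionData] = {}

        cond_ids = {c.id for c in self.conditions}
        for cid in measurements.condition_ids:
            if cid not in cond_ids:
                raise KeyError(f"measurement references unknown condition '{cid}'")
        for cond in self.conditions:
            cd = self.condition_data(cond.id)
            cond.requires_postequilibration = cd.has_steady_state
            if not cd.has_timecourse and not cd.has_steady_state:
                raise ValueError(f"condition '{cond.id}' has no measurements")
        if list(parameters.ids) != list(self.model.parameter_ids):
            raise ValueError(
                "parameter table ids must match model parameters "
                f"({list(parameters.ids)} vs {list(self.model.parameter_ids)})"
            )

    def condition_data(self, condition_id: str) -> ConditionData:
        if condition_id not in self._cache:
            self._cache[condition_id] = self.measurements.for_condition(
                condition_id, self.model.observable_ids
            )
        return self._cache[condition_id]

    def reduced(self) -> "Problem":
        """Return a problem on the moiety-reduced model (identity if none)."""
        if self.network.reduced:
            return self
        model, analysis = reduce_model(self.network)
        if analysis.n_c == 0:
            return self
        return Problem(
            network=model.network,
            conditions=[dataclasses.replace(c) for c in self.conditions],
            measurements=self.measurements,
            parameters=self.parameters,
            model=model,
        )

    def theta_nominal(self) -> np.ndarray:
        """Nominal parameters on the estimation scale."""
        return self.parameters.nominal_estimation()
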