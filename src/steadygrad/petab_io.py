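"""Problem loading and saving: model YAML plus PEtab-style TSV tables.

A problem directory contains ``model.yaml`` (steadygrad-model-v1 dialect)
and four tab-separated tables:

``conditions.tsv``
    ``conditionId``, one column per model input, and an optional
    ``preequilibrationConditionId`` referring to another row whose input
    values define the pre-equilibration phase.
``observables.tsv``
    ``observableId``, ``observableFormula`` (recompiled into the model).
``measurements.tsv``
    ``observableId``, ``simulationConditionId``, ``time`` (a number, or the
    literal ``inf`` marking a steady-state measurement), ``measurement``,
    ``noiseParameters`` (a positive number).
``parameters.tsv``
    ``parameterId``, ``parameterScale`` (``lin``/``log10``), ``lowerBound``,
    ``upperBound``, ``nominalValue``, ``estimate`` (0/1).

This is a deliberately small subset of PEtab: numeric noise only, no priors,
no observable transformations; bounds are given on the linear scale and
converted to the estimation scale internally.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import FORMAT_KEY, ParameterSet, compile_model, load_model, with_observables
from .problem import ExperimentCondition, MeasurementTable, Problem

__all__ = ["load_problem", "save_problem", "ProblemLoadError"]

MODEL_FILE = "model.yaml"
TABLES = {
    "conditions": "conditions.tsv",
    "observables": "observables.tsv",
    "measurements": "measurements.tsv",
    "parameters": "parameters.tsv",
}


class ProblemLoadError(ValueError):
    pass


def _read(directory: Path, name: str) -> pd.DataFrame:
    path = directory / TABLES[name]
    if not path.exists():
        raise ProblemLoadError(f"missing table {path.name} in {directory}")
    return pd.read_csv(path, sep="\t", dtype=str).fillna("")


def _require(df: pd.DataFrame, cols, fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ProblemLoadError(f"{fname}: missing columns {missing}")


def load_problem(directory: str | Path) -> Problem:
    """Load and validate a problem directory into a :class:`Problem`."""
    directory = Path(directory)
    network = load_model(directory / MODEL_FILE)

    obs_df = _read(directory, "observables")
    _require(obs_df, ["observableId", "observableFormula"], TABLES["observables"])
    network = with_observables(
        network, dict(zip(obs_df["observableId"], obs_df["observableFormula"]))
    )

    cond_df = _read(directory, "conditions")
    _require(cond_df, ["conditionId"], TABLES["conditions"])
    input_cols = list(network.inputs)
    _require(cond_df, input_cols, TABLES["conditions"])
    cond_rows = {}
    for i, row in cond_df.iterrows():
        cid = row["conditionId"]
        if cid in cond_rows:
            raise ProblemLoadError(f"{TABLES['conditions']}: duplicate conditionId '{cid}'")
        cond_rows[cid] = row

    meas_df = _read(directory, "measurements")
    _require(
        meas_df,
        ["observableId", "simulationConditionId", "time", "measurement", "noiseParameters"],
        TABLES["measurements"],
    )
    obs_ids = set(obs_df["observableId"])
    records = []
    for i, row in meas_df.iterrows():
        if row["observableId"] not in obs_ids:
            raise ProblemLoadError(
                f"{TABLES['measurements']} row {i}: unknown observable "
                f"'{row['observableId']}'"
            )
        if row["simulationConditionId"] not in cond_rows:
            raise ProblemLoadError(
                f"{TABLES['measurements']} row {i}: unknown condition "
                f"'{row['simulationConditionId']}'"
            )
        t = math.inf if str(row["time"]).strip().lower() == "inf" else float(row["time"])
        records.append(
            (
                row["simulationConditionId"],
                row["observableId"],
                t,
                float(row["measurement"]),
                float(row["noiseParameters"]),
            )
        )
    measurements = MeasurementTable.from_records(records)

    conditions = []
    referenced = set(measurements.condition_ids)
    for cid, row in cond_rows.items():
        if cid not in referenced:
            continue  # e.g. a condition only used for pre-equilibration
        u = np.array([float(row[c]) for c in input_cols])
        u_pre = None
        pre_id = str(row.get("preequilibrationConditionId", "") or "").strip()
        if pre_id:
            if pre_id not in cond_rows:
                raise ProblemLoadError(
                    f"{TABLES['conditions']}: condition '{cid}' references unknown "
                    f"pre-equilibration condition '{pre_id}'"
                )
            u_pre = np.array([float(cond_rows[pre_id][c]) for c in input_cols])
        conditions.append(ExperimentCondition(id=cid, u=u, u_pre=u_pre))

    par_df = _read(directory, "parameters")
    _require(
        par_df,
        ["parameterId", "parameterScale", "lowerBound", "upperBound", "nominalValue", "estimate"],
        TABLES["parameters"],
    )
    par_rows = {row["parameterId"]: row for _, row in par_df.iterrows()}
    unknown = [p for p in par_rows if p not in network.parameters]
    if unknown:
        raise ProblemLoadError(
            f"{TABLES['parameters']}: parameter '{unknown[0]}' does not appear in the model"
        )
    missing = [p for p in network.parameters if p not in par_rows]
    if missing:
        raise ProblemLoadError(f"{TABLES['parameters']}: missing model parameter '{missing[0]}'")
    scale_map = {"lin": "lin", "log10": "log10"}
    ids = list(network.parameters)
    scales = []
    for p in ids:
        s = str(par_rows[p]["parameterScale"]).strip()
        if s not in scale_map:
            raise ProblemLoadError(
                f"{TABLES['parameters']}: parameter '{p}' has unsupported scale '{s}'"
            )
        scales.append(scale_map[s])
    parameters = ParameterSet(
        ids=ids,
        nominal=np.array([float(par_rows[p]["nominalValue"]) for p in ids]),
        scales=scales,
        lower=np.array([float(par_rows[p]["lowerBound"]) for p in ids]),
        upper=np.array([float(par_rows[p]["upperBound"]) for p in ids]),
        estimate=np.array([bool(int(par_rows[p]["estimate"])) for p in ids]),
    )
    return Problem(network=network, conditions=conditions, measurements=measurements,
                   parameters=parameters)


def _model_to_dict(network) -> dict:
    if network.definition is not None:
        data = dict(network.definition)
        data["format"] = FORMAT_KEY
        return data
    data = {
        "format": FORMAT_KEY,
        "species": list(network.species),
        "parameters": list(network.parameters),
        "inputs": list(network.inputs[: network.n_u_base]),
        "initials": {n: str(e) for n, e in zip(network.species, network.initials)},
        "observables": {n: str(e) for n, e in network.observables.items()},
    }
    if network.stoichiometry.shape[1]:
        data["reactions"] = [
            {
                "reactants": {
                    network.species[i]: -int(network.stoichiometry[i, r])
                    for i in range(network.n_x)
                    if network.stoichiometry[i, r] < 0
                },
                "products": {
                    network.species[i]: int(network.stoichiometry[i, r])
                    for i in range(network.n_x)
                    if network.stoichiometry[i, r] > 0
                },
                "rate": str(network.rates[r]),
            }
            for r in range(network.stoichiometry.shape[1])
        ]
    if network.raw_odes:
        data["odes"] = {n: str(e) for n, e in network.raw_odes.items()}
    return data


def save_problem(problem: Problem, directory: str | Path) -> None:
    """Write a problem back to a directory (model YAML + four TSV tables)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    network = problem.network
    if network.reduced:
        raise ValueError("saving a moiety-reduced problem is not supported; save the full model")

    (directory / MODEL_FILE).write_text(yaml.safe_dump(_model_to_dict(network), sort_keys=False))

    obs_rows = [
        {"observableId": name, "observableFormula": str(expr)}
        for name, expr in network.observables.items()
    ]
    pd.DataFrame(obs_rows).to_csv(directory / TABLES["observables"], sep="\t", index=False)

    input_cols = list(network.inputs[: network.n_u_base])
    cond_rows = []
    extra = []
    for cond in problem.conditions:
        row = {"conditionId": cond.id, "preequilibrationConditionId": ""}
        for c, v in zip(input_cols, cond.u):
            row[c] = v
        if cond.requires_preequilibration:
            pre_id = f"{cond.id}__preeq"
            row["preequilibrationConditionId"] = pre_id
            pre_row = {"conditionId": pre_id, "preequilibrationConditionId": ""}
            for c, v in zip(input_cols, cond.u_pre):
                pre_row[c] = v
            extra.append(pre_row)
        cond_rows.append(row)
    pd.DataFrame(cond_rows + extra).to_csv(directory / TABLES["conditions"], sep="\t", index=False)

    meas = problem.measurements.df.copy()
    out = pd.DataFrame(
        {
            "observableId": meas["observable_id"],
            "simulationConditionId": meas["condition_id"],
            "time": [("inf" if not np.isfinite(t) else t) for t in meas["time"]],
            "measurement": meas["value"],
            "noiseParameters": meas["sigma"],
        }
    )
    out.to_csv(directory / TABLES["measurements"], sep="\t", index=False)

    p = problem.parameters
    pd.DataFrame(
        {
            "parameterId": p.ids,
            "parameterScale": p.scales,
            "lowerBound": p.lower,
            "upperBound": p.upper,
            "nominalValue": p.nominal,
            "estimate": p.estimate.astype(int),
        }
    ).to_csv(directory / TABLES["parameters"], sep="\t", index=False)
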