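"""Multi-start maximum-likelihood fit driven by steady-state adjoint gradients.

Fits the three-state Michaelis-Menten chain to synthetic data (time course
plus steady-state measurements, sigma = 0.01) from uniformly sampled start
points.  The Fisher information at the truth predicts which parameters the
design identifies: the inflow (k0) and terminal degradation (k3) rates are
sharply determined, while the saturation pairs (V, K) are strongly
correlated at this operating point and only weakly identified.
"""

import numpy as np

import steadygrad as sg

spec = sg.FixtureSpec("mm_chain", seed=0, sigma=0.01, equilibration="post")
problem, theta_true = sg.make_problem(spec)
ids = problem.model.parameter_ids

idx = sg.identifiable_parameters(problem, theta_true)
print("practically identifiable parameters:", [ids[i] for i in idx])

profile = sg.SolverSettings(
    rtol=1e-8, atol=1e-10,
    equilibration=sg.EquilibrationSettings(max_doublings=12),
)
report = sg.estimate(
    problem, n_starts=5, seed=1, max_iter=60, gradient_method="ssasa", settings=profile
)

best = report.best
theta_fit = problem.parameters.to_linear(best.theta)
theta_ref = problem.parameters.to_linear(theta_true)
print(f"\nbest of {len(report.starts)} successful starts: nll = {best.nll:.4f} "
      f"({best.n_iterations} iterations)")
print(f"nll at the true parameters: {sg.objective_value(problem, theta_true, profile).nll:.4f}")
print(f"\n{'parameter':10s}{'true':>10s}{'fitted':>10s}{'rel.err':>10s}")
for k, pid in enumerate(ids):
    rel = abs(theta_fit[k] - theta_ref[k]) / theta_ref[k]
    tag = "  <- identifiable" if k in idx else ""
    print(f"{pid:10s}{theta_ref[k]:10.4f}{theta_fit[k]:10.4f}{rel:9.2%}{tag}")
print()
print("Identifiable parameters land within a few tenths of a percent of the")
print("truth; the saturation parameters absorb the noise along their")
print("correlated directions, as the Fisher analysis predicts.")
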