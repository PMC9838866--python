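"""Steady-state adjoint gradient on a model with a known closed form.

Production-degradation, dX/dt = s*k_in - k_out*X, has the steady state
x* = s*k_in/k_out.  With one steady-state measurement ybar* = 3 (sigma = 1)
at (k_in, k_out) = (2, 1), the gradient of the negative log-likelihood is

    dJ/dtheta = -(ybar* - x*) d(x*)/dtheta = (-1, +2),

which the steady-state adjoint method reproduces with a single 1x1 linear
solve and zero backward integration.
"""

import numpy as np

import steadygrad as sg

network = sg.parse_model(
    {
        "species": ["X"],
        "parameters": ["k_in", "k_out"],
        "inputs": ["s"],
        "reactions": [
            {"products": {"X": 1}, "rate": "s*k_in"},
            {"reactants": {"X": 1}, "rate": "k_out*X"},
        ],
        "observables": {"obs_X": "X"},
    }
)
parameters = sg.ParameterSet(
    ids=["k_in", "k_out"], nominal=[2.0, 1.0], scales=["lin", "lin"],
    lower=[1e-3, 1e-3], upper=[1e3, 1e3],
)
condition = sg.ExperimentCondition(id="c0", u=[1.0])
measurements = sg.MeasurementTable.from_records([("c0", "obs_X", np.inf, 3.0, 1.0)])
problem = sg.Problem(network, [condition], measurements, parameters)

result = sg.gradient(problem, method="ssasa")

print(f"negative log-likelihood : {result.nll:.6f}")
print(f"gradient (linear scale) : {result.gradient_linear}")
print(f"backward RHS evals over the equilibration span: "
      f"{result.counters['backward_rhs_equilibration']}")
print()
print("The gradient matches the hand-derived (-1, +2): the objective falls")
print("when k_in rises (x* moves toward the datum 3) and rises with k_out.")
print("The zero backward-RHS counter shows the adjoint quadrature over the")
print("equilibration interval was obtained from one linear solve instead of")
print("backward ODE integration.")
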