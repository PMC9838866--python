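# Methods

## Model class and assumptions

`steadygrad` works with ODE models `dx/dt = f(x, θ, u)`, `x(t₀) = x₀(θ, u)`,
observed through `y = h(x, θ, u)` with additive Gaussian noise of known,
per-measurement standard deviation. States and parameters are nonnegative in
the intended model class (concentrations and rate constants); inputs `u` are
constant per experimental phase and carry no sensitivities. Rate expressions
are arbitrary differentiable closed forms, not just mass action; a raw-ODE
escape hatch allows models without reaction structure (conserved-moiety
detection is then skipped with a warning, since it needs a stoichiometry).

Every method here assumes that each relevant initial condition leads to an
**exponentially stable** steady state: all eigenvalues of the steady-state
Jacobian `J = ∂f/∂x|ₓ*` have negative real parts. This guarantees (i)
equilibration converges, (ii) the steady-state Jacobian is invertible after
moiety removal, and (iii) the adjoint relaxes to zero backward in time, which
is what licenses the linear-solve shortcut. Multi-stable systems are handled
operationally, not detected: post-equilibration always starts from the final
time-course state, so the steady state reached is the one continuous with
the simulated history.

State ordering is declaration order everywhere; all matrices use it
consistently. All derivatives (`∂f/∂x`, `∂f/∂θ`, `∂x₀/∂θ`, `∂h/∂x`, `∂h/∂θ`)
are generated symbolically with sympy and lambdified; no numerical
differentiation enters any gradient path except the explicit FD oracle.

## Equilibration

Steady states are found by BDF integration over doubling windows
(`t_start_window = 10` model time units, at most 30 doublings — the paper
class gives no horizon, and doubling bounds total work at about twice the
final window), testing at the start state and at every natural integrator
output point the weighted residual

    wrms = (1/n_x) Σᵢ (ẋᵢ/(rtol·xᵢ + atol))²  < 1 ,

with defaults `rtol = 1e-8`, `atol = 1e-16` (the commonly used orders of
magnitude). The printed criterion is implemented as stated — without a square
root; since the threshold is 1, the two forms are equivalent. A weight
denominator of exactly zero is a hard error; transiently negative states
produce a warning, not an error, because stiff solvers may undershoot.
States exceeding `max_state = 1e8` abort with an equilibration failure —
a divergence guard that keeps hopeless parameter regions cheap during
optimization.

After the simulation converges, a **Newton polish** (on by default) iterates
`x ← x − J⁻¹f(x)` while the wrms decreases, falling back to the simulation
result on any failure. Polishing matters beyond accuracy: the raw stopping
state carries an error of order `rtol_ss·x` that is non-smooth in θ (the
stopping point jumps with the step sequence), which would contaminate
finite-difference oracles; the polished state is accurate to machine
precision and varies smoothly.

## Gradient methods

All four engines share the same forward simulation (BDF, `rtol = 1e-10`,
`atol = 1e-12` — deliberately tighter than the equilibration tolerances so
cross-method comparisons are not integrator-noise limited) and the same
objective, and all apply the parameter-scale chain rule (log10 entries
multiplied by `θ ln 10`) as the final step.

**ssasa (default).** Per condition: pre-equilibrate if required, simulate
the time course with dense output, post-equilibrate if required. The
steady-state measurement jump `p(t″) = Σ (∂h/∂x)ᵀ r/σ²` feeds one LU solve
`Jᵀ p_int = −p(t″)`; the contribution `−p_intᵀ ∂f/∂θ|ₓ*` plus the direct
`∂h/∂θ` term replaces the entire post-equilibration backward integral. The
time-course backward pass then starts from exactly `p = 0` (the adjoint has
relaxed; using the relaxed numerical value instead would only inject noise).
After the time-course pass, `p(t₀)` feeds the pre-equilibration solve
`J(x*_pre)ᵀ p_int = −p(t₀)` under the pre-equilibration inputs; no
`−p(−t′)ᵀ ∂x₀/∂θ` term is added because the adjoint vanishes at the
pre-equilibration start. Without pre-equilibration, the explicit
`−p(t₀)ᵀ ∂x₀/∂θ` term is used. Multiple steady-state observables fold into
a single boundary jump — the model class defines one steady state per
condition. Solves are dense LU with partial pivoting (fixture scale; a
sparse path would only pay above a few hundred states). Each solve's
residual `‖Jᵀp_int + p_boundary‖` is recorded and asserted to be at
round-off level.

On a singular steady-state Jacobian the default is a hard error carrying
the reciprocal condition estimate and a moiety-removal hint; an opt-in
fallback (`allow_asa_fallback`) silently integrates that interval backward
instead and tags the result, because silent method switching can hide
modeling problems.

**asa (reference).** The long-simulation treatment: the forward trajectory
is extended over the equilibration span actually used (re-simulated densely)
and the adjoint, with its quadratures as augmented states, is integrated
backward over the same span. A `tail_scale` factor lengthens or shortens the
span; doubling it demonstrates convergence to the ssasa value as the adjoint
decays. The steady-state residual and jump are evaluated at the converged
`x*` rather than the truncated tail end, so the tail-scale experiment
isolates exactly the truncated adjoint integral — the quantity the linear
solve replaces. With pre-equilibration, the backward pass is extended over
the pre-equilibration span and the scalar product of `p(−t′)` with the
initial-state sensitivities is evaluated (not assumed zero).

**forward.** Augmented integration of `ṡ = J s + ∂f/∂θ`; at steady states,
sensitivities come from per-parameter linear solves `J s*ₖ = −∂f/∂θₖ`
(pre-equilibration sensitivities seed the time course). Independent of the
adjoint code paths, hence the primary oracle. The same observable
sensitivities assemble an expected Fisher information matrix used for
practical-identifiability assessment.

**fd.** Central differences on the estimation scale with step
`1e-5·max(1, |θₖ|)`, evaluated at oracle-grade integrator tolerances
(`rtol = 1e-12`, `atol = 1e-14`) so that the differenced objective noise
stays well below the step-induced truncation error.

Adjoint quadratures are carried as augmented states of the backward BDF
integration (so the integrator controls their error) rather than by
post-hoc quadrature of stored `p(t)`; forward states needed during backward
passes come from dense interpolation of the checkpointed forward solution.
A measurement exactly at `t₀` is applied as a jump before the
`∂x₀/∂θ` term.

Work accounting: every `GradientResult` carries counters for forward RHS
evaluations, backward RHS evaluations split into time-course and
equilibration spans, and linear solves. Under ssasa the equilibration-span
backward counter is structurally zero; the suite asserts it, and asserts
that the reference method's total backward work is strictly larger. These
counters are the implementation-independent analogue of wall-clock speedup.

## Conserved-moiety reduction

The left null space of the stoichiometric matrix is computed exactly over
the rationals (sympy), rows scaled to smallest integers — exactness is worth
more than scalability at the model sizes this package targets; heuristic
moiety finders exist for genome-scale networks but are out of scope. Per law
the eliminated state is the one with the largest absolute coefficient (ties
to the highest declaration index), subject to the eliminated submatrix of
`L` remaining invertible so multiple laws can be eliminated jointly.

Elimination is symbolic: `x_E = L_E⁻¹(T − L_K x_K)` is substituted into the
right-hand side and observables. The totals `T = L·x₀(θ, u_init)` are
expressed through **duplicated input symbols** (`<input>__init`) that stand
for the inputs active when the initial state was set: a pre-equilibrated
time course inherits the totals of the pre-equilibration condition, and the
θ-dependence of the totals propagates exactly into `∂f/∂θ` and `∂x₀/∂θ`
through ordinary symbolic differentiation. The reduced model's input vector
is the base inputs followed by these initial-phase copies.

Nonsingularity is checked via the SVD reciprocal condition estimate with
tolerance `1e-10` (a safety factor above double-precision round-off for the
solves). If the Jacobian is singular for reasons other than conservation,
reduction does not help; the error path (or the explicit fallback) applies.

## Estimation

`estimate` draws start points uniformly within the bounds **on the
estimation scale** (log10 bounds sampled in log10 space) with a seeded
generator, and runs scipy's bounded L-BFGS-B from each, driven by the
selected gradient method. The optimizer contract is "bounded,
gradient-based, deterministic given a start"; the specific trust-region
implementation used in large-scale practice is not reproduced, as the
gradient engine is orthogonal to the optimizer. Failed evaluations
(equilibration divergence, singular Jacobians) return a large penalty with
zero gradient, so hopeless starts terminate quickly; starts whose final
value is the penalty are reported as failures. For optimization runs a
looser solver profile is appropriate and used in the shipped recovery runs:
integrator tolerances `1e-8/1e-10` and at most 12 equilibration doublings —
gradient accuracy of ~1e-4 is ample for line searches, and any fixture-class
model that needs an equilibration horizon beyond `10·2¹¹` time units has no
reachable steady state.

## Synthetic fixtures: what they emulate and what they do not

The generator produces the statistical structure the method assumes:
exponentially stable steady states (Hurwitz Jacobian after reduction,
verified at generation; failing draws are regenerated with the next
sub-seed, at most 10 times) and independent Gaussian noise. Four kinds:

- `production_degradation` — 1 state, `θ = (k_in, k_out)`, input scales the
  inflow; closed-form steady state `s·k_in/k_out`.
- `conversion` — A⇌B with total `a0` (a parameter, so totals are
  θ-dependent); exercises the moiety machinery and the singular error path
  when left unreduced.
- `linear_network` — seeded random `ẋ = r·A x + s·b` with `A` strictly
  diagonally dominant (Gershgorin ⇒ Hurwitz by construction),
  `θ = (r, b₁…bₙ)`, default n = 5.
- `mm_chain` — 3-state Michaelis–Menten chain,
  `θ = (k0, V1, K1, V2, K2, k3)`, nonlinear with full-rank stoichiometry.

Default conditions: unit input, pre-equilibration at half input, 8
time points log-spaced over [0.1, 10] (equilibrating systems change on log
time scales), noise σ = 0.1 for gradient comparisons and σ = 0.01 for
recovery, all parameters log10-scaled with bounds [1e-3, 1e3]. The
cross-validation suite holds 13 problems covering all equilibration modes
(`none/pre/post/both`), with and without moieties, linear and saturating
kinetics. The post-equilibrating conversion entry carries steady-state-only
data: with time-course data to t = 10 its fast kinetics (relaxation rate
`k1+k2 = 3`) are already at steady state at the last time point, leaving no
equilibration span for the reference method to integrate over.

Passing tests on these fixtures validates the gradient mathematics, the
moiety handling and the work-count claim under the stated assumptions. They
do not probe model misspecification, non-Gaussian or θ-dependent noise
(σ is a fixed number per measurement row; the likelihood omits ∂σ/∂θ terms
by design), oscillatory or multi-stable dynamics, partial observability at
scale, or the wall-clock behavior of problems with thousands of states.

## Identifiability and the recovery check

Parameter recovery is asserted only for **practically identifiable**
parameters, determined before fitting from the expected Fisher information
at the true parameters: a parameter counts as identifiable when its
predicted relative standard deviation on the linear scale
(`ln10·√[F⁻¹]ₖₖ` for log10 entries) is below 2.5% — half the 5% recovery
band, so the check is a multi-sigma statement. On the Michaelis–Menten
recovery design (σ = 0.01) this selects the inflow and terminal degradation
rates (predicted sd ≈ 1.1% and 1.4%); the saturation pairs (V, K) are
correlated at the operating point (predicted sd 14–22%) and genuinely not
determined to 5% by these data — their fitted values absorb noise along the
correlated directions, as expected, and are excluded from the assertion.

## Numerical choices and degenerate inputs

- Backward integration uses the analytic block Jacobian of the augmented
  adjoint system; a jump-free backward segment with `p = 0` is skipped
  exactly (zero dynamics).
- The gradient-comparison metric is the scale-relative max difference
  `‖g₁−g₂‖∞ / max(‖g₁‖∞, ‖g₂‖∞)`, robust to individual near-zero
  components.
- Measurements only at `t = 0` skip integration entirely; steady-state-only
  conditions skip the time course and post-equilibrate from `x₀`.
- σ = 0 in a measurement table is rejected (degenerate likelihood); the
  data generator records σ = 1 for noise-free tables so likelihoods stay
  defined.
- Duplicate measurement times are allowed and folded into one adjoint jump.
- A zero-length equilibration span (system already at steady state at the
  last time point) is valid: the reference method then carries the boundary
  jump directly into the time-course pass.

## Known limitations

Dense linear algebra only; no events, delays, time-dependent inputs, priors
or noise-parameter estimation; no second-order adjoints; steady-state
parametric sensitivities are available through the forward path but are not
an output of the adjoint path (the adjoint yields only the objective
gradient); moiety detection requires an explicit stoichiometry. Wall-clock
performance is not a goal of this implementation — the backward-work
counters stand in for it.
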