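# Methods

## Model

The tumor is modeled as two well-mixed compartments — chemotherapy-sensitive
volume N1 and fully resistant volume N2 (mm³) — growing Gompertzian against
a shared carrying capacity K that represents the tumor vasculature.  The
capacity is stimulated by the tumor (rate b), inhibited through a
surface-to-volume interaction (rate d, acting as d·N^{2/3}·K), loses
vessels spontaneously (rate μ), and is damaged by both drugs.  Chemotherapy
follows the log-kill hypothesis and acts only on the sensitive compartment
(rate β₁ per unit dose) and on the vasculature (rate β); the
anti-angiogenic agent acts on the vasculature alone (rate γ).  Mutation is
a deterministic first-order flux between compartments (τ₁ toward
resistance, τ₂ back), which is appropriate at the cell numbers implied by
mm³-scale volumes; stochastic (birth–death) resistance acquisition is out
of scope.

Assumptions to keep in mind: drug concentrations equal administered doses
(no pharmacokinetics — doses are fractions of MTD in [0, 1] and act
instantaneously), the anti-angiogenic dose v is constant over a treatment
course, resistance is complete (β₂ = 0), and both compartments secrete
angiogenic factors identically.

### Parameters

| symbol | default | unit | meaning |
|---|---|---|---|
| λ₁ | 0.192 | 1/day | proliferation rate, sensitive cells |
| λ₂ | 0.096 | 1/day | proliferation rate, resistant cells |
| τ₁ | 2·10⁻⁵ | 1/day | mutation rate toward resistance |
| τ₂ | 1·10⁻⁵ | 1/day | back-mutation rate |
| μ | 0.0 | 1/day | endothelial loss rate |
| b | 5.85 | 1/day | vascular stimulation |
| d | 8.73·10⁻³ | 1/(day·mm²) | vascular inhibition |
| β₁ | 0.3 | 1/(day·MTD) | chemo kill rate of sensitive cells |
| β | 0.1 | 1/(day·MTD) | chemo damage to vasculature |
| γ | 2.0 | 1/(day·MTD) | anti-angiogenic damage to vasculature |

Reference initial state (280, 20, 650) mm³; critical (fatal) volume
N_crit = 8000 mm³; untreated saturating volume ((b−μ)/d)^{3/2} ≈ 17 347 mm³
(≈ 17 000 rounded).  Objective weights default to ω₁ = 5, ω₂ = 25, η₁ = 1,
η₂ = 5, ξ = 1000, ε = 10 mm³, θ = 0: the resistance penalty and the 5×
resistant weighting drive the schedule shape, while the explicit dose
penalty is implemented but inert unless switched on.

### The two chemosensitivity regimes

β₁ and β are the least certain parameters, so analyses distinguish a
low-sensitivity regime (β₁ = 0.3, β = 0.1, the table defaults) and a
high-sensitivity regime (β₁ = 0.6, β = 0.2).  The regime qualitatively
changes the 14-day optimum: under low sensitivity with nominal (small) τ₁,
sustained full dose cannot push the tumor into resistant majority within
14 days, the resistance penalty never activates, and u ≡ 1 is simply the
best schedule.  The characteristic bang–singular–bang schedules with
intermediate singular doses of 20–35% of MTD arise in the high-sensitivity
regime, which is therefore the default scenario for all short-horizon
optimization examples, the worked example, and the acceptance script.  The
sensitivity study (below) covers both regimes explicitly.

## Numerical methods

**Simulation.**  Adaptive RK45 (`scipy.integrate.solve_ivp`), relative
tolerance 10⁻⁶ by default (tightened to 10⁻⁸–10⁻¹⁰ where a test needs it),
absolute tolerance 10⁻⁸.  Piecewise-constant controls are applied
left-continuously and the integrator restarts at every control breakpoint,
so bang-bang inputs never straddle an adaptive step.  A trial state with a
non-positive component returns infinite rates, forcing the step controller
to reject and shrink rather than evaluate an undefined logarithm; a state
that genuinely leaves the positive orthant (below 10⁻¹² mm³) aborts with a
diagnostic.  Event times (doubling, critical-volume crossing) are located
by the integrator's root refinement on its dense output, well below the
10⁻⁶-day target; crossings are verified to sit within 10⁻³ mm³ of the
threshold.

**Steady states** are found as roots of the right-hand side in
log-coordinates (which keeps iterates positive) with the analytic Jacobian
available for stability classification by eigenvalue real parts.  When the
hybrid root-finder fails from a distant guess — the mutation manifold is
many orders of magnitude slower than the vascular dynamics, which makes the
landscape badly scaled — the state is first relaxed toward the attractor
with a stiff-capable integrator (LSODA) over several mutation time
constants and then polished.

**Survival analysis.**  T_s is the first passage of N1+N2 through N_crit.
"Infinity" (treatment holds the tumor subcritical indefinitely) is
operationalized as "not reached within t_max", default 1000 days.  This is
deliberate: at the default parameters the attractive equilibrium of the
treated system is a resistant tumor of total volume
((b − βu − γv − μ)/d)^{3/2} ≥ ≈ 8900 mm³ > N_crit for every dose pair in
[0, 1]², so *every* constant protocol eventually crosses the fatal volume
and the infinity category is necessarily horizon-relative.  The longest
constant-dose survival observed at defaults is ≈ 453 days (u = 0.05,
v = 1).  The best constant dose is located by a coarse grid scan followed
by bounded golden-section refinement; flat landscapes tie-break to the
smallest dose.

**Optimal control.**  Discretize-then-optimize: forward Euler on a regular
grid of 400 intervals over the 14-day window (401 state nodes; the
solution is insensitive to ±1 interval and to doubling the grid), with the
running cost integrated by the matching left-rectangle rule.  Rather than
exposing the 3(M+1) state variables and 3M Euler equality constraints to a
general NLP solver, the package solves the reduced problem: states are
eliminated exactly by the forward recursion, and the exact gradient of the
discrete objective with respect to the M control values is computed by a
reverse (adjoint) sweep using the hand-coded Jacobian of the dynamics.
The resulting smooth bound-constrained program is minimized with L-BFGS-B
(projected-gradient tolerance 10⁻¹⁰, effectively machine-precision relative
function tolerance, memory 50), multistarted from constant controls
{0, 0.5, 1} with warm restarts; the best objective wins and near-ties go to
the lower average dose.  The procedure is deterministic.  Dynamics
residuals of a reported solution are zero by construction.  Singular
(interior) arcs are maximal runs of at least 3 grid nodes with
0.02 < u < 0.98; the singular mean dose is the time average over their
union.  A schedule is classified full-dose when its time-averaged dose
strictly exceeds 90% of MTD.

Both quadratures are exposed for objective evaluation: left-rectangle on
the Euler grid (what the optimizer minimizes and reports) and trapezoid on
an RK45 trajectory (the continuous-time value of a deployed schedule).
Suboptimality gaps compare like with like — both schedules evaluated with
the continuous-time pipeline.

**Multi-window courses** are optimized sequentially (receding horizon): the
RK45-simulated terminal state of one window initializes the next window's
solve, mirroring re-planning at cycle boundaries.

**Piecewise protocols.**  A solved schedule is compressed to
MTD / c₁ / c₂ / MTD with switching times (t₁, t₂, t₃) seeded from the
singular-arc boundaries, its midpoint, and the segment means of the optimal
control, then refined by Nelder-Mead on the continuous-time objective
(switching times alone in `levels="mean"` mode, all five parameters in the
default `levels="optimize"` mode).  The refined value never exceeds the
seed's.  Refined protocols sit within ≲ 0.01% of the numerical optimum and
within ±0.2 percentage points of its final resistant fraction; a slightly
negative gap is possible (within −0.5%) because the continuous-time
refinement can marginally beat the Euler-grid optimum under continuous
evaluation.

**Sensitivity study.**  (τ₁, τ₂) pairs are drawn log-uniformly over
[10⁻⁵, 0.05] per axis (results are read on the log-log plane; plain uniform
sampling is retained for comparison), 400 samples per scenario by default
with a recorded seed, across the four (β₁, β, v) scenarios.  Per-sample
solves reduce multistart to {0.5, 1} to bound runtime.  Failures are
recorded with status labels, never resampled.  Tests and the shipped
examples run this study at 50 samples per scenario, where the qualitative
contrasts (intermediate-dose dominance under high sensitivity; a
τ₁-driven full/intermediate split under low sensitivity) are already
stable.

## Two doubling-time conventions

Two operations are provided and they deliberately disagree.  The
closed-form convention T = ln 2 / (λ (ln N_sat − ln N_init)) treats the
denominator as the instantaneous per-capita Gompertz rate of a tumor of
size N_init saturating at N_sat; with λ₁ = 0.192, N_sat = 17 000,
N_init = 300 it gives ≈ 0.89 days (≈ 21.5 h).  The numeric convention
integrates the full untreated system from (280, 20, 650) and locates the
first time the total volume doubles to 600 mm³ by event detection; it gives
≈ 55.9 h, slower, because the initial vasculature (650 mm³) is far below
the level needed to sustain the closed-form rate and must first grow.
Neither convention is privileged; consumers should state which they use.

## Observed optimizer behavior worth knowing

From the large near-critical initial state (5900, 2000, 10000) mm³ the
multistarted solver finds first-window optima that *delay* treatment
(u ≈ 0 early, ramping later): the tumor sits near its carrying capacity,
where untreated growth is slow and the population stays
sensitive-majority, so early dosing buys little volume reduction but
accelerates the resistant takeover penalized by the objective.  Every
tried start converges to this branch; MTD-start schedules are not local
optima of the discretized problem there.  Consequently, in the 28-day
protocol comparison from that state the optimized schedule ends day 14
*below* the MTD protocol's day-14 volume, while the other hallmarks of the
comparison (near-total resistance under MTD by day 14, ≈ 18% larger MTD
tumor at day 28) hold.  From the small reference state (280, 20, 650) the
familiar MTD-opening bang–singular–bang structure is optimal.

## What the simulations do and do not show

All inputs are parameter configurations; there is no external data.  The
simulated conditions use the nominal parameters above, which were
calibrated in the literature to mouse xenograft growth; conclusions about
schedule *structure* (full–singular–full, intermediate average doses,
four-phase approximability) are robust across the sampled mutation-rate
and sensitivity ranges, but absolute times and volumes inherit the
uncertainty of the rate constants and say nothing about pharmacokinetics,
toxicity constraints, or inter-patient variability, none of which are
modeled.  Local optimality is the other caveat: the transcribed problem is
non-convex, and although multistart makes the reported solutions
reproducible and they beat all enumerable bang-bang competitors on coarse
grids, global optimality is not certified.

## Problem sizes used by the shipped tests

Unit and property tests use grids of 15–60 Euler intervals and brute-force
enumeration at M = 20; the end-to-end tests solve the full M = 400
problems, run the four-phase refinement, the 28-day comparison, and the
sensitivity study at 50 samples for the two v = 0.5 scenarios.  The whole
suite completes in about a minute with numba, a few minutes without.
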