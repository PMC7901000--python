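# Methods

## The inference problem

`pulsecal` calibrates a one-dimensional pulse-wave propagation model of
the pulmonary arterial circulation against a measured (here: synthetic)
pressure time series at the inlet of the main pulmonary artery.  Four
biophysical parameters are inferred,

    theta = (s, r1, r2, c),

where `s` (g/cm/s^2) is the vessel-wall stiffness, shared across the
network, and `r1`, `r2`, `c` are dimensionless adjustment factors that
scale every terminal's nominal 3-element Windkessel triple elementwise:
`R1j = (1 - 0.5 r1) R01j`, `R2j = (1 - 0.5 r2) R02j`,
`Cj = (1 - 0.5 c) C0j`.  The prior is uniform (rescaled Beta(1,1)) on the
physiologically plausible box `s in [7e4, 5e5]`, `r1 in [-0.5, 1.92]`,
`r2 in [-0.5, 1.0]`, `c in [-2.5, 1.5]`, treated as open.  The data model
is iid Gaussian noise on the n-point pressure series with conjugate
InvGamma(a, b) prior on the noise variance, `a = n_s/2`,
`b = n_s gamma_s2 / 2`, `n_s = 1`, `gamma_s2 = min RSS / (n - d)` over the
initial design; `sigma^2` is Gibbs-sampled in closed form.

Samplers operate on unbounded coordinates `z_i = logit((theta_i - l_i) /
(u_i - l_i))`; the log-Jacobian of this map is added to the log
posterior (so the uniform prior on the original scale is exact), and its
analytic derivatives to third order feed the curvature-based samplers.
Gaussian-process inputs use the order-one scaling `x_i = theta_i / s_i`
with `s_i = max(|l_i|, |u_i|)`.

## Forward model

Cross-sectionally averaged mass and momentum balance on each elastic
segment,

    A_t + q_x = 0
    q_t + (q^2/A)_x + (A/rho) p_x = -(2 pi nu r / delta) q/A,

closed by the tube law `p = p0 + (4/3) s (1 - sqrt(A0/A))`, with blood
density `rho = 1.055 g/ml`, viscosity `mu = 0.049 g/(cm s)` (the friction
uses the kinematic viscosity `nu = mu/rho`, as dimensional consistency
requires), and boundary-layer thickness `delta = sqrt(nu T / 2 pi)`.
Junctions enforce flow conservation and pressure continuity; each
terminal couples to a 3-element Windkessel through its impedance
`Z(w) = R1 + R2/(1 + i w C R2)`.

Numerics (all choices below are the package's own where the underlying
scheme family leaves them open):

* **Integrator** — two-step (Richtmyer) Lax-Wendroff on a per-segment
  uniform grid (default 6 nodes/cm, minimum 3 nodes).  The taper source
  is discretised from local `A0` differences so that it cancels the
  elastic flux difference identically at `A = A0` (well-balanced at
  rest: a quiescent tapered vessel stays exactly quiescent).
* **Time step** — uniform, sized for the wave speed at a reference
  stiffness `s_ref` (default: the upper prior bound) with CFL factor 0.9
  and a 30% headroom, *independently of the simulated stiffness*.  This
  keeps the discrete solution map continuous in `theta` (a
  `theta`-dependent `ceil(T/dt)` makes the residual surface jump between
  step counts, which no smooth emulator can fit) at the cost of low-`s`
  solves running below their own stability limit.  A runtime CFL check
  remains; violation marks the run invalid.
* **Boundary closures** — conservative half-cell mass balances rather
  than characteristic extrapolation: the inlet area follows from the
  prescribed inflow and the first interface flux; the outlet solves a
  scalar Newton iteration coupling the half-cell balance to the
  Windkessel flow; junctions solve a 3x3 Newton system (tolerance 1e-10,
  30 iterations, with a 1e-8 stall fallback) in the three boundary
  areas.  These closures conserve mass exactly for arbitrary taper; with
  characteristic closures the steady outlet flow was biased by ~3% on
  tapered mouse-scale segments.
* **Windkessel coupling** — the outlet flow is the one-period discrete
  convolution of the trailing pressure history with the impulse response
  of the admittance `1/Z` sampled at the cardiac harmonics (the
  periodicity assumption).  The instantaneous term is solved implicitly
  inside the boundary Newton, which is what makes the coupling stable: a
  cycle-lagged update is a fixed-point iteration with per-cycle gain
  `(dp/dV) T / R >> 1` for stiff mouse-scale vessels and diverges within
  two cycles.  The first cycle is bootstrapped with the constant outlet
  pressure consistent with the mean inflow through the total parallel
  terminal resistance.
* **Burn-in to periodicity** — 5 cycles before the recorded cycle
  (default); the max-norm pressure change between consecutive cycles is
  recorded (`cycle_deltas`) and decays geometrically, typically below
  0.1 mmHg by cycle 5.
* **Failure semantics** — negative area, NaN, CFL violation,
  non-convergent Newton solves and non-positive scaled Windkessel
  elements set `valid=False` (the feasibility label), never raise.

Units are CGS internally; pressures cross the API in mmHg
(1 mmHg = 1333.22 dyn/cm^2), Windkessel elements in mmHg s/ml and
ml/mmHg.

## Surrogates

**RSS emulator.** A zero-mean GP with squared-exponential ARD kernel is
fitted to the residual sum of squares `S(theta)` at scaled inputs;
targets are z-scored internally.  Hyperparameters maximise the evidence
by multi-restart L-BFGS in log space, with the signal variance capped at
100 (z-scored targets) and lengthscales capped at three data spans —
beyond that they are unidentifiable and the kernel matrix drifts onto a
numerically degenerate flat ridge.  A jitter ladder (0, 1e-10, 1e-8,
1e-6) guards the Cholesky.  Predictive mean derivatives to third order
and the predictive-variance gradient are computed analytically from the
SE cross-covariance and chained through the diagonal `z -> theta -> x`
maps.

**Feasibility classifier.** A GP probit classifier with Matern-3/2 ARD
kernel, fitted by expectation propagation (site updates with exact
rank-1 posterior refreshes; convergence 1e-6 or 100 sweeps; evidence by
the EP approximation, optimised by Nelder-Mead).  Its predicted success
probability multiplies the prior ("modified prior"); the normaliser
cancels in MH ratios, and the probability is floored at 1e-12 inside the
log.  The Matern-3/2 kernel is once differentiable: the classifier
contributes to potential values and gradients analytically but is
excluded from the curvature metric of the manifold samplers.  A
single-class design (no failures observed — the case for the bundled toy
networks, which turn out to be feasible over the whole prior box)
degenerates gracefully to a base-rate model with zero gradient.

## The three-phase delayed-acceptance workflow

1. **Initial design** — a scrambled Sobol design over the prior box
   (default 600 points; 150 at desk scale) is simulated; successful runs
   train the emulator, all runs train the classifier.
2. **Exploratory phase** — HMC on the uncertainty-seeking potential
   `(mean - sd)/(2 sigma^2) + (n/2) log(2 pi sigma^2) - log p~`, with
   `sigma^2` fixed at `gamma_s2`.  Trajectories stop early when the
   predictive sd on the z-scored target scale exceeds 3.  Every
   trajectory end point passes the two-stage decision: stage 1 on
   emulated Hamiltonians (no solve), stage 2 on the simulator (one
   solve).  Every solve adds a classifier row; every *successful* solve
   also joins the emulator training set (active learning — MH-acceptance-
   gated admission deadlocks at reduced design sizes because a surrogate
   that is never trained never earns acceptances).  Each admission prunes
   at most one initial-design point whose RSS exceeds the 10th-percentile
   threshold of the design (oldest first); hyperparameters are refitted
   (warm-started plus one fresh restart) every third admission, and the
   classifier is refitted on every design change with hyperparameter
   re-optimisation every 25th.  A final sweep removes all remaining
   over-threshold design points and caps the training set at the
   emulator budget (400 full scale / 250 desk scale) by dropping the
   worst-RSS points; the frozen emulator is then refitted from scratch.
3. **Sampling phase** — the frozen surrogates drive one of AHMC, NUTS,
   ARMHMC or ALDMC on the potential `mean/(2 sigma^2) + (n/2) log(2 pi
   sigma^2) - log p~`; each iteration ends with the same two-stage
   decision, hence at most one solve per iteration and exactness with
   respect to the simulator posterior.  `sigma^2` stays fixed during
   burn-in and is Gibbs-updated each kept iteration.  Ten chains run
   from dispersed starts (drawn without replacement from the later half
   of the exploratory acceptances) with distinct seeds.

The stage-2 ratio `exp(-E* + E + E~* - E~)` uses the base prior inside
`E` and the classifier-modified prior inside `E~`, so the classifier's
bias on feasible ground is corrected exactly.

## Samplers

* **HMC/AHMC** — explicit leapfrog, identity mass.
* **RMHMC** — generalised leapfrog (implicit half steps by fixed-point
  iteration, tolerance 1e-8, 50 iterations; non-convergence rejects)
  with metric `M(z)` built from the Hessian of the emulated potential by
  absolute-value eigenvalue clamping (|lambda|, floored at 1e-6 of the
  spectral radius — concave regions get a large metric and short steps,
  rather than a near-singular one whose inverse explodes) and derivative
  tensor from the analytic third derivatives.
* **ALDMC** — the explicit Lagrangian integrator in velocity variables;
  volume is not preserved, so the acceptance carries the product of the
  per-step determinant ratios `det(I - eps/2 Omega(v_out)) / det(I +
  eps/2 Omega(v_in))`, which the test suite validates against a
  numerically differentiated one-step map.
* **NUTS** — multinomial no-U-turn with tree-depth cap 10 and
  dual-averaging step-size adaptation during burn-in (target acceptance
  0.8).  Within delayed acceptance, the NUTS-selected point (already
  invariant for the emulated target) is treated as the stage-1-accepted
  proposal and only the stage-2 correction is applied; iterations where
  the selected point equals the current one skip the solve.
* **Adaptive Metropolis** — the long-run exact-posterior reference
  (proposal covariance `2.38^2/d` times the regularised chain
  covariance).

**Tuning.** AHMC/ARMHMC/ALDMC tune `(eps, L)` by Bayesian optimisation:
20 space-filling probes (10 pilot samples each) on the emulated
posterior build a GP over (log eps, L); expected improvement explores
during burn-in and the best evaluated probe under the smoothed surrogate
mean is exploited from the end of burn-in on, with further
schedule-gated adaptations (`p_t = min(1, t^-0.6)`; a strict mode
disables post-burn-in adaptation).  The objective is the expected
squared jumping distance **per iteration**: the classical per-leapfrog
normalisation prices every step as a simulator solve, which is the wrong
cost model under delayed acceptance (trajectories are emulator-only and
an iteration costs at most one solve) and empirically collapses the
tuner onto single-step random walks that cannot traverse the widest
posterior direction.  The per-step-normalised estimator remains
available as `esjd_normalised`.  Default tuning boxes are sized for the
logit-space geometry of the box prior: `eps in [5e-3, 0.25]`,
`L <= 50` (HMC) and `eps in [2e-2, 0.8]`, `L <= 40` (manifold);
literature boxes are kept as named constants and everything is
overridable.

## Synthetic study conditions

The measured mouse data this methodology targets are not
redistributable, so the package generates its own: mouse-scale toy trees
(`single`, `bifurcation3`, `tree7`; segment lengths 0.2-1 cm, radii
0.01-0.05 cm), a half-sine systolic inflow with cardiac cycle
`T = 0.11 s` and stroke volume 0.022 ml (cardiac output ~0.2 ml/s),
nominal Windkessels allocated from a total peripheral resistance of
75 mmHg s/ml and compliance 3e-3 ml/mmHg by an area-proportional
parallel split (a fixture convention standing in for morphometry-derived
boundary estimates).  These place the simulated inlet pressure at
~7-28 mmHg — the physiological range for a healthy mouse.  One data set
is `y_i = m_i(theta_true) + N(0, 0.25)` (noise sd 0.5 mmHg, catheter-
grade) at `theta_true = (2e5, 0.4, 0.3, -0.5)` with n = 128 points.

What this emulates and what it does not: the synthetic data share the
generating forward model, so there is no model discrepancy, no
correlated measurement error, and — on these small feasible-everywhere
networks — no genuine simulator crash region (the classifier is
exercised instead through a wrapper that forces failure on a prescribed
region).  Passing tests therefore demonstrate the correctness and
internal efficiency of the inference machinery, not robustness to the
mis-specification real measurements carry.

A closed-form "0D" pressure-shape model (`surrogate0d_model`) with
microsecond likelihoods supports the exactness study, where pooled
delayed-acceptance draws are compared with a 150,000-draw Adaptive
Metropolis reference on the analytically sigma^2-marginalised posterior.

## Problem sizes used

Desk-scale end-to-end runs (the acceptance workflow and the test suite)
use 150 design points, 300 exploratory iterations, a 250-point emulator
budget and 10 chains of 500 burn-in + 500 kept draws on `bifurcation3`
with the default solver grid; the full-scale defaults (600 / 1000 / 400
/ 10 x (500 + 5000)) are the package defaults on `PhaseConfig`.  Burn-in
is kept at 500 even at desk scale — it is what carries the multivariate
R-hat below 1.1.

## Known limitations

* The junction closure is first-order accurate; global convergence of
  the pressure series is second order in the interior but boundary-
  limited (observed refinement ratios ~2-3 rather than 4).
* EP classification is an approximation; against brute-force latent
  quadrature at tiny n its class probabilities agree to a few parts in
  a thousand.
* The RMHMC metric uses the clamped Hessian but the unclamped third-
  derivative tensor; where clamping is active the integrator is slightly
  inconsistent with its own metric, which costs acceptance rate but not
  correctness (stage 2 corrects against the simulator regardless).
* Wall-clock efficiency comparisons across samplers are reported but
  never asserted (hardware-dependent).
* Single network-wide stiffness, iid errors and no model-discrepancy
  term: per-vessel stiffness hierarchies and correlated-error models are
  out of scope.
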