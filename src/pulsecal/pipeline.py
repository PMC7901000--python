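"""Three-phase delayed-acceptance GP-HMC calibration workflow.

Phase 1 (initial design): simulate the forward model at a Sobol design
over the prior box; successful runs train the RSS emulator, all runs
train the feasibility classifier.

Phase 2 (exploratory): HMC on the uncertainty-seeking emulated potential;
every trajectory end point passes a two-stage delayed-acceptance (DA)
Metropolis-Hastings decision — stage 1 on the emulator (cheap), stage 2
on the simulator (one PDE solve, only if stage 1 accepts).  On stage-2
acceptance the new point joins the training sets, one over-threshold
initial-design point is pruned, and both GP models are re-fitted.
Trajectories stop early when the predictive uncertainty exceeds a
threshold (the surrogate needs training there).

Phase 3 (sampling): the frozen emulator/classifier drive one of four
samplers (AHMC, NUTS, ARMHMC, ALDMC); each iteration ends with the same
two-stage DA decision, so at most one PDE solve per kept sample, and the
chain still targets the exact simulator posterior.  The noise variance
is fixed during burn-in and Gibbs-sampled afterwards.

A ledger counts every simulator call by phase; the economy of the scheme
is that conventional HMC with finite-difference gradients would need
L(d+1) solves per sample against (at most) one here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .classifier import FeasibilityClassifier, LabeledDesign
from .gp import RssEmulator, TrainingSet, potential_exploratory, potential_sampling
from .posterior import NoisePriorSpec, ParameterBox, gamma_s2_init, gibbs_sigma2
from .samplers import (
    DualAveraging,
    Potential,
    TrajectoryConfig,
    hmc_propose,
    ldmc_propose,
    nuts_step,
    rmhmc_propose,
)
from .tuning import (
    TuningHistory,
    TuningRange,
    adaptation_schedule,
    bo_initialise,
    bo_propose,
    esjd_normalised,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseConfig",
    "RunLedger",
    "CalibrationProblem",
    "ChainResult",
    "InferenceResult",
    "EmulatedPotential",
    "initial_design",
    "da_stage1",
    "da_stage2",
    "exploratory_phase",
    "sampling_phase",
    "run_inference",
    "make_pde_problem",
    "make_surrogate0d_problem",
    "conventional_pde_per_sample",
]


# ---------------------------------------------------------------------------
# configuration, ledger, problem
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseConfig:
    """Workflow sizes and thresholds.

    Defaults are the full-scale study conditions (600-point design, 1000
    exploratory iterations, 500 burn-in + 5000 kept draws, 400-point
    emulator, 10 chains); :meth:`reduced` gives the desk-scale variant
    used for fast end-to-end runs.
    """

    n_design: int = 600
    n_explore: int = 1000
    n_burn: int = 500
    n_sample: int = 5000
    sd_stop_threshold: float = 3.0
    prune_percentile: float = 10.0
    emulator_budget: int = 400
    n_chains: int = 10
    explore_epsilon: float = 2e-2
    explore_L: int = 20
    gp_refit_restarts: int = 2
    gp_refit_interval: int = 3
    classifier_reopt_interval: int = 25
    adapt_interval: int = 25
    strict_exactness: bool = False
    bo_n_configs: int = 20
    bo_n_samples_per_config: int = 10
    use_sd_in_exploratory: bool = True
    # burn-in is chosen to ensure cross-chain convergence: if the kept
    # draws miss mpsrf_target, every chain continues from its end state
    # (the continuation is further burn-in) and the last n_sample draws
    # are kept, at most max_continuations times
    mpsrf_target: float = 1.1
    max_continuations: int = 1
    # (eps, L) tuning boxes sized for the logit-space geometry of the
    # box-constrained parameters; the literature HMC_TUNING_RANGE /
    # MANIFOLD_TUNING_RANGE constants remain available as overrides
    tuning_range_hmc: "TuningRange" = None
    tuning_range_manifold: "TuningRange" = None

    def __post_init__(self):
        if min(self.n_design, self.n_explore, self.n_burn, self.n_sample, self.n_chains) < 1:
            raise ValueError("phase sizes must be positive")
        if not 0 < self.prune_percentile < 100:
            raise ValueError("prune_percentile must lie in (0, 100)")
        if self.tuning_range_hmc is None:
            object.__setattr__(self, "tuning_range_hmc", TuningRange(50, 5e-3, 0.25))
        if self.tuning_range_manifold is None:
            object.__setattr__(self, "tuning_range_manifold", TuningRange(40, 2e-2, 0.8))

    @classmethod
    def reduced(cls, **overrides) -> "PhaseConfig":
        base = dict(
            n_design=150, n_explore=300, n_burn=500, n_sample=500,
            emulator_budget=250, n_chains=10, bo_n_configs=12,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class RunLedger:
    """Simulator-call accounting with phase tags and DA counters."""

    pde_by_phase: dict = field(default_factory=lambda: {"design": 0, "exploratory": 0, "sampling": 0})
    stage1_proposals: int = 0
    stage1_accepts: int = 0
    stage2_decisions: int = 0
    stage2_accepts: int = 0
    early_stops: int = 0
    null_proposals: int = 0  # trajectory returned the current point (NUTS)

    def count_pde(self, phase: str, n: int = 1):
        self.pde_by_phase[phase] = self.pde_by_phase.get(phase, 0) + n

    @property
    def pde_total(self) -> int:
        return sum(self.pde_by_phase.values())

    @property
    def stage1_rate(self) -> float:
        return self.stage1_accepts / max(self.stage1_proposals, 1)

    @property
    def stage2_rate(self) -> float:
        return self.stage2_accepts / max(self.stage2_decisions, 1)

    def merge(self, other: "RunLedger") -> "RunLedger":
        out = RunLedger()
        for k in set(self.pde_by_phase) | set(other.pde_by_phase):
            out.pde_by_phase[k] = self.pde_by_phase.get(k, 0) + other.pde_by_phase.get(k, 0)
        for f in ("stage1_proposals", "stage1_accepts", "stage2_decisions",
                  "stage2_accepts", "early_stops", "null_proposals"):
            setattr(out, f, getattr(self, f) + getattr(other, f))
        return out

    def check_invariants(self):
        assert self.stage2_accepts <= self.stage2_decisions <= self.stage1_accepts
        assert self.stage1_accepts <= self.stage1_proposals


def conventional_pde_per_sample(L: int = 100, d: int = 4) -> int:
    """Simulator solves one HMC sample costs WITHOUT emulation: L steps,
    each needing the log likelihood (1 solve) and its d finite-difference
    gradient components (d solves)."""
    return L * (d + 1)


@dataclass
class CalibrationProblem:
    """A calibration target: data vector, box prior and a simulator.

    ``simulate(theta) -> (rss, label)`` returns the residual sum of
    squares against ``y`` (inf when invalid) and the success label.
    """

    box: ParameterBox
    y: np.ndarray
    simulate: callable
    name: str = ""

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def d(self) -> int:
        return self.box.dim


def make_pde_problem(dataset: dict) -> CalibrationProblem:
    """Wrap a synthetic (or measured) pressure dataset and the 1D solver."""
    from .hemodynamics import mpa_pressure, solve_network
    from .posterior import rss as _rss

    y = np.asarray(dataset["data"], float)
    network = dataset["network"]
    inflow = dataset["inflow"]
    const = dataset["const"]
    grid = dataset["grid"]

    def simulate(theta):
        sol = solve_network(network, inflow, theta, const, grid)
        if not sol.valid:
            return np.inf, 0
        m = mpa_pressure(sol, len(y))
        return _rss(y, m), 1

    return CalibrationProblem(ParameterBox.default(), y, simulate, name="pde")


def make_surrogate0d_problem(
    theta_true=(2.0e5, 0.4, 0.3, -0.5),
    sigma2_true: float = 0.25,
    n_points: int = 64,
    seed: int = 0,
    forbidden_predicate=None,
) -> tuple[CalibrationProblem, dict]:
    """Closed-form 0D pressure-shape problem for fast exactness studies."""
    from .posterior import rss as _rss
    from .synthetic import failure_region_wrapper, surrogate0d_model

    box = ParameterBox.default()
    clean = surrogate0d_model(theta_true, n_points, box)
    rng = np.random.default_rng(seed)
    y = clean + rng.normal(0.0, np.sqrt(sigma2_true), n_points)

    def simulate(theta):
        if not box.contains(theta):
            return np.inf, 0
        return _rss(y, surrogate0d_model(theta, n_points, box)), 1

    if forbidden_predicate is not None:
        simulate = failure_region_wrapper(simulate, forbidden_predicate)
    truth = {"theta_true": np.asarray(theta_true, float), "sigma2_true": sigma2_true,
             "clean": clean, "data": y}
    return CalibrationProblem(box, y, simulate, name="surrogate0d"), truth


# ---------------------------------------------------------------------------
# emulated potential in unbounded coordinates
# ---------------------------------------------------------------------------


class EmulatedPotential:
    """Potential bundle over z (unbounded coords) built from the GP models.

    E(z) = (mean [- sd])/(2 sigma^2) + (n/2) log(2 pi sigma^2)
           - [log p(theta) + log p(lambda=1|x) + log|J(z)|]

    The GP operates on x = theta(z)/s; derivatives chain through the
    diagonal maps z -> theta -> x.  The classifier term enters the value
    and gradient but is excluded from the Hessian/third-order output used
    for the manifold metric (its Matern-3/2 kernel is only once
    differentiable).
    """

    def __init__(self, emulator, classifier, box, sigma2, n, mode="sampling", use_sd=True):
        if mode not in ("sampling", "exploratory"):
            raise ValueError("mode must be 'sampling' or 'exploratory'")
        self.emulator = emulator
        self.classifier = classifier
        self.box = box
        self.sigma2 = float(sigma2)
        self.n = int(n)
        self.mode = mode
        self.use_sd = use_sd
        self._base_lp = -float(np.sum(np.log(box.upper - box.lower)))
        self._cache_key = None
        self._cache = {}

    # -- plumbing ----------------------------------------------------------

    def _at(self, z):
        z = np.asarray(z, float)
        key = z.tobytes()
        if key != self._cache_key:
            theta = self.box.from_unbounded(z)
            x = self.box.to_scaled(theta)
            d1, d2, d3 = self.box.dtheta_dz(z)
            s = self.box.scales
            self._cache = {
                "z": z, "theta": theta, "x": x,
                "x1": d1 / s, "x2": d2 / s, "x3": d3 / s,
            }
            self._cache_key = key
        return self._cache

    def _pred(self, c, order):
        have = c.get("pred_order", -1)
        if have < order:
            if order == 0:
                c["pred"] = self.emulator.predict(c["x"])
            else:
                c["pred"] = self.emulator.predict_derivatives(c["x"], order=order)
            c["pred_order"] = order
        return c["pred"]

    def _clf(self, c):
        if "clf" not in c:
            c["clf"] = self.classifier.log_prob_and_grad(c["x"])
        return c["clf"]

    # -- bundle interface --------------------------------------------------

    def mod_log_prior(self, z) -> float:
        c = self._at(z)
        lp_clf, _ = self._clf(c)
        return self._base_lp + lp_clf + self.box.log_jacobian(z)

    def value(self, z) -> float:
        c = self._at(z)
        pred = self._pred(c, 0)
        mlp = self.mod_log_prior(z)
        if self.mode == "exploratory":
            return potential_exploratory(pred, self.sigma2, self.n, mlp, self.use_sd)
        return potential_sampling(pred, self.sigma2, self.n, mlp)

    def grad(self, z) -> np.ndarray:
        c = self._at(z)
        pred = self._pred(c, 1)
        g_mean_x = pred.gradient
        g = g_mean_x * c["x1"]
        if self.mode == "exploratory":
            if self.use_sd:
                sd = max(pred.sd, 1e-12)
                g_sd_x = pred.variance_gradient / (2.0 * sd)
            else:
                g_sd_x = pred.variance_gradient
            g = g - g_sd_x * c["x1"]
        g = g / (2.0 * self.sigma2)
        _, g_clf_x = self._clf(c)
        _, gj, _, _ = self.box.log_jacobian_derivatives(z)
        return g - g_clf_x * c["x1"] - gj

    def hess(self, z) -> np.ndarray:
        c = self._at(z)
        pred = self._pred(c, 2)
        x1, x2 = c["x1"], c["x2"]
        H = pred.hessian * np.outer(x1, x1) + np.diag(pred.gradient * x2)
        H = H / (2.0 * self.sigma2)
        _, _, hj, _ = self.box.log_jacobian_derivatives(z)
        return H - np.diag(hj)

    def third(self, z) -> np.ndarray:
        c = self._at(z)
        pred = self._pred(c, 3)
        x1, x2, x3 = c["x1"], c["x2"], c["x3"]
        d = len(x1)
        T = pred.third * (x1[:, None, None] * x1[None, :, None] * x1[None, None, :])
        Hx = pred.hessian
        gx = pred.gradient
        for i in range(d):
            for j in range(d):
                T[i, j, j] += Hx[i, j] * x1[i] * x2[j]
                T[i, j, i] += Hx[i, j] * x2[i] * x1[j]
                T[i, i, j] += Hx[i, j] * x1[j] * x2[i]
        for i in range(d):
            T[i, i, i] += gx[i] * x3[i]
        T = T / (2.0 * self.sigma2)
        _, _, _, tj = self.box.log_jacobian_derivatives(z)
        for i in range(d):
            T[i, i, i] -= tj[i]
        return T

    def as_bundle(self) -> Potential:
        return Potential(value=self.value, grad=self.grad, hess=self.hess, third=self.third)

    def sd_standardised(self, z) -> float:
        """Predictive sd on the z-scored target scale (early-stop statistic)."""
        c = self._at(z)
        pred = self._pred(c, 0)
        y_sd = self.emulator._cache["y_sd"]
        return pred.sd / y_sd

    def true_potential(self, z, rss_value) -> float:
        """Simulator-based potential with the (unmodified) box prior."""
        if not np.isfinite(rss_value):
            return np.inf
        return (
            rss_value / (2.0 * self.sigma2)
            + 0.5 * self.n * np.log(2.0 * np.pi * self.sigma2)
            - (self._base_lp + self.box.log_jacobian(z))
        )


# ---------------------------------------------------------------------------
# DA decisions
# ---------------------------------------------------------------------------


def da_stage1(H_current: float, H_proposed: float, rng, extra_log_ratio: float = 0.0) -> bool:
    """Emulator-based pre-filter: accept w.p. min(1, exp(-dH + extra))."""
    if not np.isfinite(H_proposed):
        return False
    return bool(np.log(rng.uniform()) < H_current - H_proposed + extra_log_ratio)


def da_stage2(E_true_curr, E_true_prop, E_emul_curr, E_emul_prop, rng) -> bool:
    """Simulator-based correction: accept w.p.
    min(1, exp(-E* + E + E~* - E~)); kinetic terms cancel."""
    if not np.isfinite(E_true_prop):
        return False
    log_ratio = -E_true_prop + E_true_curr + E_emul_prop - E_emul_curr
    return bool(np.log(rng.uniform()) < log_ratio)


# ---------------------------------------------------------------------------
# phase 1: initial design
# ---------------------------------------------------------------------------


def initial_design(problem: CalibrationProblem, n_design: int, rng, ledger: RunLedger | None = None):
    """Sobol design over the box, simulated at every point.

    Returns (TrainingSet for the emulator: successes only; LabeledDesign
    for the classifier: all points; rss array aligned with the design).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    box = problem.box
    sob = qmc.Sobol(d=box.dim, scramble=True, rng=rng)
    n_pow2 = int(2 ** np.ceil(np.log2(n_design)))
    U = sob.random(n_pow2)[:n_design]
    # keep strictly interior for the logit transform
    U = np.clip(U, 1e-9, 1 - 1e-9)
    thetas = box.lower + U * (box.upper - box.lower)
    X, targets, prov = [], [], []
    labels = np.empty(n_design, int)
    rss_all = np.empty(n_design)
    for i, th in enumerate(thetas):
        r, lam = problem.simulate(th)
        if ledger is not None:
            ledger.count_pde("design")
        labels[i] = lam
        rss_all[i] = r
        if lam == 1 and np.isfinite(r):
            X.append(box.to_scaled(th))
            targets.append(r)
            prov.append("design")
    if not X:
        raise RuntimeError("no successful simulations in the initial design")
    train = TrainingSet(np.array(X), np.array(targets), tuple(prov))
    design = LabeledDesign(np.array([box.to_scaled(t) for t in thetas]), labels)
    return train, design, thetas, rss_all


# ---------------------------------------------------------------------------
# phase 2: exploratory refinement
# ---------------------------------------------------------------------------


@dataclass
class ExploratoryResult:
    emulator: RssEmulator
    classifier: FeasibilityClassifier
    sigma2: float
    noise_prior: NoisePriorSpec
    accepted_z: list
    rss_at_accepted: list
    prune_threshold: float
    ledger: RunLedger
    z_final: np.ndarray
    rss_final: float


def exploratory_phase(
    problem: CalibrationProblem,
    config: PhaseConfig,
    rng,
    ledger: RunLedger | None = None,
) -> ExploratoryResult:
    """Initial design + uncertainty-seeking HMC refinement (Algorithm phase 2)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ledger = ledger if ledger is not None else RunLedger()
    box = problem.box

    train, design, thetas, rss_all = initial_design(problem, config.n_design, rng, ledger)
    finite = rss_all[np.isfinite(rss_all)]
    T_prune = float(np.percentile(finite, config.prune_percentile))
    gamma_s2 = gamma_s2_init(rss_all, problem.n, problem.d)
    noise_prior = NoisePriorSpec(gamma_s2)
    sigma2 = gamma_s2 if gamma_s2 > 0 else 1.0

    emulator = RssEmulator(train)
    emulator.fit_hyperparameters(rng=rng, n_restarts=3)
    classifier = FeasibilityClassifier(design)
    classifier.fit(optimise=True, rng=rng, n_restarts=1, maxiter=20)

    # start from the best design point
    i_best = int(np.nanargmin(np.where(np.isfinite(rss_all), rss_all, np.nan)))
    z = box.to_unbounded(thetas[i_best])
    rss_curr = float(rss_all[i_best])

    # the stable step size depends on the curvature of the *initial*
    # emulated surface, which varies across data sets: adapt epsilon by
    # dual averaging on the stage-1 acceptance statistic (the whole
    # exploratory phase is burn-in, so adaptation is safe)
    eps = config.explore_epsilon
    dual = DualAveraging(eps, target=0.7)
    accepted_z: list[np.ndarray] = []
    rss_at_accepted: list[float] = []
    n_updates = 0
    n_added = 0

    for it in range(config.n_explore):
        cfg = TrajectoryConfig(eps, config.explore_L)
        pot = EmulatedPotential(emulator, classifier, box, sigma2, problem.n,
                                mode="exploratory", use_sd=config.use_sd_in_exploratory)
        stop_fn = (lambda zz: pot.sd_standardised(zz) > config.sd_stop_threshold)
        prop = hmc_propose(z, cfg, pot.as_bundle(), rng, stop_fn=stop_fn)
        ledger.stage1_proposals += 1
        if prop.get("steps", cfg.L) < cfg.L:
            ledger.early_stops += 1
        accept_stat = 0.0
        if prop["ok"] and np.isfinite(prop["H1"]):
            accept_stat = float(np.exp(min(prop["H0"] - prop["H1"], 0.0)))
        eps = dual.update(accept_stat)
        if not prop["ok"]:
            continue
        if not da_stage1(prop["H0"], prop["H1"], rng):
            continue
        ledger.stage1_accepts += 1
        z_star = prop["z"]
        theta_star = box.from_unbounded(z_star)
        # emulated potentials for the stage-2 ratio, evaluated with the
        # current (pre-update) surrogate
        e_emul_curr = pot.value(z)
        e_emul_star = pot.value(z_star)
        rss_star, lam_star = problem.simulate(theta_star)
        ledger.count_pde("exploratory")
        # every simulator call adds a classifier row
        classifier.design = classifier.design.add(box.to_scaled(theta_star), lam_star)
        n_updates += 1
        classifier.fit(
            optimise=(n_updates % config.classifier_reopt_interval == 0),
            rng=rng, n_restarts=1, maxiter=15,
        )
        ledger.stage2_decisions += 1
        E_curr = pot.true_potential(z, rss_curr)
        E_star = pot.true_potential(z_star, rss_star)
        if da_stage2(E_curr, E_star, e_emul_curr, e_emul_star, rng):
            ledger.stage2_accepts += 1
            z = z_star
            rss_curr = float(rss_star)
            accepted_z.append(z.copy())
            rss_at_accepted.append(rss_curr)
        # active learning: every successful simulation trains the RSS
        # surrogate (the stage-1 filter already focuses these on relevant
        # regions; uncertainty-triggered early stops land here too)
        if lam_star == 1 and np.isfinite(rss_star):
            x_star = box.to_scaled(theta_star)
            if not emulator.train._is_duplicate(x_star):
                emulator.add_point(x_star, float(rss_star))
                _prune_one(emulator, T_prune)
                n_added += 1
                if n_added % config.gp_refit_interval == 0:
                    try:
                        emulator.fit_hyperparameters(
                            rng=rng, n_restarts=config.gp_refit_restarts,
                            warm_start=True, maxiter=50,
                        )
                    except np.linalg.LinAlgError:
                        logger.warning("emulator refit failed; keeping previous hyperparameters")

    # final sweep: drop remaining over-threshold design points, then cap;
    # refit from scratch (multi-restart) — the frozen sampling-phase
    # emulator must not inherit a degenerate warm-start optimum
    _prune_all(emulator, T_prune)
    _cap_to_budget(emulator, config.emulator_budget)
    emulator.fit_hyperparameters(rng=rng, n_restarts=4, warm_start=False)
    classifier.fit(optimise=True, rng=rng, n_restarts=1, maxiter=20)
    return ExploratoryResult(
        emulator, classifier, sigma2, noise_prior, accepted_z, rss_at_accepted,
        T_prune, ledger, z, rss_curr,
    )


def _prune_one(emulator: RssEmulator, threshold: float):
    """Remove the oldest over-threshold design point (at most one)."""
    tr = emulator.train
    for i, (p, t) in enumerate(zip(tr.provenance, tr.targets)):
        if p == "design" and t > threshold:
            emulator.remove_point(i)
            return True
    return False


def _prune_all(emulator: RssEmulator, threshold: float):
    while len(emulator.train) > 2 and _prune_one(emulator, threshold):
        pass


def _cap_to_budget(emulator: RssEmulator, budget: int):
    """Drop the worst-RSS points until the training set fits the budget."""
    while len(emulator.train) > budget:
        emulator.remove_point(int(np.argmax(emulator.train.targets)))


# ---------------------------------------------------------------------------
# phase 3: sampling
# ---------------------------------------------------------------------------


@dataclass
class ChainResult:
    """Posterior draws of (theta, sigma^2) with phase metadata."""

    draws: np.ndarray  # (n_sample, d) on the original parameter scale
    sigma2: np.ndarray  # (n_sample,)
    z_draws: np.ndarray
    ledger: RunLedger
    seed: int
    sampler: str
    epsilon: float
    L: int
    accept_stage1: float
    accept_stage2: float


SAMPLERS = ("ahmc", "nuts", "armhmc", "aldmc")


def _pilot_fn_factory(potential: Potential, z0, manifold: bool, sampler: str):
    def pilot(eps, L, n_samples, rng):
        cfg = TrajectoryConfig(eps, L)
        z = np.array(z0, float)
        seg = [z.copy()]
        for _ in range(n_samples):
            if sampler == "armhmc":
                prop = rmhmc_propose(z, cfg, potential, rng)
            elif sampler == "aldmc":
                prop = ldmc_propose(z, cfg, potential, rng)
            else:
                prop = hmc_propose(z, cfg, potential, rng)
            if prop["ok"] and da_stage1(prop["H0"], prop["H1"], rng,
                                        prop.get("log_jac", 0.0)):
                z = prop["z"]
            seg.append(z.copy())
        return np.array(seg)

    return pilot


def sampling_phase(
    problem: CalibrationProblem,
    explo: ExploratoryResult,
    config: PhaseConfig,
    z0: np.ndarray,
    seed: int,
    sampler: str = "ahmc",
    tuning_history: TuningHistory | None = None,
) -> ChainResult:
    """Run one DA chain with a frozen emulator and classifier."""
    if sampler not in SAMPLERS:
        raise ValueError(f"sampler must be one of {SAMPLERS}")
    rng = np.random.default_rng(seed)
    box = problem.box
    ledger = RunLedger()
    sigma2 = explo.sigma2
    n = problem.n

    def make_pot(s2):
        return EmulatedPotential(explo.emulator, explo.classifier, box, s2, n, mode="sampling")

    pot = make_pot(sigma2)
    bundle = pot.as_bundle()
    manifold = sampler in ("armhmc", "aldmc")

    # --- tuning / pre-processing
    trange = config.tuning_range_manifold if manifold else config.tuning_range_hmc
    dual: DualAveraging | None = None
    if sampler == "nuts":
        eps = 0.5 * (trange.eps_lo + trange.eps_hi)
        L = 0
        dual = DualAveraging(eps)
    else:
        if tuning_history is None:
            pilot = _pilot_fn_factory(bundle, z0, manifold, sampler)
            tuning_history = bo_initialise(
                trange, pilot, rng, config.bo_n_configs,
                config.bo_n_samples_per_config, normalise_by_L=False,
            )
        eps, L = bo_propose(tuning_history, rng, mode="mean")

    z = np.array(z0, float)
    rss_curr, lam0 = problem.simulate(box.from_unbounded(z))
    ledger.count_pde("sampling")
    if lam0 != 1:
        raise ValueError("chain start point is infeasible")

    n_total = config.n_burn + config.n_sample
    draws = np.empty((config.n_sample, box.dim))
    s2_draws = np.empty(config.n_sample)
    z_draws = np.empty((config.n_sample, box.dim))
    seg_start = 0
    z_hist = [z.copy()]
    n_adapt = 0

    for it in range(n_total):
        in_burn = it < config.n_burn
        cfg = TrajectoryConfig(eps, max(L, 1))
        if sampler == "nuts":
            # the NUTS-selected point (already invariant for the emulated
            # target) is treated as the stage-1-accepted proposal
            z_star, info = nuts_step(z, eps, bundle, rng)
            if dual is not None and in_burn:
                eps = dual.update(info["accept_stat"])
            elif dual is not None and it == config.n_burn:
                eps = dual.adapted_epsilon
            moved = not np.array_equal(z_star, z)
            if moved:
                ledger.stage1_proposals += 1
                ledger.stage1_accepts += 1
                stage1_ok = True
            else:
                ledger.null_proposals += 1
                stage1_ok = False  # no distinct proposal: nothing to correct
        else:
            if sampler == "armhmc":
                prop = rmhmc_propose(z, cfg, bundle, rng)
            elif sampler == "aldmc":
                prop = ldmc_propose(z, cfg, bundle, rng)
            else:
                prop = hmc_propose(z, cfg, bundle, rng)
            ledger.stage1_proposals += 1
            stage1_ok = prop["ok"] and da_stage1(
                prop["H0"], prop["H1"], rng, prop.get("log_jac", 0.0)
            )
            z_star = prop["z"]
        if stage1_ok:
            if sampler != "nuts":
                ledger.stage1_accepts += 1
            theta_star = box.from_unbounded(z_star)
            rss_star, lam_star = problem.simulate(theta_star)
            ledger.count_pde("sampling")
            ledger.stage2_decisions += 1
            E_curr = pot.true_potential(z, rss_curr)
            E_star = pot.true_potential(z_star, rss_star)
            if da_stage2(E_curr, E_star, pot.value(z), pot.value(z_star), rng):
                ledger.stage2_accepts += 1
                z = z_star
                rss_curr = float(rss_star)
        z_hist.append(z.copy())
        # noise variance: fixed in burn-in, Gibbs-updated afterwards
        if not in_burn:
            sigma2 = gibbs_sigma2(rss_curr, n, explo.noise_prior, rng)
            pot = make_pot(sigma2)
            bundle = pot.as_bundle()
            k = it - config.n_burn
            z_draws[k] = z
            draws[k] = box.from_unbounded(z)
            s2_draws[k] = sigma2
        # Bayesian-optimisation adaptation (AHMC/ARMHMC/ALDMC):
        # exploratory (EI) proposals during burn-in, exploitation of the
        # surrogate mean at schedule-gated moments afterwards
        if sampler != "nuts" and tuning_history is not None:
            if it == config.n_burn - 1:
                seg = np.array(z_hist[seg_start:])
                if len(seg) >= 10:
                    tuning_history.add(eps, max(L, 1), esjd_normalised(seg, 1))
                eps, L = bo_propose(tuning_history, rng, mode="mean")
                seg_start = len(z_hist) - 1
            else:
                allowed = in_burn or not config.strict_exactness
                seg_len = len(z_hist) - seg_start
                if allowed and seg_len >= 10:
                    n_adapt += 1
                    if adaptation_schedule(n_adapt, rng):
                        seg = np.array(z_hist[seg_start:])
                        tuning_history.add(eps, max(L, 1), esjd_normalised(seg, 1))
                        eps, L = bo_propose(
                            tuning_history, rng, mode="ei" if in_burn else "mean"
                        )
                        seg_start = len(z_hist) - 1

    ledger.check_invariants()
    return ChainResult(
        draws=draws, sigma2=s2_draws, z_draws=z_draws, ledger=ledger, seed=seed,
        sampler=sampler, epsilon=float(eps), L=int(max(L, 1)),
        accept_stage1=ledger.stage1_rate, accept_stage2=ledger.stage2_rate,
    )


# ---------------------------------------------------------------------------
# end-to-end orchestration
# ---------------------------------------------------------------------------


@dataclass
class InferenceResult:
    chains: list
    exploratory: ExploratoryResult
    ledger: RunLedger
    mpsrf: float
    config: PhaseConfig
    sampler: str

    @property
    def pooled_draws(self) -> np.ndarray:
        return np.vstack([c.draws for c in self.chains])

    @property
    def pooled_sigma2(self) -> np.ndarray:
        return np.concatenate([c.sigma2 for c in self.chains])

    @property
    def stage2_rate(self) -> float:
        acc = sum(c.ledger.stage2_accepts for c in self.chains)
        dec = sum(c.ledger.stage2_decisions for c in self.chains)
        return acc / max(dec, 1)

    def report(self) -> dict:
        pooled = self.pooled_draws
        per_chain = []
        for c in self.chains:
            per_chain.append({
                "seed": c.seed, "stage1": c.accept_stage1, "stage2": c.accept_stage2,
                "epsilon": c.epsilon, "L": c.L,
                "pde_sampling": c.ledger.pde_by_phase.get("sampling", 0),
            })
        return {
            "sampler": self.sampler,
            "mpsrf": self.mpsrf,
            "stage2_rate": self.stage2_rate,
            "pde_total": self.ledger.pde_total,
            "pde_by_phase": dict(self.ledger.pde_by_phase),
            "chains": per_chain,
            "posterior_median": np.median(pooled, axis=0).tolist(),
        }


def run_inference(
    problem: CalibrationProblem,
    config: PhaseConfig,
    seed: int,
    sampler: str = "ahmc",
    share_tuning: bool = True,
) -> InferenceResult:
    """Full design/exploratory/sampling workflow with ``config.n_chains``
    chains from dispersed starts and distinct seeds."""
    from .diagnostics import mpsrf as _mpsrf

    master = np.random.default_rng(seed)
    ledger = RunLedger()
    explo = exploratory_phase(problem, config, master, ledger)

    # dispersed starts: exploratory accepted points, without replacement.
    # Tail points where the frozen surrogate is untrained make terrible
    # starts (the clamped curvature metric degenerates there and a chain
    # can reject every proposal), so candidates are screened by their
    # emulated potential: keep those within a fixed log-density band of
    # the best candidate.
    box = problem.box
    cand = list(explo.accepted_z)
    if len(cand) >= 2 * config.n_chains:
        # later acceptances are closer to equilibrium yet still dispersed
        cand = cand[len(cand) // 2 :]
    if len(cand) > config.n_chains:
        pot_screen = EmulatedPotential(explo.emulator, explo.classifier, box,
                                       explo.sigma2, problem.n, mode="sampling")
        vals = np.array([pot_screen.value(z) for z in cand])
        keep = vals <= vals.min() + 15.0  # generous typical-set band, d = 4
        if keep.sum() >= config.n_chains:
            cand = [z for z, k in zip(cand, keep) if k]
    if len(cand) < config.n_chains:
        # fall back on jittered copies of the final exploratory point,
        # keeping only feasible ones
        attempts = 0
        while len(cand) < config.n_chains and attempts < 200:
            zj = explo.z_final + 0.05 * master.standard_normal(box.dim)
            _, lam = problem.simulate(box.from_unbounded(zj))
            ledger.count_pde("exploratory")
            attempts += 1
            if lam == 1:
                cand.append(zj)
        if len(cand) < config.n_chains:
            raise RuntimeError("could not assemble feasible chain start points")
    idx = master.choice(len(cand), size=config.n_chains, replace=False)
    starts = [cand[i] for i in idx]

    # build the tuning history once on the frozen emulated posterior and
    # share it across chains (the pre-processing step of the adaptive
    # samplers; each chain may still adapt it further)
    tuning_history = None
    if share_tuning and sampler != "nuts":
        manifold = sampler in ("armhmc", "aldmc")
        trange = config.tuning_range_manifold if manifold else config.tuning_range_hmc
        pot = EmulatedPotential(explo.emulator, explo.classifier, box,
                                explo.sigma2, problem.n, mode="sampling")
        pilot = _pilot_fn_factory(pot.as_bundle(), starts[0], manifold, sampler)
        tuning_history = bo_initialise(
            trange, pilot, master, config.bo_n_configs,
            config.bo_n_samples_per_config, normalise_by_L=False,
        )

    chains = []
    mp = np.inf
    for attempt in range(config.max_continuations + 1):
        new_chains = []
        for j in range(config.n_chains):
            chain_seed = int(master.integers(0, 2**31 - 1))
            ch = sampling_phase(
                problem, explo, config, starts[j], chain_seed, sampler,
                tuning_history=tuning_history,
            )
            ledger = ledger.merge(ch.ledger)
            new_chains.append(ch)
        chains = new_chains
        mp = _mpsrf(np.array([c.draws for c in chains]))
        if mp <= config.mpsrf_target or attempt == config.max_continuations:
            break
        # not converged: continue every chain from its end state (the
        # draws just taken become additional burn-in)
        logger.warning("MPSRF %.3f > %.2f: extending burn-in by continuation",
                       mp, config.mpsrf_target)
        starts = [c.z_draws[-1] for c in chains]
    return InferenceResult(chains, explo, ledger, mp, config, sampler)
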