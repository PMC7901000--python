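"""Bayesian-optimisation tuning of the HMC step size and trajectory length.

The tuning objective is the expected squared jumping distance (ESJD),
estimated empirically from short pilot runs — classically normalised per
leapfrog step (ESJD/L) when each step costs a simulator solve, or per
iteration when trajectories run on a cheap surrogate (the
delayed-acceptance setting; see ``bo_initialise``).  A GP surrogate over (log epsilon, L) is built from 20
initial probes; expected improvement proposes new configurations.  An
"infinite adaptation" schedule makes later adaptations increasingly rare
(p_t = min(1, c/t^kappa)), preserving ergodicity in the diminishing-
adaptation sense; a strict mode disables post-burn-in adaptation
entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .gp import RssEmulator, TrainingSet

__all__ = [
    "TuningRange",
    "TuningHistory",
    "esjd_normalised",
    "bo_initialise",
    "bo_propose",
    "adaptation_schedule",
    "HMC_TUNING_RANGE",
    "MANIFOLD_TUNING_RANGE",
]


@dataclass(frozen=True)
class TuningRange:
    """Admissible leapfrog steps L and step-size interval [eps_lo, eps_hi]."""

    L_max: int
    eps_lo: float
    eps_hi: float
    L_min: int = 1

    def __post_init__(self):
        if not (0 < self.eps_lo < self.eps_hi) or self.L_max < self.L_min or self.L_min < 1:
            raise ValueError("invalid tuning range")

    def contains(self, eps: float, L: int) -> bool:
        return self.eps_lo <= eps <= self.eps_hi and self.L_min <= L <= self.L_max


#: plain-HMC tuning box: L in {1..50}, eps in [1e-4, 5e-3]
HMC_TUNING_RANGE = TuningRange(50, 1e-4, 5e-3)
#: manifold (RMHMC/LDMC) tuning box: L in {1..40}, eps in [1e-2, 8e-2]
MANIFOLD_TUNING_RANGE = TuningRange(40, 1e-2, 8e-2)


@dataclass
class TuningHistory:
    """Evaluated (eps, L) probes with their noisy normalised-ESJD scores."""

    range: TuningRange
    eps: list = field(default_factory=list)
    L: list = field(default_factory=list)
    scores: list = field(default_factory=list)

    def add(self, eps: float, L: int, score: float):
        if score < 0:
            raise ValueError("ESJD estimates are non-negative")
        self.eps.append(float(eps))
        self.L.append(int(L))
        self.scores.append(float(score))

    def __len__(self):
        return len(self.scores)

    def best(self) -> tuple[float, int]:
        i = int(np.argmax(self.scores))
        return self.eps[i], self.L[i]

    def _X(self) -> np.ndarray:
        """Probes mapped to [-1,1]^2: (log eps, L) linearly scaled."""
        le = np.log(np.asarray(self.eps))
        lo, hi = np.log(self.range.eps_lo), np.log(self.range.eps_hi)
        x1 = 2 * (le - lo) / (hi - lo) - 1
        x2 = 2 * (np.asarray(self.L, float) - self.range.L_min) / max(
            self.range.L_max - self.range.L_min, 1
        ) - 1
        return np.column_stack([x1, x2])


def esjd_normalised(chain_segment, L: int) -> float:
    """mean ||theta_{t+1} - theta_t||^2 over the segment, divided by L."""
    if L < 1:
        raise ValueError("L must be >= 1")
    X = np.atleast_2d(np.asarray(chain_segment, float))
    if X.shape[0] < 2:
        raise ValueError("need a segment of length >= 2")
    jumps = np.diff(X, axis=0)
    return float(np.mean(np.sum(jumps * jumps, axis=1)) / L)


def bo_initialise(
    trange: TuningRange,
    pilot_fn,
    rng,
    n_configs: int = 20,
    n_samples_per_config: int = 10,
    normalise_by_L: bool = True,
) -> TuningHistory:
    """Probe ``n_configs`` space-filling (eps, L) pairs.

    ``pilot_fn(eps, L, n_samples, rng)`` must run a short pilot chain on
    the emulated posterior and return the chain segment (n, d).
    ``normalise_by_L=False`` scores raw ESJD (jumping distance per
    iteration) instead of ESJD/L — appropriate when trajectory steps are
    surrogate-only and the per-iteration cost is what matters.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    from scipy.stats import qmc

    sob = qmc.Sobol(d=2, scramble=True, rng=rng)
    n_pow2 = int(2 ** np.ceil(np.log2(max(n_configs, 2))))
    u = sob.random(n_pow2)[:n_configs]
    hist = TuningHistory(trange)
    for ui in u:
        eps = float(np.exp(np.log(trange.eps_lo) + ui[0] * (np.log(trange.eps_hi) - np.log(trange.eps_lo))))
        L = int(np.clip(round(trange.L_min + ui[1] * (trange.L_max - trange.L_min)), trange.L_min, trange.L_max))
        seg = pilot_fn(eps, L, n_samples_per_config, rng)
        hist.add(eps, L, esjd_normalised(seg, L if normalise_by_L else 1))
    return hist


def bo_propose(hist: TuningHistory, rng, grid_n: int = 40, mode: str = "ei") -> tuple[float, int]:
    """Acquisition maximiser over a dense grid of the tuning box.

    ``mode="ei"``: expected improvement with a noise-aware incumbent (the
    best GP-posterior mean among evaluated probes) — exploration.
    ``mode="mean"``: GP-posterior-mean maximiser — exploitation, used
    once the tuned configuration is wanted.  Falls back to a uniform
    random probe if the surrogate degenerates.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    trange = hist.range
    if len(hist) == 0:
        raise ValueError("empty tuning history")
    X_all = hist._X()
    raw = np.asarray(hist.scores)
    # repeated configurations (common once a chain adapts) are averaged
    uniq, inv = np.unique(np.round(X_all, 9), axis=0, return_inverse=True)
    raw_u = np.array([raw[inv == k].mean() for k in range(len(uniq))])
    # ESJD spans orders of magnitude; the surrogate fits the log scale
    floor = max(raw_u.max() * 1e-4, 1e-300)
    y = np.log(raw_u + floor)
    y = y - y.min()  # shift to >= 0 for the regression container
    try:
        em = RssEmulator(TrainingSet(uniq, y))
        em.fit_hyperparameters(rng=rng, n_restarts=2)
        mu_obs, _ = em.predict_batch(uniq)
        if mode == "mean":
            # exploitation: the evaluated probe with the best smoothed score
            # (the surrogate mean is not trusted where it extrapolates)
            a, b = uniq[int(np.argmax(mu_obs))]
        else:
            incumbent = float(mu_obs.max())
            g1 = np.linspace(-1, 1, grid_n)
            nL = min(grid_n, trange.L_max - trange.L_min + 1)
            g2 = np.linspace(-1, 1, nL)
            G = np.array([[a, b] for a in g1 for b in g2])
            mu, var = em.predict_batch(G)
            sd = np.sqrt(var)
            imp = mu - incumbent
            zz = imp / np.maximum(sd, 1e-12)
            acq = np.where(sd > 1e-12, imp * norm.cdf(zz) + sd * norm.pdf(zz), np.maximum(imp, 0.0))
            a, b = G[int(np.argmax(acq))]
    except (np.linalg.LinAlgError, ValueError):
        if mode == "mean":
            return hist.best()
        a, b = rng.uniform(-1, 1, 2)
    lo, hi = np.log(trange.eps_lo), np.log(trange.eps_hi)
    eps = float(np.exp(lo + (a + 1) / 2 * (hi - lo)))
    L = int(np.clip(round(trange.L_min + (b + 1) / 2 * (trange.L_max - trange.L_min)),
                    trange.L_min, trange.L_max))
    return eps, L


def adaptation_schedule(iteration: int, rng, c: float = 1.0, kappa: float = 0.6) -> bool:
    """Adapt with probability p_t = min(1, c / t^kappa): sum p_t diverges
    while p_t -> 0, satisfying diminishing adaptation with infinite
    adaptation opportunities."""
    if iteration < 1:
        raise ValueError("iteration must be >= 1")
    p = min(1.0, c / iteration**kappa)
    return bool(rng.uniform() < p)
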