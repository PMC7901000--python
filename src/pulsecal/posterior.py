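"""Exact (simulator-based) posterior for the pulse-wave calibration.

The four calibrated parameters theta = (s, r1, r2, c) — network-wide wall
stiffness and the three Windkessel adjustment factors — carry a uniform
(rescaled Beta(1,1)) prior on a box of physiologically plausible ranges.
The data model is iid Gaussian noise on the measured inlet-pressure series,

    y_i | theta, sigma^2  ~  N(m_i(theta), sigma^2),

with a conjugate inverse-gamma prior on sigma^2 so the noise variance has
a closed-form Gibbs update.  Samplers operate in unbounded coordinates via
a per-parameter logit map; the log-Jacobian of that map is added to the
log posterior so the uniform prior on the original scale is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PARAM_NAMES",
    "DEFAULT_RANGES",
    "ParameterBox",
    "NoisePriorSpec",
    "rss",
    "log_likelihood",
    "gibbs_sigma2",
    "gamma_s2_init",
]

PARAM_NAMES = ("s", "r1", "r2", "c")

#: biologically plausible box: stiffness s (g/cm/s^2) and the three
#: dimensionless Windkessel adjustment factors
DEFAULT_RANGES = np.array(
    [[7.0e4, 5.0e5], [-0.5, 1.92], [-0.5, 1.0], [-2.5, 1.5]]
)


@dataclass(frozen=True)
class ParameterBox:
    """Box support for theta with the logit and [-1,1]-scaling transforms.

    ``lower``/``upper`` are the per-coordinate prior bounds; ``scales``
    (s_i = max(|l_i|, |u_i|)) bring the coordinates to order one for the
    Gaussian-process inputs, following the convention theta_i / s_i.
    """

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = np.atleast_1d(np.asarray(self.lower, float))
        hi = np.atleast_1d(np.asarray(self.upper, float))
        if lo.shape != hi.shape or np.any(hi <= lo):
            raise ValueError("upper bounds must exceed lower bounds")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @classmethod
    def default(cls) -> "ParameterBox":
        return cls(DEFAULT_RANGES[:, 0], DEFAULT_RANGES[:, 1])

    @property
    def dim(self) -> int:
        return len(self.lower)

    @property
    def scales(self) -> np.ndarray:
        return np.maximum(np.abs(self.lower), np.abs(self.upper))

    # -- membership / prior ------------------------------------------------

    def contains(self, theta) -> bool:
        """Strict interior test (the box is open: boundary points excluded)."""
        th = np.asarray(theta, float)
        return bool(np.all(th > self.lower) and np.all(th < self.upper))

    def log_prior(self, theta) -> float:
        """Uniform (Beta(1,1) rescaled) log density: constant inside, -inf outside."""
        if not self.contains(theta):
            return -np.inf
        return -float(np.sum(np.log(self.upper - self.lower)))

    # -- GP input scaling --------------------------------------------------

    def to_scaled(self, theta) -> np.ndarray:
        """theta_i / s_i, each in [-1, 1] over the box."""
        return np.asarray(theta, float) / self.scales

    def from_scaled(self, x) -> np.ndarray:
        return np.asarray(x, float) * self.scales

    # -- unbounded sampling coordinates -----------------------------------

    def to_unbounded(self, theta) -> np.ndarray:
        """Per-coordinate logit: z_i = log((theta_i - l_i)/(u_i - theta_i))."""
        th = np.asarray(theta, float)
        if not self.contains(th):
            raise ValueError("theta must be strictly inside the box")
        return np.log((th - self.lower) / (self.upper - th))

    def from_unbounded(self, z) -> np.ndarray:
        sig = _expit(np.asarray(z, float))
        return self.lower + (self.upper - self.lower) * sig

    def log_jacobian(self, z) -> float:
        """log |d theta / d z| of the inverse logit map."""
        sig = _expit(np.asarray(z, float))
        with np.errstate(divide="ignore"):
            return float(
                np.sum(np.log(self.upper - self.lower) + np.log(sig) + np.log1p(-sig))
            )

    def log_jacobian_derivatives(self, z):
        """(value, grad, diag hess, diag third) of log|J| w.r.t. z.

        Per coordinate: log J_i = log(u_i-l_i) + log sig + log(1-sig), so
        d/dz = 1 - 2 sig, d2/dz2 = -2 sig(1-sig),
        d3/dz3 = -2 sig(1-sig)(1-2 sig).  Cross-terms vanish.
        """
        sig = _expit(np.asarray(z, float))
        with np.errstate(divide="ignore"):
            val = float(np.sum(np.log(self.upper - self.lower) + np.log(sig) + np.log1p(-sig)))
        g = 1.0 - 2.0 * sig
        h = -2.0 * sig * (1.0 - sig)
        t = h * (1.0 - 2.0 * sig)
        return val, g, h, t

    def dtheta_dz(self, z):
        """(d theta/dz, d2 theta/dz2, d3 theta/dz3), all diagonal, per coordinate."""
        sig = _expit(np.asarray(z, float))
        w = self.upper - self.lower
        d1 = w * sig * (1.0 - sig)
        d2 = d1 * (1.0 - 2.0 * sig)
        d3 = w * sig * (1.0 - sig) * (1.0 - 6.0 * sig * (1.0 - sig))
        return d1, d2, d3


def _expit(z):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(z, float)))


# ---------------------------------------------------------------------------
# likelihood and noise model
# ---------------------------------------------------------------------------


def rss(y, m) -> float:
    """Residual sum of squares sum_i (y_i - m_i)^2."""
    y = np.asarray(y, float)
    m = np.asarray(m, float)
    if y.shape != m.shape:
        raise ValueError("series length mismatch")
    r = y - m
    return float(r @ r)


def log_likelihood(S_rss: float, sigma2: float, n: int) -> float:
    """Gaussian iid log likelihood -S/(2 sigma^2) - (n/2) log(2 pi sigma^2).

    ``S_rss = -inf``-producing invalid simulations are encoded by the
    caller passing ``S_rss = inf`` (likelihood zero).
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if not np.isfinite(S_rss):
        return -np.inf
    return -S_rss / (2.0 * sigma2) - 0.5 * n * np.log(2.0 * np.pi * sigma2)


@dataclass(frozen=True)
class NoisePriorSpec:
    """Weakly informative conjugate InvGamma(a, b) prior for sigma^2.

    a = n_s/2 and b = n_s gamma_s2 / 2, where gamma_s2 is a prior point
    value for the noise variance and n_s the prior accuracy (default 1).
    """

    gamma_s2: float
    n_s: float = 1.0

    def __post_init__(self):
        if self.gamma_s2 < 0 or self.n_s <= 0:
            raise ValueError("gamma_s2 must be >= 0 and n_s > 0")

    @property
    def a(self) -> float:
        return 0.5 * self.n_s

    @property
    def b(self) -> float:
        return 0.5 * self.n_s * self.gamma_s2


def gamma_s2_init(rss_values, n: int, d: int) -> float:
    """Prior point value for sigma^2: (min RSS over the design)/(n - d)."""
    if n <= d:
        raise ValueError("need n > d")
    vals = np.asarray(rss_values, float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no finite RSS values in the design")
    return float(vals.min() / (n - d))


def gibbs_sigma2(S_rss: float, n: int, prior: NoisePriorSpec, rng=None) -> float:
    """Draw sigma^2 | theta, y from InvGamma(n/2 + a, S/2 + b).

    With ``rng=None`` returns the posterior mean (b')/(a'-1) instead of a
    draw — the deterministic mode used in tests.
    """
    if S_rss < 0 or n < 1:
        raise ValueError("S_rss must be >= 0 and n >= 1")
    shape = 0.5 * n + prior.a
    scale = 0.5 * S_rss + prior.b
    if rng is None:
        if shape <= 1:
            raise ValueError("posterior mean undefined for shape <= 1")
        return scale / (shape - 1.0)
    return float(stats.invgamma.rvs(shape, scale=scale, random_state=rng))
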