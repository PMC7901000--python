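"""Chain diagnostics: ESS, multivariate R-hat, summaries, predictive bands.

ESS uses the Geyer initial-monotone-positive-sequence truncation of the
autocorrelation sum; the multivariate potential scale reduction factor
(MPSRF) is the Brooks-Gelman largest-eigenvalue statistic, with the
conventional MPSRF <= 1.1 convergence criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ess",
    "mpsrf",
    "posterior_summary",
    "predictive_band",
    "qq_compare",
    "EfficiencyReport",
]


def _autocorr(x: np.ndarray) -> np.ndarray:
    n = len(x)
    x = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f))[:n].real / n
    if acov[0] <= 0:
        raise ValueError("zero-variance (constant) chain")
    return acov / acov[0]


def ess(chain_1d, return_flag: bool = False):
    """Effective sample size N / (1 + 2 sum rho_k), Geyer-truncated.

    Consecutive autocorrelation pairs Gamma_m = rho_{2m} + rho_{2m+1} are
    summed while positive, enforcing monotone non-increase.  A chain with
    net anticorrelation can legitimately give ESS > N; with
    ``return_flag=True`` the second return value marks that case.
    """
    x = np.asarray(chain_1d, float)
    if x.ndim != 1 or len(x) < 10:
        raise ValueError("need a 1D chain of length >= 10")
    rho = _autocorr(x)
    n = len(x)
    # Gamma_0 = rho_0 + rho_1 = 1 + rho_1
    tau = 0.0
    prev = np.inf
    for m in range(n // 2):
        g = rho[2 * m] + (rho[2 * m + 1] if 2 * m + 1 < n else 0.0)
        if g < 0:
            break
        g = min(g, prev)
        prev = g
        tau += 2.0 * g
    tau -= 1.0  # tau = -1 + 2 sum Gamma_m  (counts rho_0 once)
    tau = max(tau, 1e-12)
    out = n / tau
    flag = out > n
    return (float(out), bool(flag)) if return_flag else float(out)


def mpsrf(chains) -> float:
    """Brooks-Gelman multivariate potential scale reduction factor.

    ``chains``: (m, n, d) array or list of (n, d) arrays, m >= 2.
    """
    ch = np.asarray(chains, float)
    if ch.ndim != 3 or ch.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n, d = ch.shape
    means = ch.mean(axis=1)  # (m, d)
    W = np.zeros((d, d))
    for j in range(m):
        W += np.cov(ch[j].T, ddof=1)
    W /= m
    Bn = np.cov(means.T, ddof=1)  # = B/n
    try:
        lam = np.linalg.eigvals(np.linalg.solve(W, Bn)).real.max()
    except np.linalg.LinAlgError:
        warnings.warn("singular within-chain covariance; ridge-regularised")
        W = W + 1e-10 * np.eye(d) * max(np.trace(W) / d, 1e-12)
        lam = np.linalg.eigvals(np.linalg.solve(W, Bn)).real.max()
    return float((n - 1) / n + (m + 1) / m * lam)


def posterior_summary(draws, names=None, quantiles=(0.025, 0.25, 0.5, 0.75, 0.975)):
    """Medians, quantiles and the empirical correlation matrix of draws (n, d)."""
    X = np.atleast_2d(np.asarray(draws, float))
    if X.size == 0:
        raise ValueError("empty draws")
    d = X.shape[1]
    names = list(names) if names is not None else [f"p{i}" for i in range(d)]
    q = np.quantile(X, quantiles, axis=0)  # type-7 interpolation (numpy default)
    return {
        "names": names,
        "median": X.shape[0] and np.median(X, axis=0),
        "quantiles": {str(p): q[i] for i, p in enumerate(quantiles)},
        "correlation": np.corrcoef(X.T) if d > 1 else np.ones((1, 1)),
    }


def predictive_band(theta_draws, sigma2_draws, predict_fn, level: float = 0.95):
    """Posterior-predictive band m(theta) +/- z * sqrt(sigma2_err + var_signal).

    ``predict_fn(theta)`` returns the predicted series (or None for a
    failed simulation, which is skipped and counted).  The band combines
    the mean posterior noise variance with the pointwise variance of the
    predicted signals; returns (median, lower, upper, n_failed).
    """
    from scipy.stats import norm

    thetas = np.atleast_2d(np.asarray(theta_draws, float))
    if len(thetas) < 50:
        raise ValueError("need >= 50 posterior draws for a stable band")
    preds = []
    n_failed = 0
    for th in thetas:
        m = predict_fn(th)
        if m is None:
            n_failed += 1
            continue
        preds.append(np.asarray(m, float))
    P = np.array(preds)
    zq = norm.ppf(0.5 + level / 2.0)
    mean_sig = P.mean(axis=0)
    var_signal = P.var(axis=0)
    s2_err = float(np.mean(sigma2_draws))
    half = zq * np.sqrt(s2_err + var_signal)
    return np.median(P, axis=0), mean_sig - half, mean_sig + half, n_failed


def qq_compare(samples_a, samples_b, n_grid: int = 99):
    """Matched empirical quantiles of two samples on a common grid.

    Returns (qa, qb, correlation); equal distributions put the points on
    the diagonal with correlation ~1.
    """
    a = np.asarray(samples_a, float).ravel()
    b = np.asarray(samples_b, float).ravel()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty samples")
    p = np.linspace(0.01, 0.99, n_grid)
    qa = np.quantile(a, p)
    qb = np.quantile(b, p)
    corr = float(np.corrcoef(qa, qb)[0, 1])
    return qa, qb, corr


@dataclass
class EfficiencyReport:
    """Per-run efficiency summary in the form used for algorithm comparison."""

    ess_per_param: np.ndarray
    n_samples: int
    n_pde: int
    cpu_seconds: float
    acceptance_stage1: float
    acceptance_stage2: float
    mpsrf: float | None = None
    anticorrelation_flags: list = field(default_factory=list)

    @property
    def min_ess(self) -> float:
        return float(np.min(self.ess_per_param))

    @property
    def min_ess_per_sample(self) -> float:
        return self.min_ess / self.n_samples

    @property
    def min_ess_per_pde(self) -> float:
        return self.min_ess / max(self.n_pde, 1)

    @property
    def min_ess_per_cpu_second(self) -> float:
        return self.min_ess / max(self.cpu_seconds, 1e-12)

    def to_dict(self) -> dict:
        return {
            "ess_per_param": [float(v) for v in self.ess_per_param],
            "min_ess": self.min_ess,
            "n_samples": self.n_samples,
            "n_pde": self.n_pde,
            "min_ess_per_sample": self.min_ess_per_sample,
            "min_ess_per_pde": self.min_ess_per_pde,
            "min_ess_per_cpu_second": self.min_ess_per_cpu_second,
            "acceptance_stage1": self.acceptance_stage1,
            "acceptance_stage2": self.acceptance_stage2,
            "mpsrf": self.mpsrf,
            "anticorrelation_flags": self.anticorrelation_flags,
        }
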