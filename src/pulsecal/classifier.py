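"""GP classification of simulator feasibility, and the modified prior.

Certain joint parameter combinations violate the physical assumptions of
the pulse-wave model (e.g. high stiffness with incompatible downstream
compliance) and the simulation fails.  A binary GP classifier with a
Matern-3/2 ARD kernel and probit link, fitted by expectation propagation
(EP), predicts the probability p(lambda=1 | theta, H) that the simulator
succeeds at scaled input theta.  That probability multiplies the box
prior ("modified prior"), discouraging the emulator-guided sampler from
proposing into infeasible regions; the unknown normaliser cancels in
Metropolis-Hastings ratios.

The Matern-3/2 kernel is once differentiable, so the classifier
contributes to potential gradients analytically but is deliberately
excluded from the curvature metric used by Riemann-manifold samplers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.special import log_ndtr, ndtr

__all__ = [
    "LabeledDesign",
    "FeasibilityClassifier",
    "modified_log_prior",
]

logger = logging.getLogger(__name__)

PROB_FLOOR = 1e-12  # floor inside log to avoid -inf from rounding


@dataclass(frozen=True)
class LabeledDesign:
    """All evaluated inputs with their success labels (both classes kept)."""

    X: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, float))
        lam = np.atleast_1d(np.asarray(self.labels, int))
        if X.shape[0] != len(lam):
            raise ValueError("inputs and labels length mismatch")
        if not np.all(np.isin(lam, (0, 1))):
            raise ValueError("labels must be 0 or 1")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "labels", lam)

    def __len__(self) -> int:
        return len(self.labels)

    def add(self, x, label: int) -> "LabeledDesign":
        x = np.asarray(x, float).ravel()
        return LabeledDesign(np.vstack([self.X, x[None, :]]), np.append(self.labels, label))

    def remove(self, index: int) -> "LabeledDesign":
        keep = np.ones(len(self), bool)
        keep[index] = False
        return LabeledDesign(self.X[keep], self.labels[keep])


_SQRT2PI = float(np.sqrt(2.0 * np.pi))


def _npdf(x):
    return np.exp(-0.5 * x * x) / _SQRT2PI


def _matern32(X1, X2, sig2, ell):
    d = (X1[:, None, :] - X2[None, :, :]) / ell
    r = np.sqrt(np.maximum(np.sum(d * d, axis=2), 0.0))
    return sig2 * (1.0 + np.sqrt(3.0) * r) * np.exp(-np.sqrt(3.0) * r)


def _matern32_grad_x(xstar, X, sig2, ell):
    """d k(x*, X_n) / d x*_i : (n, d); smooth at r = 0."""
    diff = xstar[None, :] - X
    r = np.sqrt(np.maximum(np.sum((diff / ell) ** 2, axis=1), 0.0))
    return -3.0 * sig2 * np.exp(-np.sqrt(3.0) * r)[:, None] * diff / ell**2


class FeasibilityClassifier:
    """EP-probit GP classifier over scaled parameter inputs."""

    def __init__(self, design: LabeledDesign, signal_variance=5.0, lengthscales=None):
        self.design = design
        self.signal_variance = float(signal_variance)
        d = design.X.shape[1]
        self.lengthscales = (
            np.full(d, 0.7) if lengthscales is None else np.asarray(lengthscales, float)
        )
        self._post = None
        self._degenerate_rate: float | None = None

    # -- EP ----------------------------------------------------------------

    def _ep(self, sig2, ell, max_sweeps: int = 100, tol: float = 1e-6, warm=None):
        """Run EP to a fixed point; returns the site/posterior bundle.

        ``warm=(nu, tau)`` seeds the site parameters (padded with zeros
        for new rows), typically converging in one or two sweeps.
        """
        X = self.design.X
        y = 2.0 * self.design.labels - 1.0  # {-1, +1}
        n = len(y)
        K = _matern32(X, X, sig2, ell) + 1e-8 * np.eye(n)
        nu = np.zeros(n)
        tau = np.zeros(n)
        if warm is not None:
            nw = min(len(warm[0]), n)
            nu[:nw] = warm[0][:nw]
            tau[:nw] = warm[1][:nw]
        if np.any(tau > 0):
            srt = np.sqrt(tau)
            B = np.eye(n) + srt[:, None] * K * srt[None, :]
            L = cholesky(B, lower=True)
            V = solve_triangular(L, srt[:, None] * K, lower=True)
            Sigma = K - V.T @ V
            mu = Sigma @ nu
        else:
            Sigma = K.copy()
            mu = np.zeros(n)
        z_site = np.zeros(n)
        for _ in range(max_sweeps):
            delta = 0.0
            for i in range(n):
                tau_c = 1.0 / Sigma[i, i] - tau[i]
                nu_c = mu[i] / Sigma[i, i] - nu[i]
                if tau_c <= 0:
                    continue  # skip unstable cavity
                mu_c = nu_c / tau_c
                s2_c = 1.0 / tau_c
                denom = np.sqrt(1.0 + s2_c)
                z = y[i] * mu_c / denom
                ratio = _npdf(z) / max(ndtr(z), 1e-300)
                mu_hat = mu_c + y[i] * s2_c * ratio / denom
                s2_hat = s2_c - s2_c**2 * ratio * (z + ratio) / (1.0 + s2_c)
                s2_hat = max(s2_hat, 1e-10)
                tau_new = max(1.0 / s2_hat - tau_c, 1e-10)
                nu_new = mu_hat / s2_hat - nu_c
                dtau = tau_new - tau[i]
                nu_prev = nu[i]
                delta = max(delta, abs(dtau), abs(nu_new - nu[i]))
                tau[i] = tau_new
                nu[i] = nu_new
                z_site[i] = z
                # rank-1 refresh of (Sigma, mu); with c = dtau/(1+dtau S_ii)
                # and s = Sigma[:, i]:  mu' = mu + (dnu - c (mu_i + s_i dnu)) s
                si = Sigma[:, i].copy()
                cfac = dtau / (1.0 + dtau * si[i])
                dnu = nu_new - nu_prev
                Sigma -= cfac * (si[:, None] * si[None, :])
                mu = mu + (dnu - cfac * (mu[i] + si[i] * dnu)) * si
            # full refresh for numerical hygiene
            srt = np.sqrt(tau)
            B = np.eye(n) + srt[:, None] * K * srt[None, :]
            L = cholesky(B, lower=True)
            V = solve_triangular(L, srt[:, None] * K, lower=True)
            Sigma = K - V.T @ V
            mu = Sigma @ nu
            if delta < tol:
                break
        return {"K": K, "nu": nu, "tau": tau, "L": L, "mu": mu, "Sigma": Sigma, "z": z_site}

    def _log_evidence(self, post) -> float:
        """EP approximation of log p(labels | X, hyperparameters)."""
        K, nu, tau = post["K"], post["nu"], post["tau"]
        n = len(nu)
        tau_f = np.maximum(tau, 1e-10)
        mu_site = nu / tau_f
        S_inv = np.diag(1.0 / tau_f)
        # cavity parameters from the converged posterior
        Sigma, mu = post["Sigma"], post["mu"]
        tau_c = 1.0 / np.diag(Sigma) - tau
        nu_c = mu / np.diag(Sigma) - nu
        ok = tau_c > 0
        mu_c = np.where(ok, nu_c / np.maximum(tau_c, 1e-12), 0.0)
        s2_c = np.where(ok, 1.0 / np.maximum(tau_c, 1e-12), 1.0)
        y = 2.0 * self.design.labels - 1.0
        z = y * mu_c / np.sqrt(1.0 + s2_c)
        log_moments = np.sum(log_ndtr(z))
        # log N(mu_site ; mu_c, s2_c + 1/tau) summed
        var_sum = s2_c + 1.0 / tau_f
        log_pair = -0.5 * np.sum(
            np.log(2 * np.pi * var_sum) + (mu_site - mu_c) ** 2 / var_sum
        )
        # log N(mu_site ; 0, K + S^-1)
        A = K + S_inv
        La = cholesky(A + 1e-10 * np.eye(n), lower=True)
        w = solve_triangular(La, mu_site, lower=True)
        log_joint = -0.5 * (w @ w) - np.sum(np.log(np.diag(La))) - 0.5 * n * np.log(2 * np.pi)
        return float(log_moments - log_pair + log_joint)

    # -- fitting -----------------------------------------------------------

    def fit(self, optimise: bool = True, rng=None, n_restarts: int = 2, maxiter: int = 40):
        """Fit EP sites; optionally optimise hyperparameters by EP evidence."""
        labels = self.design.labels
        if labels.min() == labels.max():
            was_degenerate = self._degenerate_rate is not None
            self._degenerate_rate = float(np.clip(labels.mean(), PROB_FLOOR, 1 - PROB_FLOOR))
            self._post = None
            if not was_degenerate:
                logger.warning(
                    "single-class design: classifier degenerates to base rate %.3f",
                    self._degenerate_rate,
                )
            return self
        self._degenerate_rate = None
        if optimise:
            rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
            d = self.design.X.shape[1]

            def neg_ev(phi):
                phi = np.clip(phi, -5.0, 6.0)  # keep hyperparameters in a sane range
                sig2 = np.exp(phi[0])
                ell = np.exp(phi[1:])
                try:
                    post = self._ep(sig2, ell, max_sweeps=15, tol=1e-4)
                    return -self._log_evidence(post)
                except np.linalg.LinAlgError:
                    return 1e10

            x0 = np.log(np.concatenate([[self.signal_variance], self.lengthscales]))
            best = None
            starts = [x0] + [
                x0 + rng.normal(0, 0.7, size=d + 1) for _ in range(max(0, n_restarts - 1))
            ]
            for s in starts:
                res = minimize(neg_ev, s, method="Nelder-Mead",
                               options={"maxiter": maxiter, "xatol": 1e-2, "fatol": 1e-2})
                if best is None or res.fun < best.fun:
                    best = res
            bx = np.clip(best.x, -5.0, 6.0)
            self.signal_variance = float(np.exp(bx[0]))
            self.lengthscales = np.exp(bx[1:])
        warm = None
        if self._post is not None:
            warm = (self._post["nu"], self._post["tau"])
        self._post = self._ep(self.signal_variance, self.lengthscales, warm=warm)
        self._precompute_predictors()
        return self

    def _precompute_predictors(self):
        """Cache the linear operators used by every prediction call:
        alpha_c = nu - S^1/2 B^-1 S^1/2 K nu  (mean weights) and
        R = S^1/2 B^-1 S^1/2  (so var = k** - ks^T R ks)."""
        post = self._post
        n = len(post["nu"])
        srt = np.sqrt(post["tau"])
        Linv_S = solve_triangular(post["L"], np.diag(srt), lower=True, check_finite=False)
        R = Linv_S.T @ Linv_S  # = S^1/2 B^-1 S^1/2
        post["R"] = R
        post["alpha_c"] = post["nu"] - R @ (post["K"] @ post["nu"])

    def refit_sites(self):
        """Re-run EP at the current hyperparameters (after design updates)."""
        return self.fit(optimise=False)

    def log_evidence(self) -> float:
        if self._post is None:
            raise RuntimeError("classifier not fitted")
        return self._log_evidence(self._post)

    # -- persistence ---------------------------------------------------------

    def to_hdf5(self, group) -> None:
        group.create_dataset("X", data=self.design.X)
        group.create_dataset("labels", data=self.design.labels)
        group.create_dataset("lengthscales", data=self.lengthscales)
        group.attrs["signal_variance"] = self.signal_variance

    @classmethod
    def from_hdf5(cls, group) -> "FeasibilityClassifier":
        """Rebuild and re-run EP (deterministic at fixed hyperparameters)."""
        obj = cls(
            LabeledDesign(group["X"][...], group["labels"][...]),
            signal_variance=float(group.attrs["signal_variance"]),
            lengthscales=group["lengthscales"][...],
        )
        return obj.fit(optimise=False)

    # -- prediction ----------------------------------------------------------

    def _latent(self, xstar: np.ndarray):
        post = self._post
        ks = _matern32(xstar[None, :], self.design.X, self.signal_variance, self.lengthscales)[0]
        fbar = ks @ post["alpha_c"]
        Rks = post["R"] @ ks
        var = self.signal_variance - ks @ Rks
        return ks, Rks, fbar, float(max(var, 1e-12))

    def predict_prob_valid(self, xstar) -> float:
        """p(lambda = 1 | x*, design) via the probit predictive."""
        xstar = np.asarray(xstar, float).ravel()
        if self._degenerate_rate is not None:
            return self._degenerate_rate
        if self._post is None:
            raise RuntimeError("classifier not fitted")
        _, _, fbar, var = self._latent(xstar)
        return float(ndtr(fbar / np.sqrt(1.0 + var)))

    def log_prob_and_grad(self, xstar):
        """(log p(lambda=1|x*), d log p / d x*) with the probability floored."""
        xstar = np.asarray(xstar, float).ravel()
        if self._degenerate_rate is not None:
            return float(np.log(self._degenerate_rate)), np.zeros_like(xstar)
        if self._post is None:
            raise RuntimeError("classifier not fitted")
        post = self._post
        ks, Rks, fbar, var = self._latent(xstar)
        s = np.sqrt(1.0 + var)
        u = fbar / s
        p = max(float(ndtr(u)), PROB_FLOOR)
        dks = _matern32_grad_x(xstar, self.design.X, self.signal_variance, self.lengthscales)
        gf = dks.T @ post["alpha_c"]
        gv = -2.0 * (dks.T @ Rks)
        du = gf / s - fbar * gv / (2.0 * s**3)
        grad = _npdf(u) * du / p
        return float(np.log(p)), grad


def modified_log_prior(theta_scaled, model: FeasibilityClassifier, base_log_prior: float) -> float:
    """log p~(theta) = log p(theta) + log p(lambda=1 | theta); normaliser dropped."""
    if not np.isfinite(base_log_prior):
        return -np.inf
    p = max(model.predict_prob_valid(theta_scaled), PROB_FLOOR)
    return base_log_prior + float(np.log(p))
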