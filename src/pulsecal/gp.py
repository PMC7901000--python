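"""Gaussian-process emulation of the residual-sum-of-squares surface.

A zero-mean GP with a squared-exponential ARD kernel is fitted to RSS
values S(theta) at order-one scaled inputs x = theta / s_i.  Targets are
z-scored internally.  Because the SE kernel is infinitely differentiable
and GPs are closed under differentiation, the predictive mean admits
analytic derivatives of any order; first, second and third derivatives
(plus the gradient of the predictive variance) are exposed for the
Hamiltonian-type samplers and their curvature-based metrics.

The two emulated "potential energy" functions that drive the sampler are

    exploratory:  E = (mean - sd)/(2 sigma^2) + (n/2) log(2 pi sigma^2) - log p~
    sampling:     E = mean/(2 sigma^2) + (n/2) log(2 pi sigma^2) - log p~

the -sd term steering exploration toward regions that are either probable
or still uncertain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

__all__ = [
    "SEKernelHyper",
    "TrainingSet",
    "GPPrediction",
    "RssEmulator",
    "potential_exploratory",
    "potential_sampling",
]

_JITTERS = (0.0, 1e-10, 1e-8, 1e-6)


@dataclass(frozen=True)
class SEKernelHyper:
    """ARD squared-exponential hyperparameters (on standardised targets)."""

    signal_variance: float
    lengthscales: np.ndarray
    nugget: float

    def __post_init__(self):
        ls = np.atleast_1d(np.asarray(self.lengthscales, float))
        object.__setattr__(self, "lengthscales", ls)
        if self.signal_variance <= 0 or self.nugget <= 0 or np.any(ls <= 0):
            raise ValueError("hyperparameters must be strictly positive")

    def pack(self) -> np.ndarray:
        return np.log(np.concatenate([[self.signal_variance], self.lengthscales, [self.nugget]]))

    @classmethod
    def unpack(cls, phi: np.ndarray) -> "SEKernelHyper":
        v = np.exp(np.asarray(phi, float))
        return cls(v[0], v[1:-1], v[-1])


@dataclass(frozen=True)
class TrainingSet:
    """Emulator training data: scaled inputs, raw RSS targets, provenance.

    Only points from successful simulations are admitted; duplicates
    (within 1e-10 in the input space) are rejected.
    """

    X: np.ndarray
    targets: np.ndarray
    provenance: tuple[str, ...] = ()

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, float))
        y = np.atleast_1d(np.asarray(self.targets, float))
        if X.shape[0] != len(y):
            raise ValueError("inputs and targets length mismatch")
        if np.any(y < 0):
            raise ValueError("RSS targets must be non-negative")
        prov = self.provenance or tuple("design" for _ in y)
        if len(prov) != len(y):
            raise ValueError("provenance length mismatch")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "targets", y)
        object.__setattr__(self, "provenance", tuple(prov))

    def __len__(self) -> int:
        return len(self.targets)

    def _is_duplicate(self, x: np.ndarray) -> bool:
        if len(self) == 0:
            return False
        return bool(np.any(np.max(np.abs(self.X - x[None, :]), axis=1) < 1e-10))

    def add(self, x, target: float, provenance: str = "exploratory") -> "TrainingSet":
        x = np.asarray(x, float).ravel()
        if target < 0:
            raise ValueError("RSS target must be non-negative")
        if self._is_duplicate(x):
            raise ValueError("duplicate training input")
        return TrainingSet(
            np.vstack([self.X, x[None, :]]) if len(self) else x[None, :],
            np.append(self.targets, target),
            self.provenance + (provenance,),
        )

    def remove(self, index: int) -> "TrainingSet":
        if len(self) == 0:
            raise ValueError("cannot remove from an empty training set")
        keep = np.ones(len(self), bool)
        keep[index] = False
        prov = tuple(p for i, p in enumerate(self.provenance) if keep[i])
        return TrainingSet(self.X[keep], self.targets[keep], prov)


@dataclass
class GPPrediction:
    mean: float
    variance: float
    gradient: np.ndarray | None = None
    hessian: np.ndarray | None = None
    third: np.ndarray | None = None
    variance_gradient: np.ndarray | None = None

    @property
    def sd(self) -> float:
        return float(np.sqrt(max(self.variance, 0.0)))


def _se_kernel(X1, X2, hyper: SEKernelHyper):
    d = (X1[:, None, :] - X2[None, :, :]) / hyper.lengthscales
    return hyper.signal_variance * np.exp(-0.5 * np.sum(d * d, axis=2))


class RssEmulator:
    """GP regression surrogate for the RSS surface on scaled inputs."""

    def __init__(self, train: TrainingSet, hyper: SEKernelHyper | None = None):
        self.train = train
        self.hyper = hyper
        self._cache = None
        if hyper is not None:
            self._refresh()

    # -- fitting -----------------------------------------------------------

    def _standardise(self):
        y = self.train.targets
        mu = float(np.mean(y))
        sd = float(np.std(y))
        if sd < 1e-12:
            sd = 1.0  # constant targets: degenerate but well-defined
        return (y - mu) / sd, mu, sd

    def _gram(self, hyper: SEKernelHyper):
        K = _se_kernel(self.train.X, self.train.X, hyper)
        K[np.diag_indices_from(K)] += hyper.nugget
        return K

    def _chol(self, K):
        for jit in _JITTERS:
            try:
                return cholesky(K + jit * np.eye(len(K)), lower=True), jit
            except np.linalg.LinAlgError:
                continue
        raise np.linalg.LinAlgError("kernel matrix not positive definite after max jitter")

    def log_marginal_likelihood(self, hyper: SEKernelHyper | None = None) -> float:
        """GP evidence of the standardised targets under the zero-mean prior."""
        hyper = hyper or self.hyper
        ys, _, _ = self._standardise()
        L, _ = self._chol(self._gram(hyper))
        alpha = cho_solve((L, True), ys)
        return float(
            -0.5 * ys @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * len(ys) * np.log(2 * np.pi)
        )

    def _evidence_and_grad(self, phi: np.ndarray):
        hyper = SEKernelHyper.unpack(phi)
        ys, _, _ = self._standardise()
        X = self.train.X
        n, d = X.shape
        diff = X[:, None, :] - X[None, :, :]
        sq = (diff / hyper.lengthscales) ** 2
        Kf = hyper.signal_variance * np.exp(-0.5 * sq.sum(axis=2))
        K = Kf + hyper.nugget * np.eye(n)
        L, _ = self._chol(K)
        alpha = cho_solve((L, True), ys)
        Kinv = cho_solve((L, True), np.eye(n))
        lml = -0.5 * ys @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * n * np.log(2 * np.pi)
        W = np.outer(alpha, alpha) - Kinv
        grad = np.empty(d + 2)
        grad[0] = 0.5 * np.sum(W * Kf)  # d/d log sigma_f^2
        for k in range(d):
            grad[1 + k] = 0.5 * np.sum(W * (Kf * sq[:, :, k]))  # d/d log l_k
        grad[-1] = 0.5 * hyper.nugget * np.trace(W)  # d/d log nugget
        return float(lml), grad

    def fit_hyperparameters(self, rng=None, n_restarts: int = 5, warm_start: bool = False,
                            maxiter: int = 200):
        """Maximise the evidence in log-hyperparameter space (multi-restart)."""
        if len(self.train) < 2:
            raise ValueError("need at least 2 training points")
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        d = self.train.X.shape[1]
        starts = []
        if warm_start and self.hyper is not None:
            starts.append(self.hyper.pack())
            n_restarts = max(1, n_restarts - 1) if n_restarts > 1 else 0
        span = np.ptp(self.train.X, axis=0)
        span[span < 1e-6] = 1.0
        base = np.log(np.concatenate([[1.0], 0.5 * span, [1e-4]]))
        if not starts:
            starts.append(base)
            n_restarts -= 1
        for _ in range(max(0, n_restarts)):
            starts.append(base + rng.normal(0.0, 1.0, size=d + 2))
        best = None
        for x0 in starts:
            res = minimize(
                lambda p: tuple(-v for v in self._evidence_and_grad(p)),
                x0,
                jac=True,
                method="L-BFGS-B",
                # targets are z-scored and lengthscales beyond a few data
                # spans are unidentifiable: cap both so the kernel matrix
                # stays away from the degenerate flat-kernel ridge
                bounds=[(np.log(1e-3), np.log(1e2))]
                + [(np.log(1e-3 * sp), np.log(3.0 * sp)) for sp in span]
                + [(np.log(1e-10), np.log(1e1))],
                options={"maxiter": maxiter},
            )
            if best is None or res.fun < best.fun:
                best = res
        self.hyper = SEKernelHyper.unpack(best.x)
        self._refresh()
        return self.hyper

    def _refresh(self):
        ys, mu, sd = self._standardise()
        L, jit = self._chol(self._gram(self.hyper))
        alpha = cho_solve((L, True), ys)
        self._cache = {"L": L, "alpha": alpha, "y_mu": mu, "y_sd": sd, "jitter": jit}

    def _require_fit(self):
        if self.hyper is None or self._cache is None:
            raise RuntimeError("emulator not fitted: call fit_hyperparameters first")

    # -- training-set updates ----------------------------------------------

    def add_point(self, x, target: float, provenance: str = "exploratory"):
        self.train = self.train.add(x, target, provenance)
        if self.hyper is not None:
            self._refresh()

    def remove_point(self, index: int):
        self.train = self.train.remove(index)
        if self.hyper is not None and len(self.train):
            self._refresh()

    # -- persistence ---------------------------------------------------------

    def to_hdf5(self, group) -> None:
        """Serialise training data and hyperparameters into an h5py group."""
        group.create_dataset("X", data=self.train.X)
        group.create_dataset("targets", data=self.train.targets)
        group.attrs["provenance"] = ",".join(self.train.provenance)
        if self.hyper is not None:
            group.create_dataset("hyper", data=self.hyper.pack())

    @classmethod
    def from_hdf5(cls, group) -> "RssEmulator":
        prov = tuple(group.attrs["provenance"].split(",")) if group.attrs.get("provenance") else ()
        train = TrainingSet(group["X"][...], group["targets"][...], prov)
        hyper = SEKernelHyper.unpack(group["hyper"][...]) if "hyper" in group else None
        return cls(train, hyper)

    # -- prediction ----------------------------------------------------------

    def predict(self, x) -> GPPrediction:
        """Exact GP conditional mean/variance of the raw-scale RSS at x."""
        self._require_fit()
        x = np.asarray(x, float).ravel()
        c = self._cache
        ks = _se_kernel(x[None, :], self.train.X, self.hyper)[0]
        mean_std = ks @ c["alpha"]
        v = solve_triangular(c["L"], ks, lower=True, check_finite=False)
        var_std = self.hyper.signal_variance + self.hyper.nugget - v @ v
        return GPPrediction(
            mean=float(c["y_mu"] + c["y_sd"] * mean_std),
            variance=float(max(var_std, 0.0) * c["y_sd"] ** 2),
        )

    def predict_batch(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised conditional mean and variance at rows of X (raw scale)."""
        self._require_fit()
        X = np.atleast_2d(np.asarray(X, float))
        c = self._cache
        Ks = _se_kernel(X, self.train.X, self.hyper)  # (m, n)
        mean_std = Ks @ c["alpha"]
        V = solve_triangular(c["L"], Ks.T, lower=True, check_finite=False)  # (n, m)
        var_std = self.hyper.signal_variance + self.hyper.nugget - np.sum(V * V, axis=0)
        return (
            c["y_mu"] + c["y_sd"] * mean_std,
            np.maximum(var_std, 0.0) * c["y_sd"] ** 2,
        )

    def predict_derivatives(self, x, order: int = 3) -> GPPrediction:
        """Prediction plus analytic derivatives of the mean w.r.t. x.

        order 1: gradient (+ gradient of the variance); order 2: + Hessian;
        order 3: + symmetric third-order tensor.  All on the raw target
        scale, with respect to the scaled input coordinates.
        """
        if order not in (1, 2, 3):
            raise ValueError("order must be 1, 2 or 3")
        self._require_fit()
        x = np.asarray(x, float).ravel()
        c = self._cache
        X = self.train.X
        ell2 = self.hyper.lengthscales**2
        ks = _se_kernel(x[None, :], X, self.hyper)[0]  # (n,)
        t = (x[None, :] - X) / ell2  # (n, d)
        alpha = c["alpha"]
        y_sd = c["y_sd"]
        d = len(x)

        pred = self.predict(x)
        ka = ks * alpha
        grad = -(t * ka[:, None]).sum(axis=0) * y_sd
        pred.gradient = grad

        # variance gradient: d var/dx = -2 (dk*)^T K^-1 k*
        Kinv_ks = cho_solve((c["L"], True), ks, check_finite=False)
        dks = -t * ks[:, None]  # (n, d): d k*/dx_i
        pred.variance_gradient = -2.0 * (dks.T @ Kinv_ks) * y_sd**2

        if order >= 2:
            # hess_ij = sum_n ka_n (t_ni t_nj - delta_ij / l_i^2)
            H = np.einsum("n,ni,nj->ij", ka, t, t) - np.diag((ka.sum()) / ell2)
            pred.hessian = H * y_sd
        if order >= 3:
            Tm = -np.einsum("n,ni,nj,nk->ijk", ka, t, t, t)
            s1 = np.einsum("n,nk->k", ka, t)  # sum ka_n t_nk
            eye = np.eye(d)
            Tm += (
                np.einsum("ij,k->ijk", eye / ell2[None, :] * eye, s1)  # delta_ij/l_i^2 * t_k
                + np.einsum("ik,j->ijk", eye / ell2[None, :] * eye, s1)
                + np.einsum("jk,i->ijk", eye / ell2[None, :] * eye, s1)
            )
            pred.third = Tm * y_sd
        return pred


# ---------------------------------------------------------------------------
# emulated potentials
# ---------------------------------------------------------------------------


def potential_exploratory(
    pred: GPPrediction, sigma2: float, n: int, mod_log_prior: float, use_sd: bool = True
) -> float:
    """Uncertainty-seeking potential (mean - sd)/(2 s2) + (n/2)log(2 pi s2) - log p~."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    spread = pred.sd if use_sd else pred.variance
    return (pred.mean - spread) / (2.0 * sigma2) + 0.5 * n * np.log(
        2.0 * np.pi * sigma2
    ) - mod_log_prior


def potential_sampling(pred: GPPrediction, sigma2: float, n: int, mod_log_prior: float) -> float:
    """Frozen-surrogate potential mean/(2 s2) + (n/2)log(2 pi s2) - log p~."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    return pred.mean / (2.0 * sigma2) + 0.5 * n * np.log(2.0 * np.pi * sigma2) - mod_log_prior
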