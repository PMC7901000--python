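"""Gradient-based MCMC kernels over a generic potential interface.

All samplers operate on a potential energy E(z) = -log target(z) in
unbounded coordinates, supplied as callables for the value, gradient and
(for the manifold samplers) Hessian and third-derivative tensor:

* ``hmc`` — explicit leapfrog, constant mass matrix;
* ``rmhmc`` — implicit generalised leapfrog with a position-dependent
  metric M(z) (negative Hessian of the log posterior, regularised to be
  positive definite), non-separable Hamiltonian including 0.5 log|2 pi M|;
* ``ldmc`` — Lagrangian dynamics with "velocity" v = M^-1 r and an
  explicit integrator; volume is not preserved so the acceptance ratio
  carries the product of per-step Jacobian determinants;
* ``nuts`` — multinomial no-U-turn sampler with dual-averaging step-size
  adaptation (identity mass);
* ``adaptive_metropolis_chain`` — Gaussian random walk with covariance
  adapted from the chain history (the long-run exact-posterior reference).

Proposal-level entry points (``*_propose``) return the trajectory end
point together with the Hamiltonians so a delayed-acceptance wrapper can
supply its own two-stage decision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "TrajectoryConfig",
    "Potential",
    "leapfrog_trajectory",
    "hmc_propose",
    "hmc_step",
    "rmhmc_propose",
    "rmhmc_step",
    "ldmc_integrate",
    "ldmc_propose",
    "ldmc_step",
    "nuts_step",
    "DualAveraging",
    "clamp_metric",
    "metric_from_potential",
    "adaptive_metropolis_chain",
]


@dataclass
class TrajectoryConfig:
    """Step size, number of integrator steps and implicit-solve controls."""

    epsilon: float
    L: int
    fp_tol: float = 1e-8
    fp_maxiter: int = 50

    def __post_init__(self):
        # L = 0 is the degenerate identity trajectory (always accepted)
        if self.epsilon <= 0 or self.L < 0:
            raise ValueError("epsilon must be > 0 and L >= 0")


@dataclass
class Potential:
    """Bundle of derivative callables for -log target."""

    value: Callable[[np.ndarray], float]
    grad: Callable[[np.ndarray], np.ndarray]
    hess: Callable[[np.ndarray], np.ndarray] | None = None
    third: Callable[[np.ndarray], np.ndarray] | None = None


def _mh_accept(log_ratio: float, rng) -> bool:
    return np.log(rng.uniform()) < log_ratio


# ---------------------------------------------------------------------------
# HMC (explicit leapfrog, constant mass)
# ---------------------------------------------------------------------------


def leapfrog_trajectory(z, r, cfg: TrajectoryConfig, grad, Minv=None, stop_fn=None):
    """Standard leapfrog for H = E(z) + 0.5 r^T M^-1 r.

    Returns (z_end, r_end, ok, n_steps_taken).  ``stop_fn(z)``, if given,
    is evaluated after every position update and terminates the
    trajectory early when it returns True (the early-stop hook of the
    exploratory phase).  A non-finite gradient aborts (ok=False).
    """
    z = np.array(z, float)
    r = np.array(r, float)
    d = len(z)
    Minv = np.eye(d) if Minv is None else Minv
    g = grad(z)
    if not np.all(np.isfinite(g)):
        return z, r, False, 0
    eps = cfg.epsilon
    r = r - 0.5 * eps * g
    for step in range(cfg.L):
        z = z + eps * (Minv @ r)
        if stop_fn is not None and stop_fn(z):
            g = grad(z)
            if not np.all(np.isfinite(g)):
                return z, r, False, step + 1
            r = r - 0.5 * eps * g
            return z, r, True, step + 1
        g = grad(z)
        if not np.all(np.isfinite(g)):
            return z, r, False, step + 1
        if step < cfg.L - 1:
            r = r - eps * g
    r = r - 0.5 * eps * g
    return z, r, True, cfg.L


def _kinetic(r, Minv):
    return 0.5 * float(r @ (Minv @ r))


def hmc_propose(z, cfg, potential: Potential, rng, M=None, stop_fn=None):
    """One leapfrog trajectory from a fresh momentum draw.

    Returns dict with the proposal, initial/final Hamiltonians and the
    (zero for HMC) extra log-Jacobian term.
    """
    z = np.asarray(z, float)
    d = len(z)
    if M is None:
        M = np.eye(d)
        Minv = M
        Lc = M
    else:
        Lc = np.linalg.cholesky(M)
        Minv = np.linalg.inv(M)
    r0 = Lc @ rng.standard_normal(d)
    E0 = potential.value(z)
    H0 = E0 + _kinetic(r0, Minv)
    z1, r1, ok, steps = leapfrog_trajectory(z, r0, cfg, potential.grad, Minv, stop_fn)
    if not ok:
        return {"z": z, "ok": False, "H0": H0, "H1": np.inf, "E1": np.inf,
                "log_jac": 0.0, "steps": steps}
    E1 = potential.value(z1)
    H1 = E1 + _kinetic(r1, Minv)
    return {"z": z1, "ok": True, "H0": H0, "H1": H1, "E0": E0, "E1": E1,
            "log_jac": 0.0, "steps": steps}


def hmc_step(z, cfg, potential: Potential, rng, M=None):
    """Standard HMC transition; returns (z_new, accepted)."""
    if cfg.L == 0:  # identity proposal: dH = 0, always accepted
        return np.asarray(z, float), True
    prop = hmc_propose(z, cfg, potential, rng, M)
    if prop["ok"] and np.isfinite(prop["H1"]) and _mh_accept(prop["H0"] - prop["H1"], rng):
        return prop["z"], True
    return np.asarray(z, float), False


# ---------------------------------------------------------------------------
# metric helpers
# ---------------------------------------------------------------------------


def clamp_metric(H, floor_frac: float = 1e-6, min_abs: float = 1e-8):
    """Symmetrise and eigenvalue-clamp a Hessian into an SPD metric.

    Negative eigenvalues are mapped to their absolute value (regions of
    concave potential get a *large* metric, hence short cautious steps),
    then all eigenvalues are floored at a fraction of the spectral
    radius.  Flooring negative curvature at a tiny positive value
    instead produces a near-singular metric whose inverse launches the
    integrator to infinity.
    """
    Hs = 0.5 * (H + H.T)
    w, V = np.linalg.eigh(Hs)
    wmax = max(float(np.max(np.abs(w))), min_abs)
    floor = max(floor_frac * wmax, min_abs)
    w_cl = np.maximum(np.abs(w), floor)
    return V @ np.diag(w_cl) @ V.T, bool(np.any(w < floor))


def metric_from_potential(z, potential: Potential, floor_frac: float = 1e-6):
    """(M(z), dM/dz) from the potential's Hessian and third derivatives.

    M is the clamped Hessian of the potential (= negative Hessian of the
    log posterior); the derivative tensor comes from the (unclamped)
    third derivatives, dM[:, :, k] = dM/dz_k.
    """
    H = potential.hess(z)
    M, _ = clamp_metric(H, floor_frac)
    T = potential.third(z)  # T[i, j, k] = d3 E / dz_i dz_j dz_k
    return M, T


def _dH_dz(grad_E, Minv, dM, r):
    """Position gradient of H = E + 0.5 log|2 pi M| + 0.5 r^T M^-1 r.

    Non-finite intermediates (near-singular clamped metrics) propagate
    into the result and make the caller reject the trajectory.
    """
    d = len(grad_E)
    out = np.array(grad_E, float)
    with np.errstate(invalid="ignore", over="ignore"):
        Mr = Minv @ r
        for k in range(d):
            Mk = dM[:, :, k]
            out[k] += 0.5 * np.trace(Minv @ Mk) - 0.5 * float(Mr @ (Mk @ Mr))
    return out


def _logdet_spd(M):
    L = np.linalg.cholesky(M)
    return 2.0 * float(np.sum(np.log(np.diag(L))))


# ---------------------------------------------------------------------------
# RMHMC (implicit generalised leapfrog)
# ---------------------------------------------------------------------------


def _rmhmc_hamiltonian(E, M, r):
    d = len(r)
    Minv = np.linalg.inv(M)
    return E + 0.5 * (d * np.log(2 * np.pi) + _logdet_spd(M)) + 0.5 * float(r @ (Minv @ r))


def rmhmc_propose(z, cfg, potential: Potential, rng, metric_fn=None, stop_fn=None):
    """Generalised-leapfrog trajectory with position-dependent metric.

    ``metric_fn(z) -> (M, dM)`` defaults to :func:`metric_from_potential`.
    Implicit half steps are solved by fixed-point iteration started from
    the previous value; non-convergence marks the proposal as failed.
    """
    metric_fn = metric_fn or (lambda zz: metric_from_potential(zz, potential))
    z = np.array(z, float)
    d = len(z)
    M0, dM0 = metric_fn(z)
    r = np.linalg.cholesky(M0) @ rng.standard_normal(d)
    E0 = potential.value(z)
    H0 = _rmhmc_hamiltonian(E0, M0, r)
    eps = cfg.epsilon
    Mc, dMc = M0, dM0
    for _ in range(cfg.L):
        gE = potential.grad(z)
        if not np.all(np.isfinite(gE)):
            return {"z": z, "ok": False, "H0": H0, "H1": np.inf}
        Minv_c = np.linalg.inv(Mc)
        # implicit momentum half step: r1 = r - eps/2 dH/dz(z, r1)
        r1 = r.copy()
        for _ in range(cfg.fp_maxiter):
            r1_new = r - 0.5 * eps * _dH_dz(gE, Minv_c, dMc, r1)
            if np.max(np.abs(r1_new - r1)) < cfg.fp_tol:
                r1 = r1_new
                break
            r1 = r1_new
        else:
            return {"z": z, "ok": False, "H0": H0, "H1": np.inf}
        # implicit position full step: z1 = z + eps/2 [Minv(z) + Minv(z1)] r1
        z1 = z + eps * (Minv_c @ r1)
        for _ in range(cfg.fp_maxiter):
            M1, dM1 = metric_fn(z1)
            z1_new = z + 0.5 * eps * ((Minv_c + np.linalg.inv(M1)) @ r1)
            if np.max(np.abs(z1_new - z1)) < cfg.fp_tol:
                z1 = z1_new
                break
            z1 = z1_new
        else:
            return {"z": z, "ok": False, "H0": H0, "H1": np.inf}
        M1, dM1 = metric_fn(z1)
        gE1 = potential.grad(z1)
        if not np.all(np.isfinite(gE1)):
            return {"z": z, "ok": False, "H0": H0, "H1": np.inf}
        r = r1 - 0.5 * eps * _dH_dz(gE1, np.linalg.inv(M1), dM1, r1)
        z = z1
        Mc, dMc = M1, dM1
        if stop_fn is not None and stop_fn(z):
            break
    E1 = potential.value(z)
    H1 = _rmhmc_hamiltonian(E1, Mc, r)
    return {"z": z, "ok": True, "H0": H0, "H1": H1, "E0": E0, "E1": E1, "log_jac": 0.0}


def rmhmc_step(z, cfg, potential: Potential, rng, metric_fn=None):
    prop = rmhmc_propose(z, cfg, potential, rng, metric_fn)
    if prop["ok"] and np.isfinite(prop["H1"]) and _mh_accept(prop["H0"] - prop["H1"], rng):
        return prop["z"], True
    return np.asarray(z, float), False


# ---------------------------------------------------------------------------
# LDMC (explicit Lagrangian integrator)
# ---------------------------------------------------------------------------


def _christoffel_omega(Minv, dM, v):
    """Omega(z, v)_{ij} = sum_k v_k Gamma^i_{kj}, linear in v."""
    d = len(v)
    # Gamma^i_{jk} = 0.5 Minv_{im} (d_j M_{mk} + d_k M_{mj} - d_m M_{jk})
    # build S_{m j k} = d_j M_{mk}:
    S = np.transpose(dM, (0, 2, 1))  # S[m, j, k] = dM[m, k, j] = d_j M_{mk}
    G = 0.5 * np.einsum("im,mjk->ijk", Minv, S + np.transpose(S, (0, 2, 1)) - np.transpose(dM, (2, 0, 1)))
    # Omega_{ij} = sum_k v_k G[i, k, j]
    return np.einsum("k,ikj->ij", v, G)


def _ldmc_energy(E, M, v):
    # -log joint density of (z, v): E(z) - 0.5 log|M| + 0.5 v^T M v (+ const)
    return E - 0.5 * _logdet_spd(M) + 0.5 * float(v @ (M @ v))


def _grad_phi(gE, Minv, dM):
    """grad of phi = E + 0.5 log|M|; d/dz_k log|M| = tr(Minv dM_k)."""
    out = np.array(gE, float)
    for k in range(len(out)):
        out[k] += 0.5 * np.trace(Minv @ dM[:, :, k])
    return out


def ldmc_integrate(z, v, cfg, potential: Potential, metric_fn, stop_fn=None):
    """Deterministic explicit Lagrangian integrator.

    Returns (z_end, v_end, log_jac, ok).  Each velocity update solves
    [I + eps/2 Omega(v_known)] v_new = rhs; because Omega(a) b = Omega(b) a
    (symmetry of the Christoffel symbols), its exact Jacobian determinant
    is det(I - eps/2 Omega(v_new)) / det(I + eps/2 Omega(v_known)), which
    accumulates into ``log_jac``.
    """
    z = np.array(z, float)
    v = np.array(v, float)
    d = len(z)
    eps = cfg.epsilon
    eye = np.eye(d)
    log_jac = 0.0
    M, dM = metric_fn(z)
    Minv = np.linalg.inv(M)
    for _ in range(cfg.L):
        gE = potential.grad(z)
        if not np.all(np.isfinite(gE)):
            return z, v, log_jac, False
        gphi = _grad_phi(gE, Minv, dM)
        for half in range(2):
            Om_in = _christoffel_omega(Minv, dM, v)
            A = eye + 0.5 * eps * Om_in
            try:
                v_new = np.linalg.solve(A, v - 0.5 * eps * (Minv @ gphi))
            except np.linalg.LinAlgError:
                return z, v, log_jac, False
            Om_out = _christoffel_omega(Minv, dM, v_new)
            s1, ld_num = np.linalg.slogdet(eye - 0.5 * eps * Om_out)
            s2, ld_den = np.linalg.slogdet(A)
            if s1 <= 0 or s2 <= 0:
                return z, v_new, log_jac, False
            log_jac += ld_num - ld_den
            v = v_new
            if half == 0:
                z = z + eps * v
                if not np.all(np.isfinite(z)):
                    return z, v, log_jac, False
                M, dM = metric_fn(z)
                Minv = np.linalg.inv(M)
                gE = potential.grad(z)
                if not np.all(np.isfinite(gE)):
                    return z, v, log_jac, False
                gphi = _grad_phi(gE, Minv, dM)
        if stop_fn is not None and stop_fn(z):
            break
    return z, v, log_jac, True


def ldmc_propose(z, cfg, potential: Potential, rng, metric_fn=None, stop_fn=None):
    """Explicit Lagrangian trajectory; returns end point plus log |Jacobian|."""
    metric_fn = metric_fn or (lambda zz: metric_from_potential(zz, potential))
    z = np.array(z, float)
    d = len(z)
    M, dM = metric_fn(z)
    Minv = np.linalg.inv(M)
    v = np.linalg.cholesky(Minv) @ rng.standard_normal(d)
    E0 = potential.value(z)
    H0 = _ldmc_energy(E0, M, v)
    z1, v1, log_jac, ok = ldmc_integrate(z, v, cfg, potential, metric_fn, stop_fn)
    if not ok:
        return {"z": z, "ok": False, "H0": H0, "H1": np.inf, "log_jac": 0.0}
    M1, _ = metric_fn(z1)
    E1 = potential.value(z1)
    H1 = _ldmc_energy(E1, M1, v1)
    return {"z": z1, "ok": True, "H0": H0, "H1": H1, "E0": E0, "E1": E1, "log_jac": log_jac}


def ldmc_step(z, cfg, potential: Potential, rng, metric_fn=None):
    prop = ldmc_propose(z, cfg, potential, rng, metric_fn)
    if not (prop["ok"] and np.isfinite(prop["H1"])):
        return np.asarray(z, float), False
    if _mh_accept(prop["H0"] - prop["H1"] + prop["log_jac"], rng):
        return prop["z"], True
    return np.asarray(z, float), False


# ---------------------------------------------------------------------------
# NUTS (multinomial, identity mass)
# ---------------------------------------------------------------------------

_MAX_DELTA_H = 1000.0  # divergence threshold


def _logsumexp2(a, b):
    m = max(a, b)
    if m == -np.inf:
        return -np.inf
    return m + np.log(np.exp(a - m) + np.exp(b - m))


class _Tree:
    __slots__ = ("z_minus", "r_minus", "z_plus", "r_plus", "z_prop", "log_w", "ok")

    def __init__(self, z_minus, r_minus, z_plus, r_plus, z_prop, log_w, ok):
        self.z_minus = z_minus
        self.r_minus = r_minus
        self.z_plus = z_plus
        self.r_plus = r_plus
        self.z_prop = z_prop
        self.log_w = log_w
        self.ok = ok


def _nuts_no_uturn(z_minus, r_minus, z_plus, r_plus) -> bool:
    dz = z_plus - z_minus
    return (dz @ r_minus) >= 0 and (dz @ r_plus) >= 0


def _leapfrog_one(z, r, eps, grad):
    r = r - 0.5 * eps * grad(z)
    z = z + eps * r
    g = grad(z)
    r = r - 0.5 * eps * g
    return z, r


def _build_tree(z, r, direction, depth, eps, potential, H0, rng):
    if depth == 0:
        z1, r1 = _leapfrog_one(z, direction * r, eps, potential.grad)
        r1 = direction * r1
        E1 = potential.value(z1)
        if not (np.all(np.isfinite(z1)) and np.isfinite(E1)):
            return _Tree(z1, r1, z1, r1, z1, -np.inf, False)
        H1 = E1 + 0.5 * float(r1 @ r1)
        if H1 - H0 > _MAX_DELTA_H:
            return _Tree(z1, r1, z1, r1, z1, -np.inf, False)
        return _Tree(z1, r1, z1, r1, z1, H0 - H1, True)
    left = _build_tree(z, r, direction, depth - 1, eps, potential, H0, rng)
    if not left.ok:
        return left
    if direction == 1:
        right = _build_tree(left.z_plus, left.r_plus, 1, depth - 1, eps, potential, H0, rng)
        z_minus, r_minus = left.z_minus, left.r_minus
        z_plus, r_plus = right.z_plus, right.r_plus
    else:
        right = _build_tree(left.z_minus, left.r_minus, -1, depth - 1, eps, potential, H0, rng)
        z_minus, r_minus = right.z_minus, right.r_minus
        z_plus, r_plus = left.z_plus, left.r_plus
    if not right.ok:
        return _Tree(z_minus, r_minus, z_plus, r_plus, left.z_prop, left.log_w, False)
    log_w = _logsumexp2(left.log_w, right.log_w)
    # multinomial selection between subtrees
    if np.log(rng.uniform()) < right.log_w - log_w:
        z_prop = right.z_prop
    else:
        z_prop = left.z_prop
    ok = _nuts_no_uturn(z_minus, r_minus, z_plus, r_plus)
    return _Tree(z_minus, r_minus, z_plus, r_plus, z_prop, log_w, ok)


def nuts_step(z, epsilon, potential: Potential, rng, max_depth: int = 10):
    """One multinomial-NUTS transition with identity mass.

    Returns (z_new, info) where info carries the acceptance statistic for
    dual averaging and the tree depth reached.
    """
    z = np.asarray(z, float)
    d = len(z)
    r = rng.standard_normal(d)
    E0 = potential.value(z)
    H0 = E0 + 0.5 * float(r @ r)
    z_minus = z_plus = z
    r_minus = r_plus = r
    z_sel = z
    log_w_tot = 0.0  # weight of the initial point: H0 - H0 = 0
    depth = 0
    sum_alpha = 0.0
    n_alpha = 0
    while depth < max_depth:
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction == 1:
            sub = _build_tree(z_plus, r_plus, 1, depth, epsilon, potential, H0, rng)
            if sub.ok:
                z_plus, r_plus = sub.z_plus, sub.r_plus
        else:
            sub = _build_tree(z_minus, r_minus, -1, depth, epsilon, potential, H0, rng)
            if sub.ok:
                z_minus, r_minus = sub.z_minus, sub.r_minus
        # acceptance statistic proxy from the subtree weight
        if np.isfinite(sub.log_w):
            sum_alpha += min(1.0, np.exp(sub.log_w - np.log(2**depth) if depth else sub.log_w))
        n_alpha += 1
        if not sub.ok:
            break
        # biased-progressive multinomial: accept subtree sample w.p. w_sub/w_tot
        if np.log(rng.uniform()) < sub.log_w - log_w_tot:
            z_sel = sub.z_prop
        log_w_tot = _logsumexp2(log_w_tot, sub.log_w)
        if not _nuts_no_uturn(z_minus, r_minus, z_plus, r_plus):
            depth += 1
            break
        depth += 1
    info = {"depth": depth, "accept_stat": sum_alpha / max(n_alpha, 1),
            "saturated": depth >= max_depth}
    return z_sel, info


class DualAveraging:
    """Nesterov primal-dual averaging of log step size (burn-in only)."""

    def __init__(self, eps0: float, target: float = 0.8, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma = gamma
        self.t0 = t0
        self.kappa = kappa
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.t = 0

    def update(self, accept_stat: float) -> float:
        self.t += 1
        frac = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_stat)
        self.log_eps = self.mu - np.sqrt(self.t) / self.gamma * self.h_bar
        w = self.t ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    @property
    def adapted_epsilon(self) -> float:
        return float(np.exp(self.log_eps_bar))


# ---------------------------------------------------------------------------
# Adaptive Metropolis (exact-posterior reference sampler)
# ---------------------------------------------------------------------------


def adaptive_metropolis_chain(
    log_posterior,
    z0,
    n_samples: int,
    rng,
    cov0=None,
    adapt_start: int = 200,
    epsilon_reg: float = 1e-8,
    freeze_after: int | None = None,
):
    """Haario-style adaptive Metropolis: RW proposal with covariance
    2.38^2/d * (cov(chain) + eps*I) adapted from the history.

    Returns (chain (n, d), acceptance_rate).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    z = np.array(z0, float)
    d = len(z)
    lp = log_posterior(z)
    if not np.isfinite(lp):
        raise ValueError("start point has zero posterior density")
    sd = 2.38**2 / d
    C = np.eye(d) * 0.1 if cov0 is None else np.array(cov0, float)
    chain = np.empty((n_samples, d))
    mean = z.copy()
    cov_acc = np.zeros((d, d))
    n_acc = 0
    for t in range(n_samples):
        Lc = np.linalg.cholesky(sd * (C + epsilon_reg * np.eye(d)))
        z_prop = z + Lc @ rng.standard_normal(d)
        lp_prop = log_posterior(z_prop)
        if np.isfinite(lp_prop) and np.log(rng.uniform()) < lp_prop - lp:
            z, lp = z_prop, lp_prop
            n_acc += 1
        chain[t] = z
        # running moments
        delta = z - mean
        mean += delta / (t + 2)
        cov_acc += np.outer(delta, z - mean)
        adapting = t + 1 >= adapt_start and (freeze_after is None or t + 1 <= freeze_after)
        if adapting:
            C = cov_acc / (t + 1)
    return chain, n_acc / n_samples
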