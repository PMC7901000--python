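"""1D pulse-wave propagation on an arterial tree with Windkessel outlets.

Solves the cross-sectionally averaged mass/momentum equations

    A_t + q_x = 0
    q_t + (q^2/A)_x + (A/rho) p_x = -2 pi nu r / delta * q/A

closed by the elastic tube law  p = p0 + (4/3) s (1 - sqrt(A0/A)),
on a rooted binary tree of vessel segments.  Flow is prescribed at the
inlet of the root vessel, junctions enforce flow conservation and pressure
continuity, and each terminal vessel is coupled to a 3-element Windkessel
(R1, R2, C) through its frequency-domain impedance.

Units are CGS internally (cm, s, g); pressures cross the API in mmHg and
Windkessel elements in mmHg s/ml and ml/mmHg.  The integrator is the
two-step (Richtmyer) Lax-Wendroff scheme; boundary and junction coupling
uses the Riemann invariants u -/+ 4c of the hyperbolic system.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "MMHG",
    "FluidConstants",
    "VesselSegment",
    "WindkesselParams",
    "VesselNetwork",
    "InflowWaveform",
    "SolverGrid",
    "HemodynamicSolution",
    "InvalidParameterError",
    "constitutive_pressure",
    "wave_speed",
    "windkessel_impedance",
    "windkessel_outflow",
    "scale_windkessel",
    "solve_network",
    "mpa_pressure",
    "check_validity",
    "load_network",
    "save_network",
    "load_waveform_csv",
    "save_waveform_csv",
]

#: dyn/cm^2 per mmHg
MMHG = 1333.22


class InvalidParameterError(ValueError):
    """Raised for parameter values outside the physical domain of an operation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FluidConstants:
    """Blood properties and cardiac timing.

    rho : blood density, g/ml (1.055 for mouse blood)
    mu : dynamic viscosity, g/(cm s)
    p0 : transmural reference pressure, mmHg (pressure at A = A0)
    T_cycle : length of one cardiac cycle, s
    """

    rho: float = 1.055
    mu: float = 0.049
    p0: float = 0.0
    T_cycle: float = 0.11

    def __post_init__(self):
        if self.rho <= 0 or self.mu <= 0 or self.T_cycle <= 0:
            raise InvalidParameterError("rho, mu and T_cycle must be positive")

    @property
    def delta(self) -> float:
        """Boundary-layer thickness sqrt(nu T / 2 pi), cm."""
        return float(np.sqrt(self.mu / self.rho * self.T_cycle / (2.0 * np.pi)))


@dataclass(frozen=True)
class VesselSegment:
    """An elastic vessel segment with (optionally linearly tapered) radius."""

    id: str
    length: float  # cm
    r_prox: float  # proximal radius, cm
    r_dist: float | None = None  # distal radius; None = constant radius

    def __post_init__(self):
        if self.length <= 0:
            raise InvalidParameterError(f"segment {self.id}: length must be > 0")
        rd = self.r_prox if self.r_dist is None else self.r_dist
        if self.r_prox <= 0 or rd <= 0:
            raise InvalidParameterError(f"segment {self.id}: radii must be > 0")

    def area_unstressed(self, xi: np.ndarray) -> np.ndarray:
        """A0 at relative positions xi in [0, 1] along the segment, cm^2."""
        rd = self.r_prox if self.r_dist is None else self.r_dist
        r = self.r_prox + (rd - self.r_prox) * np.asarray(xi, dtype=float)
        return np.pi * r**2


@dataclass(frozen=True)
class WindkesselParams:
    """3-element Windkessel: proximal/distal resistance (mmHg s/ml), compliance (ml/mmHg)."""

    R1: float
    R2: float
    C: float

    def __post_init__(self):
        if self.R1 <= 0 or self.R2 <= 0 or self.C <= 0:
            raise InvalidParameterError("Windkessel elements must be positive")


@dataclass(frozen=True)
class VesselNetwork:
    """Rooted binary tree of vessel segments with per-terminal nominal Windkessels.

    ``children`` maps a parent segment id to its two daughter ids; every
    segment absent from ``children`` is a terminal and must carry a nominal
    Windkessel triple (R01, R02, C0) in ``nominal_windkessel``.
    """

    segments: tuple[VesselSegment, ...]
    children: dict[str, tuple[str, str]]
    root: str
    nominal_windkessel: dict[str, tuple[float, float, float]]

    def __post_init__(self):
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate segment ids")
        idset = set(ids)
        if self.root not in idset:
            raise ValueError("root id not among segments")
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            sid = stack.pop()
            if sid in seen:
                raise ValueError("network connectivity is not a tree")
            seen.add(sid)
            kids = self.children.get(sid, ())
            if kids:
                if len(kids) != 2:
                    raise ValueError(f"{sid}: non-leaf must have exactly two children")
                stack.extend(kids)
        if seen != idset:
            raise ValueError("segments not reachable from root")
        for sid in idset:
            if sid not in self.children and sid not in self.nominal_windkessel:
                raise ValueError(f"terminal {sid} lacks a nominal Windkessel triple")

    @property
    def terminals(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.segments if s.id not in self.children)

    def segment(self, sid: str) -> VesselSegment:
        for s in self.segments:
            if s.id == sid:
                return s
        raise KeyError(sid)


@dataclass(frozen=True)
class InflowWaveform:
    """Periodic inlet flow over one cardiac cycle: times (s), flows (ml/s)."""

    times: np.ndarray
    flows: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, float)
        f = np.asarray(self.flows, float)
        if t.shape != f.shape or t.ndim != 1 or len(t) < 2:
            raise ValueError("times and flows must be equal-length 1D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "flows", f)

    def at(self, t: np.ndarray, T: float) -> np.ndarray:
        """Flow at times t, interpreting the waveform as T-periodic."""
        tt = np.mod(np.asarray(t, float), T)
        tp = np.concatenate([self.times, [self.times[0] + T]])
        fp = np.concatenate([self.flows, [self.flows[0]]])
        return np.interp(tt, tp, fp)


@dataclass(frozen=True)
class SolverGrid:
    """Discretisation controls for the Lax-Wendroff solver.

    nx_per_cm : spatial nodes per cm of vessel (>= 2)
    cfl : Courant safety factor in (0, 1)
    n_cycles : cardiac cycles integrated before the recorded output cycle
    output_points : number of samples kept per cycle in the output series
    s_ref : reference stiffness (g/cm/s^2) fixing the time step.  The
        step is sized for the wave speed at ``s_ref`` (with 30% headroom
        for within-cycle speed growth), independently of the stiffness
        being simulated, so the discrete solution map is continuous in
        the parameters — a requirement for emulating its residual
        surface with a smooth GP.  Defaults to the upper prior bound.
    """

    nx_per_cm: float = 6.0
    cfl: float = 0.9
    n_cycles: int = 5
    output_points: int = 128
    s_ref: float = 5.0e5

    def __post_init__(self):
        if self.nx_per_cm < 2:
            raise ValueError("nx_per_cm must be >= 2")
        if not 0 < self.cfl < 1:
            raise ValueError("cfl must lie in (0, 1)")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


@dataclass
class HemodynamicSolution:
    """Final-cycle fields on the space-time grid, plus a validity label."""

    valid: bool
    failure_reason: str
    times: np.ndarray  # (nt,) s, relative to cycle start
    node_x: dict[str, np.ndarray]  # per-segment node coordinates, cm
    A: dict[str, np.ndarray]  # per-segment (nt, nx) cm^2
    q: dict[str, np.ndarray]  # per-segment (nt, nx) ml/s
    p: dict[str, np.ndarray]  # per-segment (nt, nx) mmHg
    root: str = ""
    cycle_delta_mmhg: float = np.nan  # max |p - p_prev_cycle| at the inlet node
    cycle_deltas: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# constitutive law and Windkessel
# ---------------------------------------------------------------------------


def constitutive_pressure(A, A0, s, p0: float = 0.0):
    """Tube-law pressure p = p0 + (4/3) s (1 - sqrt(A0/A)), in mmHg.

    ``s`` is the wall stiffness in g/cm/s^2 (CGS stress); the elastic term
    is converted to mmHg with 1 mmHg = 1333.22 g/(cm s^2).
    """
    A = np.asarray(A, float)
    A0 = np.asarray(A0, float)
    if np.any(A <= 0) or np.any(A0 <= 0) or s <= 0:
        raise InvalidParameterError("A, A0 and s must be positive")
    return p0 + (4.0 / 3.0) * s * (1.0 - np.sqrt(A0 / A)) / MMHG


def wave_speed(A, A0, s, rho: float = 1.055):
    """Local pulse-wave speed c = sqrt((2 s / 3 rho) sqrt(A0/A)), cm/s."""
    A = np.asarray(A, float)
    A0 = np.asarray(A0, float)
    return np.sqrt(2.0 * s / (3.0 * rho) * np.sqrt(A0 / A))


def windkessel_impedance(wk: WindkesselParams, omega):
    """Input impedance Z(w) = R1 + R2 / (1 + i w C R2) of a 3-element Windkessel."""
    omega = np.asarray(omega, float)
    return wk.R1 + wk.R2 / (1.0 + 1j * omega * wk.C * wk.R2)


def windkessel_outflow(times: np.ndarray, pressures: np.ndarray, wk: WindkesselParams) -> np.ndarray:
    """Flow through a Windkessel driven by a one-period pressure series.

    ``times`` must be a uniform grid t_j = t0 + j*dt covering exactly one
    period (no duplicated endpoint); the flow is obtained harmonic by
    harmonic as Q(w_k) = P(w_k) / Z(w_k) with w_k = 2 pi k / T.
    Pressure in mmHg yields flow in ml/s.
    """
    t = np.asarray(times, float)
    p = np.asarray(pressures, float)
    if t.shape != p.shape or t.ndim != 1 or len(t) < 2:
        raise InvalidParameterError("times and pressures must be equal-length 1D arrays")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
        raise InvalidParameterError("pressure history must be on a uniform grid")
    n = len(t)
    T = n * dt[0]
    P = np.fft.rfft(p)
    omega = 2.0 * np.pi * np.arange(len(P)) / T
    Q = P / windkessel_impedance(wk, omega)
    return np.fft.irfft(Q, n=n)


def scale_windkessel(nominal: tuple[float, float, float], r1: float, r2: float, c: float) -> WindkesselParams:
    """Scale a nominal triple elementwise by (1 - 0.5*r): R1 = (1-0.5 r1) R01 etc."""
    R01, R02, C0 = nominal
    R1 = (1.0 - 0.5 * r1) * R01
    R2 = (1.0 - 0.5 * r2) * R02
    C = (1.0 - 0.5 * c) * C0
    if R1 <= 0 or R2 <= 0 or C <= 0:
        raise InvalidParameterError(
            f"scaled Windkessel not positive: R1={R1:.3g} R2={R2:.3g} C={C:.3g}"
        )
    return WindkesselParams(R1, R2, C)


# ---------------------------------------------------------------------------
# Lax-Wendroff kernel (numba)
# ---------------------------------------------------------------------------
# State is packed into flat node arrays; per-segment slices are given by
# (off[i], nx[i]).  All quantities CGS.  Status codes returned by the kernel:
STATUS_OK = 0
STATUS_NONFINITE = 1
STATUS_NEG_AREA = 2
STATUS_CFL = 3
STATUS_JUNCTION = 4

_STATUS_MSG = {
    STATUS_OK: "",
    STATUS_NONFINITE: "non-finite state",
    STATUS_NEG_AREA: "non-positive cross-sectional area",
    STATUS_CFL: "CFL violation",
    STATUS_JUNCTION: "junction Newton solve did not converge",
}


@njit(cache=True, fastmath=False)
def _tube_p(A, A0, s):  # CGS pressure
    return (4.0 / 3.0) * s * (1.0 - np.sqrt(A0 / A))


@njit(cache=True, fastmath=False)
def _c(A, A0, s, rho):
    return np.sqrt(2.0 * s / (3.0 * rho) * np.sqrt(A0 / A))


@njit(cache=True, fastmath=False)
def _solve_outlet_A(A_init, A_old, A0, s, rho, kcell, qh_last, y0, conv_known, p0_cgs):
    """Conservative outlet closure: the boundary half-cell mass balance
    (A - A_old) * kcell = qh_last - q_wk(A) with the Windkessel flow
    q_wk(A) = y0 * p(A) + conv_known solved implicitly for A."""
    A = A_init
    for _ in range(60):
        pw = p0_cgs + _tube_p(A, A0, s)
        qL = y0 * pw + conv_known
        f = (A - A_old) * kcell - (qh_last - qL)
        dpdA = (2.0 / 3.0) * s * np.sqrt(A0) / A**1.5
        df = kcell + y0 * dpdA
        step = f / df
        if A - step <= 0.0:
            A *= 0.5
            continue
        A = A - step
        if abs(f) < 1e-12 * (abs(qh_last) + abs(qL) + 1e-6):
            return A, True
    pw = p0_cgs + _tube_p(A, A0, s)
    qL = y0 * pw + conv_known
    f = (A - A_old) * kcell - (qh_last - qL)
    return A, abs(f) < 1e-8 * (abs(qh_last) + abs(qL) + 1e-6)


@njit(cache=True, fastmath=False)
def _junction_newton(Ap, A1, A2, A0p, A01, A02, kp, k1, k2,
                     qhp, qh1, qh2, Ap0, A10, A20, s, rho):
    """Conservative junction closure.

    Unknowns are the three boundary areas; the flows follow from the
    half-cell mass balances q_p = qhp - kp (Ap - Ap0) (parent outlet) and
    q_i = qhi + ki (Ai - Ai0) (daughter inlets); the residuals enforce
    flow conservation and pressure continuity.  Returns (Ap, A1, A2, ok).
    """
    for _ in range(30):
        qp = qhp - kp * (Ap - Ap0)
        q1 = qh1 + k1 * (A1 - A10)
        q2 = qh2 + k2 * (A2 - A20)
        pp = _tube_p(Ap, A0p, s)
        p1 = _tube_p(A1, A01, s)
        p2 = _tube_p(A2, A02, s)
        r0 = qp - q1 - q2
        r1 = pp - p1
        r2 = pp - p2
        scale_q = abs(qp) + abs(q1) + abs(q2) + 1e-6
        scale_p = abs(pp) + abs(p1) + abs(p2) + 1.0
        if abs(r0) < 1e-10 * scale_q and abs(r1) < 1e-10 * scale_p and abs(r2) < 1e-10 * scale_p:
            return Ap, A1, A2, True
        dpp = (2.0 / 3.0) * s * np.sqrt(A0p) / Ap**1.5
        dp1 = (2.0 / 3.0) * s * np.sqrt(A01) / A1**1.5
        dp2 = (2.0 / 3.0) * s * np.sqrt(A02) / A2**1.5
        # rows: [-kp, -k1, -k2], [dpp, -dp1, 0], [dpp, 0, -dp2];
        # eliminate dA1 = (dpp dAp - r1)/dp1, dA2 likewise
        denom = -kp - dpp * (k1 / dp1 + k2 / dp2)
        if denom == 0.0 or not np.isfinite(denom):
            return Ap, A1, A2, False
        dAp = (r0 + k1 * r1 / dp1 + k2 * r2 / dp2) / denom
        dA1 = (dpp * dAp - r1) / dp1
        dA2 = (dpp * dAp - r2) / dp2
        if Ap - dAp <= 0.0:
            dAp = 0.5 * Ap
        if A1 - dA1 <= 0.0:
            dA1 = 0.5 * A1
        if A2 - dA2 <= 0.0:
            dA2 = 0.5 * A2
        Ap -= dAp
        A1 -= dA1
        A2 -= dA2
    # stalled at roundoff: accept if the residuals are still small
    qp = qhp - kp * (Ap - Ap0)
    q1 = qh1 + k1 * (A1 - A10)
    q2 = qh2 + k2 * (A2 - A20)
    pp = _tube_p(Ap, A0p, s)
    p1 = _tube_p(A1, A01, s)
    p2 = _tube_p(A2, A02, s)
    scale_q = abs(qp) + abs(q1) + abs(q2) + 1e-6
    scale_p = abs(pp) + abs(p1) + abs(p2) + 1.0
    ok = (
        abs(qp - q1 - q2) < 1e-8 * scale_q
        and abs(pp - p1) < 1e-8 * scale_p
        and abs(pp - p2) < 1e-8 * scale_p
    )
    return Ap, A1, A2, ok


@njit(cache=True, fastmath=False)
def _advance_cycle(
    A,
    q,
    off,
    nx,
    dx,
    A0,
    s,
    rho,
    fric,  # 2*pi*nu/delta
    dt,
    nsteps,
    q_in,  # (2*nsteps+1,) inlet flow at half-step resolution
    junc,  # (nj, 3) segment indices: parent, d1, d2
    outs,  # (no,) terminal segment indices
    y_adm,  # (no, nsteps) admittance impulse response, CGS flow per CGS pressure
    ph,  # (no, nsteps) circular outlet-pressure history, CGS (mutated)
    g_start,  # global time index of the cycle start (for the circular buffer)
    p0_cgs,
    root,
    rec_A,
    rec_q,
    record,
):
    nseg = len(nx)
    ntot = A.shape[0]
    Ah = np.empty(ntot)  # half-step values at j+1/2 (index j)
    qh = np.empty(ntot)
    if record:
        for k in range(ntot):
            rec_A[0, k] = A[k]
            rec_q[0, k] = q[k]
    for step in range(nsteps):
        # --- CFL / sanity check
        for i in range(nseg):
            o = off[i]
            for j in range(nx[i]):
                a = A[o + j]
                if not np.isfinite(a) or a <= 0.0 or not np.isfinite(q[o + j]):
                    return STATUS_NEG_AREA if (np.isfinite(a) and a <= 0.0) else STATUS_NONFINITE
                sp = abs(q[o + j] / a) + _c(a, A0[o + j], s, rho)
                if sp * dt > dx[i]:
                    return STATUS_CFL
        # --- half step (Richtmyer): values at cell interfaces.  The taper
        # source uses the one-sided A0 difference of the same cell so that
        # it cancels the elastic flux difference exactly at A = A0
        # (well-balanced at rest).
        for i in range(nseg):
            o = off[i]
            for j in range(nx[i] - 1):
                Al = A[o + j]
                Ar = A[o + j + 1]
                ql = q[o + j]
                qr = q[o + j + 1]
                A0l = A0[o + j]
                A0r = A0[o + j + 1]
                F2l = ql * ql / Al + (4.0 * s / (3.0 * rho)) * np.sqrt(A0l * Al)
                F2r = qr * qr / Ar + (4.0 * s / (3.0 * rho)) * np.sqrt(A0r * Ar)
                rl = np.sqrt(Al / np.pi)
                rr = np.sqrt(Ar / np.pi)
                fric_mid = -0.5 * fric * (rl * ql / Al + rr * qr / Ar)
                Amid = 0.5 * (Al + Ar)
                A0mid = 0.5 * (A0l + A0r)
                taper_mid = (4.0 * s / (3.0 * rho)) * np.sqrt(Amid / A0mid) * (A0r - A0l) / dx[i]
                Ah[o + j] = Amid - 0.5 * dt / dx[i] * (qr - ql)
                qh[o + j] = (
                    0.5 * (ql + qr)
                    - 0.5 * dt / dx[i] * (F2r - F2l)
                    + 0.5 * dt * (fric_mid + taper_mid)
                )
                if Ah[o + j] <= 0.0 or not np.isfinite(Ah[o + j]):
                    return STATUS_NEG_AREA
        # --- full step on interior nodes (taper source from the A0
        # difference across the two adjacent interfaces, same balance)
        Anew = np.empty(ntot)
        qnew = np.empty(ntot)
        for i in range(nseg):
            o = off[i]
            for j in range(1, nx[i] - 1):
                Al = Ah[o + j - 1]
                Ar = Ah[o + j]
                ql = qh[o + j - 1]
                qr = qh[o + j]
                A0l = 0.5 * (A0[o + j - 1] + A0[o + j])
                A0r = 0.5 * (A0[o + j] + A0[o + j + 1])
                F2l = ql * ql / Al + (4.0 * s / (3.0 * rho)) * np.sqrt(A0l * Al)
                F2r = qr * qr / Ar + (4.0 * s / (3.0 * rho)) * np.sqrt(A0r * Ar)
                rl = np.sqrt(Al / np.pi)
                rr = np.sqrt(Ar / np.pi)
                fric_node = -0.5 * fric * (rl * ql / Al + rr * qr / Ar)
                taper_node = (
                    (4.0 * s / (3.0 * rho))
                    * np.sqrt(A[o + j] / A0[o + j])
                    * (A0r - A0l) / dx[i]
                )
                Anew[o + j] = A[o + j] - dt / dx[i] * (qr - ql)
                qnew[o + j] = (
                    q[o + j]
                    - dt / dx[i] * (F2r - F2l)
                    + dt * (fric_node + taper_node)
                )
        # --- inlet of root: prescribed flow; area from the boundary
        # half-cell mass balance with the time-centred interface flux
        o = off[root]
        Ain = A[o] + 2.0 * dt / dx[root] * (q_in[2 * step + 1] - qh[o])
        if Ain <= 0.0 or not np.isfinite(Ain):
            return STATUS_NEG_AREA
        Anew[o] = Ain
        qnew[o] = q_in[2 * (step + 1)]
        # --- terminal outlets: Windkessel admittance convolution over the
        # trailing period, coupled through the conservative half-cell
        # mass balance
        g1 = g_start + step + 1  # global index of the new time level
        for k in range(len(outs)):
            i = outs[k]
            o = off[i]
            e = o + nx[i] - 1
            conv = 0.0
            for m in range(1, nsteps):
                conv += y_adm[k, m] * ph[k, (g1 - m) % nsteps]
            kcell = dx[i] / (2.0 * dt)
            AL, ok = _solve_outlet_A(
                A[e], A[e], A0[e], s, rho, kcell, qh[e - 1], y_adm[k, 0], conv, p0_cgs
            )
            if not ok or AL <= 0.0:
                return STATUS_JUNCTION
            pL = p0_cgs + _tube_p(AL, A0[e], s)
            ph[k, g1 % nsteps] = pL
            Anew[e] = AL
            qnew[e] = y_adm[k, 0] * pL + conv
        # --- junctions: conservative half-cell closure with flow
        # conservation and pressure continuity
        for k in range(junc.shape[0]):
            ip = junc[k, 0]
            i1 = junc[k, 1]
            i2 = junc[k, 2]
            ep = off[ip] + nx[ip] - 1
            o1 = off[i1]
            o2 = off[i2]
            kp = dx[ip] / (2.0 * dt)
            k1 = dx[i1] / (2.0 * dt)
            k2 = dx[i2] / (2.0 * dt)
            Ap, A1, A2, ok = _junction_newton(
                A[ep], A[o1], A[o2], A0[ep], A0[o1], A0[o2],
                kp, k1, k2, qh[ep - 1], qh[o1], qh[o2],
                A[ep], A[o1], A[o2], s, rho,
            )
            if not ok:
                return STATUS_JUNCTION
            Anew[ep] = Ap
            qnew[ep] = qh[ep - 1] - kp * (Ap - A[ep])
            Anew[o1] = A1
            qnew[o1] = qh[o1] + k1 * (A1 - A[o1])
            Anew[o2] = A2
            qnew[o2] = qh[o2] + k2 * (A2 - A[o2])
        for kk in range(ntot):
            A[kk] = Anew[kk]
            q[kk] = qnew[kk]
        if record:
            for kk in range(ntot):
                rec_A[step + 1, kk] = A[kk]
                rec_q[step + 1, kk] = q[kk]
    return STATUS_OK


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def _pack_network(network: VesselNetwork, grid: SolverGrid):
    """Order segments, build packed node arrays and topology index tables."""
    order = [s.id for s in network.segments]
    idx = {sid: i for i, sid in enumerate(order)}
    nseg = len(order)
    nx = np.empty(nseg, np.int64)
    dx = np.empty(nseg, float)
    for i, sid in enumerate(order):
        seg = network.segment(sid)
        n = max(3, int(round(seg.length * grid.nx_per_cm)) + 1)
        nx[i] = n
        dx[i] = seg.length / (n - 1)
    off = np.zeros(nseg, np.int64)
    off[1:] = np.cumsum(nx)[:-1]
    ntot = int(nx.sum())
    A0 = np.empty(ntot)
    for i, sid in enumerate(order):
        seg = network.segment(sid)
        xi = np.linspace(0.0, 1.0, nx[i])
        A0[off[i] : off[i] + nx[i]] = seg.area_unstressed(xi)
    junc = np.array(
        [[idx[p], idx[d1], idx[d2]] for p, (d1, d2) in network.children.items()],
        np.int64,
    ).reshape(-1, 3)
    outs = np.array([idx[t] for t in network.terminals], np.int64)
    return order, idx, nx, dx, off, A0, junc, outs


def solve_network(
    network: VesselNetwork,
    inflow: InflowWaveform,
    theta,
    const: FluidConstants = FluidConstants(),
    grid: SolverGrid = SolverGrid(),
) -> HemodynamicSolution:
    """Integrate the pulse-wave system for ``theta = (s, r1, r2, c)``.

    Runs ``grid.n_cycles`` cardiac cycles from rest (A = A0, q = 0) to damp
    the initial transient, then records one further cycle.  Terminal
    Windkessel outflows use the frequency-domain impedance driven by the
    previous cycle's outlet pressure (periodicity assumption); the first
    cycle is bootstrapped with p = p0.

    Parameter-induced failures (negative area, NaN, CFL violation,
    non-convergent junction solve, non-positive scaled Windkessel) never
    raise: they return a solution with ``valid=False`` — the label source
    for the feasibility classifier.  Malformed networks/grids do raise.
    """
    s, r1, r2, c = (float(v) for v in np.asarray(theta, float))
    if s <= 0:
        return _invalid("non-positive stiffness", network)
    try:
        wk = {t: scale_windkessel(network.nominal_windkessel[t], r1, r2, c) for t in network.terminals}
    except InvalidParameterError as err:
        return _invalid(str(err), network)

    order, idx, nx, dx, off, A0, junc, outs = _pack_network(network, grid)
    rho = const.rho
    nu = const.mu / rho
    fric = 2.0 * np.pi * nu / const.delta
    T = const.T_cycle
    p0_cgs = const.p0 * MMHG

    A = A0.copy()
    q = np.zeros_like(A)

    # parameter-independent time step: sized for the reference stiffness
    # (>= any simulated s) with 30% headroom for within-cycle speed growth
    s_dt = max(grid.s_ref, s)
    vmax0 = float(np.max(wave_speed(A, A0, s_dt, rho)))
    dt = grid.cfl * float(np.min(dx)) / (1.3 * vmax0)
    nsteps = int(np.ceil(T / dt))
    dt = T / nsteps

    t_half = np.arange(2 * nsteps + 1) * (dt / 2.0)
    q_in = inflow.at(t_half, T)

    # Admittance impulse responses over one cycle: y_m is the inverse DFT
    # of Y(w_k) = 1/Z(w_k) at the cardiac harmonics, so the outlet flow is
    # the one-period convolution q^n = sum_m y_m p^{n-m} (periodicity
    # assumption of the Windkessel coupling).  CGS flow per CGS pressure.
    no = len(outs)
    omega = 2.0 * np.pi * np.fft.fftfreq(nsteps, d=dt)
    y_adm = np.empty((no, nsteps))
    for k in range(no):
        wkk = wk[order[outs[k]]]
        Y = 1.0 / windkessel_impedance(wkk, omega)
        y_adm[k] = np.real(np.fft.ifft(Y)) / MMHG
    # history bootstrap: constant outlet pressure consistent with the mean
    # inflow through the total parallel terminal resistance
    q_mean = float(np.mean(inflow.at(np.arange(nsteps) * dt, T)))
    g_total = sum(1.0 / (wk[t].R1 + wk[t].R2) for t in network.terminals)
    p_boot_cgs = (const.p0 + q_mean / g_total) * MMHG
    ph = np.full((no, nsteps), p_boot_cgs)

    rec_A = np.empty((nsteps + 1, len(A)))
    rec_q = np.empty((nsteps + 1, len(A)))

    root_i = idx[network.root]
    inlet_node = off[root_i]
    p_inlet_prev = None
    cycle_deltas = []
    t_cycle_grid = np.arange(nsteps) * dt

    total_cycles = grid.n_cycles + 1
    for cyc in range(total_cycles):
        status = _advance_cycle(
            A, q, off, nx, dx, A0, s, rho, fric, dt, nsteps,
            q_in, junc, outs, y_adm, ph, cyc * nsteps, p0_cgs,
            root_i, rec_A, rec_q, True,
        )
        if status != STATUS_OK:
            return _invalid(_STATUS_MSG[status], network)
        if not np.all(np.isfinite(rec_A)) or np.any(rec_A <= 0):
            return _invalid(_STATUS_MSG[STATUS_NONFINITE], network)
        # periodicity burn-in diagnostic at the inlet node
        p_inlet = const.p0 + _tube_p_np(rec_A[:nsteps, inlet_node], A0[inlet_node], s) / MMHG
        if p_inlet_prev is not None:
            cycle_deltas.append(float(np.max(np.abs(p_inlet - p_inlet_prev))))
        p_inlet_prev = p_inlet

    # assemble the final recorded cycle
    times = np.arange(nsteps) * dt
    node_x: dict[str, np.ndarray] = {}
    A_out: dict[str, np.ndarray] = {}
    q_out_d: dict[str, np.ndarray] = {}
    p_out: dict[str, np.ndarray] = {}
    for i, sid in enumerate(order):
        sl = slice(off[i], off[i] + nx[i])
        node_x[sid] = dx[i] * np.arange(nx[i])
        A_out[sid] = rec_A[:nsteps, sl].copy()
        q_out_d[sid] = rec_q[:nsteps, sl].copy()
        p_out[sid] = const.p0 + _tube_p_np(rec_A[:nsteps, sl], A0[sl][None, :], s) / MMHG
    return HemodynamicSolution(
        valid=True,
        failure_reason="",
        times=times,
        node_x=node_x,
        A=A_out,
        q=q_out_d,
        p=p_out,
        root=network.root,
        cycle_delta_mmhg=cycle_deltas[-1] if cycle_deltas else np.nan,
        cycle_deltas=np.asarray(cycle_deltas),
    )


def _tube_p_np(A, A0, s):
    return (4.0 / 3.0) * s * (1.0 - np.sqrt(A0 / np.asarray(A, float)))


def _invalid(reason: str, network: VesselNetwork) -> HemodynamicSolution:
    return HemodynamicSolution(
        valid=False,
        failure_reason=reason,
        times=np.empty(0),
        node_x={},
        A={},
        q={},
        p={},
        root=network.root,
    )


def mpa_pressure(sol: HemodynamicSolution, n: int) -> np.ndarray:
    """Inlet-node pressure of the root segment resampled to n uniform points.

    The data convention is t_j = j*T/n over one cycle (periodic, no
    duplicated endpoint); resampling is linear with periodic wrap.
    """
    if not sol.valid:
        raise InvalidParameterError("cannot extract pressure from an invalid solution")
    t = sol.times
    p = sol.p[sol.root][:, 0]
    T = t[-1] + (t[1] - t[0])
    tq = np.arange(n) * T / n
    tp = np.concatenate([t, [t[0] + T]])
    pp = np.concatenate([p, [p[0]]])
    return np.interp(tq, tp, pp)


def check_validity(sol: HemodynamicSolution) -> int:
    """Binary success label: 1 for a valid simulation, 0 otherwise."""
    return 1 if sol.valid else 0


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def save_network(network: VesselNetwork, path) -> None:
    doc = {
        "segments": [
            {
                "id": s.id,
                "length_cm": s.length,
                "r_prox_cm": s.r_prox,
                "r_dist_cm": s.r_prox if s.r_dist is None else s.r_dist,
            }
            for s in network.segments
        ],
        "tree": {p: list(kids) for p, kids in network.children.items()},
        "root": network.root,
        "windkessel": {t: list(v) for t, v in network.nominal_windkessel.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_network(path) -> VesselNetwork:
    with open(path) as fh:
        doc = json.load(fh)
    segs = tuple(
        VesselSegment(d["id"], d["length_cm"], d["r_prox_cm"], d.get("r_dist_cm"))
        for d in doc["segments"]
    )
    return VesselNetwork(
        segments=segs,
        children={p: (k[0], k[1]) for p, k in doc["tree"].items()},
        root=doc["root"],
        nominal_windkessel={t: tuple(v) for t, v in doc["windkessel"].items()},
    )


def save_waveform_csv(path, times, values, header: str = "time_s,value") -> None:
    arr = np.column_stack([np.asarray(times, float), np.asarray(values, float)])
    np.savetxt(path, arr, delimiter=",", header=header, comments="")


def load_waveform_csv(path) -> tuple[np.ndarray, np.ndarray]:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return arr[:, 0], arr[:, 1]
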