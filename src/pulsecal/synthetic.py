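"""Synthetic study conditions: toy networks, inflows, data, test targets.

The measured mouse haemodynamics this methodology targets are not
redistributable, so every experiment here runs on synthetic analogues:

* mouse-scale toy vessel trees (segment lengths 0.2-1 cm, radii
  0.01-0.05 cm) with nominal per-terminal Windkessel triples allocated
  from a total peripheral resistance and compliance;
* a parametric pulsatile inflow (half-sine systolic ejection);
* one-cycle pressure data generated by the forward model at a known
  parameter vector with iid additive Gaussian noise;
* a fast closed-form "0D" pressure model for exactness studies where
  thousands of posterior evaluations are needed;
* analytic targets (correlated 4D Gaussian, 2D banana) with derivatives
  to third order for sampler validation;
* a wrapper that forces simulator failure on a prescribed region, giving
  a controlled ground truth for the feasibility classifier.

Default conditions: cardiac cycle T = 0.11 s and stroke volume 0.022 ml
(cardiac output ~0.2 ml/s, heart rate ~545 bpm), total peripheral
resistance 75 mmHg s/ml and total compliance 3e-3 ml/mmHg, placing mean
inlet pressure near 15 mmHg with ~10-25 mmHg pulse excursions — the
physiological range for a healthy mouse pulmonary circulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hemodynamics import (
    FluidConstants,
    InflowWaveform,
    SolverGrid,
    VesselNetwork,
    VesselSegment,
    mpa_pressure,
    solve_network,
)
from .posterior import ParameterBox

__all__ = [
    "SyntheticSpec",
    "toy_network",
    "nominal_windkessel",
    "synthetic_inflow",
    "generate_synthetic_pressure",
    "surrogate0d_model",
    "analytic_target",
    "failure_region_wrapper",
    "DEFAULT_T_CYCLE",
    "DEFAULT_STROKE_VOLUME",
]

DEFAULT_T_CYCLE = 0.11  # s
DEFAULT_STROKE_VOLUME = 0.022  # ml
DEFAULT_TOTAL_RESISTANCE = 75.0  # mmHg s/ml
DEFAULT_TOTAL_COMPLIANCE = 3.0e-3  # ml/mmHg


# ---------------------------------------------------------------------------
# geometry and boundary fixtures
# ---------------------------------------------------------------------------

_GEOMETRIES = {
    "single": {
        "segments": [("mpa", 0.8, 0.05, 0.045)],
        "tree": {},
    },
    "bifurcation3": {
        "segments": [
            ("mpa", 0.7, 0.05, 0.047),
            ("lpa", 0.55, 0.036, 0.032),
            ("rpa", 0.5, 0.034, 0.030),
        ],
        "tree": {"mpa": ("lpa", "rpa")},
    },
    "tree7": {
        "segments": [
            ("mpa", 0.7, 0.05, 0.047),
            ("lpa", 0.5, 0.036, 0.032),
            ("rpa", 0.45, 0.034, 0.030),
            ("l1", 0.35, 0.024, 0.021),
            ("l2", 0.3, 0.022, 0.019),
            ("r1", 0.32, 0.023, 0.020),
            ("r2", 0.28, 0.021, 0.018),
        ],
        "tree": {"mpa": ("lpa", "rpa"), "lpa": ("l1", "l2"), "rpa": ("r1", "r2")},
    },
}


def nominal_windkessel(
    terminal_areas: dict[str, float],
    total_peripheral_resistance: float = DEFAULT_TOTAL_RESISTANCE,
    total_compliance: float = DEFAULT_TOTAL_COMPLIANCE,
    r1_fraction: float = 0.2,
) -> dict[str, tuple[float, float, float]]:
    """Allocate nominal (R01, R02, C0) per terminal from network totals.

    Branch resistances split inversely proportional to terminal
    cross-sectional area so that the parallel combination reproduces the
    total (sum of 1/(R01+R02) = 1/R_total); R01:R02 = r1_fraction :
    1-r1_fraction.  Compliances split proportional to area and sum to the
    total.  This area-based rule is a fixture convention standing in for
    morphometry-derived boundary estimates of real networks.
    """
    if total_peripheral_resistance <= 0 or total_compliance <= 0:
        raise ValueError("totals must be positive")
    areas = {k: float(v) for k, v in terminal_areas.items()}
    if any(a <= 0 for a in areas.values()):
        raise ValueError("terminal areas must be positive")
    a_sum = sum(areas.values())
    out = {}
    for tid, a in areas.items():
        # conductance share = area share
        branch_R = total_peripheral_resistance * a_sum / a
        C0 = total_compliance * a / a_sum
        out[tid] = (r1_fraction * branch_R, (1.0 - r1_fraction) * branch_R, C0)
    return out


def toy_network(
    kind: str = "bifurcation3",
    total_peripheral_resistance: float = DEFAULT_TOTAL_RESISTANCE,
    total_compliance: float = DEFAULT_TOTAL_COMPLIANCE,
) -> VesselNetwork:
    """Mouse-scale toy arterial trees: 'single', 'bifurcation3' or 'tree7'."""
    if kind not in _GEOMETRIES:
        raise ValueError(f"unknown network kind {kind!r}; choose from {sorted(_GEOMETRIES)}")
    geo = _GEOMETRIES[kind]
    segs = tuple(VesselSegment(i, ln, rp, rd) for i, ln, rp, rd in geo["segments"])
    tree = dict(geo["tree"])
    terminals = [s.id for s in segs if s.id not in tree]
    areas = {t: float(np.pi * next(s for s in segs if s.id == t).r_dist ** 2) for t in terminals}
    wk = nominal_windkessel(areas, total_peripheral_resistance, total_compliance)
    return VesselNetwork(segments=segs, children=tree, root=segs[0].id, nominal_windkessel=wk)


def synthetic_inflow(
    T_cycle: float = DEFAULT_T_CYCLE,
    stroke_volume: float = DEFAULT_STROKE_VOLUME,
    systole_fraction: float = 0.4,
    n_points: int = 128,
) -> InflowWaveform:
    """Half-sine systolic ejection, zero diastolic flow, given stroke volume."""
    if not 0 < systole_fraction < 1:
        raise ValueError("systole_fraction must lie in (0, 1)")
    t = np.linspace(0.0, T_cycle, n_points, endpoint=False)
    ts = systole_fraction * T_cycle
    f = np.where(t < ts, np.sin(np.pi * t / ts), 0.0)
    # exact integral of the half-sine over one period: 2 ts / pi
    f *= stroke_volume / (2.0 * ts / np.pi)
    return InflowWaveform(t, f)


# ---------------------------------------------------------------------------
# synthetic data generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions for one synthetic data set.

    ``sigma2_true = 0.25`` mmHg^2 (sd 0.5 mmHg) emulates catheter
    measurement noise on a 10-25 mmHg signal.
    """

    theta_true: tuple = (2.0e5, 0.4, 0.3, -0.5)
    sigma2_true: float = 0.25
    n_points: int = 128
    seed: int = 0
    network_kind: str = "bifurcation3"
    T_cycle: float = DEFAULT_T_CYCLE
    stroke_volume: float = DEFAULT_STROKE_VOLUME
    systole_fraction: float = 0.4

    def __post_init__(self):
        box = ParameterBox.default()
        if not box.contains(np.asarray(self.theta_true)):
            raise ValueError("theta_true must lie inside the prior box")


def generate_synthetic_pressure(
    spec: SyntheticSpec,
    grid: SolverGrid | None = None,
    const: FluidConstants | None = None,
):
    """One noisy pressure data set y_i = m_i(theta_true) + N(0, sigma2_true).

    Returns dict with times, data, clean model output, the truth record
    and the network/inflow used (so the inference run shares them).
    """
    const = const or FluidConstants(T_cycle=spec.T_cycle)
    grid = grid or SolverGrid()
    network = toy_network(spec.network_kind)
    inflow = synthetic_inflow(spec.T_cycle, spec.stroke_volume, spec.systole_fraction)
    sol = solve_network(network, inflow, spec.theta_true, const, grid)
    if not sol.valid:
        raise ValueError(f"theta_true yields an invalid simulation: {sol.failure_reason}")
    m = mpa_pressure(sol, spec.n_points)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, np.sqrt(spec.sigma2_true), size=spec.n_points)
    times = np.arange(spec.n_points) * spec.T_cycle / spec.n_points
    return {
        "times": times,
        "data": m + noise,
        "clean": m,
        "theta_true": np.asarray(spec.theta_true, float),
        "sigma2_true": spec.sigma2_true,
        "network": network,
        "inflow": inflow,
        "const": const,
        "grid": grid,
        "seed": spec.seed,
    }


# ---------------------------------------------------------------------------
# fast 0D pressure model (closed form, for exactness studies)
# ---------------------------------------------------------------------------


def surrogate0d_model(theta, n_points: int = 64, box: ParameterBox | None = None) -> np.ndarray:
    """Cheap closed-form one-cycle pressure shape depending on all four
    parameters (through their box-normalised values).

    Not a physical model: a stand-in posterior whose likelihood costs
    microseconds, used where exactness comparisons need ~1e5 evaluations.
    """
    box = box or ParameterBox.default()
    th = np.asarray(theta, float)
    u = (th - box.lower) / (box.upper - box.lower)  # in (0,1)
    tau = np.arange(n_points) / n_points
    return (
        10.0
        + 6.0 * u[0]
        + 3.0 * u[1] * np.sin(2 * np.pi * tau)
        + 3.0 * u[2] * np.cos(2 * np.pi * tau)
        + 2.0 * u[3] * np.sin(4 * np.pi * tau)
    )


# ---------------------------------------------------------------------------
# analytic sampler-validation targets
# ---------------------------------------------------------------------------


def analytic_target(kind: str = "gauss4_corr"):
    """Closed-form potential bundles with known moments.

    'gauss4_corr': 4D zero-mean Gaussian with correlation 0.9 between
    coordinates (1,2) and (3,4) — mirrors the strong pairwise posterior
    correlations of the haemodynamic calibration.  'banana2': the classic
    curved 2D density with known mode at the origin-bend.
    Returns (Potential, info dict).
    """
    from .samplers import Potential

    if kind == "gauss4_corr":
        S = np.eye(4)
        S[0, 1] = S[1, 0] = 0.9
        S[2, 3] = S[3, 2] = 0.9
        P = np.linalg.inv(S)
        pot = Potential(
            value=lambda z: 0.5 * float(z @ P @ z),
            grad=lambda z: P @ z,
            hess=lambda z: P.copy(),
            third=lambda z: np.zeros((4, 4, 4)),
        )
        return pot, {"mean": np.zeros(4), "cov": S, "dim": 4}
    if kind == "banana2":
        b = 0.5

        def value(z):
            return 0.5 * z[0] ** 2 / 4.0 + 0.5 * (z[1] + b * z[0] ** 2 - 4 * b) ** 2

        def grad(z):
            w = z[1] + b * z[0] ** 2 - 4 * b
            return np.array([z[0] / 4.0 + 2 * b * z[0] * w, w])

        def hess(z):
            w = z[1] + b * z[0] ** 2 - 4 * b
            return np.array(
                [[0.25 + 2 * b * w + 4 * b**2 * z[0] ** 2, 2 * b * z[0]], [2 * b * z[0], 1.0]]
            )

        def third(z):
            T = np.zeros((2, 2, 2))
            T[0, 0, 0] = 12 * b**2 * z[0]
            T[0, 0, 1] = T[0, 1, 0] = T[1, 0, 0] = 2 * b
            return T

        pot = Potential(value=value, grad=grad, hess=hess, third=third)
        return pot, {"mode": np.array([0.0, 4 * b]), "dim": 2}
    raise ValueError(f"unknown analytic target {kind!r}")


# ---------------------------------------------------------------------------
# controlled failure regions
# ---------------------------------------------------------------------------


def failure_region_wrapper(simulate, forbidden_predicate):
    """Wrap a simulate(theta) -> (rss, label) callable so that any theta
    with ``forbidden_predicate(theta)`` True is forced to fail (rss=inf,
    label 0).  Gives a known ground-truth feasibility boundary for
    classifier tests."""

    def wrapped(theta):
        if forbidden_predicate(np.asarray(theta, float)):
            return np.inf, 0
        return simulate(theta)

    return wrapped
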