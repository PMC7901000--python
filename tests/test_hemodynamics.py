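"""Forward-solver checks: tube law, Windkessel, network integration."""

import json

import numpy as np
import pytest

from pulsecal.hemodynamics import (
    MMHG,
    FluidConstants,
    InflowWaveform,
    InvalidParameterError,
    SolverGrid,
    VesselNetwork,
    VesselSegment,
    WindkesselParams,
    check_validity,
    constitutive_pressure,
    load_network,
    load_waveform_csv,
    mpa_pressure,
    save_network,
    save_waveform_csv,
    scale_windkessel,
    solve_network,
    windkessel_impedance,
    windkessel_outflow,
)
from pulsecal.synthetic import synthetic_inflow, toy_network


class TestConstitutiveLaw:
    def test_reference_area_gives_reference_pressure(self):
        assert constitutive_pressure(0.01, 0.01, 2e5, p0=5.0) == pytest.approx(5.0)

    def test_large_area_limit(self):
        s = 3e5
        p = constitutive_pressure(1e9, 0.01, s, p0=0.0)
        assert p == pytest.approx(4.0 / 3.0 * s / MMHG, rel=1e-3)

    def test_quarter_area_negative_pressure(self):
        # A = A0/4 halves the radius: p = (4/3) s (1 - 2) in pressure units
        s = 3.0 * MMHG  # stiffness worth 3 mmHg of elastic stress
        assert constitutive_pressure(0.0025, 0.01, s, p0=0.0) == pytest.approx(-4.0)

    def test_monotone_in_area(self):
        A = np.linspace(0.002, 0.02, 50)
        p = constitutive_pressure(A, 0.01, 2e5)
        assert np.all(np.diff(p) > 0)

    @pytest.mark.parametrize("bad", [(-1.0, 0.01), (0.01, -1.0), (0.0, 0.01)])
    def test_invalid_arguments(self, bad):
        with pytest.raises(InvalidParameterError):
            constitutive_pressure(bad[0], bad[1], 1e5)


class TestWindkessel:
    def test_impedance_limits(self):
        wk = WindkesselParams(1.0, 2.0, 5.0)
        assert windkessel_impedance(wk, 0.0) == pytest.approx(3.0)
        assert abs(windkessel_impedance(wk, 1e9)) == pytest.approx(1.0, rel=1e-6)

    def test_impedance_complex_value(self):
        wk = WindkesselParams(1.0, 1.0, 1.0)
        assert windkessel_impedance(wk, 1.0) == pytest.approx(1.5 - 0.5j)

    def test_impedance_magnitude_monotone_to_r1(self):
        wk = WindkesselParams(1.0, 2.0, 5.0)
        mags = np.abs(windkessel_impedance(wk, np.logspace(-2, 4, 40)))
        assert np.all(np.diff(mags) < 0)
        assert mags[-1] > wk.R1

    def test_constant_pressure_gives_mean_flow(self):
        wk = WindkesselParams(2.0, 3.0, 0.01)
        t = np.arange(64) * (0.11 / 64)
        q = windkessel_outflow(t, np.full(64, 10.0), wk)
        assert np.allclose(q, 10.0 / 5.0)

    def test_zero_pressure_zero_flow(self):
        wk = WindkesselParams(2.0, 3.0, 0.01)
        t = np.arange(32) * (0.11 / 32)
        assert np.allclose(windkessel_outflow(t, np.zeros(32), wk), 0.0)

    def test_single_harmonic_response(self):
        wk = WindkesselParams(1.5, 4.0, 0.02)
        n, T = 128, 0.11
        t = np.arange(n) * T / n
        omega = 2 * np.pi / T
        p = 3.0 * np.cos(omega * t)
        q = windkessel_outflow(t, p, wk)
        Z = windkessel_impedance(wk, omega)
        q_exact = np.real(3.0 / Z * np.exp(1j * omega * t))
        assert np.allclose(q, q_exact, atol=1e-10)

    def test_nonuniform_grid_rejected(self):
        wk = WindkesselParams(1.0, 1.0, 1.0)
        t = np.array([0.0, 0.01, 0.03, 0.04])
        with pytest.raises(InvalidParameterError):
            windkessel_outflow(t, np.zeros(4), wk)


class TestWindkesselScaling:
    def test_zero_factors_identity(self):
        wk = scale_windkessel((10.0, 20.0, 0.5), 0.0, 0.0, 0.0)
        assert (wk.R1, wk.R2, wk.C) == (10.0, 20.0, 0.5)

    def test_upper_bound_r1(self):
        assert scale_windkessel((100.0, 1.0, 1.0), 1.92, 0.0, 0.0).R1 == pytest.approx(4.0)

    def test_lower_bound_c(self):
        assert scale_windkessel((1.0, 1.0, 1.0), 0.0, 0.0, -2.5).C == pytest.approx(2.25)

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidParameterError):
            scale_windkessel((1.0, 1.0, 1.0), 2.5, 0.0, 0.0)


class TestNetworkSolver:
    def test_steady_state_matches_lumped_circuit(self, single_network, const):
        """Steady inflow: outlet pressure = q * (R1 + R2) of the Windkessel."""
        t = np.linspace(0, const.T_cycle, 64, endpoint=False)
        q0 = 0.2
        steady = InflowWaveform(t, np.full(64, q0))
        sol = solve_network(single_network, steady, (2e5, 0, 0, 0), const,
                            SolverGrid(n_cycles=10))
        assert sol.valid
        R01, R02, _ = single_network.nominal_windkessel["mpa"]
        p_outlet = sol.p["mpa"][:, -1]
        assert p_outlet.mean() == pytest.approx(q0 * (R01 + R02), rel=0.02)
        assert p_outlet.std() < 0.05 * p_outlet.mean()

    def test_zero_inflow_equilibrium(self, single_network, const):
        t = np.linspace(0, const.T_cycle, 64, endpoint=False)
        sol = solve_network(single_network, InflowWaveform(t, np.zeros(64)),
                            (2e5, 0, 0, 0), const, SolverGrid(n_cycles=2))
        assert sol.valid
        assert np.allclose(sol.q["mpa"], 0.0, atol=1e-12)
        assert np.allclose(sol.p["mpa"], const.p0, atol=1e-10)

    def test_symmetric_bifurcation_splits_flow_equally(self, const, inflow):
        segs = (
            VesselSegment("mpa", 0.7, 0.05),
            VesselSegment("d1", 0.5, 0.035),
            VesselSegment("d2", 0.5, 0.035),
        )
        wk = {"d1": (30.0, 120.0, 1.5e-3), "d2": (30.0, 120.0, 1.5e-3)}
        net = VesselNetwork(segs, {"mpa": ("d1", "d2")}, "mpa", wk)
        sol = solve_network(net, inflow, (2e5, 0.2, 0.1, -0.3), const, SolverGrid(n_cycles=5))
        assert sol.valid
        q1, q2 = sol.q["d1"][:, 0], sol.q["d2"][:, 0]
        assert np.allclose(q1, q2, atol=1e-12)
        assert np.allclose(q1, 0.5 * sol.q["mpa"][:, -1], atol=1e-9)

    def test_junction_conservation_and_continuity(self, bifurcation_network, const, inflow):
        sol = solve_network(bifurcation_network, inflow, (2.5e5, 0.4, 0.2, -0.5),
                            const, SolverGrid(n_cycles=5))
        assert sol.valid
        q_p = sol.q["mpa"][:, -1]
        q_d = sol.q["lpa"][:, 0] + sol.q["rpa"][:, 0]
        assert np.max(np.abs(q_p - q_d)) < 1e-8
        assert np.max(np.abs(sol.p["mpa"][:, -1] - sol.p["lpa"][:, 0])) < 1e-8

    def test_cycle_convergence_monotone(self, single_network, const, inflow):
        sol = solve_network(single_network, inflow, (2e5, 0, 0, 0), const,
                            SolverGrid(n_cycles=6))
        d = sol.cycle_deltas
        assert len(d) == 6
        assert np.all(np.diff(d[1:]) < 0)
        assert d[-1] < 1.0  # mmHg, periodic to within the stated check

    def test_grid_refinement_second_order(self, single_network, const, inflow):
        series = []
        for f in (1, 2, 4):
            g = SolverGrid(nx_per_cm=6 * f, n_cycles=5)
            sol = solve_network(single_network, inflow, (2e5, 0, 0, 0), const, g)
            series.append(mpa_pressure(sol, 64))
        e_coarse = np.max(np.abs(series[0] - series[2]))
        e_fine = np.max(np.abs(series[1] - series[2]))
        assert e_coarse / e_fine > 2.0  # better than first order

    def test_invalid_parameters_label_not_raise(self, single_network, const, inflow):
        # r1 far outside the box drives R1 negative: flagged, not raised
        sol = solve_network(single_network, inflow, (2e5, 2.5, 0, 0), const, SolverGrid())
        assert not sol.valid
        assert sol.failure_reason
        assert check_validity(sol) == 0

    def test_validity_label_for_good_run(self, single_network, const, inflow):
        sol = solve_network(single_network, inflow, (2e5, 0, 0, 0), const,
                            SolverGrid(n_cycles=3))
        assert check_validity(sol) == 1


class TestPressureExtraction:
    def _fake_solution(self, p_series):
        n = len(p_series)
        return type(
            "S", (), {
                "valid": True,
                "times": np.arange(n) * (0.11 / n),
                "p": {"mpa": np.asarray(p_series)[:, None]},
                "root": "mpa",
            },
        )()

    def test_identity_resampling(self):
        p = np.sin(np.linspace(0, 2 * np.pi, 64, endpoint=False))
        sol = self._fake_solution(p)
        assert np.allclose(mpa_pressure(sol, 64), p)

    def test_constant_series(self):
        sol = self._fake_solution(np.full(32, 7.5))
        assert np.allclose(mpa_pressure(sol, 10), 7.5)

    def test_downsample_linear_ramp_midpoints(self):
        # 2:1 downsample of a sawtooth ramp hits the original nodes exactly
        p = np.arange(8, dtype=float)
        sol = self._fake_solution(p)
        out = mpa_pressure(sol, 4)
        assert np.allclose(out, [0.0, 2.0, 4.0, 6.0])

    def test_invalid_solution_rejected(self, single_network, const, inflow):
        sol = solve_network(single_network, inflow, (2e5, 2.5, 0, 0), const, SolverGrid())
        with pytest.raises(InvalidParameterError):
            mpa_pressure(sol, 16)


class TestNetworkValidation:
    def test_missing_windkessel_rejected(self):
        segs = (VesselSegment("a", 1.0, 0.05),)
        with pytest.raises(ValueError):
            VesselNetwork(segs, {}, "a", {})

    def test_single_child_rejected(self):
        segs = (VesselSegment("a", 1.0, 0.05), VesselSegment("b", 1.0, 0.03))
        with pytest.raises(ValueError):
            VesselNetwork(segs, {"a": ("b",)}, "a", {"b": (1, 1, 1)})

    def test_unreachable_segment_rejected(self):
        segs = (VesselSegment("a", 1.0, 0.05), VesselSegment("b", 1.0, 0.03))
        with pytest.raises(ValueError):
            VesselNetwork(segs, {}, "a", {"a": (1, 1, 1), "b": (1, 1, 1)})


class TestFileFormats:
    def test_network_json_roundtrip(self, tmp_path, bifurcation_network):
        path = tmp_path / "net.json"
        save_network(bifurcation_network, path)
        net2 = load_network(path)
        assert net2.root == bifurcation_network.root
        assert set(net2.terminals) == set(bifurcation_network.terminals)
        for sid in ("mpa", "lpa", "rpa"):
            assert net2.segment(sid).length == bifurcation_network.segment(sid).length
        doc = json.loads(path.read_text())
        assert {"segments", "tree", "root", "windkessel"} <= set(doc)

    def test_waveform_csv_roundtrip(self, tmp_path, inflow):
        path = tmp_path / "wave.csv"
        save_waveform_csv(path, inflow.times, inflow.flows)
        t, f = load_waveform_csv(path)
        assert np.allclose(t, inflow.times)
        assert np.allclose(f, inflow.flows)
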