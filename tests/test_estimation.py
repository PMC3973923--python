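"""Inverse problem, E/I decomposition, voltage reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from firingclamp.calibration import (
    FIG1_SURFACE,
    CalibrationSurface,
    SurfaceCoeffs,
)
from firingclamp.estimation import (
    ReversalSpec,
    compose,
    decompose,
    estimate_pipeline,
    invert_features,
    reconstruct_voltage,
)

REV = ReversalSpec(V_E_mV=0.0, V_I_mV=-74.0, V_0_mV=-76.8)


class TestInversion:
    def test_round_trip_on_worked_example_surface(self):
        vs, vp = FIG1_SURFACE.subthr(100.0, 2.0), FIG1_SURFACE.pulse(100.0, 2.0)
        # (100 pA, 2 nS) is inside a domain extended for this check
        surface = CalibrationSurface(
            subthr=FIG1_SURFACE.subthr,
            pulse=FIG1_SURFACE.pulse,
            I_domain_pA=(-50.0, 200.0),
            G_domain_nS=(0.0, 4.0),
        )
        I, G, status = invert_features(surface, vs, vp)
        assert status == "ok"
        assert I == pytest.approx(100.0, abs=1e-6)
        assert G == pytest.approx(2.0, abs=1e-6)

    def test_round_trip_grid_over_domain(self):
        surface = CalibrationSurface(
            subthr=FIG1_SURFACE.subthr,
            pulse=FIG1_SURFACE.pulse,
            I_domain_pA=(-50.0, 200.0),
            G_domain_nS=(0.0, 4.0),
        )
        for I0 in np.linspace(-50, 200, 6):
            for G0 in np.linspace(0, 4, 6):
                vs, vp = surface.subthr(I0, G0), surface.pulse(I0, G0)
                I, G, status = invert_features(surface, vs, vp)
                assert status == "ok"
                assert abs(I - I0) < 1e-6
                assert abs(G - G0) < 1e-6

    def test_origin_fixed_point(self):
        vs, vp = FIG1_SURFACE.subthr(0.0, 0.0), FIG1_SURFACE.pulse(0.0, 0.0)
        I, G, status = invert_features(FIG1_SURFACE, vs, vp)
        assert status == "ok"
        assert abs(I) < 1e-8 and abs(G) < 1e-8

    def test_degenerate_bilinear_matches_linear_solve(self):
        """With a_IG = 0 in both surfaces the system is linear; the
        closed-form path must agree with a direct 2x2 matrix solve."""
        surface = CalibrationSurface(
            subthr=SurfaceCoeffs(a_IG=0.0, a_I=0.08, a_G=0.8, a_0=-77.0),
            pulse=SurfaceCoeffs(a_IG=0.0, a_I=0.05, a_G=-0.5, a_0=-35.0),
            I_domain_pA=(-50.0, 200.0),
            G_domain_nS=(0.0, 4.0),
        )
        vs, vp = -70.0, -36.0
        A = np.array([[0.08, 0.8], [0.05, -0.5]])
        b = np.array([vs + 77.0, vp + 35.0])
        expected = np.linalg.solve(A, b)
        I, G, status = invert_features(surface, vs, vp)
        assert status == "ok"
        assert I == pytest.approx(expected[0], abs=1e-9)
        assert G == pytest.approx(expected[1], abs=1e-9)

    def test_unsolvable_features_fail_not_extrapolate(self):
        I, G, status = invert_features(FIG1_SURFACE, -76.8 + 500.0, -34.9 - 500.0)
        assert status == "failed"
        assert np.isnan(I) and np.isnan(G)

    def _two_root_surface_and_features(self, r1=1.0, r2=2.0):
        """Construct a bilinear pair whose G-quadratic has roots r1, r2
        inside the domain, by solving for the feature values."""
        s = SurfaceCoeffs(a_IG=0.01, a_I=0.1, a_G=1.0, a_0=-77.0)
        p = SurfaceCoeffs(a_IG=-0.02, a_I=0.05, a_G=-1.0, a_0=-35.0)
        surface = CalibrationSurface(
            subthr=s, pulse=p, I_domain_pA=(-50.0, 200.0), G_domain_nS=(0.0, 2.8)
        )
        a, b, c = s.a_IG, s.a_I, s.a_G
        e, f, g = p.a_IG, p.a_I, p.a_G
        A = -e * c + g * a
        B_target = -A * (r1 + r2)
        C_target = A * r1 * r2
        # B = e ys - f c + g b - a yp ; C = f ys - b yp
        M = np.array([[e, -a], [f, -b]])
        ys, yp = np.linalg.solve(M, [B_target + f * c - g * b, C_target])
        return surface, s.a_0 + ys, p.a_0 + yp

    def test_two_roots_continuity_rule(self):
        surface, vs, vp = self._two_root_surface_and_features(1.0, 2.0)
        _, G, status = invert_features(surface, vs, vp, previous=(0.0, 1.9))
        assert status == "ok"
        assert G == pytest.approx(2.0, abs=1e-9)
        _, G, _ = invert_features(surface, vs, vp, previous=(0.0, 1.1))
        assert G == pytest.approx(1.0, abs=1e-9)

    def test_two_roots_domain_center_rule(self):
        surface, vs, vp = self._two_root_surface_and_features(1.0, 2.0)
        # domain center G = 1.4 -> root 1.0 is closer
        _, G, status = invert_features(surface, vs, vp)
        assert status == "ok"
        assert G == pytest.approx(1.0, abs=1e-9)


class TestDecomposition:
    def test_pure_inhibition(self):
        G = 2.5
        I = G * (REV.V_I_mV - REV.V_0_mV)
        ge, gi = decompose(I, G, REV)
        assert ge == pytest.approx(0.0, abs=1e-12)
        assert gi == pytest.approx(G)

    def test_origin(self):
        assert decompose(0.0, 0.0, REV) == (0.0, 0.0)

    def test_single_population_limit(self):
        I, G = compose(1.3, 0.0, REV)
        assert I == pytest.approx(1.3 * (REV.V_E_mV - REV.V_0_mV))
        assert G == pytest.approx(1.3)

    def test_round_trip_1000_random_pairs(self):
        rng = np.random.default_rng(0)
        ge = rng.uniform(0, 5, 1000)
        gi = rng.uniform(0, 5, 1000)
        I, G = compose(ge, gi, REV)
        ge2, gi2 = decompose(I, G, REV)
        assert np.max(np.abs(ge2 - ge)) < 1e-10
        assert np.max(np.abs(gi2 - gi)) < 1e-10

    @settings(deadline=None, max_examples=100)
    @given(
        ge=st.floats(0, 50), gi=st.floats(0, 50),
        ve=st.floats(-20, 20), vi=st.floats(-90, -40),
        v0=st.floats(-85, -60),
    )
    def test_compose_decompose_inverse_property(self, ge, gi, ve, vi, v0):
        if abs(ve - vi) < 1.0:
            return
        rev = ReversalSpec(V_E_mV=ve, V_I_mV=vi, V_0_mV=v0)
        I, G = compose(ge, gi, rev)
        ge2, gi2 = decompose(I, G, rev)
        assert ge2 == pytest.approx(ge, abs=1e-8)
        assert gi2 == pytest.approx(gi, abs=1e-8)
        assert G == pytest.approx(ge2 + gi2, abs=1e-12)

    def test_time_varying_reversal(self):
        vi = np.array([-74.0, -60.0, -50.0])
        I, G = compose(np.ones(3), 2 * np.ones(3), REV, V_I_mV=vi)
        ge, gi = decompose(I, G, REV, V_I_mV=vi)
        assert np.allclose(ge, 1.0)
        assert np.allclose(gi, 2.0)

    def test_ill_conditioned_reversals_rejected(self):
        with pytest.raises(ValueError):
            ReversalSpec(V_E_mV=-74.0, V_I_mV=-74.5)
        with pytest.raises(ValueError):
            decompose(0.0, 0.0, REV, V_I_mV=REV.V_E_mV + 0.5)


class TestVoltageReconstruction:
    def test_resting_limit(self):
        assert reconstruct_voltage(1.5, REV, 0.0, 0.0) == pytest.approx(REV.V_0_mV)

    def test_shunt_dominated_limit(self):
        v = reconstruct_voltage(1.5, REV, 0.0, 1e6)
        assert v == pytest.approx(REV.V_I_mV, abs=0.01)

    def test_hand_arithmetic(self):
        v = reconstruct_voltage(1.5, REV, 1.0, 2.0)
        expected = (1.5 * -76.8 + 1.0 * 0.0 + 2.0 * -74.0) / (1.5 + 1.0 + 2.0)
        assert v == pytest.approx(expected)

    def test_nonpositive_total_conductance_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_voltage(0.0, REV, 0.0, 0.0)


class TestPipeline:
    def test_quiescent_run_estimates_near_zero(self, experiment):
        trace, markers = experiment.run(None, 500.0)
        est = experiment.estimate(trace, markers)
        ok = est.ok
        assert ok.mean() > 0.9
        assert abs(np.nanmean(est.G_E_nS[ok])) < 0.1
        assert abs(np.nanmean(est.G_I_nS[ok])) < 0.3

    def test_sum_identity_holds(self, experiment):
        trace, markers = experiment.run(None, 300.0)
        est = experiment.estimate(trace, markers)
        ok = est.ok
        assert np.allclose(
            est.G_nS[ok], est.G_E_nS[ok] + est.G_I_nS[ok], atol=1e-10
        )

    def test_failed_cycles_carried_with_status(self, experiment):
        from firingclamp.features import ProbeFeatureSeries

        trace, markers = experiment.run(None, 100.0)
        n = len(markers)
        feats = ProbeFeatureSeries(
            cycle=markers.index,
            t_center_ms=markers.t_start_ms + 4.0,
            V_subthr_mV=np.full(n, np.nan),
            V_pulse_mV=np.full(n, np.nan),
            qc=np.array(["spike_contaminated"] * n),
        )
        est = estimate_pipeline(
            trace, markers, experiment.surface, experiment.rev, features=feats
        )
        assert len(est) == n
        assert set(est.status) == {"bad_feature"}
        assert np.isnan(est.G_nS).all()
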