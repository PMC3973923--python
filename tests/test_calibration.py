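"""Calibration stimulus, cycle averaging, and surface fitting."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from firingclamp.calibration import (
    FIG1_SURFACE,
    CalibrationModel,
    CalibrationSurface,
    SurfaceCoeffs,
    cycle_average_controls,
    evaluate_surface,
    fit_surfaces,
    make_calibration_signals,
)
from firingclamp.features import ProbeFeatureSeries
from firingclamp.protocol import ControlSignals, CycleMarkers


def grid_markers(n_cycles, period=5.0):
    idx = np.arange(n_cycles)
    return CycleMarkers(
        index=idx,
        t_start_ms=idx * period,
        t_pulse_end_ms=idx * period + 0.81,
        t_neg_end_ms=idx * period + 2.0,
        t_cycle_end_ms=(idx + 1) * period,
        terminated_by=np.array(["voltage_cross"] * n_cycles),
        spike_ok=np.ones(n_cycles, dtype=bool),
    )


def features_from_surface(surface, I, G, noise=0.0, rng=None):
    vs = surface.subthr(I, G)
    vp = surface.pulse(I, G)
    if noise:
        vs = vs + rng.normal(0, noise, len(I))
        vp = vp + rng.normal(0, noise, len(I))
    n = len(I)
    return ProbeFeatureSeries(
        cycle=np.arange(n),
        t_center_ms=np.arange(n) * 5.0 + 4.0,
        V_subthr_mV=np.asarray(vs),
        V_pulse_mV=np.asarray(vp),
        qc=np.array(["ok"] * n),
    )


def scatter_points(n=200, seed=0):
    rng = np.random.default_rng(seed)
    I = rng.uniform(-50.0, 200.0, n)
    G = rng.uniform(0.0, 4.0, n)
    return I, G, pd.DataFrame({"cycle": np.arange(n), "I_pA": I, "G_nS": G})


class TestWorkedExampleSurfaces:
    def test_origin_values(self):
        vs, vp = evaluate_surface(FIG1_SURFACE, 0.0, 0.0)
        assert vs == pytest.approx(-76.8)
        assert vp == pytest.approx(-34.9)

    def test_hand_arithmetic_point(self):
        # 0.002*200 + 0.079*100 + 0.8*2 - 76.8
        vs = FIG1_SURFACE.subthr(100.0, 2.0)
        assert vs == pytest.approx(0.002 * 200 + 0.079 * 100 + 0.8 * 2 - 76.8)

    def test_exact_coefficient_recovery(self):
        """Fitting data generated exactly from the printed polynomials
        recovers all eight coefficients to 6 significant digits."""
        I, G, controls = scatter_points()
        feats = features_from_surface(FIG1_SURFACE, I, G)
        fit = CalibrationModel(feats, controls).fit(form="bilinear4")
        for got, want in [
            (fit.surface.subthr, FIG1_SURFACE.subthr),
            (fit.surface.pulse, FIG1_SURFACE.pulse),
        ]:
            for name in ("a_IG", "a_I", "a_G", "a_0"):
                assert getattr(got, name) == pytest.approx(
                    getattr(want, name), rel=1e-6
                )
        assert max(fit.surface.residual_rms_mV) < 1e-8

    def test_extrapolation_warns(self):
        with pytest.warns(UserWarning, match="outside its fit domain"):
            evaluate_surface(FIG1_SURFACE, 1000.0, 0.0)


class TestFitStatistics:
    def test_noisy_fit_is_unbiased(self):
        """Monte Carlo: with 0.5 mV feature noise the coefficient
        estimates are unbiased (mean error < 3 SE of the mean)."""
        I, G, controls = scatter_points(n=150, seed=1)
        rng = np.random.default_rng(42)
        errs = {k: [] for k in ("a_IG", "a_I", "a_G", "a_0")}
        ses = {k: [] for k in errs}
        for _ in range(100):
            feats = features_from_surface(FIG1_SURFACE, I, G, noise=0.5, rng=rng)
            fit = CalibrationModel(feats, controls).fit(form="bilinear4")
            for k_i, k in enumerate(errs):
                errs[k].append(
                    getattr(fit.surface.subthr, k) - getattr(FIG1_SURFACE.subthr, k)
                )
                ses[k].append(fit.bse["subthr"][k_i])
        for k in errs:
            se_mean = np.mean(ses[k]) / math.sqrt(len(errs[k]))
            assert abs(np.mean(errs[k])) < 3 * se_mean

    def test_bilinear_cross_term_zero_when_absent(self):
        surface_no_cross = CalibrationSurface(
            subthr=SurfaceCoeffs(a_IG=0.0, a_I=0.08, a_G=0.8, a_0=-77.0),
            pulse=SurfaceCoeffs(a_IG=0.0, a_I=0.05, a_G=-0.5, a_0=-35.0),
        )
        I, G, controls = scatter_points(n=200, seed=2)
        rng = np.random.default_rng(7)
        feats = features_from_surface(surface_no_cross, I, G, noise=0.3, rng=rng)
        fit = CalibrationModel(feats, controls).fit(form="bilinear4")
        assert abs(fit.surface.subthr.a_IG) < 3 * fit.bse["subthr"][0]

    def test_quadratic6_never_increases_rms(self):
        I, G, controls = scatter_points(n=250, seed=3)
        rng = np.random.default_rng(5)
        feats = features_from_surface(FIG1_SURFACE, I, G, noise=0.4, rng=rng)
        model = CalibrationModel(feats, controls)
        rms4 = model.fit(form="bilinear4").surface.residual_rms_mV
        rms6 = model.fit(form="quadratic6").surface.residual_rms_mV
        assert rms6[0] <= rms4[0] * (1 + 1e-9)
        assert rms6[1] <= rms4[1] * (1 + 1e-9)

    def test_rank_deficient_design_raises(self):
        n = 40
        I = np.linspace(-20, 60, n)
        G = np.full(n, 2.0)  # constant G: G and intercept columns collinear
        controls = pd.DataFrame({"cycle": np.arange(n), "I_pA": I, "G_nS": G})
        feats = features_from_surface(FIG1_SURFACE, I, G)
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            CalibrationModel(feats, controls).fit()

    def test_too_few_points_raises(self):
        I, G, controls = scatter_points(n=3)
        feats = features_from_surface(FIG1_SURFACE, I, G)
        with pytest.raises(ValueError, match="calibration points"):
            CalibrationModel(feats, controls).fit()

    def test_summary_reports_fit(self, experiment):
        text = experiment.calibration.summary()
        assert "residual RMS" in text
        assert "a_IG" in text

    def test_bilinear_surface_linear_in_each_argument(self):
        s = FIG1_SURFACE.subthr
        I = np.linspace(-50, 200, 7)
        at_g = s(I, 2.0)
        assert np.allclose(np.diff(at_g, 2), 0.0, atol=1e-12)
        G = np.linspace(0, 4, 7)
        at_i = s(100.0, G)
        assert np.allclose(np.diff(at_i, 2), 0.0, atol=1e-12)


class TestCalibrationStimulus:
    def test_paper_periods_warn_commensurate(self):
        with pytest.warns(UserWarning, match="commensurate"):
            make_calibration_signals(periods_ms=(40.0, 70.0), duration_ms=100.0)

    def test_conductance_clipped_at_zero(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sig = make_calibration_signals(
                G_range_nS=(0.0, 2.0), duration_ms=500.0
            )
        assert sig.G_nS.min() >= 0.0

    def test_zero_amplitude_gives_constant_signals(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sig = make_calibration_signals(
                I_range_pA=(10.0, 10.0 + 1e-12),
                G_range_nS=(1.0, 1.0),
                duration_ms=200.0,
            )
        assert np.ptp(sig.I_pA) < 1e-9
        assert np.ptp(sig.G_nS) < 1e-9

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            make_calibration_signals(I_range_pA=(50.0, -50.0))

    def test_detuned_periods_cover_the_plane(self):
        """Histogram oracle: per-cycle (I, G) means fill a 5x5 grid when
        the periods are not commensurate with the probe period."""
        sig = make_calibration_signals(
            periods_ms=(41.3, 69.1), duration_ms=4000.0, dt_ms=0.03
        )
        markers = grid_markers(int(4000.0 / 5.0))
        ctl = cycle_average_controls(sig, markers)
        H, _, _ = np.histogram2d(
            ctl["I_pA"], ctl["G_nS"], bins=5,
            range=[[ctl["I_pA"].min(), ctl["I_pA"].max()],
                   [ctl["G_nS"].min(), ctl["G_nS"].max()]],
        )
        assert (H >= 1).all()


class TestCycleAveraging:
    def test_constant_signals(self):
        n = round(50.0 / 0.03)
        sig = ControlSignals(dt_ms=0.03, I_pA=np.full(n, 7.0), G_nS=np.full(n, 2.0))
        ctl = cycle_average_controls(sig, grid_markers(10))
        assert np.allclose(ctl["I_pA"], 7.0)
        assert np.allclose(ctl["G_nS"], 2.0)

    def test_linear_ramp_gives_midpoint(self):
        dt = 0.03
        n = round(50.0 / dt)
        t = np.arange(n) * dt
        sig = ControlSignals(dt_ms=dt, I_pA=2.0 * t, G_nS=np.zeros(n))
        ctl = cycle_average_controls(sig, grid_markers(10))
        mid = 2.0 * (np.arange(10) * 5.0 + 2.5)
        assert np.max(np.abs(ctl["I_pA"] - mid)) < 2.0 * dt + 1e-9

    def test_sinusoid_matches_closed_form_discrete_mean(self):
        """Oracle: the mean of sin over n equally spaced samples has the
        Dirichlet-kernel closed form."""
        dt = 0.05  # cycle length is an exact multiple of dt
        T = 40.0
        omega = 2 * math.pi / T
        n_tot = round(50.0 / dt)
        t = np.arange(n_tot) * dt
        sig = ControlSignals(dt_ms=dt, I_pA=np.sin(omega * t), G_nS=np.zeros(n_tot))
        markers = grid_markers(10)
        ctl = cycle_average_controls(sig, markers)
        m = round(5.0 / dt)
        for i in range(10):
            t0 = i * 5.0
            expected = (
                math.sin(omega * (t0 + (m - 1) * dt / 2))
                * math.sin(m * omega * dt / 2)
                / (m * math.sin(omega * dt / 2))
            )
            assert ctl["I_pA"][i] == pytest.approx(expected, abs=1e-9)

    def test_signals_must_cover_cycles(self):
        sig = ControlSignals(dt_ms=0.03, I_pA=np.zeros(10), G_nS=np.zeros(10))
        with pytest.raises(ValueError, match="cover"):
            cycle_average_controls(sig, grid_markers(5))
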