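"""Diffusion model, correlation-curve fitting, release-model fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csmkinetics.correlate import CorrelationCurve
from csmkinetics.errors import InvalidConfigError, InvalidParameterError
from csmkinetics.fcs import (
    DiffusionModelSpec,
    KineticsSeries,
    fit_biexponential,
    fit_correlation,
    fit_exp_plateau,
    joint_release_time,
    normalize_series,
)
from csmkinetics.models import biexp_decay, exp_plateau, g_diffusion_3d


class TestDiffusionModel:
    def test_zero_lag_is_amplitude(self):
        assert g_diffusion_3d(0.0, 1.0, 1e-3) == pytest.approx(1.0)

    def test_half_amplitude_at_tau_d_for_large_kappa(self):
        # axial term negligible for an elongated volume
        assert g_diffusion_3d(1e-3, 1.0, 1e-3, kappa=1e4) == pytest.approx(0.5, rel=1e-4)

    def test_value_at_tau_d_kappa_5(self):
        # 0.5 * (1 + 1/25)^(-1/2)
        assert g_diffusion_3d(1.0, 1.0, 1.0, kappa=5.0) == pytest.approx(0.4903, abs=1e-4)

    def test_triplet_fraction_range_enforced(self):
        with pytest.raises(ValueError):
            g_diffusion_3d(1.0, 1.0, 1.0, triplet_fraction=1.0)

    @given(st.floats(0.1, 50.0), st.floats(1.5, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_monotone_nonincreasing_without_triplet(self, tau_d, kappa):
        tau = np.logspace(-3, 3, 200) * tau_d
        g = g_diffusion_3d(tau, 1.0, tau_d, kappa=kappa)
        assert np.all(np.diff(g) <= 0)


class TestFitCorrelation:
    def _curve(self, **kw):
        lags = np.logspace(-5, 0, 60)
        values = g_diffusion_3d(lags, kw.pop("amplitude", 0.5), kw.pop("tau_d1", 1e-3), **kw)
        return CorrelationCurve(lags, values, (0, 0))

    def test_noiseless_single_species_recovered_exactly(self):
        curve = self._curve(amplitude=0.5, tau_d1=1e-3, kappa=5.0)
        fit = fit_correlation(curve, DiffusionModelSpec(kappa=5.0))
        assert fit.amplitude == pytest.approx(0.5, rel=1e-6)
        assert fit.tau_d1 == pytest.approx(1e-3, rel=1e-6)

    def test_noiseless_two_species_recovered(self):
        curve = self._curve(amplitude=0.4, tau_d1=5e-3, tau_d2=2e-4, fraction_1=0.6,
                            kappa=5.0)
        fit = fit_correlation(curve, DiffusionModelSpec(n_species=2, kappa=5.0))
        assert fit.tau_d1 == pytest.approx(5e-3, rel=1e-4)
        assert fit.tau_d2 == pytest.approx(2e-4, rel=1e-4)
        assert fit.fraction_1 == pytest.approx(0.6, abs=1e-4)
        # mean diffusion time is the fraction-weighted arithmetic mean
        assert fit.mean_diffusion_time == pytest.approx(0.6 * 5e-3 + 0.4 * 2e-4, rel=1e-4)

    def test_identifiability_guard_kappa_with_two_species(self):
        with pytest.raises(InvalidConfigError):
            DiffusionModelSpec(n_species=2, fit_kappa=True)
        # explicit override allowed
        DiffusionModelSpec(n_species=2, fit_kappa=True, allow_unidentifiable=True)

    def test_too_few_lags_rejected(self):
        curve = CorrelationCurve(np.logspace(-4, -3, 5),
                                 np.linspace(0.5, 0.3, 5), (0, 0))
        with pytest.raises(Exception):
            fit_correlation(curve)


class TestExpPlateauFit:
    def test_noiseless_exact(self):
        t = np.arange(0.0, 181.0, 1.0)
        series = KineticsSeries(t, exp_plateau(t, 84.0, 0.087))
        fit = fit_exp_plateau(series)
        assert fit.mean_time == pytest.approx(84.0, rel=1e-6)
        assert fit.plateau == pytest.approx(0.087, abs=1e-8)
        assert fit.mean_time_identifiable

    def test_flat_series_flagged_unidentifiable(self):
        t = np.arange(0.0, 60.0, 1.0)
        fit = fit_exp_plateau(KineticsSeries(t, np.ones_like(t)))
        assert fit.plateau == pytest.approx(1.0, abs=1e-3)
        assert not fit.mean_time_identifiable

    def test_nan_windows_skipped(self):
        t = np.arange(0.0, 120.0, 1.0)
        y = exp_plateau(t, 30.0, 0.1)
        y[::7] = np.nan
        fit = fit_exp_plateau(KineticsSeries(t, y))
        assert fit.mean_time == pytest.approx(30.0, rel=1e-6)

    def test_too_short_series_rejected(self):
        with pytest.raises(InvalidConfigError):
            fit_exp_plateau(KineticsSeries(np.arange(3.0), np.ones(3)))


class TestBiexponentialFit:
    def test_noiseless_exact_and_ordered(self):
        t = np.arange(0.0, 50.0, 0.2)
        y = biexp_decay(t, 1.0, 25.0, 0.3, 0.1)
        fit = fit_biexponential(KineticsSeries(t, y))
        assert fit.mean_time == pytest.approx(1.0, rel=1e-5)
        assert fit.mean_time_2 == pytest.approx(25.0, rel=1e-5)
        assert fit.mean_time < fit.mean_time_2
        assert fit.a1 == pytest.approx(1.0 - 0.3 - 0.1, abs=1e-5)

    def test_single_exponential_flags_slow_component(self):
        t = np.arange(0.0, 50.0, 0.5)
        y = biexp_decay(t, 2.0, 30.0, 0.0, 0.05)  # a2 = 0: no slow component
        fit = fit_biexponential(KineticsSeries(t, y))
        assert not fit.mean_time_2_identifiable

    def test_noisy_recovery_over_20_seeds(self):
        t = np.arange(0.0, 50.0, 1.0)
        truth = biexp_decay(t, 1.0, 25.0, 0.3, 0.1)
        t1s, t2s = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            fit = fit_biexponential(
                KineticsSeries(t, truth + rng.normal(0, 0.01, t.size))
            )
            t1s.append(fit.mean_time)
            t2s.append(fit.mean_time_2)
        assert abs(np.median(t1s) - 1.0) / 1.0 < 0.25
        assert abs(np.median(t2s) - 25.0) / 25.0 < 0.25


class TestNormalizeSeries:
    def test_control_equal_sample_gives_unity(self):
        t = np.arange(0.0, 50.0, 1.0)
        y = exp_plateau(t, 20.0, 0.1)
        out = normalize_series(KineticsSeries(t, y), KineticsSeries(t, y))
        assert np.allclose(out.values, 1.0)

    def test_rescale_only_preserves_shape(self):
        t = np.arange(0.0, 50.0, 1.0)
        y = 0.8 * exp_plateau(t, 20.0, 0.0)
        out = normalize_series(KineticsSeries(t, y))
        assert out.values[0] == pytest.approx(1.0)
        assert np.allclose(out.values, y / 0.8)

    def test_division_by_slow_control_recovers_fast_time(self):
        """Dividing a 60-min decay by a 600-min control decay leaves a decay
        whose fitted mean time is 1/(1/60 - 1/600) scaled back ... i.e. the
        ratio of exponentials is exp(-t(1/60 - 1/600)); fitting recovers the
        corrected timescale within 2% of the analytic value."""
        t = np.arange(0.0, 181.0, 1.0)
        sample = KineticsSeries(t, np.exp(-t / 60.0))
        control = KineticsSeries(t, np.exp(-t / 600.0))
        out = normalize_series(sample, control)
        fit = fit_exp_plateau(out)
        expected = 1.0 / (1.0 / 60.0 - 1.0 / 600.0)
        assert fit.mean_time == pytest.approx(expected, rel=0.02)

    def test_interpolates_control_grid(self):
        t = np.arange(0.0, 50.0, 1.0)
        tc = np.arange(0.0, 60.0, 2.5)
        sample = KineticsSeries(t, np.exp(-t / 20.0))
        control = KineticsSeries(tc, np.full(tc.size, 2.0))
        out = normalize_series(sample, control)
        assert out.values[0] == pytest.approx(1.0)


class TestJointReleaseTime:
    def test_printed_end_release_times_give_49_min(self):
        assert joint_release_time(84.0, 119.0) == pytest.approx(49.24, abs=0.01)

    def test_symmetry_halves(self):
        assert joint_release_time(30.0, 30.0) == pytest.approx(15.0)

    def test_infinite_partner(self):
        assert joint_release_time(60.0, np.inf) == pytest.approx(60.0)

    def test_invalid_input(self):
        with pytest.raises(InvalidParameterError):
            joint_release_time(-1.0, 10.0)

    @given(st.floats(1e-3, 1e6), st.floats(1e-3, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_never_exceeds_faster_channel(self, ta, tb):
        assert joint_release_time(ta, tb) <= min(ta, tb) + 1e-12
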