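"""DNase assay calibration, activation fits, the six-species ODE scheme and
its global fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csmkinetics.dnase import (
    PUBLISHED_RATES,
    Calibration,
    DnaseTrace,
    KineticParams,
    ReactionState,
    TitrationDataset,
    calibrate,
    fit_activation,
    global_fit,
    kinetic_derivatives,
    simulate_kinetics,
)
from csmkinetics.errors import (
    CalibrationError,
    IdentifiabilityError,
    InvalidParameterError,
)
from csmkinetics.models import activation
from csmkinetics.synthetic import TitrationSimConfig, simulate_titration


class TestCalibration:
    def test_exact_line_through_origin(self):
        cal = calibrate([(50.0, 500.0), (100.0, 1000.0)])
        assert cal.scale == pytest.approx(0.1)
        assert cal.intercept == pytest.approx(0.0, abs=1e-9)
        assert cal.to_concentration(500.0) == pytest.approx(50.0)

    def test_single_point_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate([(50.0, 500.0)])

    def test_narrow_span_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate([(50.0, 500.0), (60.0, 600.0)])

    def test_noisy_four_point_scale_within_10_percent(self):
        rng = np.random.default_rng(0)
        amounts = np.array([25.0, 50.0, 100.0, 200.0])
        signals = amounts / 0.1 + 20.0
        signals *= 1.0 + rng.normal(0, 0.05, 4)
        cal = calibrate(list(zip(amounts, signals)))
        assert abs(cal.scale - 0.1) / 0.1 < 0.10


class TestActivationFit:
    def test_noiseless_exact(self):
        t = np.arange(10.0, 300 * 60.0, 60.0)
        trace = DnaseTrace(t, activation(t, 40.0, 68 * 60.0), calibrated=True)
        fit = fit_activation(trace)
        assert fit.mean_time / 60.0 == pytest.approx(68.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(40.0, rel=1e-6)

    def test_pure_linear_trace_degenerates_to_background(self):
        t = np.arange(10.0, 6000.0, 30.0)
        trace = DnaseTrace(t, 0.005 * t, calibrated=True)
        fit = fit_activation(trace, with_background=True)
        assert fit.amplitude < 0.5
        assert fit.background_rate == pytest.approx(0.005, rel=0.05)

    def test_mean_time_flat_across_rna_titration(self):
        """Varying amplitude (RNA saturation) with constant mean time: fitted
        mean times stay within 15% across the titration."""
        t = np.arange(10.0, 300 * 60.0, 60.0)
        rng = np.random.default_rng(1)
        fitted = []
        for amp in (5.0, 10.0, 20.0, 40.0):
            y = activation(t, amp, 68 * 60.0) + rng.normal(0, 0.2, t.size)
            fitted.append(fit_activation(DnaseTrace(t, y, calibrated=True)).mean_time)
        fitted = np.array(fitted) / 60.0
        assert np.all(np.abs(fitted - 68.0) / 68.0 < 0.15)


class TestDerivatives:
    def test_zero_state_zero_derivatives(self):
        d = kinetic_derivatives(ReactionState(0, 0, 0, 0, 0, 0), PUBLISHED_RATES)
        assert np.allclose(d.to_array(), 0.0)

    @given(st.lists(st.floats(0.0, 100.0), min_size=6, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_conservation_exact_for_any_state(self, y):
        d = kinetic_derivatives(ReactionState(*y), PUBLISHED_RATES).to_array()
        # complex total: N + A + NS + AS; DNA total: S + NS + AS + P
        assert d[0] + d[1] + d[2] + d[3] == pytest.approx(0.0, abs=1e-12)
        assert d[4] + d[2] + d[3] + d[5] == pytest.approx(0.0, abs=1e-12)

    def test_initial_binding_flux_hand_value(self):
        # dAS at t=0 for 2 nM activated complex and 100 nM DNA:
        # 6.6e3 /(M s) * 2e-9 M * 100e-9 M = 1.32e-3 nM/s
        state = ReactionState(0.0, 2.0, 0.0, 0.0, 100.0, 0.0)
        d = kinetic_derivatives(state, PUBLISHED_RATES)
        assert d.as_ == pytest.approx(1.32e-3, rel=1e-9)

    def test_negative_state_rejected(self):
        with pytest.raises(InvalidParameterError):
            kinetic_derivatives(ReactionState(-1.0, 0, 0, 0, 0, 0), PUBLISHED_RATES)


class TestSimulateKinetics:
    times = np.arange(10.0, 18000.0, 30.0)

    def test_conservation_along_trajectory(self):
        tr = simulate_kinetics(
            PUBLISHED_RATES, dict(csm_total=2.0, rna_total=2.0, dna_total=100.0), self.times
        )
        st_ = tr.states
        assert np.max(np.abs(st_[:, :4].sum(axis=1) - 2.0)) / 2.0 < 1e-8
        assert np.max(np.abs(st_[:, [2, 3, 4, 5]].sum(axis=1) - 100.0)) / 100.0 < 1e-8
        assert np.all(st_ >= -1e-9)
        assert np.all(np.diff(st_[:, 5]) >= -1e-9)  # cleaved DNA non-decreasing

    def test_no_cleavage_reaches_binding_equilibrium(self):
        params = KineticParams(6.6e3, 1.1e-2, 0.0, 0.0, 0.0)
        tr = simulate_kinetics(
            params, dict(csm_total=2.0, rna_total=0.0, dna_total=500.0), self.times
        )
        assert np.allclose(tr.states[:, 5], 0.0, atol=1e-10)  # P stays 0
        # occupancy in the excess-DNA limit: S / (S + K_d)
        kd_nm = params.kd * 1e9
        occupancy = tr.states[-1, 2] / 2.0
        assert occupancy == pytest.approx(500.0 / (500.0 + kd_nm), rel=0.01)

    def test_activated_pool_decays_with_deactivation_time(self):
        tr = simulate_kinetics(
            PUBLISHED_RATES, dict(csm_total=2.0, rna_total=4.0, dna_total=100.0), self.times
        )
        act = tr.states[:, 1] + tr.states[:, 3]
        k = -np.polyfit(self.times, np.log(act), 1)[0]
        assert 1.0 / k == pytest.approx(1.0 / PUBLISHED_RATES.k_deact, rel=0.01)

    def test_no_deactivation_gives_constant_steady_slope(self):
        params = KineticParams(6.6e3, 1.1e-2, 1.9e-4, 8.5e-3, 0.0)
        tr = simulate_kinetics(
            params, dict(csm_total=2.0, rna_total=2.0, dna_total=500.0), self.times
        )
        p = tr.states[:, 5]
        late = np.diff(p[len(p) // 2:]).mean()
        very_late = np.diff(p[-100:]).mean()
        assert very_late == pytest.approx(late, rel=0.05)
        assert very_late > 0

    def test_independent_stiff_integrator_agrees(self):
        """LSODA and Radau solutions of the same scheme agree to 1e-6
        relative on the observable."""
        init = dict(csm_total=2.0, rna_total=2.0, dna_total=100.0)
        a = simulate_kinetics(PUBLISHED_RATES, init, self.times, method="LSODA",
                              rtol=1e-10, atol=1e-12)
        b = simulate_kinetics(PUBLISHED_RATES, init, self.times, method="Radau",
                              rtol=1e-10, atol=1e-12)
        scale = np.max(np.abs(a.signal))
        assert np.max(np.abs(a.signal - b.signal)) / scale < 1e-6

    def test_activation_like_shape(self):
        """Cleaved-DNA trace from the published constants fits a saturating
        exponential with mean time in the 60-90 min range."""
        tr = simulate_kinetics(
            PUBLISHED_RATES, dict(csm_total=2.0, rna_total=2.0, dna_total=100.0), self.times
        )
        fit = fit_activation(tr, with_background=True)
        assert 60.0 <= fit.mean_time / 60.0 <= 90.0


class TestSimulateTitration:
    def test_zero_cleavage_rates_give_zero_cleaved_component(self):
        params = KineticParams(6.6e3, 1.1e-2, 0.0, 0.0, 1.9e-4,
                               bound_signal_fraction=0.0)
        ds = simulate_titration(TitrationSimConfig(
            kinetic_params=params, dna_concentrations=(50.0, 100.0),
            duration=3000.0, sampling_interval=30.0))
        for tr in ds:
            assert np.allclose(tr.signal, 0.0, atol=1e-9)

    def test_no_rna_means_no_activated_species(self):
        ds = simulate_titration(TitrationSimConfig(
            kinetic_params=PUBLISHED_RATES, rna_total=0.0,
            dna_concentrations=(100.0,), duration=3000.0, sampling_interval=30.0))
        # regenerate states for the same condition
        tr = simulate_kinetics(PUBLISHED_RATES,
                               dict(csm_total=2.0, rna_total=0.0, dna_total=100.0),
                               ds.traces[0].times)
        assert np.allclose(tr.states[:, 1], 0.0, atol=1e-12)
        assert np.allclose(tr.states[:, 3], 0.0, atol=1e-12)

    def test_reproducible_given_seed(self):
        cfg = TitrationSimConfig(kinetic_params=PUBLISHED_RATES,
                                 dna_concentrations=(50.0,), duration=600.0,
                                 sampling_interval=10.0, noise_sd=0.1, rng_seed=3)
        a = simulate_titration(cfg).traces[0].signal
        b = simulate_titration(cfg).traces[0].signal
        assert np.array_equal(a, b)


class TestGlobalFit:
    def _dataset(self, noise, seed, dt=20.0, duration=12000.0):
        traces = []
        for rna, off in ((2.0, 0), (0.0, 1)):
            ds = simulate_titration(TitrationSimConfig(
                kinetic_params=PUBLISHED_RATES, rna_total=rna,
                dna_concentrations=(25.0, 100.0), duration=duration,
                sampling_interval=dt, noise_sd=noise, rng_seed=seed * 2 + off))
            traces.extend(ds.traces)
        return TitrationDataset(traces)

    def test_noiseless_self_consistency(self):
        res = global_fit(self._dataset(0.0, 1), n_starts=6, seed=0)
        for name in ("k_bind_plus", "k_bind_minus", "k_cleave_n",
                     "k_cleave_a", "k_deact"):
            fit, true = getattr(res.params, name), getattr(PUBLISHED_RATES, name)
            assert abs(fit - true) / true < 0.05, name

    def test_single_trace_is_underdetermined(self):
        ds = simulate_titration(TitrationSimConfig(
            kinetic_params=PUBLISHED_RATES, dna_concentrations=(100.0,),
            duration=600.0, sampling_interval=30.0))
        with pytest.raises(IdentifiabilityError):
            global_fit(ds, n_starts=2)

    def test_no_rna_flags_activation_parameters(self):
        traces = simulate_titration(TitrationSimConfig(
            kinetic_params=PUBLISHED_RATES, rna_total=0.0,
            dna_concentrations=(25.0, 100.0), duration=6000.0,
            sampling_interval=30.0)).traces
        res = global_fit(TitrationDataset(traces), n_starts=4, seed=0)
        assert set(res.unidentifiable) == {"k_cleave_a", "k_deact"}


def test_rna_sweep_amplitude_saturates_at_equimolar():
    """Sweeping RNA from sub- to super-stoichiometric over the complex: the
    total cleaved ssDNA saturates once RNA exceeds the complex concentration,
    while the reaction mean time stays flat - fast RNA turnover does not
    extend the DNase-active period."""
    times = np.arange(10.0, 18000.0, 60.0)
    amps, mean_times = [], []
    for rna in (0.5, 1.0, 2.0, 4.0, 8.0):
        tr = simulate_kinetics(
            PUBLISHED_RATES, dict(csm_total=2.0, rna_total=rna, dna_total=100.0), times
        )
        fit = fit_activation(tr, with_background=True)
        amps.append(fit.amplitude)
        mean_times.append(fit.mean_time)
    assert amps[0] < amps[1] < amps[2]  # grows while substoichiometric
    assert amps[3] == pytest.approx(amps[2], rel=0.01)  # saturated
    assert amps[4] == pytest.approx(amps[2], rel=0.01)
    mt = np.array(mean_times[1:])
    assert mt.max() / mt.min() < 1.25  # duration roughly constant


def test_kd_from_printed_rate_constants_is_2_micromolar():
    assert PUBLISHED_RATES.kd == pytest.approx(1.67e-6, rel=0.01)
    # one significant figure
    assert float(f"{PUBLISHED_RATES.kd:.0e}") == pytest.approx(2e-6)


def test_calibration_roundtrip_on_trace():
    t = np.arange(10.0, 1000.0, 10.0)
    conc = activation(t, 40.0, 2000.0)
    cal = Calibration(scale=0.1, intercept=50.0)
    raw = conc / cal.scale + cal.intercept
    trace = DnaseTrace(t, raw)
    back = cal.apply(trace)
    assert back.calibrated
    assert np.allclose(back.signal, conc)
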