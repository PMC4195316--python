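"""Transfer-function estimation: filters, sinusoid fit, Welch, analytic oracle."""

import numpy as np
import pytest
from scipy import signal as sps

from mfr.signals import ContinuousSignal, gen_bandlimited_gaussian, gen_sinusoid
from mfr.neurons import NeuronParams, SpikeTrain, fI_curve, simulate, simulate_ideal
from mfr.estimation import (
    SpectralSettings,
    alpha_filter,
    analytic_lif_transfer,
    direct_transfer_function,
    instantaneous_rate,
    sampling_rate_filter,
    sinusoid_fit_transfer,
    welch_csd,
)
from mfr.bundles import make_fixture

DT = 0.025


class TestSamplingRateFilter:
    def test_conserves_spike_count(self):
        train = SpikeTrain([10.0, 20.0, 30.0], 0.025, 100.0)
        y = sampling_rate_filter(train)
        assert y.samples.sum() == 3.0
        assert set(np.unique(y.samples)) <= {0.0, 1.0}

    def test_empty_train_all_zero(self):
        y = sampling_rate_filter(SpikeTrain([], 0.025, 50.0))
        assert not y.samples.any()

    def test_colliding_spikes_capped_with_warning(self):
        train = SpikeTrain([10.2, 10.4], 0.025, 50.0)
        with pytest.warns(UserWarning, match="capped"):
            y = sampling_rate_filter(train, dt=1.0)
        assert y.samples.max() == 1.0


class TestAlphaFilter:
    def test_single_spike_peaks_one_tau_later(self):
        train = SpikeTrain([100.0], 1.0, 2000.0)
        y = alpha_filter(train, tau_alpha_ms=100.0)
        assert y.times()[np.argmax(y.samples)] == pytest.approx(200.0, abs=2.0)

    def test_linearity(self):
        a = SpikeTrain([100.0, 300.0], 1.0, 2000.0)
        b = SpikeTrain([500.0], 1.0, 2000.0)
        both = SpikeTrain([100.0, 300.0, 500.0], 1.0, 2000.0)
        np.testing.assert_allclose(
            alpha_filter(both).samples,
            alpha_filter(a).samples + alpha_filter(b).samples,
            atol=1e-12,
        )

    def test_unit_area_per_spike(self):
        train = SpikeTrain([100.0], 1.0, 3000.0)
        y = alpha_filter(train, tau_alpha_ms=100.0)
        assert y.samples.sum() * y.dt == pytest.approx(1.0, rel=1e-6)


class TestInstantaneousRate:
    def test_periodic_train(self):
        train = SpikeTrain(np.arange(25.0, 1000.0, 25.0), 0.025, 1000.0)
        t, r = instantaneous_rate(train)
        np.testing.assert_allclose(r, 40.0)
        assert t[0] == 50.0

    def test_too_few_spikes_empty(self):
        t, r = instantaneous_rate(SpikeTrain([10.0], 0.025, 100.0))
        assert t.size == 0 and r.size == 0


class TestSinusoidFit:
    def test_constant_rate_fits_zero_amplitude(self):
        p = NeuronParams.lif()
        train = simulate(p, np.full(400_000, 8.0), DT)
        fit = sinusoid_fit_transfer(train, 5.0, warmup_ms=1000.0)
        assert fit.amplitude < 0.05
        assert fit.offset == pytest.approx(1000.0 / train.isis().mean(), rel=0.01)

    def test_matches_analytic_rate_response_at_5hz(self, lif_params, lif_calibration):
        # gain ratio and phase against the linearized closed form
        i0, a_i = lif_calibration
        n = int(round(60_000.0 / DT))
        t_s = np.arange(n) * DT / 1000.0
        fits = {}
        for f in (0.5, 5.0):
            train = simulate(lif_params, i0 + a_i * np.sin(2 * np.pi * f * t_s), DT)
            fits[f] = sinusoid_fit_transfer(train, f, a_i=a_i, warmup_ms=2000.0)
        oracle = analytic_lif_transfer(lif_params, 40.0, np.array([0.5, 5.0]), kind="rate")
        measured_ratio = fits[5.0].gain / fits[0.5].gain
        assert measured_ratio == pytest.approx(oracle.gain[1], rel=0.05)
        assert fits[5.0].phase_deg == pytest.approx(oracle.phase_deg[1], abs=2.0)

    def test_quasi_static_limit_is_fi_slope(self, lif_params, lif_calibration):
        # at f -> 0 the rate modulation follows the static f-I curve
        i0, a_i = lif_calibration
        n = int(round(60_000.0 / DT))
        t_s = np.arange(n) * DT / 1000.0
        train = simulate(lif_params, i0 + a_i * np.sin(2 * np.pi * 0.1 * t_s), DT)
        fit = sinusoid_fit_transfer(train, 0.1, a_i=a_i, warmup_ms=2000.0)
        di = 0.05
        r_lo, r_hi = fI_curve(lif_params, [i0 - di, i0 + di], duration_ms=20_000.0)
        dc_gain = (r_hi - r_lo) / (2 * di)
        assert fit.gain == pytest.approx(dc_gain, rel=0.05)

    def test_too_few_spikes_flagged(self):
        train = SpikeTrain([10.0, 20.0], 0.025, 1000.0)
        with pytest.raises(ValueError, match="few spikes"):
            sinusoid_fit_transfer(train, 5.0)


class TestWelch:
    def test_self_coherence_is_exactly_one(self):
        x = gen_bandlimited_gaussian(20.0, 30_000.0, 1.0, seed=41)
        cs = welch_csd(x, x)
        band = (cs.frequencies >= 0.5) & (cs.frequencies <= 20.0)
        np.testing.assert_allclose(cs.coherence()[band], 1.0, atol=1e-10)

    def test_independent_signals_low_coherence(self):
        x = gen_bandlimited_gaussian(20.0, 120_000.0, 1.0, seed=42)
        y = gen_bandlimited_gaussian(20.0, 120_000.0, 1.0, seed=43)
        cs = welch_csd(x, y)
        band = (cs.frequencies >= 0.5) & (cs.frequencies <= 20.0)
        assert cs.coherence()[band].mean() < 0.05

    def test_white_input_flat_spectrum(self):
        # flatness judged on 4-Hz blocks; raw bins carry ~0.4 dB Welch noise
        x = gen_bandlimited_gaussian(499.0, 120_000.0, 1.0, seed=44)
        cs = welch_csd(x, x)
        band = (cs.frequencies >= 1.0) & (cs.frequencies <= 400.0)
        pxx = cs.pxx[band]
        nb = pxx.size // 8
        blocks = pxx[: nb * 8].reshape(nb, 8).mean(axis=1)
        db = 10 * np.log10(blocks / np.median(blocks))
        assert np.max(np.abs(db)) < 1.0

    def test_matches_scipy_coherence(self):
        # independent reference implementation of the same statistic
        x = gen_bandlimited_gaussian(20.0, 30_000.0, 1.0, seed=45)
        y = ContinuousSignal(np.roll(x.samples, 30) + 0.1, 1.0)
        cs = welch_csd(x, y)
        f_ref, c_ref = sps.coherence(
            x.samples, y.samples, fs=1000.0, nperseg=2000, noverlap=1000
        )
        np.testing.assert_allclose(cs.coherence(), c_ref, atol=1e-10)

    def test_short_signal_rejected(self):
        x = gen_bandlimited_gaussian(20.0, 5_000.0, 1.0, seed=46)
        with pytest.raises(ValueError, match="segments"):
            welch_csd(x, x)


class TestDirectTransfer:
    def test_pure_scaling_flat_gain_zero_phase(self):
        x = gen_bandlimited_gaussian(20.0, 30_000.0, 1.0, seed=47)
        y = ContinuousSignal(2.0 * x.samples, 1.0)
        tf = direct_transfer_function(x, y, band=(0.5, 20.0))
        np.testing.assert_allclose(tf.gain_db, 0.0, atol=1e-9)
        np.testing.assert_allclose(tf.phase_deg, 0.0, atol=1e-9)
        assert np.abs(tf.raw[0]) == pytest.approx(2.0, abs=1e-9)

    def test_known_lti_filter_recovered(self):
        bundle = make_fixture("lti_known")
        tf = direct_transfer_function(bundle.stimulus, bundle.output, band=(0.5, 150.0))
        w, h = sps.freqz(
            bundle.results["b"], bundle.results["a"], worN=tf.frequencies, fs=1000.0
        )
        true_db = 20 * np.log10(np.abs(h)) - 20 * np.log10(np.abs(h[0]))
        true_ph = np.degrees(np.unwrap(np.angle(h)))
        assert np.max(np.abs(tf.gain_db - true_db)) < 0.5
        assert np.max(np.abs(tf.phase_deg - true_ph)) < 3.0

    def test_ideal_encoder_transfer_flat(self):
        # carrier 40 spikes/s, a = 1: flat gain within 1 dB across the band
        x = gen_bandlimited_gaussian(20.0, 121_000.0, DT, seed=48)
        rate = 40.0 * (1.0 + 1.0 * x.samples)
        train = simulate_ideal(ContinuousSignal(rate, DT, "spikes/s"))
        from mfr.signals import antialiased_decimate

        warm = int(1000.0 / DT)
        y = sampling_rate_filter(train)
        ya = antialiased_decimate(ContinuousSignal(y.samples[warm:], DT), 1.0)
        xa = ContinuousSignal(x.samples[warm:][::40][: ya.n], 1.0, "normalized")
        tf = direct_transfer_function(xa, ya, band=(0.5, 20.0))
        assert np.max(np.abs(tf.gain_db)) < 1.0

    def test_lif_direct_estimate_matches_analytic_below_nyquist(self, baseline_run):
        tf = direct_transfer_function(
            baseline_run["xa"], baseline_run["ya"], band=(0.5, 20.0)
        )
        oracle = analytic_lif_transfer(
            baseline_run["params"], 40.0, tf.frequencies, kind="spike_train"
        )
        assert np.max(np.abs(tf.gain_db - oracle.gain_db)) < 1.0


class TestAnalyticTransfer:
    def test_normalized_at_lowest_frequency(self):
        tf = analytic_lif_transfer(NeuronParams.lif(), 40.0, np.arange(0.5, 200.0, 0.5))
        assert tf.gain_db[0] == 0.0

    def test_spike_train_resonance_peaks_at_carrier_multiples(self):
        f = np.arange(0.5, 200.0, 0.5)
        tf = analytic_lif_transfer(NeuronParams.lif(), 40.0, f, kind="spike_train")
        for k in (1, 2, 3):
            near = np.abs(f - 40.0 * k) <= 1.0
            away = np.abs(f - 40.0 * k + 20.0) <= 1.0
            assert tf.gain_db[near].max() > tf.gain_db[away].max() + 10.0

    def test_rate_kind_has_lobes_above_carrier(self):
        f = np.arange(0.5, 200.0, 0.5)
        g = analytic_lif_transfer(NeuronParams.lif(), 40.0, f, kind="rate").gain
        above = g[f > 40.0]
        interior = above[1:-1]
        assert np.any((interior > above[:-2]) & (interior > above[2:]))

    def test_rate_and_train_agree_quasi_statically(self):
        f = np.array([0.5, 1.0, 2.0])
        a = analytic_lif_transfer(NeuronParams.lif(), 40.0, f, kind="rate")
        b = analytic_lif_transfer(NeuronParams.lif(), 40.0, f, kind="spike_train")
        np.testing.assert_allclose(np.abs(a.raw), np.abs(b.raw), rtol=0.01)


def test_sinusoid_fit_reports_transfer_where_ideal_observer_sees_none(
    lif_params, lif_calibration
):
    """Above the Nyquist rate the sinusoid fit still returns finite gain,
    although coherence-based VAF is near zero there -- the method's
    prior-knowledge artifact."""
    from mfr.signals import antialiased_decimate
    from mfr.reconstruction import vaf_spectrum

    i0, a_i = lif_calibration
    f = 35.0  # above the 20-Hz Nyquist rate of a 40 spikes/s carrier
    n = int(round(61_000.0 / DT))
    t_s = np.arange(n) * DT / 1000.0
    train = simulate(lif_params, i0 + a_i * np.sin(2 * np.pi * f * t_s), DT)
    fit = sinusoid_fit_transfer(train, f, a_i=a_i, warmup_ms=1000.0)
    assert np.isfinite(fit.gain) and fit.gain > 0.0

    x = gen_bandlimited_gaussian(45.0, 121_000.0, DT, seed=49)
    noisy = simulate(lif_params, i0 + a_i * x.samples, DT)
    warm = int(1000.0 / DT)
    y = sampling_rate_filter(noisy)
    ya = antialiased_decimate(ContinuousSignal(y.samples[warm:], DT), 1.0)
    xa = antialiased_decimate(ContinuousSignal(x.samples[warm:], DT), 1.0)
    vaf_hi = vaf_spectrum(xa, ya, band=(33.0, 37.0))
    assert vaf_hi.mean_vaf < 10.0
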