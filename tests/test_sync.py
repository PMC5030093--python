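"""Spike-field coherence, phase conventions, STA and rate-matched dilution."""

import numpy as np
import pytest

from bgoscillo import sync, synthgen
from bgoscillo.types import ContinuousSignal, SpikeTrain, ValidationError

from conftest import make_train

FS = 781.3
F0 = 10.0


def cosine_lfp(span_s, f0=F0, fs=FS, noise_sd=0.0, seed=0):
    t = np.arange(int(span_s * fs)) / fs
    x = np.cos(2 * np.pi * f0 * t)
    if noise_sd > 0:
        x = x + noise_sd * np.random.default_rng(seed).standard_normal(t.size)
    return ContinuousSignal(x, fs_hz=fs, kind="lfp")


def spikes_at_phase(theta_deg, span_s, f0=F0):
    """Deterministic spikes at a fixed LFP phase (0 deg = positive peak)."""
    k = np.arange(1, int(span_s * f0) - 1)
    times = np.deg2rad(theta_deg) / (2 * np.pi * f0) + k / f0
    return make_train(times, span_s=span_s)


class TestSpikeRateSignal:
    def test_regular_spiking_dominated_by_its_frequency(self):
        train = make_train(np.arange(1, 590) / 10.0, span_s=60.0)
        sig = sync.spike_rate_signal(train, FS, span_s=60.0)
        spec = np.abs(np.fft.rfft(sig.samples))
        freqs = np.fft.rfftfreq(sig.n_samples, d=1.0 / FS)
        assert abs(freqs[np.argmax(spec)] - 10.0) < 0.1

    def test_output_is_z_normalized(self):
        rng = np.random.default_rng(0)
        train = make_train(np.sort(rng.uniform(0, 60, 300)), span_s=60.0)
        sig = sync.spike_rate_signal(train, FS, span_s=60.0)
        assert sig.samples.mean() == pytest.approx(0.0, abs=1e-9)
        assert sig.samples.std() == pytest.approx(1.0, abs=1e-9)

    def test_single_spike_gives_smooth_unimodal_pulse(self):
        train = make_train([30.0], span_s=60.0)
        n = int(60.0 * FS)
        idx = np.minimum((train.spike_times * FS).astype(int), n - 1)
        impulses = np.bincount(idx, minlength=n).astype(float)
        from scipy import signal as sps

        sos = sps.butter(4, 100.0, btype="lowpass", fs=FS, output="sos")
        pulse = sps.sosfiltfilt(sos, impulses)
        assert np.sum(pulse) == pytest.approx(1.0, rel=1e-6)  # integral kept
        peak = np.argmax(pulse)
        assert abs(peak - idx[0]) <= 1

    def test_empty_train_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            sync.spike_rate_signal(make_train([], span_s=10.0), FS)


class TestCoherence:
    def test_self_coherence_is_one_everywhere(self):
        rng = np.random.default_rng(1)
        x = ContinuousSignal(rng.standard_normal(int(60 * FS)), fs_hz=FS, kind="lfp")
        sig = ContinuousSignal(x.samples.copy(), fs_hz=FS, kind="envelope")
        coh = sync.ms_coherence(sig, x)
        np.testing.assert_allclose(coh.coh, 1.0, atol=1e-9)
        assert 8.0 <= coh.peak_hz <= 15.0

    def test_independent_noise_near_bias_floor(self):
        rng = np.random.default_rng(2)
        n = int(600 * FS)
        a = ContinuousSignal(rng.standard_normal(n), fs_hz=FS, kind="envelope")
        b = ContinuousSignal(rng.standard_normal(n), fs_hz=FS, kind="lfp")
        coh = sync.ms_coherence(a, b)
        in_band = (coh.f >= 8.0) & (coh.f <= 15.0)
        assert coh.coh[in_band].mean() < 5.0 / coh.n_segments
        assert np.all(coh.coh >= 0.0) and np.all(coh.coh <= 1.0)

    def test_entrained_spikes_peak_at_oscillation_frequency(self):
        cfg = synthgen.SessionConfig(
            state="parkinsonian", osc_depth=0.8, seed=4
        )
        train, lfp, _ = synthgen.gen_oscillatory_pair(
            cfg, "TAN", entrained=True, span_s=300.0, include_mua=False
        )
        sig = sync.spike_rate_signal(train, lfp.fs_hz, span_s=train.span_s)
        coh = sync.ms_coherence(sig, lfp)
        df = coh.f[1] - coh.f[0]
        assert abs(coh.peak_hz - 10.0) <= df
        # and clearly above the independent-pair bias floor
        assert coh.peak_coh > 10.0 / coh.n_segments

    def test_mismatched_sampling_rates_rejected(self):
        a = ContinuousSignal(np.zeros(10000), fs_hz=FS)
        b = ContinuousSignal(np.zeros(10000), fs_hz=500.0, kind="lfp")
        with pytest.raises(ValidationError, match="rates"):
            sync.ms_coherence(a, b)

    def test_too_short_for_two_segments_rejected(self):
        a = ContinuousSignal(np.zeros(2344), fs_hz=FS)
        with pytest.raises(ValidationError, match="segments"):
            sync.ms_coherence(a, ContinuousSignal(np.zeros(2344), fs_hz=FS, kind="lfp"))


class TestPhase:
    @pytest.mark.parametrize("theta", [0.0, 90.0, 180.0, 210.0, 300.0])
    def test_phase_convention_recovers_spike_phase(self, theta):
        span = 60.0
        lfp = cosine_lfp(span)
        train = spikes_at_phase(theta, span)
        sig = sync.spike_rate_signal(train, FS, span_s=span)
        coh = sync.ms_coherence(sig, lfp)
        diff = (coh.phase_at_peak_deg - theta + 180.0) % 360.0 - 180.0
        assert abs(diff) < 5.0

    def test_delaying_the_lfp_shifts_phase_back(self):
        # lfp'(t) = lfp(t - dt): spikes land 360 * f0 * dt deg earlier
        span = 60.0
        theta = 210.0
        shift = 10  # samples
        dt = shift / FS
        lfp = cosine_lfp(span)
        delayed = ContinuousSignal(
            np.roll(lfp.samples, shift), fs_hz=FS, kind="lfp"
        )
        train = spikes_at_phase(theta, span)
        sig = sync.spike_rate_signal(train, FS, span_s=span)
        p0 = sync.ms_coherence(sig, lfp).phase_at_peak_deg
        p1 = sync.ms_coherence(sig, delayed).phase_at_peak_deg
        expected = -360.0 * F0 * dt
        diff = (p1 - p0 - expected + 180.0) % 360.0 - 180.0
        assert abs(diff) < 5.0

    def test_phase_histogram_circular_mean(self):
        phases = [350.0, 10.0, 0.0]  # wraps around zero
        hist = sync.phase_histogram(phases)
        assert hist.counts.sum() == 3
        assert hist.mean_deg == pytest.approx(0.0, abs=1e-6) or hist.mean_deg > 355.0
        assert hist.resultant_length > 0.9

    def test_trough_locked_population_mean_in_180_270(self):
        rng = np.random.default_rng(5)
        phases = np.mod(225.0 + 30.0 * rng.standard_normal(50), 360.0)
        hist = sync.phase_histogram(phases)
        assert 180.0 <= hist.mean_deg <= 270.0


class TestRegression:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        slope, intercept, r, p = sync.peak_vs_coherence_regression(x, 2 * x)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert r == pytest.approx(1.0)

    def test_anticorrelated_pairs_give_negative_r(self):
        x = np.arange(20.0)
        _, _, r, _ = sync.peak_vs_coherence_regression(x, -3 * x + 1.0)
        assert r == pytest.approx(-1.0)

    def test_independent_pairs_give_small_r(self):
        rng = np.random.default_rng(6)
        hits = 0
        for k in range(20):
            x = rng.standard_normal(100)
            y = rng.standard_normal(100)
            _, _, r, _ = sync.peak_vs_coherence_regression(x, y)
            hits += abs(r) < 0.3
        assert hits >= 19

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            sync.peak_vs_coherence_regression(np.ones(10), np.arange(10.0))


class TestSta:
    def test_random_spikes_on_white_lfp_average_to_zero(self):
        rng = np.random.default_rng(7)
        span = 600.0
        lfp = ContinuousSignal(
            rng.standard_normal(int(span * FS)), fs_hz=FS, kind="lfp"
        )
        times = np.sort(rng.uniform(1, span - 1, size=3000))
        sta = sync.sta_lfp(make_train(times, span_s=span), lfp)
        # 30 Hz low-pass leaves ~30/390 of unit variance; mean of n segments
        resid_sd = np.sqrt(0.08 / sta.n_spikes)
        assert np.max(np.abs(sta.sta)) < 6 * resid_sd

    def test_trough_locked_spikes_give_oscillatory_sta_with_minimum_at_zero(self):
        span = 120.0
        lfp = cosine_lfp(span, noise_sd=0.3, seed=8)
        train = spikes_at_phase(180.0, span)
        sta = sync.sta_lfp(train, lfp)
        mid = sta.lags.size // 2
        assert sta.sta[mid] == pytest.approx(np.min(sta.sta), abs=0.05)
        # ~10 Hz periodicity: maxima near +/- half cycle
        half_cycle = int(round(FS / F0 / 2))
        assert sta.sta[mid + half_cycle] > 0.5 * np.max(sta.sta)

    def test_doubling_window_preserves_central_overlap(self):
        span = 120.0
        lfp = cosine_lfp(span, noise_sd=0.3, seed=9)
        train = spikes_at_phase(200.0, span)
        inside = train.spike_times[
            (train.spike_times > 1.0) & (train.spike_times < span - 1.0)
        ]
        train = make_train(inside, span_s=span)
        small = sync.sta_lfp(train, lfp, window_s=0.25)
        large = sync.sta_lfp(train, lfp, window_s=0.5)
        half = (large.sta.size - small.sta.size) // 2
        center = large.sta[half : half + small.sta.size]
        np.testing.assert_allclose(center, small.sta, atol=1e-3)

    def test_no_usable_spikes_rejected(self):
        lfp = cosine_lfp(1.0)
        with pytest.raises(ValidationError, match="window"):
            sync.sta_lfp(make_train([0.01], span_s=1.0), lfp, window_s=0.5)


class TestDilution:
    def test_count_arithmetic(self):
        # 20 Hz over 100 s diluted to 2 Hz: exactly 200 spikes remain
        rng = np.random.default_rng(10)
        times = np.sort(rng.uniform(0, 100, size=2000))
        train = make_train(times, span_s=100.0)
        out = sync.dilute_spike_train(train, 2.0, seed=0)
        assert out.n_spikes == 200
        assert np.all(np.diff(out.spike_times) > 0)
        assert np.all(np.isin(out.spike_times, times))

    def test_target_at_or_above_rate_is_identity(self):
        times = np.sort(np.random.default_rng(11).uniform(0, 100, size=300))
        train = make_train(times, span_s=100.0)
        out = sync.dilute_spike_train(train, 5.0, seed=0)
        assert out is train

    def test_dilution_preserves_sta_shape(self):
        cfg = synthgen.SessionConfig(
            state="parkinsonian", osc_depth=0.8, seed=12
        )
        train, lfp, _ = synthgen.gen_oscillatory_pair(
            cfg, "GPe", entrained=True, span_s=600.0, include_mua=False
        )
        sta_full = sync.sta_lfp(train, lfp)
        diluted = sync.dilute_spike_train(train, 3.0, seed=1)
        sta_dil = sync.sta_lfp(diluted, lfp)
        r = np.corrcoef(sta_full.sta, sta_dil.sta)[0, 1]
        assert r > 0.9

    def test_zero_retained_spikes_rejected(self):
        train = make_train(np.linspace(0.1, 0.9, 20), span_s=1.0)
        with pytest.raises(ValidationError):
            sync.dilute_spike_train(train, 0.5, seed=0)
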