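"""PSTH estimation, baseline statistics and the responsive-bin detector."""

import numpy as np
import pytest

from bgoscillo import psth
from bgoscillo.types import ValidationError

from conftest import make_train, make_trials


def flat_psth(values, pre_s=0.5, dt=0.001):
    """Psth object with prescribed rate samples (bypasses spike binning)."""
    values = np.asarray(values, dtype=float)
    t = np.arange(values.size) * dt - pre_s
    return psth.Psth(unit_id="u", key=("appetitive", "delayed"), t=t,
                     rate=values, n_trials=1)


class TestComputePsth:
    def test_no_spikes_gives_zero_rate(self):
        trials = make_trials(3)
        train = make_train([], span_s=40.0)
        p = psth.compute_psth(train, trials, ("appetitive", "delayed"))
        assert np.all(p.rate == 0.0)
        assert p.t[0] == pytest.approx(-0.5)
        assert p.t[-1] == pytest.approx(8.0 - 0.001)

    def test_single_spike_peak_matches_kernel_height(self):
        # one trial, one spike: the smoothed peak is 1000 * g(0) for the
        # unit-area discrete Gaussian with SD 20 samples, ~19.95 spikes/s
        trials = make_trials(1)
        cue_on = trials.df["cue_on_s"].iloc[0]
        train = make_train([cue_on + 1.0], span_s=20.0)
        p = psth.compute_psth(train, trials, ("appetitive", "delayed"))
        k = np.arange(-80, 81)
        g0 = 1.0 / np.exp(-0.5 * (k / 20.0) ** 2).sum()
        assert p.rate.max() == pytest.approx(1000.0 * g0, rel=1e-9)
        assert p.rate.max() == pytest.approx(19.95, abs=0.01)

    def test_smoothing_conserves_spike_mass(self):
        rng = np.random.default_rng(1)
        trials = make_trials(5)
        span = 60.0
        times = np.sort(rng.uniform(0, span, size=800))
        train = make_train(times, span_s=span)
        p = psth.compute_psth(train, trials, ("appetitive", "delayed"))
        # raw count inside the analysis windows, per trial
        total = 0
        for cue_on in trials.df["cue_on_s"]:
            total += np.sum((times >= cue_on - 0.5) & (times < cue_on + 8.0))
        assert p.rate.sum() * p.dt * p.n_trials == pytest.approx(total, rel=0.02)

    def test_homogeneous_poisson_recovers_rate(self):
        rng = np.random.default_rng(2)
        trials = make_trials(200, condition="immediate", spacing_s=5.0)
        span = float(trials.df["outcome_s"].iloc[-1]) + 5.0
        n = rng.poisson(60.0 * span)
        train = make_train(np.sort(rng.uniform(0, span, size=n)), span_s=span)
        p = psth.compute_psth(train, trials, ("appetitive", "immediate"))
        se = np.sqrt(60.0 / (200 * 2.5))
        assert abs(p.rate.mean() - 60.0) < 3 * se

    def test_zero_trials_is_an_error(self):
        trials = make_trials(3, trial_type="neutral")
        train = make_train([1.0], span_s=40.0)
        with pytest.raises(ValidationError, match="no trials"):
            psth.compute_psth(train, trials, ("appetitive", "delayed"))


class TestBaselineStats:
    def test_constant_trace_has_zero_spread(self):
        p = flat_psth(np.full(1000, 12.0))
        bl = psth.baseline_stats(p)
        assert bl.mean_hz == 12.0
        assert bl.sd_hz == 0.0
        assert bl.abs_dev_mean_hz == 0.0

    def test_two_level_baseline_arithmetic(self):
        vals = np.full(1000, 0.0)
        vals[:500] = np.where(np.arange(500) % 2 == 0, 8.0, 12.0)
        bl = psth.baseline_stats(flat_psth(vals))
        assert bl.mean_hz == pytest.approx(10.0)
        assert bl.abs_dev_mean_hz == pytest.approx(2.0)
        assert bl.sd_hz == pytest.approx(2.0)

    def test_silent_unit_triggers_floor_path(self):
        bl = psth.baseline_stats(flat_psth(np.zeros(1000)))
        assert bl.mean_hz == 0.0 and bl.sd_hz == 0.0
        flags, pol, floored = psth.detect_responsive_bins(
            np.array([5.0]), bl, sd_floor=1.0
        )
        assert floored and flags[0] and pol[0] == 1


class TestRelativeAbsoluteResponses:
    def test_rate_equal_to_mean_gives_zero_everywhere(self):
        p = flat_psth(np.full(1000, 7.0))
        bl = psth.baseline_stats(p)
        assert np.all(psth.relative_response(p, bl) == 0.0)
        assert np.all(psth.absolute_response(p, bl) == 0.0)

    def test_pure_decrease_maps_to_positive_absolute(self):
        vals = np.full(1000, 20.0)
        vals[500:] = 14.0  # decrease of 6 spikes/s after cue
        p = flat_psth(vals)
        bl = psth.baseline_stats(p)
        rel = psth.relative_response(p, bl)
        ab = psth.absolute_response(p, bl)
        assert rel[-1] == pytest.approx(-6.0)
        assert ab[-1] == pytest.approx(6.0)  # constant baseline: abs_dev = 0

    def test_symmetric_modulation_cancels_in_rel_not_abs(self):
        up = np.full(1000, 10.0)
        up[500:] = 15.0
        down = np.full(1000, 10.0)
        down[500:] = 5.0
        rels, abss = [], []
        for vals in (up, down):
            p = flat_psth(vals)
            bl = psth.baseline_stats(p)
            rels.append(psth.relative_response(p, bl)[500:].mean())
            abss.append(psth.absolute_response(p, bl)[500:].mean())
        assert np.mean(rels) == pytest.approx(0.0, abs=1e-9)
        assert np.mean(abss) == pytest.approx(5.0)

    def test_absolute_dominates_relative_up_to_baseline_dev(self):
        # |x - m| >= x - m per sample, so abs >= rel - abs_dev_mean exactly;
        # populations mixing increases and decreases push abs above rel
        rng = np.random.default_rng(3)
        for _ in range(20):
            vals = rng.uniform(0, 30, size=1000)
            p = flat_psth(vals)
            bl = psth.baseline_stats(p)
            ab = psth.absolute_response(p, bl)
            rel = psth.relative_response(p, bl)
            assert np.all(ab >= rel - bl.abs_dev_mean_hz - 1e-12)
            assert ab.mean() >= rel.mean() - bl.abs_dev_mean_hz - 1e-12


class TestResponsiveBins:
    def test_threshold_rule(self):
        bl = psth.BaselineStats(mean_hz=10.0, sd_hz=2.0, abs_dev_mean_hz=1.5)
        binned = np.array([5.0, 3.9, -4.1, -3.9, 0.0, 4.0])
        flags, pol, _ = psth.detect_responsive_bins(binned, bl)
        np.testing.assert_array_equal(pol, [1, 0, -1, 0, 0, 1])
        np.testing.assert_array_equal(flags, pol != 0)

    def test_gaussian_null_type_one_error(self):
        # ~4.55% of standard-normal bins fall beyond +/-2 SD; never above 5%
        rng = np.random.default_rng(12345)
        draws = rng.standard_normal(100_000)
        bl = psth.BaselineStats(mean_hz=0.0, sd_hz=1.0, abs_dev_mean_hz=0.8)
        flags, _, _ = psth.detect_responsive_bins(draws, bl)
        frac = flags.mean()
        assert frac <= 0.05
        assert frac == pytest.approx(0.0455, abs=0.004)

    def test_bin_response_averages_20ms_windows(self):
        t = np.arange(2500) * 0.001 - 0.5
        trace = np.arange(2500, dtype=float)
        bin_t, binned = psth.bin_response(trace, t)
        assert binned.size == 100
        assert bin_t[1] - bin_t[0] == pytest.approx(0.02)
        assert binned[0] == pytest.approx(trace[500:520].mean())


class TestFractionResponsive:
    def test_unanimous_bin_gives_fraction_one(self):
        from conftest import make_profile

        profiles = [
            make_profile([3.0, 0.0], [1, 0], unit_id=f"u{i}") for i in range(4)
        ]
        _, frac, _ = psth.fraction_responsive(profiles)
        assert frac[0] == 1.0 and frac[1] == 0.0

    def test_cue_modulated_population_peaks_in_cue_period(self):
        from bgoscillo import synthgen

        trials = make_trials(15, condition="delayed", spacing_s=11.0)
        profile = synthgen.RateProfile(baseline_hz=60.0, segments=[("cue", 1, 30.0)])
        units = [
            synthgen.gen_modulated_spike_train(
                profile, trials, seed=k, span_s=175.0, unit_id=f"u{k}"
            )
            for k in range(6)
        ]
        profiles = psth.build_profiles(units, trials, [("appetitive", "delayed")])
        _, _, period_means = psth.fraction_responsive(profiles)
        assert period_means["cue"] > 3 * max(period_means["delay"], 0.02)

    def test_empty_profile_list_is_error(self):
        with pytest.raises(ValidationError):
            psth.fraction_responsive([])
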