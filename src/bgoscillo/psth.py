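"""Task-aligned firing-rate estimation and responsive-bin detection.

For each unit and each trial type x condition key, spikes are summed across
trials on a 1-ms grid running from 0.5 s before cue onset to outcome
delivery, scaled to spikes/s, and smoothed with a unit-area Gaussian window
(SD = 20 ms). The baseline is the last 500 ms of the inter-trial interval
(the 0.5 s immediately preceding cue onset): its mean defines the relative
PSTH (rate minus baseline mean) and, together with the mean absolute
deviation over the same window, the absolute PSTH
``|rate - mean| - mean_abs_dev`` whose natural zero is the baseline.

The relative PSTH is then segmented into consecutive non-overlapping 20-ms
bins from cue onset to outcome; a bin is responsive when its activity is at
least 2 baseline SDs away from zero (two-sided, the 95% normal band, i.e.
p < 0.05 under a Gaussian null), with polarity +1 for increases and -1 for
decreases. A unit is "modulated" for a key when at least one responsive bin
lies past cue onset.

Baseline statistics are computed on the smoothed trial-averaged trace (the
same object the detector thresholds), pooling the 1-ms samples of the
baseline window. Near-silent units can have a zero baseline SD; the detector
then substitutes a caller-supplied floor — by convention the smallest
non-zero baseline SD in the population — and flags the unit, rather than
dividing by zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import SpikeTrain, TrialTable, ValidationError

DT_S = 0.001           # PSTH resolution
SMOOTH_SD_S = 0.020    # Gaussian smoothing SD
PRE_CUE_S = 0.5        # baseline window length before cue onset
BIN_S = 0.020          # responsive-bin width
KERNEL_TRUNC_SD = 4.0


def trial_key(trial_type: str, condition: str) -> tuple:
    return (trial_type, condition)


def gaussian_kernel(sd_samples: float, trunc_sd: float = KERNEL_TRUNC_SD) -> np.ndarray:
    """Discrete unit-area Gaussian, truncated at +/- trunc_sd, renormalized."""
    half = int(np.ceil(trunc_sd * sd_samples))
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sd_samples) ** 2)
    return k / k.sum()


def smooth_reflect(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve with reflected (mirror) padding so edges keep unit mass."""
    half = (kernel.size - 1) // 2
    padded = np.pad(x, half, mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


@dataclass
class Psth:
    """Trial-averaged smoothed firing rate on a 1-ms grid.

    ``t`` is relative to cue onset and runs from ``-PRE_CUE_S`` to the
    outcome time (2 s for immediate trials, 8 s for delayed).
    """

    unit_id: str
    key: tuple
    t: np.ndarray
    rate: np.ndarray
    n_trials: int
    dt: float = DT_S


@dataclass
class BaselineStats:
    mean_hz: float
    sd_hz: float
    abs_dev_mean_hz: float

    def __post_init__(self) -> None:
        if self.sd_hz < 0 or self.abs_dev_mean_hz < 0:
            raise ValidationError("baseline SD and abs-dev mean must be >= 0")


@dataclass
class ResponseProfile:
    """Binned response of one unit for one trial key, with detector output."""

    unit_id: str
    structure: str
    key: tuple
    bin_t: np.ndarray          # bin start times, s relative to cue onset
    rel: np.ndarray            # binned relative response, spikes/s
    abs: np.ndarray            # binned absolute response, spikes/s
    responsive: np.ndarray     # bool per bin
    polarity: np.ndarray       # {+1, -1, 0} per bin
    baseline: BaselineStats
    sd_floored: bool = False

    @property
    def modulated(self) -> bool:
        """True when any responsive bin starts at or after cue onset."""
        return bool(np.any(self.responsive & (self.bin_t >= 0)))


def _post_cue_dur(condition: str, cue_dur=2.0, delay_dur=6.0) -> float:
    return cue_dur if condition == "immediate" else cue_dur + delay_dur


def compute_psth(
    spikes: SpikeTrain,
    trials: TrialTable,
    key: tuple,
    pre_s: float = PRE_CUE_S,
    dt: float = DT_S,
    smooth_sd_s: float = SMOOTH_SD_S,
) -> Psth:
    """Trial-averaged, Gaussian-smoothed PSTH for one trial key.

    Counts are summed across trials in 1-ms bins, scaled to spikes/s
    (``count / n_trials / dt``) and convolved with a unit-area Gaussian
    (SD 20 ms, truncated at 4 SD, reflected padding), which conserves spike
    mass up to edge effects.
    """
    ttype, cond = key
    rows = trials.select(ttype, cond)
    if len(rows) == 0:
        raise ValidationError(f"no trials for key {key}")
    post = _post_cue_dur(cond, trials.cue_dur_s, trials.delay_dur_s)
    n_bins = int(round((pre_s + post) / dt))
    t = (np.arange(n_bins) * dt) - pre_s
    counts = np.zeros(n_bins)
    for cue_on in rows["cue_on_s"].to_numpy():
        start = cue_on - pre_s
        if start < 0:
            raise ValidationError(
                f"baseline window of trial at cue_on={cue_on:.3f}s precedes t=0"
            )
        rel = spikes.spike_times - start
        sel = rel[(rel >= 0) & (rel < pre_s + post)]
        idx = np.minimum((sel / dt).astype(int), n_bins - 1)
        np.add.at(counts, idx, 1.0)
    rate = counts / len(rows) / dt
    kernel = gaussian_kernel(smooth_sd_s / dt)
    rate = smooth_reflect(rate, kernel)
    return Psth(
        unit_id=spikes.unit_id, key=key, t=t, rate=rate, n_trials=len(rows), dt=dt
    )


def baseline_stats(psth: Psth, pre_s: float = PRE_CUE_S) -> BaselineStats:
    """Mean, SD and mean |deviation| of the smoothed rate over the baseline.

    Statistics pool the 1-ms samples of the trial-averaged trace in the
    ``pre_s`` window before cue onset.
    """
    mask = psth.t < 0
    if not np.any(mask):
        raise ValidationError("PSTH has no pre-cue baseline window")
    base = psth.rate[mask & (psth.t >= -pre_s)]
    mean = float(base.mean())
    sd = float(base.std())
    abs_dev = float(np.abs(base - mean).mean())
    return BaselineStats(mean_hz=mean, sd_hz=sd, abs_dev_mean_hz=abs_dev)


def relative_response(psth: Psth, baseline: BaselineStats) -> np.ndarray:
    """Relative PSTH: smoothed rate minus the baseline mean."""
    return psth.rate - baseline.mean_hz


def absolute_response(psth: Psth, baseline: BaselineStats) -> np.ndarray:
    """Absolute PSTH: |rate - baseline mean| - baseline mean |deviation|.

    Subtracting the baseline mean absolute deviation restores a natural zero
    during baseline; a pure decrease of d spikes/s maps to a positive
    deflection of about d, which is why population absolute responses exceed
    relative ones whenever increases and decreases coexist.
    """
    return np.abs(psth.rate - baseline.mean_hz) - baseline.abs_dev_mean_hz


def bin_response(trace: np.ndarray, t: np.ndarray, dt: float = DT_S,
                 bin_s: float = BIN_S) -> tuple[np.ndarray, np.ndarray]:
    """Average a 1-ms trace into consecutive 20-ms bins from cue onset on.

    Returns ``(bin_start_times, bin_means)``; only full bins in ``t >= 0``
    are produced.
    """
    per = int(round(bin_s / dt))
    post = trace[t >= 0]
    n_full = post.size // per
    binned = post[: n_full * per].reshape(n_full, per).mean(axis=1)
    bin_t = np.arange(n_full) * bin_s
    return bin_t, binned


def detect_responsive_bins(
    binned_rel: np.ndarray,
    baseline: BaselineStats,
    sd_floor: float | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Flag bins at least 2 baseline SDs from zero; polarity is the sign.

    Two-sided threshold at the 95% normal band (p < 0.05 under a Gaussian
    null). If the baseline SD is zero (near-silent unit) and ``sd_floor`` is
    given, the floor substitutes the SD and the returned ``floored`` flag is
    True; with no floor, no bin can be declared responsive.

    Returns ``(responsive, polarity, floored)``.
    """
    sd = baseline.sd_hz
    floored = False
    if sd == 0.0:
        if sd_floor is not None and sd_floor > 0:
            sd = sd_floor
            floored = True
        else:
            z = np.zeros_like(binned_rel)
            return z.astype(bool), z.astype(int), False
    up = binned_rel >= 2.0 * sd
    down = binned_rel <= -2.0 * sd
    polarity = np.where(up, 1, np.where(down, -1, 0)).astype(int)
    return polarity != 0, polarity, floored


def response_profile(
    spikes: SpikeTrain,
    trials: TrialTable,
    key: tuple,
    sd_floor: float | None = None,
) -> ResponseProfile:
    """Full PSTH -> baseline -> binning -> detection chain for one key."""
    p = compute_psth(spikes, trials, key)
    bl = baseline_stats(p)
    rel = relative_response(p, bl)
    ab = absolute_response(p, bl)
    bin_t, rel_b = bin_response(rel, p.t)
    _, abs_b = bin_response(ab, p.t)
    responsive, polarity, floored = detect_responsive_bins(rel_b, bl, sd_floor)
    return ResponseProfile(
        unit_id=spikes.unit_id,
        structure=spikes.structure,
        key=key,
        bin_t=bin_t,
        rel=rel_b,
        abs=abs_b,
        responsive=responsive,
        polarity=polarity,
        baseline=bl,
        sd_floored=floored,
    )


def population_sd_floor(units, trials: TrialTable, keys) -> float | None:
    """Smallest non-zero baseline SD across a population of (unit, key)."""
    sds = []
    for u in units:
        for key in keys:
            try:
                sds.append(baseline_stats(compute_psth(u, trials, key)).sd_hz)
            except ValidationError:
                continue
    nonzero = [s for s in sds if s > 0]
    return min(nonzero) if nonzero else None


def build_profiles(
    units,
    trials: TrialTable,
    keys,
    sd_floor: float | None = None,
) -> list[ResponseProfile]:
    """Response profiles for every (unit, key); each pair is one sample.

    When ``sd_floor`` is None it is taken as the smallest non-zero baseline
    SD of the population, so silent-baseline units are thresholded against
    the most permissive scale observed rather than skipped.
    """
    if sd_floor is None:
        sd_floor = population_sd_floor(units, trials, keys)
    return [response_profile(u, trials, k, sd_floor) for u in units for k in keys]


def fraction_responsive(
    profiles: list[ResponseProfile],
    periods: dict | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Per-bin fraction of responsive profiles, plus task-period means.

    All profiles must share a bin grid (same condition). Default periods:
    cue ``[0, 2)`` s and, when the grid extends past 2 s, delay ``[2, 8)`` s.
    """
    if not profiles:
        raise ValidationError("empty profile list")
    bin_t = profiles[0].bin_t
    for p in profiles[1:]:
        if p.bin_t.size != bin_t.size:
            raise ValidationError("profiles mix immediate and delayed grids")
    flags = np.stack([p.responsive for p in profiles])
    frac = flags.mean(axis=0)
    if periods is None:
        periods = {"cue": (0.0, 2.0)}
        if bin_t[-1] >= 2.0:
            periods["delay"] = (2.0, 8.0)
    period_means = {
        name: float(frac[(bin_t >= lo) & (bin_t < hi)].mean())
        for name, (lo, hi) in periods.items()
        if np.any((bin_t >= lo) & (bin_t < hi))
    }
    return bin_t, frac, period_means
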