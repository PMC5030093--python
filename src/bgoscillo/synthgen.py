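"""Synthetic sessions with the statistical structure the analyses assume.

The generator emulates a temporal-discounting classical-conditioning session:
six trial types (appetitive / neutral / aversive crossed with immediate /
delayed outcome), a 2-s visual cue, a 6-s delay in the delayed condition, a
0.15-s outcome period and a 6-10 s inter-trial interval, with randomized
trial order and ITI duration.

Spiking is modelled as an inhomogeneous Poisson process realized by thinning:
the minimal point-process assumption that supports every downstream statistic
(PSTHs, responsive-bin detection, coherence, spike-triggered averages)
without committing to any particular spike-generation dynamics. Task
modulations are step changes of the rate within the cue / delay / outcome
periods; oscillatory entrainment is a sinusoidal rate modulation
``r(t) = b * (1 + depth * cos(2*pi*f*t - theta))`` phase-locked to a
synthetic LFP.

The LFP is pink (1/f) noise plus an oscillatory sinusoid; the phase
convention throughout the package is 0 deg = LFP positive peak, with phase
increasing later in the cycle, so spikes locked near the LFP trough sit at
180-270 deg. The multi-unit surrogate is band-limited Gaussian noise
(250-6000 Hz at 25 kHz) whose amplitude is modulated at the oscillation
frequency when the unit class is entrained — exactly the structure the
rectification + Welch pipeline is designed to detect.

Every unit draws from its own RNG stream derived from the master seed by
stable hashing of the unit label, so adding units to a session never
perturbs the realizations of existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .types import (
    CONDITIONS,
    STATES,
    TRIAL_TYPES,
    ContinuousSignal,
    SpikeTrain,
    TrialTable,
    ValidationError,
)

#: Baseline discharge rates (spikes/s) typical of each structure: projection
#: neurons of the striatum are nearly silent, cholinergic interneurons tick
#: at ~5/s, and the subthalamic and pallidal/nigral populations fire tens of
#: spikes per second.
DEFAULT_BASELINES_HZ = {
    "MSN": 2.0,
    "TAN": 5.0,
    "STN": 30.0,
    "GPe": 60.0,
    "GPi": 70.0,
    "SNr": 60.0,
}

#: Which unit classes the pathological oscillation entrains. Striatal
#: projection neurons are the notable exception: the oscillatory LFP around
#: them is strong but their spiking stays unlocked.
DEFAULT_ENTRAINMENT = {
    "MSN": False,
    "TAN": True,
    "STN": True,
    "GPe": True,
    "GPi": True,
    "SNr": True,
}


@dataclass
class SessionConfig:
    """Parameters of one synthetic recording session.

    Timing defaults mirror the behavioural task (2-s cue, 6-s delay, 0.15-s
    outcome, 6-10 s ITI). ``osc_freq_hz``/``osc_depth``/``osc_phase_deg``
    describe the low-beta oscillation of the parkinsonian regime:
    ``osc_phase_deg`` is the LFP phase (0 deg = positive peak) at which the
    entrained spike rate peaks; the default 200 deg puts spikes just past the
    trough, in the 180-270 deg range where locked units concentrate.
    """

    n_trials_per_type: int = 20
    cue_dur_s: float = 2.0
    delay_dur_s: float = 6.0
    outcome_dur_s: float = 0.15
    iti_range_s: tuple = (6.0, 10.0)
    structures: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES_HZ))
    state: str = "normal"
    osc_freq_hz: float = 10.0
    osc_depth: float = 0.0
    osc_phase_deg: float = 200.0
    lfp_fs_hz: float = 781.3
    raw_fs_hz: float = 25000.0
    lfp_osc_amp: float = 1.0
    lfp_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.iti_range_s
        if lo > hi:
            raise ValidationError("iti_range_s: min must be <= max")
        if lo < 0:
            raise ValidationError("iti_range_s must be non-negative")
        if not 0.0 <= self.osc_depth <= 1.0:
            raise ValidationError("osc_depth must lie in [0, 1]")
        for name in ("cue_dur_s", "delay_dur_s", "outcome_dur_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for label, rate in self.structures.items():
            if rate < 0:
                raise ValidationError(f"baseline rate of {label} must be >= 0")
        if self.state not in STATES:
            raise ValidationError(f"unknown state {self.state!r}")
        if not 0 < self.osc_freq_hz < self.lfp_fs_hz / 2:
            raise ValidationError("osc_freq_hz must lie in (0, lfp Nyquist)")


def unit_rng(master_seed: int, unit_label: str) -> np.random.Generator:
    """Per-unit RNG stream: stable CRC32 hash of the label spawns the seed."""
    key = zlib.crc32(unit_label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), key]))


# ---------------------------------------------------------------------------
# trial schedule


def gen_trial_schedule(config: SessionConfig, seed=None) -> TrialTable:
    """Randomized trial order and ITIs for one session.

    Each of the six type x condition combinations occurs
    ``n_trials_per_type`` times, in a uniformly shuffled order. The first cue
    comes after one ITI draw (so a 0.5-s pre-cue baseline window always
    exists); each subsequent cue follows the previous outcome period by an
    ITI drawn uniformly from ``iti_range_s``.
    """
    if config.n_trials_per_type <= 0:
        raise ValidationError("n_trials_per_type must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    combos = [(t, c) for t in TRIAL_TYPES for c in CONDITIONS]
    order = combos * config.n_trials_per_type
    rng.shuffle(order)

    lo, hi = config.iti_range_s
    rows = []
    t = float(rng.uniform(lo, hi))
    for i, (ttype, cond) in enumerate(order):
        cue_on = t
        cue_off = cue_on + config.cue_dur_s
        outcome = cue_off + (0.0 if cond == "immediate" else config.delay_dur_s)
        rows.append(
            {
                "trial_id": i,
                "type": ttype,
                "condition": cond,
                "cue_on_s": cue_on,
                "cue_off_s": cue_off,
                "outcome_s": outcome,
            }
        )
        t = outcome + config.outcome_dur_s + float(rng.uniform(lo, hi))
    df = pd.DataFrame(rows)
    return TrialTable(df=df, cue_dur_s=config.cue_dur_s, delay_dur_s=config.delay_dur_s)


def session_span_s(trials: TrialTable, config: SessionConfig, tail_s: float = 5.0) -> float:
    """Recording span covering the whole schedule plus a short tail."""
    return float(trials.df["outcome_s"].max() + config.outcome_dur_s + tail_s)


# ---------------------------------------------------------------------------
# task-modulated point process


@dataclass
class RateProfile:
    """Trial-aligned rate template: baseline plus step modulations per period.

    ``segments`` is a list of ``(period, polarity, magnitude_hz)`` with
    period in ``{"cue", "delay", "outcome"}`` and polarity +1/-1; during
    that period the rate is ``baseline + polarity * magnitude``. The rate
    must remain non-negative everywhere.
    """

    baseline_hz: float
    segments: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.baseline_hz < 0:
            raise ValidationError("baseline rate must be >= 0")
        deltas = {"cue": 0.0, "delay": 0.0, "outcome": 0.0}
        for period, polarity, magnitude in self.segments:
            if period not in deltas:
                raise ValidationError(f"unknown task period {period!r}")
            if polarity not in (-1, 1):
                raise ValidationError("segment polarity must be +1 or -1")
            if magnitude < 0:
                raise ValidationError("segment magnitude must be >= 0")
            deltas[period] += polarity * magnitude
        self._deltas = deltas
        for period, d in deltas.items():
            if self.baseline_hz + d < 0:
                raise ValidationError(
                    f"rate during {period} would be negative "
                    f"({self.baseline_hz + d:.3f} spikes/s)"
                )

    def delta_hz(self, period: str) -> float:
        return self._deltas[period]


def session_rate(
    times: np.ndarray,
    profile: RateProfile,
    trials: TrialTable,
    outcome_dur_s: float = 0.15,
) -> np.ndarray:
    """Instantaneous rate (spikes/s) at ``times`` for a profile + schedule.

    Half-open period windows: cue ``[cue_on, cue_off)``, delay
    ``[cue_off, outcome)`` (delayed trials only), outcome
    ``[outcome, outcome + outcome_dur)``.
    """
    times = np.asarray(times, dtype=float)
    rate = np.full(times.shape, profile.baseline_hz)
    df = trials.df
    cue_on = df["cue_on_s"].to_numpy()
    cue_off = df["cue_off_s"].to_numpy()
    outcome = df["outcome_s"].to_numpy()
    # map each time to the trial whose cue_on precedes it (if any)
    idx = np.searchsorted(cue_on, times, side="right") - 1
    valid = idx >= 0
    iv = idx[valid]
    tv = times[valid]
    in_cue = tv < cue_off[iv]
    in_delay = (tv >= cue_off[iv]) & (tv < outcome[iv])
    in_outcome = (tv >= outcome[iv]) & (tv < outcome[iv] + outcome_dur_s)
    add = np.zeros(tv.shape)
    add[in_cue] = profile.delta_hz("cue")
    add[in_delay] = profile.delta_hz("delay")
    add[in_outcome] = profile.delta_hz("outcome")
    rate[valid] += add
    return rate


def _poisson_thinning(rate_fn, rate_max: float, span_s: float, rng) -> np.ndarray:
    """Inhomogeneous Poisson realization on [0, span) by thinning."""
    if rate_max <= 0:
        return np.empty(0)
    n_cand = rng.poisson(rate_max * span_s)
    cand = np.sort(rng.uniform(0.0, span_s, size=n_cand))
    if cand.size == 0:
        return cand
    keep = rng.uniform(0.0, rate_max, size=cand.size) < rate_fn(cand)
    return cand[keep]


def gen_modulated_spike_train(
    profile: RateProfile,
    trials: TrialTable,
    seed,
    unit_id: str = "unit",
    structure: str = "GPe",
    state: str = "normal",
    span_s: float | None = None,
    isolation_score: float = 0.9,
    outcome_dur_s: float = 0.15,
) -> SpikeTrain:
    """Task-modulated inhomogeneous Poisson spike train for one unit.

    The expected spike count equals the integral of the piecewise-constant
    rate; realizations are reproducible under the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if span_s is None:
        span_s = float(trials.df["outcome_s"].max() + outcome_dur_s + 5.0)
    rate_max = profile.baseline_hz + max(
        0.0, *(profile.delta_hz(p) for p in ("cue", "delay", "outcome"))
    )
    times = _poisson_thinning(
        lambda t: session_rate(t, profile, trials, outcome_dur_s),
        rate_max,
        span_s,
        rng,
    )
    return SpikeTrain(
        unit_id=unit_id,
        structure=structure,
        state=state,
        spike_times=times,
        span_s=span_s,
        isolation_score=isolation_score,
    )


# ---------------------------------------------------------------------------
# oscillatory regime


def pink_noise(n: int, rng, sd: float = 1.0) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping of white Gaussian noise."""
    if n == 0:
        return np.empty(0)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0  # keep DC finite
    spec = spec / np.sqrt(f)
    out = np.fft.irfft(spec, n=n)
    out -= out.mean()
    s = out.std()
    return out * (sd / s) if s > 0 else out


def gen_lfp(config: SessionConfig, span_s: float, rng, osc: bool = True) -> ContinuousSignal:
    """Synthetic LFP: pink noise plus (optionally) an oscillatory sinusoid.

    The oscillation is ``amp * cos(2*pi*f*t)`` so the LFP phase reference
    (0 deg = positive peak) coincides with the session clock at t = 0.
    """
    n = int(round(span_s * config.lfp_fs_hz))
    t = np.arange(n) / config.lfp_fs_hz
    x = pink_noise(n, rng, sd=config.lfp_noise_sd)
    if osc:
        x = x + config.lfp_osc_amp * np.cos(2 * np.pi * config.osc_freq_hz * t)
    return ContinuousSignal(samples=x, fs_hz=config.lfp_fs_hz, kind="lfp")


MUA_BAND_HZ = (250.0, 6000.0)


def gen_mua(
    config: SessionConfig,
    span_s: float,
    rng,
    entrained: bool,
) -> ContinuousSignal:
    """Broadband multi-unit surrogate at the raw sampling rate.

    Band-limited Gaussian noise (250-6000 Hz) whose instantaneous amplitude
    is ``1 + osc_depth * cos(2*pi*f*t - theta)`` when entrained: the
    envelope, not the carrier, carries the oscillation, which is what
    rectification exposes.
    """
    n = int(round(span_s * config.raw_fs_hz))
    sos = sps.butter(
        4, MUA_BAND_HZ, btype="bandpass", fs=config.raw_fs_hz, output="sos"
    )
    carrier = sps.sosfiltfilt(sos, rng.standard_normal(n))
    if entrained and config.osc_depth > 0:
        t = np.arange(n) / config.raw_fs_hz
        theta = np.deg2rad(config.osc_phase_deg)
        carrier = carrier * (
            1.0 + config.osc_depth * np.cos(2 * np.pi * config.osc_freq_hz * t - theta)
        )
    return ContinuousSignal(
        samples=carrier,
        fs_hz=config.raw_fs_hz,
        kind="mua",
        filter_log=[
            {
                "type": "butter_bandpass",
                "band_hz": list(MUA_BAND_HZ),
                "order": 4,
                "zero_phase": True,
            }
        ],
    )


def gen_oscillatory_pair(
    config: SessionConfig,
    structure: str = "TAN",
    entrained: bool | None = None,
    span_s: float = 600.0,
    seed=None,
    unit_id: str | None = None,
    include_mua: bool = True,
) -> tuple[SpikeTrain, ContinuousSignal, ContinuousSignal | None]:
    """One unit with its adjacent LFP and multi-unit trace.

    When entrained, the spike rate is
    ``b * (1 + depth * cos(2*pi*f*t - theta))`` with ``theta =
    osc_phase_deg``: spikes concentrate at that LFP phase (0 deg = LFP
    positive peak). With ``entrained=False`` the rate is constant while the
    LFP still oscillates — the striatal-projection-neuron dissociation.

    Returns ``(spike_train, lfp, mua)``; ``mua`` is None when
    ``include_mua=False`` (the 25 kHz trace is by far the largest output).
    """
    if entrained is None:
        entrained = DEFAULT_ENTRAINMENT.get(structure, True)
    depth = config.osc_depth if entrained else 0.0
    if depth > 1.0:
        raise ValidationError("osc_depth > 1 would imply a negative rate")
    baseline = config.structures.get(structure, DEFAULT_BASELINES_HZ.get(structure))
    if baseline is None:
        raise ValidationError(f"no baseline rate for structure {structure!r}")
    if unit_id is None:
        unit_id = f"{structure}_osc"
    master = config.seed if seed is None else seed
    rng_spk = unit_rng(master, unit_id + "/spikes")
    rng_lfp = unit_rng(master, unit_id + "/lfp")
    rng_mua = unit_rng(master, unit_id + "/mua")

    f0 = config.osc_freq_hz
    theta = np.deg2rad(config.osc_phase_deg)
    if depth > 0:
        rate_fn = lambda t: baseline * (1.0 + depth * np.cos(2 * np.pi * f0 * t - theta))
        rate_max = baseline * (1.0 + depth)
    else:
        rate_fn = lambda t: np.full(np.shape(t), baseline)
        rate_max = baseline
    times = _poisson_thinning(rate_fn, rate_max, span_s, rng_spk)
    train = SpikeTrain(
        unit_id=unit_id,
        structure=structure,
        state=config.state,
        spike_times=times,
        span_s=span_s,
        isolation_score=0.9,
    )
    lfp = gen_lfp(config, span_s, rng_lfp, osc=True)
    mua = gen_mua(config, span_s, rng_mua, entrained) if include_mua else None
    return train, lfp, mua


def inject_spectral_lines(
    signal: ContinuousSignal, line_freqs, amplitudes
) -> ContinuousSignal:
    """Add pure sinusoidal contaminants (mains-like sharp PSD lines).

    The original signal is recoverable by subtracting the same sinusoids;
    used to exercise the PSD artifact-removal rule.
    """
    line_freqs = np.atleast_1d(np.asarray(line_freqs, dtype=float))
    amplitudes = np.broadcast_to(
        np.asarray(amplitudes, dtype=float), line_freqs.shape
    )
    if np.any(line_freqs >= signal.nyquist_hz):
        raise ValidationError("line frequency at or above Nyquist")
    if line_freqs.size == 0:
        return signal.with_samples(signal.samples.copy())
    t = signal.times()
    contaminated = signal.samples.astype(float).copy()
    for f, a in zip(line_freqs, amplitudes):
        contaminated += a * np.sin(2 * np.pi * f * t)
    return signal.with_samples(contaminated)


# ---------------------------------------------------------------------------
# whole-session convenience


def gen_task_session(
    config: SessionConfig,
    profiles: dict,
    n_units_per_structure: int = 5,
) -> tuple[TrialTable, list[SpikeTrain]]:
    """Trial schedule plus task-modulated units for several structures.

    ``profiles`` maps structure label -> RateProfile. Each unit gets its own
    RNG stream keyed by its label, so the population is reproducible and
    stable under insertion of new units.
    """
    trials = gen_trial_schedule(config)
    span = session_span_s(trials, config)
    units = []
    for structure, profile in profiles.items():
        for k in range(n_units_per_structure):
            uid = f"{structure}_{config.state}_{k:03d}"
            rng = unit_rng(config.seed, uid)
            units.append(
                gen_modulated_spike_train(
                    profile,
                    trials,
                    rng,
                    unit_id=uid,
                    structure=structure,
                    state=config.state,
                    span_s=span,
                    outcome_dur_s=config.outcome_dur_s,
                )
            )
    return trials, units
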