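"""Spike-LFP synchronization: coherence, phase, regression and STAs.

The spike train is turned into a continuous signal by binning spike times
into an impulse train at the LFP sampling rate, low-pass filtering at 100 Hz
(4-pole Butterworth, zero-phase) and z-normalizing. Magnitude-squared
coherence between this signal and the z-normalized LFP uses the same Welch
segmentation as the LFP PSD (3-s Hamming window, 50% overlap, nfft 2344), so
coherence values lie in [0, 1] by construction and self-coherence is
identically 1.

The phase of spiking relative to the LFP is the cross-spectrum angle at the
8-15 Hz coherence peak, mapped to [0, 360) with the package convention
0 deg = LFP positive peak and phase increasing later in the cycle (90 deg =
quarter cycle after the peak, 180 deg = trough). Population phase
distributions are summarized by 20-deg histograms and the circular mean
(resultant-vector angle).

The spike-triggered average (STA) of the LFP averages the z-normalized,
30 Hz low-passed LFP in a symmetric window around each spike; the 30 Hz
filter removes spike-waveform residue from the same electrode. To compare
units of very different rates on equal footing, spike trains firing above a
target rate can be randomly diluted — uniform subsampling without
replacement down to ``floor(target_rate * span)`` spikes — which leaves the
conditional expectation of the LFP around the retained spikes, and hence the
STA shape, unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from .spectral import NFFT_LFP, OSC_BAND_HZ, WELCH_OVERLAP, WELCH_WINDOW_S, zscore_signal
from .types import ContinuousSignal, SpikeTrain, ValidationError

SPIKE_LP_HZ = 100.0
STA_LP_HZ = 30.0
DEFAULT_STA_WINDOW_S = 0.25
PHASE_BIN_DEG = 20.0


@dataclass
class CoherenceResult:
    f: np.ndarray
    coh: np.ndarray
    peak_hz: float
    peak_coh: float
    phase_at_peak_deg: float
    n_segments: int


@dataclass
class StaResult:
    lags: np.ndarray
    sta: np.ndarray
    n_spikes: int
    diluted: bool = False
    target_rate_hz: float | None = None


@dataclass
class PhaseHistogram:
    bin_edges_deg: np.ndarray
    counts: np.ndarray
    mean_deg: float
    resultant_length: float


def spike_rate_signal(
    spikes: SpikeTrain,
    fs_out: float,
    span_s: float | None = None,
    cutoff_hz: float = SPIKE_LP_HZ,
) -> ContinuousSignal:
    """Continuous spike-density signal: binned impulses, 100 Hz LP, z-norm."""
    if fs_out <= 2 * cutoff_hz:
        raise ValidationError("fs_out must exceed twice the low-pass cutoff")
    if spikes.n_spikes == 0:
        raise ValidationError(f"unit {spikes.unit_id!r}: empty spike train")
    span = spikes.span_s if span_s is None else span_s
    n = int(round(span * fs_out))
    idx = np.minimum((spikes.spike_times * fs_out).astype(int), n - 1)
    impulses = np.bincount(idx, minlength=n).astype(float)
    sos = sps.butter(4, cutoff_hz, btype="lowpass", fs=fs_out, output="sos")
    x = sps.sosfiltfilt(sos, impulses)
    return ContinuousSignal(
        samples=zscore_signal(x),
        fs_hz=fs_out,
        kind="envelope",
        filter_log=[
            {
                "type": "butter_lowpass",
                "band_hz": [cutoff_hz],
                "order": 4,
                "zero_phase": True,
            }
        ],
    )


def _segment_params(fs: float, n: int, nfft: int, window_s: float):
    nperseg = int(round(window_s * fs))
    if n < 2 * nperseg - int(nperseg * WELCH_OVERLAP):
        raise ValidationError(
            "need at least two Welch segments for a coherence estimate"
        )
    noverlap = int(nperseg * WELCH_OVERLAP)
    n_segments = 1 + (n - nperseg) // (nperseg - noverlap)
    return nperseg, noverlap, n_segments


def ms_coherence(
    spike_sig: ContinuousSignal,
    lfp: ContinuousSignal,
    band: tuple = OSC_BAND_HZ,
    nfft: int = NFFT_LFP,
    window_s: float = WELCH_WINDOW_S,
) -> CoherenceResult:
    """Magnitude-squared coherence with peak and phase in the 8-15 Hz band.

    Both signals must share a sampling rate; the shorter span truncates the
    longer. The phase is the angle of the cross-spectrum of (LFP, spikes) at
    the coherence-peak frequency, negated and wrapped so that spikes sitting
    exactly on LFP positive peaks score 0 deg and later phases are positive.
    """
    if abs(spike_sig.fs_hz - lfp.fs_hz) > 1e-6:
        raise ValidationError(
            f"sampling rates differ: {spike_sig.fs_hz} vs {lfp.fs_hz} Hz"
        )
    n = min(spike_sig.n_samples, lfp.n_samples)
    x = zscore_signal(lfp.samples[:n])
    y = spike_sig.samples[:n]
    fs = lfp.fs_hz
    nperseg, noverlap, n_segments = _segment_params(fs, n, nfft, window_s)
    win = sps.get_window("hamming", nperseg)
    kw = dict(fs=fs, window=win, nperseg=nperseg, noverlap=noverlap, nfft=nfft,
              detrend="constant")
    f, coh = sps.coherence(x, y, **kw)
    _, pxy = sps.csd(x, y, **kw)
    in_band = (f >= band[0]) & (f <= band[1])
    if not np.any(in_band):
        raise ValidationError("band outside the frequency range")
    bi = int(np.argmax(coh[in_band]))
    peak_idx = np.flatnonzero(in_band)[bi]
    if np.abs(pxy[peak_idx]) == 0.0:
        phase = float("nan")
    else:
        # scipy's csd(x, y) averages conj(X)*Y; its angle is (arg Y - arg X).
        # A spike density cos(w t - theta) against an LFP cos(w t) then gives
        # -theta, so negate to report the LFP phase at which spikes fire.
        phase = float(np.mod(-np.degrees(np.angle(pxy[peak_idx])), 360.0))
    return CoherenceResult(
        f=f,
        coh=coh,
        peak_hz=float(f[peak_idx]),
        peak_coh=float(coh[peak_idx]),
        phase_at_peak_deg=phase,
        n_segments=n_segments,
    )


def phase_histogram(
    phases_deg,
    bin_deg: float = PHASE_BIN_DEG,
) -> PhaseHistogram:
    """Circular histogram and resultant-vector mean of pair phases."""
    phases = np.mod(np.asarray(phases_deg, dtype=float), 360.0)
    phases = phases[~np.isnan(phases)]
    if phases.size == 0:
        raise ValidationError("no defined phases to histogram")
    edges = np.arange(0.0, 360.0 + bin_deg, bin_deg)
    counts, _ = np.histogram(phases, bins=edges)
    rad = np.deg2rad(phases)
    resultant = np.mean(np.exp(1j * rad))
    mean_deg = float(np.mod(np.degrees(np.angle(resultant)), 360.0))
    return PhaseHistogram(
        bin_edges_deg=edges,
        counts=counts,
        mean_deg=mean_deg,
        resultant_length=float(np.abs(resultant)),
    )


def peak_vs_coherence_regression(lfp_band_z, coh_peaks):
    """OLS line plus Pearson r between LFP band power z and coherence peaks.

    Returns ``(slope, intercept, r, p)`` with the two-sided p of r.
    """
    x = np.asarray(lfp_band_z, dtype=float)
    y = np.asarray(coh_peaks, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need >= 3 paired observations")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValidationError("zero variance in a regression variable")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue), float(res.pvalue)


def sta_lfp(
    spikes: SpikeTrain,
    lfp: ContinuousSignal,
    window_s: float = DEFAULT_STA_WINDOW_S,
    lowpass_hz: float | None = STA_LP_HZ,
) -> StaResult:
    """Spike-triggered average of the (z-normalized, 30 Hz low-passed) LFP.

    Spikes whose +/-window extends beyond the LFP span are dropped and do
    not contribute; at least one usable spike is required.
    """
    x = zscore_signal(lfp.samples)
    if lowpass_hz is not None:
        sos = sps.butter(4, lowpass_hz, btype="lowpass", fs=lfp.fs_hz, output="sos")
        x = sps.sosfiltfilt(sos, x)
    half = int(round(window_s * lfp.fs_hz))
    centers = np.round(spikes.spike_times * lfp.fs_hz).astype(int)
    usable = centers[(centers - half >= 0) & (centers + half < x.size)]
    if usable.size == 0:
        raise ValidationError(
            f"unit {spikes.unit_id!r}: no spikes with a full +/-{window_s}s window"
        )
    offsets = np.arange(-half, half + 1)
    segs = x[usable[:, None] + offsets[None, :]]
    return StaResult(
        lags=offsets / lfp.fs_hz,
        sta=segs.mean(axis=0),
        n_spikes=int(usable.size),
    )


def dilute_spike_train(
    spikes: SpikeTrain,
    target_rate_hz: float,
    seed,
) -> SpikeTrain:
    """Random dilution of a spike train down to a target mean rate.

    Units at or below the target are returned unchanged. Otherwise a uniform
    random subset of ``floor(target_rate * span)`` spikes is retained
    (without replacement, time order preserved) so the diluted rate equals
    the target.
    """
    if target_rate_hz <= 0:
        raise ValidationError("target rate must be > 0")
    if spikes.rate_hz <= target_rate_hz:
        return spikes
    n_keep = int(np.floor(target_rate_hz * spikes.span_s))
    if n_keep == 0:
        raise ValidationError("target rate retains zero spikes over the span")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = np.sort(rng.choice(spikes.n_spikes, size=n_keep, replace=False))
    return SpikeTrain(
        unit_id=spikes.unit_id,
        structure=spikes.structure,
        state=spikes.state,
        spike_times=spikes.spike_times[keep],
        span_s=spikes.span_s,
        isolation_score=spikes.isolation_score,
    )
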