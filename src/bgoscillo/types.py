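"""Core in-memory containers shared by every pipeline stage.

Three containers anchor the data model:

``SpikeTrain``
    Timestamped activity of one sorted unit, with the metadata needed by the
    inclusion criteria (structure label, stable recording span, isolation
    score) and by the state comparisons (``normal`` vs ``parkinsonian``).

``ContinuousSignal``
    A uniformly sampled trace (raw wideband, multi-unit band, LFP, or a
    rectified envelope) carrying its sampling rate and an append-only log of
    the filters applied to it, so any spectrum can be traced back to its
    preprocessing.

``TrialTable``
    The event schedule of one behavioural session: per trial a cue onset and
    offset, an outcome time, the trial type (appetitive / neutral / aversive)
    and the condition (immediate / delayed). All task alignment is performed
    against this table, with half-open ``[start, end)`` windows on a
    session-relative, 0-based time axis in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRUCTURES = ("MSN", "TAN", "STN", "GPe", "GPi", "SNr")
STATES = ("normal", "parkinsonian")
TRIAL_TYPES = ("appetitive", "neutral", "aversive")
CONDITIONS = ("immediate", "delayed")
SIGNAL_KINDS = ("raw", "mua", "lfp", "envelope")


class ValidationError(ValueError):
    """A record violates a structural invariant; the message names it."""


@dataclass
class SpikeTrain:
    """Spike times of one unit plus the metadata used for quality filtering.

    Parameters
    ----------
    unit_id : str
        Unique identifier of the sorted unit.
    structure : str
        One of ``MSN, TAN, STN, GPe, GPi, SNr``.
    state : str
        ``normal`` or ``parkinsonian``.
    spike_times : ndarray
        Spike times in seconds, strictly within ``[0, span_s]``, ascending.
    span_s : float
        Duration of the stable recording period, seconds.
    isolation_score : float
        Sorting quality in ``[0, 1]`` (0 = multi-unit, 1 = perfect isolation).
    """

    unit_id: str
    structure: str
    state: str
    spike_times: np.ndarray
    span_s: float
    isolation_score: float

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValidationError(
                f"unit {self.unit_id!r}: unknown structure {self.structure!r}"
            )
        if self.state not in STATES:
            raise ValidationError(
                f"unit {self.unit_id!r}: unknown state {self.state!r}"
            )
        if self.span_s <= 0:
            raise ValidationError(f"unit {self.unit_id!r}: span_s must be > 0")
        if not 0.0 <= self.isolation_score <= 1.0:
            raise ValidationError(
                f"unit {self.unit_id!r}: isolation score "
                f"{self.isolation_score} outside [0, 1]"
            )
        t = self.spike_times
        if t.ndim != 1:
            raise ValidationError(f"unit {self.unit_id!r}: times must be 1-D")
        if t.size:
            if np.any(np.diff(t) < 0):
                raise ValidationError(
                    f"unit {self.unit_id!r}: spike times not ascending"
                )
            if t[0] < 0 or t[-1] > self.span_s:
                raise ValidationError(
                    f"unit {self.unit_id!r}: spike times outside [0, span_s]"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def rate_hz(self) -> float:
        """Mean discharge rate over the stable span."""
        return self.n_spikes / self.span_s


@dataclass
class ContinuousSignal:
    """Uniformly sampled trace with sampling rate and filter provenance.

    ``filter_log`` is append-only: every filtering step registers a dict
    ``{"type", "band_hz", "order", "zero_phase"}`` so downstream spectra are
    traceable to their preprocessing.
    """

    samples: np.ndarray
    fs_hz: float
    kind: str = "raw"
    filter_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise ValidationError("fs_hz must be > 0")
        if self.kind not in SIGNAL_KINDS:
            raise ValidationError(f"unknown signal kind {self.kind!r}")
        if self.samples.ndim != 1:
            raise ValidationError("samples must be a 1-D vector")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def nyquist_hz(self) -> float:
        return self.fs_hz / 2.0

    def with_samples(self, samples, kind=None, extra_filter=None) -> "ContinuousSignal":
        """New signal sharing provenance, optionally logging one more filter."""
        log = [dict(entry) for entry in self.filter_log]
        if extra_filter is not None:
            log.append(dict(extra_filter))
        return ContinuousSignal(
            samples=np.asarray(samples, dtype=float),
            fs_hz=self.fs_hz,
            kind=self.kind if kind is None else kind,
            filter_log=log,
        )

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz


TRIAL_COLUMNS = ["trial_id", "type", "condition", "cue_on_s", "cue_off_s", "outcome_s"]


@dataclass
class TrialTable:
    """Event schedule of a session; one row per trial.

    The cue is on for ``cue_dur_s`` (2 s by default); the outcome follows the
    cue offset immediately or after ``delay_dur_s`` (6 s) depending on the
    condition. Validation checks those timing invariants and monotone,
    non-overlapping trials.
    """

    df: pd.DataFrame
    cue_dur_s: float = 2.0
    delay_dur_s: float = 6.0

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()

    def validate(self, atol: float = 1e-6) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"trial table missing columns {missing}")
        df = self.df
        if not df["type"].isin(TRIAL_TYPES).all():
            bad = sorted(set(df["type"]) - set(TRIAL_TYPES))
            raise ValidationError(f"unknown trial types {bad}")
        if not df["condition"].isin(CONDITIONS).all():
            bad = sorted(set(df["condition"]) - set(CONDITIONS))
            raise ValidationError(f"unknown conditions {bad}")
        cue_len = df["cue_off_s"] - df["cue_on_s"]
        if not np.allclose(cue_len, self.cue_dur_s, atol=atol):
            raise ValidationError("cue_off - cue_on must equal the cue duration")
        lag = df["outcome_s"] - df["cue_off_s"]
        expect = np.where(df["condition"] == "immediate", 0.0, self.delay_dur_s)
        if not np.allclose(lag, expect, atol=atol):
            raise ValidationError(
                "outcome - cue_off must be 0 (immediate) or the delay duration"
            )
        if len(df) > 1 and np.any(np.diff(df["cue_on_s"].to_numpy()) <= 0):
            raise ValidationError("trials must be in ascending time order")

    def __len__(self) -> int:
        return len(self.df)

    def select(self, trial_type=None, condition=None) -> pd.DataFrame:
        """Rows matching a type and/or condition (None = no constraint)."""
        df = self.df
        if trial_type is not None:
            df = df[df["type"] == trial_type]
        if condition is not None:
            df = df[df["condition"] == condition]
        return df

    @property
    def end_s(self) -> float:
        return float(self.df["outcome_s"].max())
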