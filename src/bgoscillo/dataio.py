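"""On-disk formats and the unit inclusion criteria.

Formats are deliberately plain so every intermediate is inspectable with
standard tools and readable from any language:

* spike trains — one spike time (seconds) per line in ``<unit_id>.spikes.txt``
  plus a JSON sidecar ``<unit_id>.spikes.json`` with the metadata;
* continuous signals — little-endian float32 flat binary ``<name>.f32`` plus a
  JSON sidecar with sampling rate, kind and filter log;
* trial tables — CSV with a header.

Spike times are written with microsecond precision, comfortably finer than
the 25 microsecond tick of a 40 kHz acquisition clock, so a write/read cycle
is lossless for acquisition-grade timestamps.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    STRUCTURES,
    TRIAL_COLUMNS,
    ContinuousSignal,
    SpikeTrain,
    TrialTable,
    ValidationError,
)

_TIME_FMT = "%.6f"  # 1 us resolution on disk


# ---------------------------------------------------------------------------
# spike trains


def write_spike_train(train: SpikeTrain, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    txt = directory / f"{train.unit_id}.spikes.txt"
    np.savetxt(txt, train.spike_times, fmt=_TIME_FMT)
    meta = {
        "unit_id": train.unit_id,
        "structure": train.structure,
        "state": train.state,
        "span_s": train.span_s,
        "isolation_score": train.isolation_score,
        "n_spikes": train.n_spikes,
    }
    (directory / f"{train.unit_id}.spikes.json").write_text(json.dumps(meta, indent=1))
    return txt


def read_spike_train(txt_path) -> SpikeTrain:
    txt_path = Path(txt_path)
    sidecar = txt_path.with_suffix(".json")  # .spikes.txt -> .spikes.json
    if not sidecar.exists():
        raise ValidationError(f"missing sidecar {sidecar} for {txt_path}")
    meta = json.loads(sidecar.read_text())
    if txt_path.read_text().strip():
        times = np.loadtxt(txt_path, ndmin=1, dtype=float)
    else:
        times = np.empty(0)
    try:
        train = SpikeTrain(
            unit_id=meta["unit_id"],
            structure=meta["structure"],
            state=meta["state"],
            spike_times=times,
            span_s=float(meta["span_s"]),
            isolation_score=float(meta["isolation_score"]),
        )
    except KeyError as exc:
        raise ValidationError(f"{sidecar}: missing field {exc}") from exc
    if "n_spikes" in meta and int(meta["n_spikes"]) != train.n_spikes:
        raise ValidationError(
            f"{txt_path}: sidecar says {meta['n_spikes']} spikes, "
            f"file holds {train.n_spikes}"
        )
    return train


def write_spike_trains(trains, directory) -> list[Path]:
    return [write_spike_train(t, directory) for t in trains]


def read_spike_trains(directory) -> list[SpikeTrain]:
    directory = Path(directory)
    paths = sorted(directory.glob("*.spikes.txt"))
    return [read_spike_train(p) for p in paths]


# ---------------------------------------------------------------------------
# continuous signals


def _signal_base(path) -> str:
    """Record name without the .f32/.json extension (dots in stems kept)."""
    s = str(path)
    for ext in (".f32", ".json"):
        if s.endswith(ext):
            return s[: -len(ext)]
    return s


def write_signal(signal: ContinuousSignal, path) -> Path:
    """Write float32 flat binary + JSON sidecar; ``path`` without extension."""
    base = _signal_base(path)
    Path(base).parent.mkdir(parents=True, exist_ok=True)
    bin_path = Path(base + ".f32")
    signal.samples.astype("<f4").tofile(bin_path)
    meta = {
        "fs_hz": signal.fs_hz,
        "kind": signal.kind,
        "n_samples": signal.n_samples,
        "dtype": "<f4",
        "filter_log": signal.filter_log,
    }
    Path(base + ".json").write_text(json.dumps(meta, indent=1))
    return bin_path


def read_signal(path) -> ContinuousSignal:
    base = _signal_base(path)
    bin_path = Path(base + ".f32")
    sidecar = Path(base + ".json")
    if not sidecar.exists():
        raise ValidationError(f"missing sidecar {sidecar} for {bin_path}")
    meta = json.loads(sidecar.read_text())
    samples = np.fromfile(bin_path, dtype=meta.get("dtype", "<f4")).astype(float)
    if "n_samples" in meta and samples.size != int(meta["n_samples"]):
        raise ValidationError(
            f"{bin_path}: expected {meta['n_samples']} samples, got {samples.size}"
        )
    return ContinuousSignal(
        samples=samples,
        fs_hz=float(meta["fs_hz"]),
        kind=meta.get("kind", "raw"),
        filter_log=list(meta.get("filter_log", [])),
    )


# ---------------------------------------------------------------------------
# trial tables


def write_trials(trials: TrialTable, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trials.df.to_csv(path, index=False, float_format=_TIME_FMT)
    return path


def read_trials(path, cue_dur_s: float = 2.0, delay_dur_s: float = 6.0) -> TrialTable:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return TrialTable(df=df, cue_dur_s=cue_dur_s, delay_dur_s=delay_dur_s)


# ---------------------------------------------------------------------------
# inclusion criteria

#: (min stable span s, min isolation score) per structure group. MSN and STN
#: use relaxed thresholds: MSN somata are small and the STN is densely packed,
#: which makes long stable, well-isolated recordings hard to obtain there.
RELAXED_STRUCTURES = ("MSN", "STN")
SPAN_MIN_S = {"default": 900.0, "relaxed": 540.0}
ISOLATION_MIN = {"default": 0.7, "relaxed": 0.6}


def unit_passes_inclusion(train: SpikeTrain) -> bool:
    """Quality gate on one unit: stable span and isolation score thresholds.

    GPe/GPi/SNr/TAN units need >= 15 min of stable recording and isolation
    >= 0.7; MSN and STN units need >= 9 min and isolation >= 0.6.
    """
    if train.structure not in STRUCTURES:
        raise ValidationError(
            f"unit {train.unit_id!r}: unknown structure {train.structure!r}"
        )
    group = "relaxed" if train.structure in RELAXED_STRUCTURES else "default"
    return (
        train.span_s >= SPAN_MIN_S[group]
        and train.isolation_score >= ISOLATION_MIN[group]
    )


def apply_inclusion_criteria(units) -> tuple[list[SpikeTrain], list[SpikeTrain]]:
    """Partition units into (kept, rejected); exhaustive and disjoint."""
    kept, rejected = [], []
    for u in units:
        (kept if unit_passes_inclusion(u) else rejected).append(u)
    return kept, rejected


def validate_directory(directory) -> dict:
    """Validate all records under a directory; returns a summary dict."""
    directory = Path(directory)
    if not directory.is_dir():
        raise ValidationError(f"not a directory: {directory}")
    summary = {"spike_trains": 0, "signals": 0, "trial_tables": 0, "errors": []}
    for p in sorted(directory.rglob("*.spikes.txt")):
        try:
            read_spike_train(p)
            summary["spike_trains"] += 1
        except (ValidationError, ValueError) as exc:
            summary["errors"].append(f"{p}: {exc}")
    for p in sorted(directory.rglob("*.f32")):
        try:
            read_signal(p)
            summary["signals"] += 1
        except (ValidationError, ValueError) as exc:
            summary["errors"].append(f"{p}: {exc}")
    for p in sorted(directory.rglob("*trials*.csv")):
        try:
            read_trials(p)
            summary["trial_tables"] += 1
        except (ValidationError, ValueError) as exc:
            summary["errors"].append(f"{p}: {exc}")
    return summary
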