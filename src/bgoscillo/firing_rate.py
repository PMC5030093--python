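"""Discharge-rate summaries and normal vs parkinsonian comparisons.

Each unit's rate is its spike count over its stable recording span. Units
are grouped by (structure, state) with mean, SEM and count; the state
comparison expresses the parkinsonian group mean as a percentage of the
normal one (100% = unchanged).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ValidationError


def summarize_rates(units) -> pd.DataFrame:
    """Per-unit discharge rates over the stable span."""
    if not units:
        raise ValidationError("no units to summarize")
    return pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in units],
            "structure": [u.structure for u in units],
            "state": [u.state for u in units],
            "n_spikes": [u.n_spikes for u in units],
            "span_s": [u.span_s for u in units],
            "rate_hz": [u.rate_hz for u in units],
        }
    )


def group_summary(rates: pd.DataFrame) -> pd.DataFrame:
    """Mean, SEM and n of the rate per (structure, state)."""
    g = rates.groupby(["structure", "state"])["rate_hz"]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "mean_hz", "sem": "sem_hz", "count": "n_units"})


def percent_change(
    rates: pd.DataFrame,
    before_state: str = "normal",
    after_state: str = "parkinsonian",
) -> pd.DataFrame:
    """After-state group mean as a percentage of the before-state mean.

    Structures missing either state, or with a zero before-mean, get NaN
    (missing marker) rather than a fabricated value.
    """
    summary = group_summary(rates)
    rows = []
    for structure in sorted(summary["structure"].unique()):
        sub = summary[summary["structure"] == structure]
        before = sub[sub["state"] == before_state]["mean_hz"]
        after = sub[sub["state"] == after_state]["mean_hz"]
        if len(before) and len(after) and float(before.iloc[0]) > 0:
            pct = 100.0 * float(after.iloc[0]) / float(before.iloc[0])
        else:
            pct = float("nan")
        rows.append({"structure": structure, "percent_change": pct})
    return pd.DataFrame(rows)


def rate_histogram(rates: pd.DataFrame, bin_hz: float = 5.0):
    """Rate distribution per (structure, state); returns edges and counts."""
    top = float(np.ceil(rates["rate_hz"].max() / bin_hz) * bin_hz) or bin_hz
    edges = np.arange(0.0, top + bin_hz, bin_hz)
    out = {}
    for (structure, state), sub in rates.groupby(["structure", "state"]):
        counts, _ = np.histogram(sub["rate_hz"], bins=edges)
        out[(structure, state)] = counts
    return edges, out
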