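"""Principal response polarity and input-downstream similarity coefficients.

A unit's response over a task period is labelled an *increase* or a
*decrease* when at least 75% of its modulated (responsive) bins in that
period share that polarity; otherwise it is unclassified. Every basal-ganglia
input unit (MSN or STN) is then paired with every downstream unit (GPe, GPi
or SNr) — the recordings being non-simultaneous, pairing is across the full
cross product — and each pair is classified by the two principal polarities
(Inc-Inc, Inc-Dec, Dec-Inc, Dec-Dec).

The similarity coefficient of a pair is the zero-lag coefficient of the
cross-correlation of the two binned relative PSTHs over the period. Among
normalizations consistent with the stated [-1, +1] range, the mean-removed,
unit-normalized (Pearson) form is used: identical profiles score +1,
sign-flipped ones -1, and the value is invariant to affine rescaling of
either input. Trial types are pooled when aggregating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .psth import ResponseProfile
from .types import ValidationError

POLARITY_RULE_FRACTION = 0.75
INPUT_STRUCTURES = ("MSN", "STN")
DOWNSTREAM_STRUCTURES = ("GPe", "GPi", "SNr")


@dataclass
class PolarityLabel:
    label: str              # {"increase", "decrease", "unclassified"}
    n_increase_bins: int
    n_decrease_bins: int

    @property
    def n_modulated(self) -> int:
        return self.n_increase_bins + self.n_decrease_bins


def principal_polarity(
    profile: ResponseProfile,
    period: tuple[float, float],
) -> PolarityLabel:
    """Dominant polarity of the modulated bins within ``period`` (s).

    Applies the 75% rule to the responsive bins whose start lies in the
    half-open period window; zero modulated bins leave the unit
    unclassified with a zero basis.
    """
    lo, hi = period
    sel = (profile.bin_t >= lo) & (profile.bin_t < hi)
    if not np.any(sel):
        raise ValidationError(f"period {period} outside profile time range")
    pol = profile.polarity[sel]
    n_inc = int((pol == 1).sum())
    n_dec = int((pol == -1).sum())
    total = n_inc + n_dec
    label = "unclassified"
    if total > 0:
        if n_inc / total >= POLARITY_RULE_FRACTION:
            label = "increase"
        elif n_dec / total >= POLARITY_RULE_FRACTION:
            label = "decrease"
    return PolarityLabel(label=label, n_increase_bins=n_inc, n_decrease_bins=n_dec)


def similarity_coefficient(rel_a: np.ndarray, rel_b: np.ndarray) -> float:
    """Zero-lag normalized cross-correlation of two binned responses.

    Mean-removed and unit-normalized, hence in [-1, +1]; NaN when either
    vector is constant (zero variance leaves the coefficient undefined).
    """
    a = np.asarray(rel_a, dtype=float)
    b = np.asarray(rel_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("binned responses must have equal length")
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return float("nan")
    return float(np.dot(a, b) / (na * nb))


def polarity_fractions(profiles, period) -> dict:
    """Fractions of increase / decrease / unclassified labels in a set."""
    labels = [principal_polarity(p, period).label for p in profiles]
    n = len(labels)
    if n == 0:
        raise ValidationError("empty profile list")
    return {
        lab: labels.count(lab) / n
        for lab in ("increase", "decrease", "unclassified")
    }


PAIR_CLASSES = ("Inc-Inc", "Inc-Dec", "Dec-Inc", "Dec-Dec")
_SHORT = {"increase": "Inc", "decrease": "Dec"}


def pair_analysis(
    inputs: list[ResponseProfile],
    downstream: list[ResponseProfile],
    period: tuple[float, float],
) -> pd.DataFrame:
    """Similarity coefficients of all input x downstream pairs by class.

    Unclassified units are excluded from the four polarity classes; pairs
    with an undefined coefficient (constant profile) are dropped. Profiles
    of different trial types are pooled. Returns one row per
    (input_structure, pair_class) with the mean coefficient and pair count;
    classes with no pairs are reported with NaN mean and n = 0.
    """
    for p in inputs:
        if p.structure not in INPUT_STRUCTURES:
            raise ValidationError(
                f"{p.unit_id}: {p.structure} is not an input structure"
            )
    for p in downstream:
        if p.structure not in DOWNSTREAM_STRUCTURES:
            raise ValidationError(
                f"{p.unit_id}: {p.structure} is not a downstream structure"
            )
    lo, hi = period
    records = []
    for pi in inputs:
        li = principal_polarity(pi, period)
        if li.label == "unclassified":
            continue
        sel_i = (pi.bin_t >= lo) & (pi.bin_t < hi)
        for pd_ in downstream:
            ld = principal_polarity(pd_, period)
            if ld.label == "unclassified":
                continue
            sel_d = (pd_.bin_t >= lo) & (pd_.bin_t < hi)
            coef = similarity_coefficient(pi.rel[sel_i], pd_.rel[sel_d])
            if np.isnan(coef):
                continue
            records.append(
                {
                    "input_structure": pi.structure,
                    "pair_class": f"{_SHORT[li.label]}-{_SHORT[ld.label]}",
                    "coefficient": coef,
                }
            )
    raw = pd.DataFrame(records, columns=["input_structure", "pair_class", "coefficient"])
    rows = []
    for struct in sorted({p.structure for p in inputs}):
        for cls in PAIR_CLASSES:
            sub = raw[(raw["input_structure"] == struct) & (raw["pair_class"] == cls)]
            rows.append(
                {
                    "input_structure": struct,
                    "pair_class": cls,
                    "mean_coefficient": float(sub["coefficient"].mean())
                    if len(sub)
                    else float("nan"),
                    "n_pairs": int(len(sub)),
                }
            )
    return pd.DataFrame(rows)
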