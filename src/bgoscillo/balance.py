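"""Time-varying increase/decrease balance of population activity.

At each 20-ms bin, among the profiles with a responsive bin there, the
fraction showing an increase (polarity +1) and a decrease (-1) is computed,
together with the mean magnitude (|relative response| in spikes/s) of each
class. The I/D balance weights the fractions by their magnitudes:

    I = frac_inc * mag_inc,  D = frac_dec * mag_dec
    balance = (I - D) / (I + D)

so +1 means increases fully dominate, -1 decreases, 0 parity. Each
(unit, trial-type) profile counts as one sample. Bins with no responsive
profile are undefined (NaN) and are excluded from period means rather than
zero-filled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .psth import ResponseProfile
from .types import ValidationError


def id_balance(frac_inc: float, frac_dec: float, mag_inc: float, mag_dec: float) -> float:
    """Magnitude-weighted relative dominance of increases over decreases.

    Returns NaN when both weighted terms vanish (no responsive activity).
    """
    i = frac_inc * mag_inc
    d = frac_dec * mag_dec
    if i < 0 or d < 0:
        raise ValidationError("fractions and magnitudes must be >= 0")
    if i + d == 0:
        return float("nan")
    return (i - d) / (i + d)


def _stack(profiles: list[ResponseProfile]):
    if not profiles:
        raise ValidationError("empty profile list")
    bin_t = profiles[0].bin_t
    for p in profiles[1:]:
        if p.bin_t.size != bin_t.size:
            raise ValidationError("profiles mix immediate and delayed grids")
    polarity = np.stack([p.polarity for p in profiles])      # (units, bins)
    rel = np.stack([p.rel for p in profiles])
    return bin_t, polarity, rel


def inc_dec_fractions(profiles: list[ResponseProfile]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin fractions of increases and decreases among responsive bins.

    Returns ``(bin_t, frac_inc, frac_dec)``; NaN where no profile is
    responsive. Where defined, ``frac_inc + frac_dec == 1``.
    """
    bin_t, polarity, _ = _stack(profiles)
    n_resp = (polarity != 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_inc = np.where(n_resp > 0, (polarity == 1).sum(axis=0) / n_resp, np.nan)
        frac_dec = np.where(n_resp > 0, (polarity == -1).sum(axis=0) / n_resp, np.nan)
    return bin_t, frac_inc, frac_dec


def inc_dec_magnitudes(profiles: list[ResponseProfile]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin mean |relative response| of increasing and decreasing units.

    NaN where a class has no member at that bin.
    """
    bin_t, polarity, rel = _stack(profiles)
    mag = np.abs(rel)
    out = []
    for pol in (1, -1):
        mask = polarity == pol
        n = mask.sum(axis=0)
        s = np.where(mask, mag, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out.append(np.where(n > 0, s / np.maximum(n, 1), np.nan))
    return bin_t, out[0], out[1]


def balance_series(
    profiles: list[ResponseProfile],
    periods: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full balance time course plus period means.

    Returns a DataFrame with columns ``t, frac_inc, frac_dec, mag_inc,
    mag_dec, id_balance`` and a dict of period-mean balances (undefined bins
    excluded, not zero-filled). Classes absent at a bin contribute a zero
    weighted term, so a bin with only increases scores +1.
    """
    bin_t, frac_inc, frac_dec = inc_dec_fractions(profiles)
    _, mag_inc, mag_dec = inc_dec_magnitudes(profiles)
    i = np.nan_to_num(frac_inc) * np.nan_to_num(mag_inc)
    d = np.nan_to_num(frac_dec) * np.nan_to_num(mag_dec)
    with np.errstate(invalid="ignore", divide="ignore"):
        bal = np.where(i + d > 0, (i - d) / (i + d), np.nan)
    df = pd.DataFrame(
        {
            "t": bin_t,
            "frac_inc": frac_inc,
            "frac_dec": frac_dec,
            "mag_inc": mag_inc,
            "mag_dec": mag_dec,
            "id_balance": bal,
        }
    )
    if periods is None:
        periods = {"cue": (0.0, 2.0)}
        if bin_t[-1] >= 2.0:
            periods["delay"] = (2.0, 8.0)
    period_means = {}
    for name, (lo, hi) in periods.items():
        sel = bal[(bin_t >= lo) & (bin_t < hi)]
        sel = sel[~np.isnan(sel)]
        period_means[name] = float(sel.mean()) if sel.size else float("nan")
    return df, period_means
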