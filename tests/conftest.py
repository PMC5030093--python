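"""Shared fixtures: small deterministic sessions and helper builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bgoscillo import synthgen
from bgoscillo.psth import BaselineStats, ResponseProfile
from bgoscillo.types import SpikeTrain, TrialTable


@pytest.fixture
def small_config():
    return synthgen.SessionConfig(n_trials_per_type=5, seed=123)


@pytest.fixture
def small_schedule(small_config):
    return synthgen.gen_trial_schedule(small_config)


def make_trials(n, condition="delayed", trial_type="appetitive", spacing_s=None):
    """Regularly spaced single-key trial table starting at t = 1 s."""
    post = 2.0 if condition == "immediate" else 8.0
    if spacing_s is None:
        spacing_s = post + 3.0
    cue_on = 1.0 + spacing_s * np.arange(n)
    df = pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "type": trial_type,
            "condition": condition,
            "cue_on_s": cue_on,
            "cue_off_s": cue_on + 2.0,
            "outcome_s": cue_on + post,
        }
    )
    return TrialTable(df=df)


def make_train(times, span_s, structure="GPe", state="normal", unit_id="u0"):
    return SpikeTrain(
        unit_id=unit_id,
        structure=structure,
        state=state,
        spike_times=np.asarray(times, dtype=float),
        span_s=span_s,
        isolation_score=0.9,
    )


def make_profile(rel, polarity, structure="GPe", unit_id="u0", bin_s=0.02):
    """ResponseProfile straight from binned values (detector bypassed)."""
    rel = np.asarray(rel, dtype=float)
    polarity = np.asarray(polarity, dtype=int)
    return ResponseProfile(
        unit_id=unit_id,
        structure=structure,
        key=("appetitive", "delayed"),
        bin_t=np.arange(rel.size) * bin_s,
        rel=rel,
        abs=np.abs(rel),
        responsive=polarity != 0,
        polarity=polarity,
        baseline=BaselineStats(mean_hz=10.0, sd_hz=1.0, abs_dev_mean_hz=0.8),
    )
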