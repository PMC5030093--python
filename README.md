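# bgoscillo

Analysis pipeline for spiking and field-potential recordings along the
basal-ganglia (BG) main axis — striatum (projection neurons, MSN; cholinergic
interneurons, TAN), subthalamic nucleus (STN) and the downstream pallidal and
nigral nuclei (GPe, GPi, SNr) — during a cued conditioning task, in the
normal and the parkinsonian state. It is written for systems
neurophysiologists who need the task-locked response statistics and the
pathological-oscillation analyses of such datasets as tested, reusable code,
together with a synthetic-session generator that reproduces the statistical
structure of the recordings so every stage can be validated end to end
without access to raw data.

## What it computes

**Task-locked response statistics.** Per unit and trial type, spikes are
accumulated in 1-ms bins across trials and smoothed with a Gaussian window
(SD = 20 ms). With baseline mean *m* and mean absolute deviation *d* taken
over the last 500 ms of the inter-trial interval, the relative PSTH is
*r(t) − m* and the absolute PSTH is *|r(t) − m| − d*. The relative PSTH is
segmented into 20-ms bins; a bin is *responsive* when it lies at least 2
baseline SDs from zero (two-sided, p < 0.05 under a Gaussian null). From the
responsive bins the package derives: the fraction of responsive units over
time; the fractions and mean magnitudes of increases and decreases; and the
magnitude-weighted increase/decrease balance

    I = frac_inc · mag_inc,  D = frac_dec · mag_dec,
    I/D balance = (I − D) / (I + D)  ∈ [−1, +1].

A unit's principal polarity over a task period is *increase* (*decrease*)
when ≥ 75% of its modulated bins share that sign; BG input units (MSN, STN)
are paired with downstream units (GPe, GPi, SNr) and each pair's response
similarity is the zero-lag coefficient of the cross-correlation of their
binned relative PSTHs (Pearson form, in [−1, +1]).

**Oscillation analyses.** The raw 25-kHz trace is band-passed 250–6000 Hz,
z-normalized and rectified; Welch spectra (3-s Hamming window, 50% overlap,
nfft = 75000 at 25 kHz or 2344 at the 781.3-Hz LFP rate, 1/3-Hz resolution,
per-segment demeaning) of this envelope expose multi-unit burst frequencies.
The 8–15 Hz band peak is scored as a z-value against the 55–75 Hz tail mean
and SD. LFP spectra are cleaned of sharp contaminant lines: any local peak
exceeding twice the mean of its ±2-bin neighbours is blanked together with
those neighbours. Spike–LFP locking is quantified by magnitude-squared
coherence between the 100-Hz-low-passed, z-normalized spike train and the
LFP (same Welch segmentation; coherence ∈ [0, 1] by construction), with the
phase at the 8–15 Hz coherence peak reported in the convention 0° = LFP
positive peak (180° = trough), and by spike-triggered averages of the
30-Hz-low-passed LFP, with random spike-train dilution to a common target
rate as a rate-matching control.

## Worked example

Generate a parkinsonian cholinergic-interneuron-like unit entrained at
10 Hz (depth 0.8), with its adjacent LFP and multi-unit trace, and run the
oscillation analyses:

```python
import numpy as np
from bgoscillo import synthgen, spectral, sync

cfg = synthgen.SessionConfig(state="parkinsonian", osc_depth=0.8,
                             osc_freq_hz=10.0, seed=42)
train, lfp, mua = synthgen.gen_oscillatory_pair(
    cfg, structure="TAN", span_s=300.0, include_mua=True)

env = spectral.preprocess_mua(mua)
peak = spectral.psd_peak_zscore(spectral.welch_psd(env))
print(f"envelope 8-15 Hz peak: {peak.peak_hz:.2f} Hz, z = {peak.z:.1f}")

sig = sync.spike_rate_signal(train, lfp.fs_hz, span_s=train.span_s)
coh = sync.ms_coherence(sig, lfp)
print(f"coherence peak: {coh.peak_coh:.3f} at {coh.peak_hz:.2f} Hz, "
      f"phase {coh.phase_at_peak_deg:.0f} deg")

sta = sync.sta_lfp(train, lfp)
diluted = sync.dilute_spike_train(train, 2.0, seed=0)
sta_d = sync.sta_lfp(diluted, lfp)
print(f"STA dilution correlation: "
      f"{np.corrcoef(sta.sta, sta_d.sta)[0, 1]:.3f}")
```

Output:

```
envelope 8-15 Hz peak: 10.00 Hz, z = 76734.9
coherence peak: 0.675 at 10.00 Hz, phase 199 deg
STA dilution correlation: 0.998
```

The envelope spectrum recovers the injected 10-Hz burst modulation (an
enormous z against the flat 55–75 Hz tail); the spike–LFP coherence peaks at
the same frequency with spikes locked near the LFP trough (199°, inside the
180–270° range characteristic of entrained BG units); and diluting the unit
from ~5 to 2 spikes/s leaves the STA waveform essentially unchanged
(r = 0.998), confirming that dilution is a fair rate-matching control. The
same analyses on a striatal-projection-neuron-like unit (`structure="MSN"`,
not entrained) return a null-level z and bias-level coherence while its LFP
still oscillates — the input/downstream dissociation the pipeline is built
to expose.

The full pipeline (synthesis → validation → PSTH/balance → pairing →
spectra → coherence/STA → rates → report with figures and a manifest) runs
from one config:

```bash
bg-oscillo run --out report/ --seed 1
```

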