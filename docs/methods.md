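# Methods

This note documents the models, estimators and numerical conventions the
package implements, the assumptions behind the synthetic-data generator, and
the design choices made where the procedure was genuinely open.

## Task model and time conventions

All analyses are anchored to a trial table describing a cued conditioning
session: six trial types (appetitive / neutral / aversive crossed with
immediate / delayed outcome), a 2-s visual cue, a 6-s delay between cue
offset and outcome in the delayed condition, a 0.15-s outcome period, and an
inter-trial interval drawn uniformly from 6–10 s with randomized trial
order. Time is session-relative, 0-based, in seconds; every alignment window
is half-open `[start, end)`. Task periods after cue onset are cue `[0, 2)` s
and delay `[2, 8)` s.

Units carry a structure label (MSN, TAN, STN, GPe, GPi, SNr), a state
(normal / parkinsonian), the duration of their stable recording span and an
isolation score in [0, 1]. The inclusion filter keeps a unit when its span
is at least 15 min and its isolation at least 0.7, relaxed to 9 min and 0.6
for MSN and STN units (small somata and dense packing make long
well-isolated recordings in those targets disproportionately hard); the
filter is a pure function of (structure, span, isolation) and partitions any
population exhaustively and disjointly.

## PSTH estimation and responsive bins

Spike counts are accumulated in 1-ms bins from 0.5 s before cue onset to the
outcome, summed over the trials of one type × condition, scaled to spikes/s
and convolved with a unit-area discrete Gaussian of SD 20 ms. Numerical
choices: the kernel is truncated at ±4 SD and renormalized (mass error of
the untruncated tail < 1e-4); edges use reflected padding, which preserves
total spike mass to the edge bins.

Baseline statistics (mean m, SD s, mean absolute deviation d) are computed
over the 0.5-s pre-cue window of the smoothed trial-averaged trace — the
same object the detector later thresholds — pooling its 1-ms samples. The
relative PSTH is r(t) − m; the absolute PSTH is |r(t) − m| − d, whose
subtraction of d restores a natural zero during baseline. Note the exact
relation abs ≥ rel − d per sample: the population-level excess of absolute
over relative responses emerges when increases and decreases coexist and
cancel in the relative average, which is the measure's purpose.

The relative PSTH is averaged into consecutive, non-overlapping 20-ms bins
from cue onset to outcome; a bin is responsive when its value is ≥ +2s or
≤ −2s (two-sided 95% normal band; the measured false-positive rate on a
Gaussian null is 2Φ(−2) ≈ 4.55%). A unit is *modulated* when at least one
responsive bin starts at or after cue onset.

Degenerate inputs: a near-silent unit can have s = 0. The detector then
substitutes a caller-supplied floor — by default the smallest non-zero
baseline SD in the analyzed population — and flags the unit, rather than
dividing by zero or silently declaring everything responsive. With no floor
available, no bin is flagged.

## Increase/decrease balance

At each 20-ms bin, among profiles responsive there, frac_inc and frac_dec
are the polarity fractions (summing to 1 where defined) and mag_inc/mag_dec
the mean |relative response| of each class. The balance is
(I − D)/(I + D) with I = frac_inc·mag_inc and D = frac_dec·mag_dec: bounded
in [−1, 1], ±1 exactly when one class is absent, antisymmetric under
exchange of the classes. Each (unit, trial type) profile is one sample; bins
with no responsive profile are undefined (NaN) and excluded from period
means rather than zero-filled, so sparse bins do not drag means toward zero.

## Principal polarity and pair similarity

Over a task period, a profile's principal polarity is *increase*
(*decrease*) when at least 75% of its modulated bins are positive
(negative); ties and mixtures below 75% are unclassified and excluded from
pair classes (but counted in polarity-fraction summaries). The 75% rule is
applied per task period, matching the per-period character of the
polarity-fraction analyses; a whole-span label can be obtained by passing
the full cue→outcome window as the period.

The similarity coefficient of two equal-length binned relative PSTHs is
their zero-lag cross-correlation coefficient in the mean-removed,
unit-normalized (Pearson) form — the normalization consistent with the
stated [−1, +1] range, which raw covariance would not guarantee. Constant
profiles leave it undefined (NaN). Pairs are the full cross product of input
(MSN, STN) and downstream (GPe, GPi, SNr) profiles — the recordings are not
simultaneous, so pairing carries no trial-by-trial information — classified
by the two principal polarities, with trial types pooled.

## Spectra of multi-unit envelopes and LFPs

The multi-unit pipeline band-passes the raw trace 250–6000 Hz (4-pole
Butterworth), z-normalizes (making the statistic independent of electrode
impedance and spike amplitude; a zero-variance trace maps to zeros rather
than raising), and rectifies with the absolute operator. The rectified
envelope carries burst periodicities far below the carrier band.

All spectra use Welch's method: 3-s Hamming windows, 50% overlap, the mean
of every windowed segment subtracted (removing the DC the rectifier
introduces), nfft = 75000 at 25 kHz and 2344 at 781.3 Hz — both exactly
one segment length, so no zero-padding — giving 1/3-Hz bin spacing
(fs/nfft). Filters are applied zero-phase (forward–backward), matching
offline usage.

The 8–15 Hz band peak is z-scored against the mean and SD of the 55–75 Hz
tail. Because the peak is a maximum over ~21 bins, its null distribution is
not centred at zero: with no oscillation the z-value concentrates around
+1–3 (the expected maximum of that many near-independent bin estimates).
This bias is immaterial in practice — entrained units at modulation depth
0.8 score z in the tens of thousands — and the tests therefore check the
dissociation (entrained ≫ null) and the bounded null range, not z ≈ 0.

LFP spectra are computed on the z-normalized LFP without rectification. The
artifact-removal rule scans the spectrum once, in ascending frequency, for
strict local maxima whose power exceeds twice the mean of the bins two steps
either side; each hit blanks the five bins centred on the peak (NaN).
Overlapping removals union; peaks within two bins of either edge are
skipped and kept; the pass is idempotent and never creates power. Broad
genuine humps fail the 2× criterion and survive. The scan is not iterated
after removals: a single pass over the original spectrum suffices for
line-like contaminants and avoids eroding genuine structure adjacent to a
removed line.

## Spike–field coherence, phase and STA

The spike train becomes a continuous signal by binning spike times into an
impulse train at the LFP rate (781.3 Hz — the common analysis grid, since
the LFP is the band-limited signal), low-pass filtering at 100 Hz (4-pole,
zero-phase) and z-normalizing. Magnitude-squared coherence with the
z-normalized LFP uses the LFP Welch segmentation, guaranteeing values in
[0, 1] and self-coherence ≡ 1; at least two segments are required (one
segment degenerates to coherence 1 everywhere). For independent signals the
estimator's bias floor is ≈ 1/n_segments, which the tests use as the null
reference.

Phase convention: 0° = LFP positive peak, increasing later in the cycle
(180° = trough). The reported phase is the negated angle of the averaged
cross-spectrum of (LFP, spike signal) at the 8–15 Hz coherence-peak bin,
wrapped to [0°, 360°); with this sign, spikes firing exactly at LFP positive
peaks score 0° and at troughs 180°, and delaying the LFP by Δt shifts the
phase by −360°·f·Δt, both verified in tests. Population phases are
summarized by 20°-bin histograms and the resultant-vector circular mean.
The LFP-power vs coherence relation is summarized by ordinary least squares
with the Pearson r and its two-sided p.

The STA averages the z-normalized, 30-Hz low-passed LFP (the low-pass
removes same-electrode spike residue) over a symmetric ±0.25-s window — more
than two cycles at 10 Hz — dropping spikes whose window is truncated.
Dilution control: units firing above a target rate (by convention the mean
MSN rate) are randomly subsampled without replacement to
⌊target·span⌋ spikes. Subsampling uniformly at random preserves the
conditional expectation of the LFP around retained spikes, so the STA shape
is invariant; the tests confirm waveform correlation > 0.9 at realistic
counts.

## Synthetic-session generator

The generator produces the statistical structure the analyses assume, not a
biophysical circuit model.

* **Point process.** Spiking is an inhomogeneous Poisson process realized by
  thinning against the peak rate — the minimal assumption supporting all
  downstream statistics; refractoriness, bursting and rate adaptation are
  deliberately absent. Task modulations are step rate changes on the cue /
  delay / outcome periods; effect sizes are free parameters (the analyses'
  detection thresholds, not the generator, decide what is "responsive").
* **Baseline rates** default to values typical of each structure: MSN 2,
  TAN 5, STN 30, GPe 60, GPi 70, SNr 60 spikes/s.
* **Oscillatory regime.** An entrained unit's rate is
  b·(1 + depth·cos(2πft − θ)) with f = 10 Hz and θ = 200° by default, so
  spikes concentrate just past the LFP trough (the 180–270° region).
  MSN-like units are not entrained — their rate stays constant while the
  adjacent LFP oscillates — reproducing the input/downstream dissociation.
* **LFP** = pink (1/f) noise (SD 0.5) + a unit-amplitude cosine at the
  oscillation frequency (phase 0 at t = 0, the phase reference). **MUA** =
  Gaussian noise band-limited to 250–6000 Hz at 25 kHz whose instantaneous
  amplitude is modulated by the same factor when entrained: the envelope,
  not the carrier, carries the oscillation, which is exactly what the
  rectification pipeline detects. Sharp sinusoidal lines can be injected
  into any signal to exercise artifact removal.
* **Reproducibility.** Every unit draws from its own RNG stream obtained
  from the master seed and a CRC32 hash of the unit label, so adding units
  never perturbs existing realizations; identical config + seed gives
  bit-identical output.

What the generator does *not* emulate: spike waveforms and sorting errors,
non-Poisson discharge statistics, volume-conducted LFP structure across
electrodes, behavioural (licking/blinking) signals, and within-session
non-stationarity. Passing tests therefore validate the estimators'
correctness and calibration on data satisfying their stated assumptions, not
robustness to every pathology of real recordings.

## Problem sizes in the tests

The test suite exercises the oscillation-recovery analyses at 10 units per
class with 10-minute spans (entrainment depth 0.8), balance recovery at 12
units × 15 trials per type, and the detector calibration at 10^5 null bins —
sizes at which every recovered quantity has comfortable margin over its
sampling error while the whole suite runs in a few minutes on one core.

## Known limitations

* The baseline SD pools the 1-ms samples of the trial-averaged smoothed
  trace; per-trial baseline variability is not modelled separately (a
  documented switch point if needed).
* The artifact rule, applied to a spectrum whose lines sit within two bins
  of each other, unions their removal windows; closely spaced lines are not
  disambiguated.
* The band-peak z-score inherits the max-statistic bias described above;
  comparisons should always be against a matched null, which is how the
  package's own tests use it.
* Coherence p-values per pair are not computed; population summaries average
  all pairs.
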