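# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `freqtag`.

## Paradigm and analysis model

The stimulation paradigm presents isochronous four-word sentences built from
320-ms monosyllabic words; twelve sentences form one 15.36-s trial, thirty
trials form one session, and eight of the thirty trials contain a behavioral
outlier (three consecutive words replaced from a roved position). Syllables,
two-word phrases, and sentences therefore repeat at 1/0.32, 1/0.64, and
1/1.28 Hz. The acoustic control session slices each syllable into five 72-ms
slices with 10-ms overlap (10-ms linear crossfade at slice edges) and
shuffles slices at the same within-sentence position across all sentences of
the session, which preserves syllable-rate acoustics and destroys the
linguistic structure.

Analysis epochs drop the first sentence of each trial (onset transient),
leaving 14.08 s = 11 × 1.28 s. This duration is load-bearing: the DFT
resolution is 1/14.08 ≈ 0.0710 Hz and all three stimulation rates fall
exactly on bins 11, 22, and 44. `target_frequencies` raises if a configured
epoch length breaks this commensurability rather than silently using the
nearest bin.

The four spectra (evoked power E, phase coherence R, induced power I,
normalized power En) are defined in the README. Two conventions matter:

- **Grand averaging is done in the power/coherence domain.** Subject spectra
  are averaged as powers, never as complex coefficients, since response
  phase varies across subjects.
- **Channel handling for the global spectrum**: E is averaged over channels
  first, then normalized (En of the average, not the average of En).
  Per-channel En is used only for topographies.

### Null distribution of normalized power

At a background bin, each subject's evoked power is proportional to a
chi-square with 2 dof (real and imaginary parts of the summed coefficient).
Averaging n subjects gives 2n dof at the target bin; the 14 flanking bins
pool 28n dof. Hence

    2 · 7 · En  ~  F(2n, 28n)        (F(32, 448) at n = 16)

which the test statistic uses directly. This construction is verified by
simulation (2000 null grand averages, KS test) in both the test suite and
the acceptance script. For a single subject the same argument gives
F(2, 28); `ftest_normalized_power(..., n_subjects=1)` exposes that variant.

### Empirical null

For channel-averaged statistics the parametric null is conservative or
wrong because channels are correlated, so grand-average and single-subject
tests can instead use an empirical null: the same statistic at all bins in
a configured range that are not integer multiples of the sentential bin
(±1 guard bin), pooled over subjects for single-subject tests. The p-value
is the add-one rank `(1 + #{null ≥ obs}) / (1 + #null)`, which is exact for
exchangeable nulls and never returns 0. The default range is 0.3–5.5 Hz:
wide enough that at least 50 finite normalized-power bins survive both the
harmonic exclusion and the ±0.5-Hz normalization edge (En is undefined
within 7 bins of the axis ends).

### Other tests

- **Rayleigh**: R is exactly the Rayleigh Z over K trials; the p-value uses
  the standard small-sample correction `exp(−Z)·(1 + (2Z − Z²)/(4K))`,
  clipped to [0, 1].
- **FDR**: Benjamini–Hochberg step-up across the 16 subjects, separately
  per target frequency and per statistic (power vs. coherence).
- **Condition comparison**: the ratio of grand-averaged channel-averaged
  evoked powers at a target bin, referred to F(2n, 2n), upper tail.
- **Topography classification**: a ridge-regularized linear discriminant
  (ridge = 1e-3 × mean pooled feature variance; if the training maps have
  zero variance any positive ridge yields the same direction, so the ridge
  falls back to 1) trained on all subjects' first-half-trial maps, one
  sample per subject per class. Each subject contributes one Bernoulli
  outcome on held-out second-half maps — correct iff assigning the higher
  decision score to class 1 matches truth — and the one-sided binomial test
  uses N = 16 subjects against 0.5. Counting subjects (not the 32 test
  maps) is the stricter reading and is what the per-subject pairing
  supports.
- **Behavior**: Pearson r between per-subject sentential-rate En and
  percent-correct scores, two-sided t-test. Behavioral outliers are
  excluded by a leave-one-out >3 SD rule (a subject is flagged iff their
  score is more than 3 SDs from the mean of the remaining subjects), which
  reliably isolates a single ~33% scorer inside a tight ~84 ± 6 cluster
  without flagging anyone in the cluster.

## Preprocessing chain

Fixed order: ICA-based EOG rejection on the broadband recording → 25-Hz
zero-phase lowpass → common-average re-reference → epoching. Choices:

- **Filter**: windowed-FIR zero-phase lowpass (via MNE) with a 0.25·cutoff
  transition band. The contract is specified by response, not design:
  passband (≤ 0.9·cutoff) within 0.5 dB, stopband (≥ 1.3·cutoff) ≥ 40 dB.
- **EOG rejection**: channels are reduced to 80 principal components, the
  components unmixed with extended-infomax ICA (the EEGLAB-lineage
  algorithm), and a component removed iff the mean squared weight of its
  channel-space topography over the 14 most anterior channels exceeds 10×
  the mean squared weight over all other channels. "Most anterior" is
  defined by the layout's y coordinate since no channel IDs are canonical
  for a generated layout. A `weight_mode="abs"` variant (mean absolute
  weights) is available. The unmixing is estimated on every 5th sample —
  topography estimation does not need the full record — and applied to all
  samples; non-finite or near-singular unmixing raises `IcaError` rather
  than passing data through silently. Reconstruction without the removed
  components necessarily also applies the 80-component PCA truncation.
- **Epoching**: half-open sample windows `[onset + 1.28 s, onset + 15.36 s)`
  with 0-based indexing; outlier trials are excluded by default (the
  analysis of whether to include them is not settled by the design, so the
  switch `exclude_outlier_trials` exposes it; excluding is the default
  because outlier trials contain deviant content).

## The synthetic-data generator

`simulate_subject_eeg` builds, per subject and condition,

    EEG(c, t) = Σ_level a_level · sin(2π f_level (t − onset) + φ_subj) · topo_level(c)
                + pink noise + alpha-band oscillation (random phase per trial)

with responses present only during trials and phase-locked to trial onset.
What the defaults encode, and why:

- **Response amplitudes** 3.5 / 2.0 / 6.5 µV (sentential / phrasal /
  syllabic) against per-channel pink noise of 10 µV SD. These were derived
  analytically from the regime this paradigm operates in: for a sinusoid of
  amplitude A against background PSD S(f), the grand-average F statistic is
  ≈ 1 + K·T·A²·d/(2·S(f)) with K = 22 trials, T = 14.08 s and d the
  topography dilution from channel averaging (~0.06 here). The defaults put
  the grand F near 9 / 4 / 100 at the three rates and leave roughly half of
  single subjects significant at the slow rates — matching the magnitude of
  effects EEG frequency tagging of phrases and sentences actually yields.
- **Subject variability**: per-subject, per-level lognormal amplitude
  multipliers (σ = 0.4) and wrapped-normal response phases (σ = 0.5 rad).
  Traits are drawn from a per-subject seed stream so they are identical
  across conditions.
- **Control condition**: sentential and phrasal amplitudes zero; syllabic
  scaled by 0.65 (the syllabic response to the unintelligible control is
  reliably weaker, plausibly an attention/intelligibility effect).
- **Background**: 1/f pink noise (exponent 1.0, spectrum flattened below
  0.1 Hz, scaled to the target time-domain SD) plus a subject-specific
  alpha oscillator (8–12 Hz, 5 µV, random phase per trial) that lands in
  the induced but not the evoked spectrum.
- **Stimulus envelope**: each syllable is a gamma-like attack–decay kernel
  (`t²·e^(−t/τ)`, unit peak) with ±20% per-syllable amplitude jitter —
  spoken words differ in intensity, and without jitter the within-position
  slice shuffle of the control construction would be a no-op on the
  envelope. Only the 320-ms periodicity matters to any statistic under
  test.
- **Behavior**: percent correct = clip(57 + 4·(sentential amplitude in µV)
  + N(0, 6.4), 0, 100), giving a ~72% mean and a population neural–behavior
  correlation near 0.7.
- **Sampling rate** 100 Hz (a real lab records at 1000 Hz); legitimate
  because everything analyzed lives below 25 Hz, and it keeps a full
  16-subject, 2-condition study runnable in well under a minute.
- **Seeding**: one root seed fans out through named `SeedSequence` streams
  (traits / noise / behavior / stimulus), so any subject or stage can be
  re-simulated in isolation and identical seeds are bit-identical.

What the generator does **not** emulate: real scalp mixing (volume
conduction beyond smooth Gaussian topographies), non-stationary artifacts
other than injected test components, harmonic structure of responses
(available via `second_harmonic`, off by default), heteroscedastic
channel noise, or the acoustic content of outlier words (outlier trials are
flagged, not rendered). Passing tests therefore demonstrate correctness of
the analysis pipeline and calibration of its statistics under a plausible
signal model — not that any particular real dataset would yield the same
numbers.

## Problem sizes in the test suite and acceptance script

The full-study runs use the design scale (16 subjects × 2 conditions ×
30 trials, 22 analyzed, 128 channels, fs = 100 Hz) with ICA disabled when
no artifact is simulated; ICA behavior is exercised on smaller sessions
(32 channels, 20 components) where its contracts — removal of an injected
frontal component, no removals on clean data, determinism — are checked
directly. The amplitude-ladder monotonicity check uses 8 subjects and
12 trials per rung. Null calibrations simulate at the DFT-coefficient level
(complex Gaussians), which is the exact null of the F construction and
orders of magnitude faster than time-domain simulation.

## Known limitations

- The F(32, 448) reference for channel-averaged grand power is knowingly
  conservative under inter-channel correlation; the empirical-null route is
  provided for exactly that reason, and both are reported.
- EDF output quantizes to 16 bits over each channel's observed range
  (≤ 0.5 LSB round-trip error); files use integer microvolt physical
  limits.
- The infomax ICA step estimates its unmixing on decimated samples; with
  heavily non-stationary artifacts a full-rate fit (decim=1) may separate
  marginally better at ~5× the cost.
- `phase_coherence` drops zero-magnitude coefficients (undefined phase)
  from the affected bin's sums with a warning; the divisor stays K, so R's
  maximum remains K and such bins are biased low rather than undefined.
- The behavioral score model is linear with Gaussian noise and clipping;
  ceiling effects near 100% compress the recoverable correlation.
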