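# Methods

`vowelvar` quantifies how variable a speaker's vowel productions are across
and within repetitions, and whether that variability differs between adults
who stutter (AWS) and adults who do not (ANS) when they speak under normal
(NAF) versus 100-ms delayed (DAF) auditory feedback.  This note documents
the models, the numerical choices, and what the synthetic cohorts do and do
not establish.

## The measurement model

### Feedforward window

Auditory feedback of an ongoing vowel cannot influence that same vowel's
articulation until roughly 100 ms after voicing begins, so the **first
50 ms** of each vowel reflects feedforward planning only.  All variability
measures are computed on formant frames whose centers fall in the half-open
interval `[onset, onset + 50 ms)`.  The half-open convention makes the frame
count a pure function of onset, hop (5 ms default, hence ~10 frames) and
window length; trials with fewer than 3 frames in the window are excluded
and logged.  Onsets/offsets come from the annotation table (emulating manual
labelling); an energy-threshold detector (RMS ≥ 0.2 × peak sustained ≥
30 ms) is available as a clearly flagged fallback.

### Formant tracking

Audio is decimated to 11,025 Hz (anti-aliased FIR), pre-emphasized, and cut
into 25-ms Hamming frames every 5 ms.  Each frame is fitted with an
autocorrelation-method LPC model (Levinson–Durbin; order 17 by default, the
conventional male-speaker order — 15 for female speakers).  Complex roots
`m·e^{iθ}` of the prediction polynomial give candidates with frequency
`θ·fs/2π` and bandwidth `−(fs/π)·ln m`; candidates below 50 Hz or within
50 Hz of Nyquist are discarded.  Candidates are assigned to formant slots
F1–F4 by a Viterbi dynamic program minimizing, over the whole trial,

```
Σ_t [ w_nom Σ_k (ln f_k,t − ln nominal_k)²  +  w_bw Σ_k B_k,t / f_k,t ]
  + w_cont Σ_t Σ_k (ln f_k,t − ln f_k,t−1)²
```

with default weights (continuity, bandwidth, nominal) = (2.0, 0.5, 1.0) and
nominal formants (500, 1500, 2500, 3500) Hz; all terms are dimensionless on
the log-frequency scale so the defaults are the same order of magnitude for
typical tracks.  Assignment states enumerate increasing-frequency candidate
combinations, so the ordering invariant F1 < F2 < F3 < F4 holds by
construction.  Frames with fewer candidates than slots (e.g. silence) are
filled with nominal values and flagged.  Ties cannot arise in exact
arithmetic degeneracies we care about; `argmin` picks the first minimal
state, which is deterministic for fixed input.

The default pre-emphasis is **0.85**.  With the synthetic generator's
spectrally flat impulse-train source, the common 0.98 value over-tilts the
spectrum and biases low first formants (/i/ at 270 Hz) upward by ~35 Hz;
0.85 keeps per-vowel median window-mean errors at ≤ 7 Hz (F1) and ≤ 17 Hz
(F2).  For recorded speech, whose glottal source already rolls off, a higher
coefficient may be preferable; it is a config field.

### Mel scale and the dependent variables

Frequencies are warped as `mel = 2595·log10(1 + f/700)` (O'Shaughnessy/HTK
constants).  Per trial *i* in a participant × vowel × condition cell, let
`(m1_i, m2_i)` be window-mean Mel F1/F2 and `(s1_i, s2_i)` the within-window
SDs (ddof = 1).  With deviations `d_k,i = m_k,i − mean_i(m_k)`:

* **Trial-to-trial variability** `TTV = sqrt((1/n) Σ_i (d1_i² + d2_i²))` —
  the RMS Euclidean deviation of each trial's planned (F1, F2) point from
  the cell's grand average.  Mean-centering is the default (median is a
  config switch); a pooled-RMS variant dividing by 2n (smaller by √2) is
  also available, and every calibration statement in the tests refers to
  the Euclidean form.
* **Within-trial variability** `WTV = sqrt((1/2n) Σ_i (s1_i² + s2_i²))`,
  computed over the 50-ms window only, so it indexes early articulatory
  precision rather than feedback corrections.
* **Inter-vowel distance**: mean of the 6 pairwise Euclidean distances among
  the four vowel centroids of a participant × condition, in Mel (Hz optional).
* Secondary measures per trial: duration `(offset − onset)` in ms and RMS
  intensity in dBFS (uncalibrated; only condition differences are
  interpreted).

Because TTV and WTV are non-negative, the analysis table carries their
natural logs (base only rescales the linear model; F-tests are unchanged).
Cells with zero variability have no log and are dropped with a warning.
For iid Gaussian Mel offsets with SD σ per formant,
`E[TTV] ≈ σ·√2·√((n−1)/n)`; the estimator is checked against this
expectation to within 2% in the tests.

## The inference model

One observation per participant × vowel × condition (192 rows for 24
participants) enters a linear mixed model: full factorial fixed effects of
group × condition × vowel plus a participant random intercept.  For this
*balanced* split-plot design the REML solution coincides with classical
expected-mean-squares strata, which the package computes in closed form:

* group (between-subject) is tested against participants-within-groups,
  `df = n_subj − 2` → **F(1, 22)**;
* condition, vowel and all interactions are tested against the
  within-subject residual, `df = n_subj·(w−1) − 14` with `w = 8` cells per
  participant → **F(·, 154)**.

Variance components follow from the mean squares
(`σ²_participant = (MS_subj − MS_resid)/w`, truncated at zero with a flag,
matching REML's boundary behaviour).  The implementation is verified in the
test suite against an independent REML mixed-model fit with Satterthwaite
df (R's lmerTest under sum contrasts) to ~1e−6, and its null behaviour is
calibrated by simulation (each F-test rejects at 4–6% under α = 0.05 across
2,000 null cohorts).  Unbalanced tables are refused with an explicit error
rather than approximated — exactness and testability over generality.

Post-hoc pairwise contrasts of marginal means use exact balanced-design
standard errors expressed in stratum mean squares, with Tukey adjustment
via the studentized-range distribution.  The df is that of the stratum the
contrast is tested against: the residual stratum for within-subject
contrasts, the participant stratum for contrasts spanning groups (for
mixed-strata cell contrasts this is slightly conservative relative to a
Satterthwaite combination — e.g. df 22 where Kenward–Roger gives ~25).
The condition-within-group simple effects (DAF − NAF in each group) cancel
the participant intercept, are tested on the residual stratum, and are
Šidák-adjusted as a two-contrast family.  WTV–TTV association is the
Pearson correlation of participant-level means within each group ×
condition, with the usual two-sided t-test.

## The synthetic cohort generator

No recordings ship with the package, so a generator produces cohorts whose
ground truth is known exactly.

**Audio.**  Each trial is a Klatt-style source-filter synthesis at
44,100 Hz: an impulse train at f0 = 120 Hz with 1% cycle-to-cycle jitter
(natural pitch jitter; a perfectly periodic source samples the spectrum on
an exact harmonic comb and biases LPC estimates near harmonics), filtered
through a cascade of unity-DC-gain second-order resonators at the trial's
instantaneous formant frequencies, with 15-ms raised-cosine ramps, −6 dBFS
peak normalization, and per-vowel/condition intensity offsets.  Formants
are piecewise-constant over 5-ms blocks and the exact block values are
stored as the trial's ground-truth track, so tracker accuracy is measurable
to the Hz.

**Targets.**  Canonical adult-male American English front vowels (ARPAbet):
/i/ = iy (270, 2290), /ɪ/ = ih (390, 1990), /ɛ/ = eh (530, 1840), /æ/ = ae
(660, 1720) Hz for F1/F2, shared F3 = 2500 and F4 = 3500 Hz, bandwidths
(80, 120, 160, 200) Hz.  Durations 240/200/230/300 ms make /æ/ the longest
vowel; /i/ is 2 dB quieter — both standard phonetic regularities.

**Variability structure.**  Per trial, the Mel F1/F2 targets are offset by
iid draws with SD `sigma_trial[group][condition]` scaled per vowel
(/i/ × 0.74 … /æ/ × 1.11, making /i/ the least variable), and each
participant carries a lognormal multiplier (log-SD 0.3) — the source of the
participant random intercept on the log-TTV scale.  Within a trial the Mel
formants drift along a smooth zero-mean quadratic (orthonormal shifted
Legendre basis) with SD `sigma_within` (8 Mel default, /æ/ × 1.3 highest).
The default `sigma_trial` cells are, in log Mel units,
`log 20 − 0.125 + 0.5·[AWS] ± 0.125` (≈ 17.7/22.7 Mel for ANS NAF/DAF and
37.4/29.1 Mel for AWS): the AWS baseline sits 0.5 log units above ANS (a
between-group t ≈ 4 at these variance components, the size of effect the
design is meant to detect), and DAF *raises* ANS dispersion but *lowers*
AWS dispersion by 0.25 log units — the crossover of interest.  DAF also
multiplies duration by 1.2 and adds 2 dB of intensity, typical published
DAF consequences.  The delayed feedback loop itself is not simulated; DAF
enters only through these measured consequences, which is what the analysis
pipeline can see.

**Table-level shortcut.**  `simulate_log_ttv_table` draws per-cell log-TTV
values directly (baseline 3.0, vowel effects −0.3/0/0.05/0.1, participant
SD 0.3, residual SD 0.2, centered ±0.25 crossover, group shift 0.5) for
simulation studies that need thousands of cohorts — type-I calibration and
power — without audio.

**What passing tests show — and don't.**  The generator establishes that
the estimator chain is unbiased and calibrated *given its assumptions*:
stationary Gaussian dispersion, clean single-vowel tokens, exact
annotations, no consonant context, no tracking gross errors, no missing
cells.  Real recordings add coarticulation, f0 movement, amplitude
modulation, room noise and annotation error; tracker accuracy numbers here
are upper bounds on clean-speech performance, not field performance.  The
exclusion bookkeeping (per-group × condition rate table) exists for real
data; the default generator produces no exclusions.

## Problem sizes and determinism

Everything is driven by integer seeds through `numpy` `SeedSequence`
spawning: identical seeds give bit-identical cohorts, tables and reports.
The bundled simulation studies use: 1,000 cells for TTV recovery, 100
synthesized vowels for tracker accuracy, 2,000 table-level null cohorts for
type-I calibration, 200 cohorts for crossover power, and a 14-participant ×
4-trials-per-cell audio cohort (448 trials, 112 cells) for the end-to-end
tracked-vs-truth comparison; each is a few seconds to ~30 s on one core,
and all sizes are parameters.

## Known limitations

* The ANOVA engine is balanced-only by design; unbalanced real datasets
  must be subset or imputed upstream.
* LPC order 17/15 presumes the 11,025-Hz analysis rate; changing
  `analysis_fs` without rescaling the order will misbehave.
* The synthesizer is acoustic, not articulatory: no consonant transitions,
  no disfluencies, no feedback loop.
* dBFS intensity is relative; absolute SPL claims are out of scope.
* Tukey adjustment for cross-group cell contrasts uses the conservative
  participant-stratum df rather than a Satterthwaite blend.
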