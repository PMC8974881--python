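# Methods

`neopain` implements a complete, testable pipeline for one question in
neonatal pain research: how well do behavioural, physiological and
neurophysiological responses — separately and combined — discriminate a
noxious stimulus (a clinical heel lance) from a closely matched non-noxious
control, when each infant contributes one paired observation per condition?
Real recordings of this kind are not publicly available, so the package
pairs the analysis machinery with a synthetic-cohort generator that
reproduces the statistical structure the analysis assumes.

## The synthetic cohort model

Each subject receives a latent responsiveness factor
`r = max(0.05, 1 + N(0, responsiveness_sd))` (default SD 0.3) shared across
modalities and conditions. Every noxious effect size is multiplied by `r`;
control recordings contain the same baseline processes with all effects set
to zero. This single shared factor is what couples modalities within a
subject: strong responders respond strongly everywhere, which is the
between-modality correlation structure that makes multimodal combination
informative without making any single modality sufficient.

Per modality:

* **EEG (Cz)** — Gaussian white noise (default SD 3 µV) plus, in noxious
  trials, a biphasic evoked deflection of amplitude `eeg_amp_uv x r`
  at a latency jittered uniformly within ±50 ms. The deflection is the
  canonical template (below) in its unit-sample-energy scaling.
* **EMG (both legs)** — white noise plus a Hann-enveloped amplitude-
  modulated noise burst starting at U(0.05, 0.5) s with duration
  U(0.5, 3) s; the contralateral leg uses 0.55 of the ipsilateral
  amplitude, so the ipsilateral response always dominates.
* **Heartbeats** — an inhomogeneous rate model: beats are placed by time
  rescaling of the integrated rate 60/RR(t), where RR(t) follows a
  subject-specific baseline (N(140, 8) bpm) plus, in noxious trials, a
  rise of `hr_rise_bpm x r` shaped as `(t/12) exp(1 - t/12)` (unit peak at
  12 s), plus smooth Gaussian rate noise. Time rescaling guarantees
  strictly increasing beat times at any rate.
* **SpO2 (1 Hz)** — subject baseline near 97%, Gaussian noise, and in
  noxious trials a Gaussian-shaped dip of depth `spo2_dip_pct x r`
  occurring with probability 0.5 at a lag of 8–20 s: saturation dips are
  occasional rather than obligatory, which is why this modality
  discriminates poorly on purpose.
* **Facial actions** — a per-trial Gamma(3, mean/3) intensity shared by
  the three actions (brow bulge, eye squeeze, nasolabial furrow), each
  multiplied by an independent log-normal factor and truncated to the
  [0, 30] s scoring window. Noxious trials raise the mean by
  `facial_mean_s x r` over the 2 s baseline mean. Sharing the intensity
  makes the three durations strongly correlated, as facial actions are in
  practice.

Missingness removes whole modalities per observation, independently, with
configured probabilities — emulating per-study recording coverage and
artifact rejection.

Randomness is organised as one top-level seed keying independent
per-subject, per-modality, per-condition streams
(`SeedSequence((seed, subject_index, tag))`), so a subject's data are
identical regardless of cohort size or simulation order.

**Effect-size defaults.** The generator's defaults (EEG 6.5, EMG 4.5,
HR rise 8 bpm, SpO2 dip 1.0% with probability 0.5, facial +4 s) were
calibrated once so that *single-measure* discrimination sits at the levels
reported for real heel-lance responses — facial ≈ 0.65–0.70 accuracy,
heart rate ≈ 0.73, saturation near chance, EEG ≈ 0.65, ipsilateral EMG
≈ 0.77 — with the multimodal combination clearly higher. Absolute signal
units are internal to the generator (the canonical template's µV scale is
not published), so matching reported discriminability, rather than raw
amplitudes, is the meaningful anchor. The synthetic full model typically
exceeds the discrimination reported for real infants (test AUC ≈ 0.95–0.98
versus ≈ 0.90) because the single latent responsiveness factor is a cleaner
correlation structure than real physiology.

**What the generator does not emulate:** background EEG rhythms and 1/f
spectra (noise is white by default), movement and electrode artifacts,
ECG contamination of EMG, pulse-oximeter quantisation and dropout,
gestational-age dependence of responses (age is simulated but does not
modulate effects), and behavioural-state covariates. Passing tests
therefore demonstrate the correctness and calibration of the *analysis*
under the stated statistical structure, not clinical performance on real
recordings.

## The evoked-response template

The canonical noxious-evoked EEG waveform is a stand-in with the documented
shape constraints: a difference of two Gaussians on [0.35, 0.70) s
(negative lobe centred at 400 ms, SD 25 ms; positive lobe at 530 ms, SD
45 ms), lobe weights fixed so the extrema magnitudes stand in ratio 5:7,
normalised to unit sum of squared samples. It is deterministic given the
sampling rate and requires fs ≥ 200 Hz.

Template magnitude is the least-squares scaling of the template against a
trial over the 400–700 ms window, `beta = <x, T> / <T, T>`, after Woody
alignment (below). Two numerical points matter:

* **Filter-matched projection.** The 0.5–70 Hz analysis band-pass removes
  roughly 8% of the raw template's energy (the biphasic waveform has net
  area, hence DC content). The projection reference is therefore the
  template passed through the same filter chain as the data, so the
  distortion cancels in the ratio and an injected deflection of amplitude
  `a` projects back to `a` (verified to within 2% in the closed-loop
  tests, sub-sample latency jitter included).
* **Units across sampling rates.** With unit *sample* energy the template's
  sample amplitude scales as 1/sqrt(fs), so projections of
  non-template-shaped content scale with sqrt(fs). Magnitudes are fully
  comparable across rates for template-shaped signals (the measure's
  target); broadband background contributes a rate-dependent noise scale.
  All magnitudes within one analysis are computed at one configured rate.

## Signal measures

* **Filtering** — zero-phase 4th-order Butterworth band-pass (EEG
  0.5–70 Hz, EMG 10–500 Hz) with zero-phase notches (Q = 30) at 50 Hz and
  harmonics up to the band edge. A nominal edge at or above Nyquist is
  capped at 0.95 x Nyquist with a logged warning (e.g. the 500 Hz EMG edge
  at fs = 500 Hz).
* **Woody alignment** — integer-sample shifts within ±100 ms maximising
  the Pearson correlation with the reference over 400–700 ms; ties go to
  the smallest absolute shift, then the negative one; translation is by
  sample shift with zero-filled edges, never wrap-around. The template
  magnitude aligns to the (filtered) template itself; the automated
  peak-to-peak aligns to the cohort-average noxious epoch (training data
  only), falling back to the template when no noxious EEG is available.
* **Automated peak-to-peak** — max over [450, 650) ms minus min over
  [350, 450) ms; negative for inverted waveforms.
* **EMG RMS** — mean RMS over the four 250 ms windows of the first
  poststimulus second.
* **EMG burst detection** — threshold = mean + 3 SD of 250 ms-window RMS
  over the [-2, 0) s baseline (windows stepped by 50 ms); onset is the
  first poststimulus window above threshold; offset starts the first run
  of ≥ 4 consecutive sub-threshold windows; amplitude is the absolute
  sample maximum between them. No onset gives (0, 0); a burst still above
  threshold at the epoch end sets a no-endpoint flag and the duration and
  amplitude are treated as missing downstream. All four constants are
  arguments. *Known limitation:* with only 2 s of baseline the threshold
  estimate is noisy, and pure-noise epochs cross it somewhere in the
  14.5 s search in roughly 45% of cases; the spurious detections are tiny
  (median ≈ 0.05 s versus ≥ 0.5 s for real bursts) and behave as a small
  noise floor on the duration/amplitude measures.
* **Heart rate** — bpm at each integer second in [-15, 30] as 60 / mean of
  the RR intervals ending in the trailing 5 s window; undefined (missing)
  seconds are skipped downstream.
* **Change grids** — for heart rate {mean, max, normalised mean,
  normalised max} and for SpO2 {mean, min, normalised mean, normalised
  min} over windows of 5–30 s: change from the [-15, 0) s baseline mean,
  with normalised variants divided by the baseline sample SD (ddof 1).
  A zero baseline SD makes the normalised variants missing rather than
  infinite; an entirely missing baseline makes all 24 measures missing.
  SpO2 uses the same 15 s baseline convention as heart rate.

The 59 per-observation measures are: BB, ES, NF (facial durations), the 24
heart-rate and 24 saturation grid measures, EEGt (template magnitude),
EEGa (automated peak-to-peak), and RMS/DUR/AMP for each leg. Degenerate or
unavailable inputs propagate as missing values with a logged reason; the
extraction never aborts on a bad modality.

## Subject-bootstrapped random forest

Because conditions are paired within subjects, each tree's bootstrap draws
S subjects with replacement from the S distinct training subjects; a
subject drawn k times contributes both its observations k times. An
observation's out-of-bag (OOB) score uses only trees whose bag excludes its
*subject*, so the paired observation can never leak into the bag that
predicts its partner. With S subjects the expected OOB-eligible fraction is
(1 - 1/S)^S ≈ e⁻¹.

Trees are Breiman-style: Gini impurity, midpoint thresholds between
consecutive distinct values, per-node feature subsampling of size
mtry = ceil(sqrt(p)), grown to purity (minimum leaf 1, no pruning). Split
ties break by feature-name order then lower threshold, making fits
deterministic given the seed (each tree draws from
`SeedSequence((seed, tree_index))`).

Missing values are handled by per-tree in-bag median imputation: medians
are computed from the tree's own in-bag rows at fit time, stored, and
reused at prediction time. A feature missing for every in-bag row of a
tree is simply unusable in that tree (logged, not fatal). Surrogate splits
were considered and rejected: median imputation is deterministic, cheap,
keeps OOB honest, and behaves sensibly when whole modalities are absent.

Vote scores are the fraction of eligible trees voting "noxious"; an exact
0.5 tie is labelled control (conservative toward non-noxious) and flagged.
The default ensemble size is 1000 trees; both it and the imputation rule
are reported in output metadata rather than presented as canonical.

## Evaluation statistics

Accuracy, sensitivity and specificity carry 95% Wilson score intervals (no
continuity correction). ROC curves enumerate distinct score thresholds;
the trapezoid AUC equals the Mann-Whitney statistic with ties counted one
half. AUC confidence intervals are percentile bootstrap (default 2000
resamples) drawn at the *subject* level so paired observations move
together; degenerate resamples (one class absent) are redrawn. Paired
models are compared by two-sided mid-P McNemar tests on per-observation
correctness and by DeLong's structural-component test on correlated AUCs.
Models are compared to chance with the exact (minimum-likelihood) two-sided
binomial test. Term (≥ 37 weeks) versus preterm accuracy uses a Yates-
corrected 2x2 chi-square with a small-expected-cell warning flag. Between-
measure association uses pairwise-complete Spearman correlation with
mid-rank ties and t-approximation p-values (pairs with fewer than three
complete rows are missing); the non-significance mask is p ≥ 0.05.

Calibration checks in the test suite: the mid-P McNemar type-I error on
equally wrong independent models lands in [0.03, 0.08] at nominal 5%, and
the subject-level bootstrap AUC interval covers a true AUC of 0.8 between
91% and 98% of the time at 50 paired subjects.

## Experiments

`run_within_modality` fits, for each modality, a forest per single measure
plus the combined-measure forest (facial: BB/ES/NF/all three; each EMG
leg: RMS/DUR/AMP/all three; heart rate: 24 models; SpO2: 24 models; EEG:
EEGt vs EEGa), ranks them by OOB accuracy then AUC, and compares each to
the family reference (the combined model where one exists, otherwise the
best-ranked model) by mid-P McNemar and DeLong.

`run_multimodal` trains the full model — by default one selected measure
per modality (NF, heart-rate max change over 15 s, SpO2 min change over
30 s, EEGt, and EMG RMS of both legs) — on the training subjects with at
least three of the five modality groups, reports OOB metrics overall and
stratified term/preterm with the chi-square comparison, and validates the
full model, each single-measure model and the behavioural+physiological
subset (NF + HR + SpO2) on an independent test set whose subjects must
have every modality present. Synthetic test cohorts are generated with
zero missingness from an independent seed, mirroring the selection of
complete-data infants into a balanced test set.

Problem sizes: the default experiment uses 77 training subjects (with
10–15% per-modality missingness) and 32 test subjects with 1000-tree
forests; the replicated multimodal-advantage check in the test suite uses
60/30 subjects and 300-tree forests over 20 seeded replicates, sizes at
which the forests' OOB estimates are stable while a full run stays in the
tens of seconds.

## Reproducibility

Everything is deterministic from explicit seeds: cohorts from the
generator seed, forests from the fitting seed, bootstrap intervals from
the evaluation seed; an experiment derives all three from one master seed.
Reports embed the seed and a configuration hash, and re-running an
experiment with the same seed reproduces `metrics.json` byte for byte.
`scripts/acceptance.py --seed N --out results/acceptance.json` recomputes
the headline quantities (measure-grid cardinalities, OOB eligible-tree
fraction, training OOB metrics, and test accuracy/AUC of the full,
behavioural+physiological and best single-measure models) from scratch.
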