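# neopain

Multimodal discrimination of noxious vs non-noxious stimulus responses in
neonates: synthetic paired cohorts, stimulus-locked signal measures,
subject-bootstrapped random forests, and paired-model statistics.

## The problem

Infants cannot report pain, so neonatal pain assessment relies on surrogate
responses: facial grimacing, limb reflex withdrawal (EMG), heart-rate rise,
oxygen-saturation dips, and noxious-evoked EEG activity at the vertex. A
central methodological question is whether combining *modalities* improves
discrimination between a noxious stimulus (a clinical heel lance) and a
closely matched non-noxious control, and whether multiple *measures within*
a modality add anything over a single well-chosen one. This package
implements the full analysis as a reusable, tested pipeline for
researchers working with paired stimulus-locked recordings — and, because
such infant recordings are not public, ships a synthetic-cohort generator
that reproduces the design's statistical structure (paired conditions, a
shared per-subject responsiveness factor coupling modalities, per-modality
missingness) so every stage is testable end to end.

## What's inside

* `neopain.synthetic` — paired noxious/control cohorts: evoked EEG
  deflections at jittered latency, bilateral EMG reflex bursts, heartbeat
  times from an inhomogeneous rate model, saturation dips, facial-action
  durations; whole-modality missingness; manifest + CSV round-trip I/O.
* `neopain.features` — zero-phase band-pass/notch filtering, epoching with
  prestimulus baseline correction, Woody latency alignment (±100 ms),
  evoked-template projection and automated peak-to-peak amplitude, EMG RMS
  and threshold-based burst duration/amplitude, per-second heart rate from
  RR intervals, and the 4 x 6 windowed change grids for heart rate and
  SpO2 — 59 named measures per observation, with principled missingness.
* `neopain.forest` — a from-scratch random forest that bootstraps
  *subjects* rather than observations, with Gini splits, per-tree in-bag
  median imputation for missing values, honest out-of-bag (OOB) voting,
  and exact JSON serialisation.
* `neopain.stats` — Wilson score intervals, ROC/AUC (Mann-Whitney with
  ties one half), subject-level percentile-bootstrap AUC intervals,
  two-sided mid-P McNemar tests, DeLong's test for correlated AUCs, exact
  binomial tests, Yates-corrected chi-square, Spearman matrices.
* `neopain.pipeline` / `neopain.cli` — the two experiment designs
  (within-modality measure comparison; multimodal train + independent
  validation) with deterministic, hash-stamped reports.

The forest is the methodological core: because each subject contributes a
noxious *and* a control observation, classical bagging would let one half
of a pair predict the other. Resampling whole subjects, and restricting
each observation's OOB vote to trees whose bag excludes its subject, keeps
the OOB performance estimate honest; the expected eligible-tree fraction is
(1 − 1/S)^S ≈ e⁻¹.

## Worked example

```python
from neopain import (CohortConfig, simulate_cohort, extract_feature_table,
                     fit_forest, oob_votes, confusion_metrics, roc_and_auc)

cohort = simulate_cohort(CohortConfig(n_subjects=30, seed=42))
table, _ = extract_feature_table(cohort)
measures = ["NF", "HR_max_15", "SAT_min_30", "EEGt", "RMSi", "RMSc"]
forest = fit_forest(table[measures], table["condition"],
                    table["subject_id"], n_trees=500, seed=0)
votes = oob_votes(forest, table[measures], table["subject_id"])
m = confusion_metrics(votes.label, table["condition"])
_, auc = roc_and_auc(votes.score, table["condition"])
print(f"OOB accuracy {m.accuracy:.2f} "
      f"(95% CI {m.accuracy_ci[0]:.2f}-{m.accuracy_ci[1]:.2f}), "
      f"sensitivity {m.sensitivity:.2f}, specificity {m.specificity:.2f}, "
      f"AUC {auc:.2f}")
```

prints

```
OOB accuracy 0.88 (95% CI 0.78-0.94), sensitivity 0.83, specificity 0.93, AUC 0.96
```

Sixty paired observations from 30 subjects are simulated, the six
selected measures (nasolabial-furrow duration, heart-rate max change over
15 s, SpO2 min change over 30 s, EEG template magnitude, and EMG RMS of
both legs) are extracted through the full filter/align/measure chains, and
a 500-tree subject-bootstrapped forest scores each observation using only
trees that never saw that subject. The accuracy is the fraction of
observations whose OOB vote identifies the correct condition, with a
Wilson 95% interval; sensitivity and specificity are the noxious- and
control-specific rates; the AUC summarises the vote scores across all
thresholds.

The same flow is available from the shell:

```bash
neopain simulate --seed 42 --subjects 30 --out cohort/
neopain extract --cohort cohort/ --out features.csv
neopain fit --features features.csv --measures NF,HR_max_15,RMSi --trees 500 --seed 0 --out model.json
neopain evaluate --model model.json --features features.csv --out eval/
neopain compare --experiment multimodal --seed 1 --out results/
```

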