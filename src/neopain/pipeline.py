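"""End-to-end experiments: within-modality comparison and multimodal
train/validate.

Two experiment designs are provided:

* ``run_within_modality`` -- for each modality, trains forests on each
  single measure and on the combined measure set, ranks them by OOB
  accuracy then AUC, and compares each against the family's reference
  model (mid-P McNemar on correctness, DeLong on OOB scores).
* ``run_multimodal`` -- trains the full multimodal forest (one selected
  measure per modality) on the training subjects that have at least three
  modalities, reports OOB metrics overall and stratified by gestational
  age (term >= 37 weeks vs preterm), then validates the full model, each
  single-measure model and the behavioural+physiological subset on an
  independent, complete-data test set.

Test subjects are disjoint from training subjects and must have every
modality available (the completeness rule that balances the test set).
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats
from .features import HR_MEASURES, SAT_MEASURES, extract_feature_table
from .forest import fit_forest, oob_votes, predict_votes
from .synthetic import Cohort, CohortConfig, read_cohort, simulate_cohort

logger = logging.getLogger(__name__)

#: default measure set of the full multimodal model: one selected measure
#: per modality (facial nasolabial furrow, heart-rate max change over 15 s,
#: SpO2 min change over 30 s, EEG template magnitude, EMG RMS of both legs)
FULL_MODEL_MEASURES = ("NF", "HR_max_15", "SAT_min_30", "EEGt", "RMSi", "RMSc")
#: the behavioural + physiological subset (no neurophysiological measures)
BEHAV_PHYS_MEASURES = ("NF", "HR_max_15", "SAT_min_30")

#: representative measures for the between-modality correlation matrix
CORRELATION_MEASURES = ("BB", "ES", "NF", "EEGt", "EEGa", "HR_max_15",
                        "SAT_min_30", "RMSi", "DURi", "AMPi", "RMSc", "DURc",
                        "AMPc")

_MODALITY_GROUPS = {
    "facial": ("avail_facial",),
    "heart_rate": ("avail_heart_rate",),
    "spo2": ("avail_spo2",),
    "eeg": ("avail_eeg",),
    "emg": ("avail_emg_ipsi", "avail_emg_contra"),
}


@dataclass
class ExperimentConfig:
    """Configuration of one experiment run.

    ``seed`` is the master seed: the training cohort, test cohort, forest
    fitting and bootstrap intervals all derive their streams from it.
    When ``cohort_dir``/``test_cohort_dir`` are set, cohorts are loaded
    from manifests instead of simulated.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_dir: str | None = None
    test_cohort_dir: str | None = None
    n_test_subjects: int = 32
    n_trees: int = 1000
    mtry: int | None = None
    n_boot: int = 2000
    alpha: float = 0.05
    min_modalities: int = 3
    seed: int = 0
    multimodal_measures: tuple[str, ...] = FULL_MODEL_MEASURES
    behavioral_measures: tuple[str, ...] = BEHAV_PHYS_MEASURES

    def forest_seed(self) -> int:
        return (self.seed + 1) % 2 ** 31

    def bootstrap_seed(self) -> int:
        return (self.seed + 2) % 2 ** 31

    def test_cohort_seed(self) -> int:
        return (self.seed + 1_000_003) % 2 ** 31

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["multimodal_measures"] = list(self.multimodal_measures)
        d["behavioral_measures"] = list(self.behavioral_measures)
        return d

    def config_hash(self) -> str:
        text = json.dumps(self.to_jsonable(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


# ----------------------------------------------------------------------
# cohort/table preparation
# ----------------------------------------------------------------------
def build_cohorts(config: ExperimentConfig) -> tuple[Cohort, Cohort]:
    """Simulate (or load) the training and test cohorts.

    The synthetic test cohort mirrors the study's selection rule -- only
    infants with every modality recorded artifact-free enter the test set
    -- by being generated with zero missingness, from an independent seed.
    """
    if config.cohort_dir is not None:
        train = read_cohort(config.cohort_dir)
        if config.test_cohort_dir is None:
            raise ValueError("test_cohort_dir is required when loading cohorts")
        test = read_cohort(config.test_cohort_dir)
        return train, test
    train_cfg = replace(config.cohort, seed=config.seed)
    test_cfg = replace(
        config.cohort, n_subjects=config.n_test_subjects,
        seed=config.test_cohort_seed(),
        missing_facial=0.0, missing_heart_rate=0.0, missing_spo2=0.0,
        missing_eeg=0.0, missing_emg_ipsi=0.0, missing_emg_contra=0.0)
    train = simulate_cohort(train_cfg, subject_prefix="T")
    test = simulate_cohort(test_cfg, subject_prefix="V")
    return train, test


def validate_split(train_table: pd.DataFrame, test_table: pd.DataFrame) -> None:
    """Enforce subject disjointness and test-set completeness."""
    overlap = set(train_table["subject_id"]) & set(test_table["subject_id"])
    if overlap:
        raise ValueError(f"train/test subjects overlap: {sorted(overlap)}")
    avail_cols = [c for c in test_table.columns if c.startswith("avail_")]
    bad = test_table.loc[~test_table[avail_cols].all(axis=1), "subject_id"]
    if len(bad):
        raise ValueError(
            f"test subjects with missing modalities: {sorted(set(bad))}; "
            f"the test set must be complete")


def _xys(table: pd.DataFrame, measures: list[str] | tuple[str, ...]):
    X = table[list(measures)]
    y = table["condition"].to_numpy()
    subjects = table["subject_id"].to_numpy()
    return X, y, subjects


def _fit_and_oob(table: pd.DataFrame, measures, config: ExperimentConfig):
    X, y, subjects = _xys(table, measures)
    forest = fit_forest(X, y, subjects, n_trees=config.n_trees,
                        mtry=config.mtry, seed=config.forest_seed())
    votes = oob_votes(forest, X, subjects)
    metrics = stats.evaluate_model(votes.score, votes.label, y, subjects,
                                   n_boot=config.n_boot, alpha=config.alpha,
                                   seed=config.bootstrap_seed())
    return forest, votes, metrics


# ----------------------------------------------------------------------
# within-modality experiment
# ----------------------------------------------------------------------
def _within_modality_families() -> dict[str, tuple[dict[str, tuple[str, ...]], str | None]]:
    """Model families per modality: measure sets plus the comparison
    reference (None = compare against the best-ranked model)."""
    return {
        "facial": ({"BB": ("BB",), "ES": ("ES",), "NF": ("NF",),
                    "facial_all": ("BB", "ES", "NF")}, "facial_all"),
        "emg_ipsi": ({"RMSi": ("RMSi",), "DURi": ("DURi",), "AMPi": ("AMPi",),
                      "emg_ipsi_all": ("RMSi", "DURi", "AMPi")}, "emg_ipsi_all"),
        "emg_contra": ({"RMSc": ("RMSc",), "DURc": ("DURc",), "AMPc": ("AMPc",),
                        "emg_contra_all": ("RMSc", "DURc", "AMPc")},
                       "emg_contra_all"),
        "heart_rate": ({m: (m,) for m in HR_MEASURES}, None),
        "spo2": ({m: (m,) for m in SAT_MEASURES}, None),
        "eeg": ({"EEGt": ("EEGt",), "EEGa": ("EEGa",)}, None),
    }


def run_within_modality(config: ExperimentConfig,
                        train_table: pd.DataFrame | None = None) -> dict:
    """Rank measures within every modality by OOB discrimination.

    Returns ``{"tables": {family: DataFrame}, "best": {family: model}}``;
    each family table is ranked by (accuracy, AUC) and carries mid-P
    McNemar and DeLong comparisons against the family reference.
    """
    if train_table is None:
        train, _ = build_cohorts(config)
        train_table, _ = extract_feature_table(train)
    truth = train_table["condition"].to_numpy()
    out_tables: dict[str, pd.DataFrame] = {}
    best: dict[str, str] = {}
    for family, (models, reference) in _within_modality_families().items():
        family_measures = sorted({m for ms in models.values() for m in ms})
        if train_table[family_measures].isna().all().all():
            logger.warning("modality %s absent from the cohort; skipped", family)
            continue
        fitted = {}
        for name, measures in models.items():
            _, votes, metrics = _fit_and_oob(train_table, measures, config)
            fitted[name] = (votes, metrics)
        ranked = sorted(
            fitted,
            key=lambda n: (fitted[n][1].accuracy, fitted[n][1].auc),
            reverse=True)
        ref = reference if reference is not None else ranked[0]
        ref_votes = fitted[ref][0]
        ref_correct = np.asarray(ref_votes.label) == truth
        rows = []
        for name in ranked:
            votes, metrics = fitted[name]
            correct = np.asarray(votes.label) == truth
            row = {
                "model": name,
                "measures": "+".join(models[name]),
                "n_observations": metrics.n_observations,
                "accuracy": metrics.accuracy,
                "accuracy_lo": metrics.accuracy_ci[0],
                "accuracy_hi": metrics.accuracy_ci[1],
                "sensitivity": metrics.sensitivity,
                "specificity": metrics.specificity,
                "auc": metrics.auc,
                "auc_lo": metrics.auc_ci[0] if metrics.auc_ci else np.nan,
                "auc_hi": metrics.auc_ci[1] if metrics.auc_ci else np.nan,
            }
            if name == ref:
                row["mcnemar_p_vs_ref"] = np.nan
                row["delong_p_vs_ref"] = np.nan
            else:
                row["mcnemar_p_vs_ref"] = stats.mcnemar_midp(correct, ref_correct)
                *_, p = stats.delong_paired_test(votes.score, ref_votes.score,
                                                 truth)
                row["delong_p_vs_ref"] = p
            rows.append(row)
        out_tables[family] = pd.DataFrame(rows)
        best[family] = ranked[0]
    return {"tables": out_tables, "best": best,
            "seed": config.seed, "config_hash": config.config_hash()}


# ----------------------------------------------------------------------
# multimodal experiment
# ----------------------------------------------------------------------
def multimodal_training_subset(train_table: pd.DataFrame,
                               min_modalities: int = 3) -> pd.DataFrame:
    """Keep training subjects with at least ``min_modalities`` of the five
    modality groups available (EMG counts once, either leg)."""
    keep_subjects = []
    for subject, grp in train_table.groupby("subject_id", sort=False):
        n_mod = sum(
            bool(grp[list(cols)].any(axis=None))
            for cols in _MODALITY_GROUPS.values())
        if n_mod >= min_modalities:
            keep_subjects.append(subject)
    return train_table[train_table["subject_id"].isin(keep_subjects)]


def _metrics_entry(metrics: stats.ModelMetrics) -> dict:
    return metrics.to_dict()


def run_multimodal(config: ExperimentConfig,
                   train_table: pd.DataFrame | None = None,
                   test_table: pd.DataFrame | None = None) -> dict:
    """Train the full multimodal model and validate on the test set.

    Returns a JSON-serialisable results bundle: training OOB metrics
    (overall and stratified term/preterm with the chi-square comparison),
    test-set metrics for the full model, each single-measure model and the
    behavioural+physiological subset (each compared against the full model
    by mid-P McNemar and DeLong, and against chance by the exact binomial
    test), plus the between-measure Spearman matrix and ROC points.
    """
    if train_table is None or test_table is None:
        train, test = build_cohorts(config)
        train_table, _ = extract_feature_table(train)
        test_table, _ = extract_feature_table(test)
    validate_split(train_table, test_table)
    subset = multimodal_training_subset(train_table, config.min_modalities)
    if subset["subject_id"].nunique() < 2:
        raise ValueError("fewer than two training subjects satisfy the "
                         "minimum-modality rule")

    results: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_jsonable(),
        "measures": list(config.multimodal_measures),
    }

    # --- training: full model, OOB ---------------------------------
    full_forest, oob, oob_metrics = _fit_and_oob(
        subset, config.multimodal_measures, config)
    truth_train = subset["condition"].to_numpy()
    correct = np.asarray(oob.label) == truth_train
    term_mask = (subset["gestational_age_weeks"] >= 37.0).to_numpy()
    strat: dict = {}
    for name, mask in (("term", term_mask), ("preterm", ~term_mask)):
        if mask.sum() == 0:
            strat[name] = None
            continue
        m = stats.confusion_metrics(np.asarray(oob.label)[mask],
                                    truth_train[mask], config.alpha)
        if 0 < stats._as_binary(truth_train[mask]).sum() < mask.sum():
            _, m.auc = stats.roc_and_auc(oob.score[mask], truth_train[mask])
        strat[name] = _metrics_entry(m)
    if term_mask.any() and (~term_mask).any():
        chi, p, small = stats.chi_square_accuracy(
            int(correct[term_mask].sum()), int(term_mask.sum()),
            int(correct[~term_mask].sum()), int((~term_mask).sum()))
        strat["chi_square"] = {"statistic": chi, "p": p,
                               "small_sample_warning": small}
    results["train"] = {
        "n_subjects": int(subset["subject_id"].nunique()),
        "n_observations": int(len(subset)),
        "oob": _metrics_entry(oob_metrics),
        "oob_eligible_tree_fraction":
            float(np.mean(oob.n_eligible / config.n_trees)),
        "stratified": strat,
    }

    # --- test-set validation ----------------------------------------
    model_sets: dict[str, tuple[str, ...]] = {
        "full": tuple(config.multimodal_measures)}
    for m in config.multimodal_measures:
        model_sets[m] = (m,)
    model_sets["behavioral_physiological"] = tuple(config.behavioral_measures)

    truth_test = test_table["condition"].to_numpy()
    test_subjects = test_table["subject_id"].to_numpy()
    votes_by_model: dict[str, np.ndarray] = {}
    test_results: dict = {}
    roc_points: dict = {}
    for name, measures in model_sets.items():
        forest = full_forest if name == "full" else fit_forest(
            *_xys(subset, measures)[:1], subset["condition"].to_numpy(),
            subset["subject_id"].to_numpy(), n_trees=config.n_trees,
            mtry=config.mtry, seed=config.forest_seed())
        votes = predict_votes(forest, test_table[list(measures)])
        metrics = stats.evaluate_model(votes.score, votes.label, truth_test,
                                       test_subjects, n_boot=config.n_boot,
                                       alpha=config.alpha,
                                       seed=config.bootstrap_seed())
        curve, _ = stats.roc_and_auc(votes.score, truth_test)
        roc_points[name] = {"threshold": curve.thresholds.tolist(),
                            "fpr": curve.fpr.tolist(),
                            "tpr": curve.tpr.tolist()}
        correct_test = np.asarray(votes.label) == truth_test
        entry = {
            "measures": list(measures),
            "metrics": _metrics_entry(metrics),
            "binomial_p_vs_chance": stats.exact_binomial_two_sided(
                int(correct_test.sum()), len(truth_test)),
        }
        votes_by_model[name] = votes
        test_results[name] = entry

    full_votes = votes_by_model["full"]
    full_correct = np.asarray(full_votes.label) == truth_test
    for name, entry in test_results.items():
        if name == "full":
            entry["mcnemar_p_vs_full"] = None
            entry["delong_p_vs_full"] = None
            continue
        votes = votes_by_model[name]
        correct_test = np.asarray(votes.label) == truth_test
        entry["mcnemar_p_vs_full"] = stats.mcnemar_midp(correct_test,
                                                        full_correct)
        *_, p = stats.delong_paired_test(votes.score, full_votes.score,
                                         truth_test)
        entry["delong_p_vs_full"] = p
    results["test"] = {"n_subjects": int(test_table["subject_id"].nunique()),
                       "n_observations": int(len(test_table)),
                       "models": test_results}
    results["roc"] = roc_points

    # --- correlation structure --------------------------------------
    corr_cols = [c for c in CORRELATION_MEASURES if c in train_table.columns]
    rho, pmat, ns = stats.spearman_matrix(train_table[corr_cols], config.alpha)
    results["spearman"] = {
        "measures": corr_cols,
        "rho": [[None if not np.isfinite(v) else float(v) for v in row]
                for row in rho.to_numpy()],
        "ns": ns.to_numpy().tolist(),
    }
    return results


# ----------------------------------------------------------------------
# reporting
# ----------------------------------------------------------------------
def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def report(results: dict, directory: str | Path) -> list[Path]:
    """Write a results bundle: metrics JSON, comparison CSVs, ROC-point
    CSVs and a plain-text summary.  Every file embeds the config hash and
    seed.  Returns the paths written."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        probe = directory / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as err:
        raise ValueError(f"output directory {directory} is not writable: {err}")

    written: list[Path] = []
    stamp = {"config_hash": results.get("config_hash"),
             "seed": results.get("seed")}

    payload = {k: v for k, v in results.items() if k != "tables"}
    json_path = directory / "metrics.json"
    json_path.write_text(json.dumps(_jsonable(payload), sort_keys=True,
                                    indent=1))
    written.append(json_path)

    for family, table in results.get("tables", {}).items():
        path = directory / f"within_{family}.csv"
        with open(path, "w") as fh:
            fh.write(f"# config_hash={stamp['config_hash']} seed={stamp['seed']}\n")
            table.to_csv(fh, index=False)
        written.append(path)

    for model, pts in results.get("roc", {}).items():
        path = directory / f"roc_{model}.csv"
        frame = pd.DataFrame(pts)[["threshold", "fpr", "tpr"]]
        with open(path, "w") as fh:
            fh.write(f"# config_hash={stamp['config_hash']} seed={stamp['seed']}\n")
            frame.to_csv(fh, index=False)
        written.append(path)

    lines = [f"config_hash: {stamp['config_hash']}", f"seed: {stamp['seed']}"]
    if "test" in results:
        lines.append("test-set models:")
        for name, entry in results["test"]["models"].items():
            m = entry["metrics"]
            lines.append(
                f"  {name}: accuracy={m['accuracy']:.3f} auc="
                + (f"{m['auc']:.3f}" if m["auc"] is not None else "NA"))
    if "tables" in results:
        for family, table in results["tables"].items():
            lines.append(f"within-modality {family}: "
                         + ", ".join(table["model"].tolist()))
    summary = directory / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    written.append(summary)
    return written
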