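"""Discrimination metrics and paired-model statistics.

Implements the evaluation toolkit for paired binary classifiers:
proportions with Wilson score intervals, ROC curves and AUC (trapezoid =
Mann-Whitney with ties counted one half), subject-level bootstrap AUC
confidence intervals, two-sided mid-P McNemar tests on paired correctness,
DeLong's test for correlated AUCs, exact binomial tests against chance,
Yates-corrected chi-square comparison of accuracies between strata, and
pairwise-complete Spearman correlation matrices.

"noxious" (class 1) is the positive class throughout: sensitivity is the
fraction of noxious observations identified, specificity the fraction of
control observations identified.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


def _as_binary(truth) -> np.ndarray:
    arr = np.asarray(truth)
    if arr.dtype.kind in "UO":
        return (arr == "noxious").astype(np.int64)
    return arr.astype(np.int64)


# ----------------------------------------------------------------------
# proportions
# ----------------------------------------------------------------------
def wilson_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """95% (by default) Wilson score interval for a binomial proportion,
    without continuity correction."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid k={k}, n={n}")
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    phat = k / n
    denom = 1.0 + z * z / n
    centre = phat + z * z / (2.0 * n)
    half = z * math.sqrt(phat * (1.0 - phat) / n + z * z / (4.0 * n * n))
    return (centre - half) / denom, (centre + half) / denom


@dataclass
class ModelMetrics:
    """Discrimination metrics of one model on one set of observations.

    Undefined metrics (empty input or a class absent from the truth) are
    NaN and listed in ``undefined``; they are never silently 0.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    n_observations: int
    accuracy_ci: tuple[float, float] | None = None
    sensitivity_ci: tuple[float, float] | None = None
    specificity_ci: tuple[float, float] | None = None
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def _clean(v):
            if isinstance(v, tuple):
                return [_clean(x) for x in v]
            if isinstance(v, float) and math.isnan(v):
                return None
            return v
        return {k: _clean(v) for k, v in self.__dict__.items()}


def confusion_metrics(predicted, truth, alpha: float = 0.05) -> ModelMetrics:
    """Accuracy, sensitivity and specificity (with Wilson intervals) from
    predicted and true labels."""
    pred = _as_binary(predicted)
    true = _as_binary(truth)
    if pred.size != true.size:
        raise ValueError("predicted and truth must have equal length")
    undefined: list[str] = []
    n = true.size
    if n == 0:
        return ModelMetrics(math.nan, math.nan, math.nan, 0,
                            undefined=["accuracy", "sensitivity", "specificity"])
    correct = pred == true
    acc = correct.mean()
    acc_ci = wilson_interval(int(correct.sum()), n, alpha)
    n_pos = int((true == 1).sum())
    n_neg = n - n_pos
    if n_pos == 0:
        sens, sens_ci = math.nan, None
        undefined.append("sensitivity")
    else:
        k = int(correct[true == 1].sum())
        sens, sens_ci = k / n_pos, wilson_interval(k, n_pos, alpha)
    if n_neg == 0:
        spec, spec_ci = math.nan, None
        undefined.append("specificity")
    else:
        k = int(correct[true == 0].sum())
        spec, spec_ci = k / n_neg, wilson_interval(k, n_neg, alpha)
    return ModelMetrics(float(acc), float(sens), float(spec), n,
                        accuracy_ci=acc_ci, sensitivity_ci=sens_ci,
                        specificity_ci=spec_ci, undefined=undefined)


# ----------------------------------------------------------------------
# ROC / AUC
# ----------------------------------------------------------------------
@dataclass
class ROCCurve:
    """ROC points over all distinct score thresholds, including the (0,0)
    and (1,1) endpoints; both coordinates are nondecreasing."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_and_auc(scores, truth) -> tuple[ROCCurve, float]:
    """ROC curve over distinct-score thresholds and the trapezoid AUC
    (equal to the Mann-Whitney statistic with ties counted one half)."""
    s = np.asarray(scores, dtype=float)
    y = _as_binary(truth)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build a ROC curve")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.concatenate([distinct, [y.size - 1]])
    tps = np.cumsum(y_sorted)[idx]
    fps = (idx + 1) - tps
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    thresholds = np.concatenate([[np.inf], s_sorted[idx]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds), auc


def _auc_fast(scores: np.ndarray, y: np.ndarray) -> float:
    """Rank-based AUC (ties one half); used inside the bootstrap loop."""
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    ranks = sps.rankdata(scores)
    return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def bootstrap_auc_ci(scores, truth, subject_ids, n_boot: int = 2000,
                     alpha: float = 0.05, seed: int = 0
                     ) -> tuple[float, float]:
    """Percentile bootstrap interval for the AUC, resampling at the
    subject level so a subject's paired observations move together.
    Resamples with one class absent are redrawn (up to 10 x ``n_boot``
    attempts in total)."""
    s = np.asarray(scores, dtype=float)
    y = _as_binary(truth)
    subject_ids = np.asarray(subject_ids)
    subjects, subj_idx = np.unique(subject_ids, return_inverse=True)
    S = subjects.size
    rows_by_subject = [np.nonzero(subj_idx == i)[0] for i in range(S)]
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x0b0075)))
    aucs = np.empty(n_boot)
    attempts = 0
    i = 0
    while i < n_boot:
        attempts += 1
        if attempts > 10 * n_boot:
            raise RuntimeError(
                "bootstrap resamples are persistently degenerate (one class "
                "absent); the data cannot support an AUC interval")
        draw = rng.integers(0, S, size=S)
        rows = np.concatenate([rows_by_subject[d] for d in draw])
        yb = y[rows]
        if yb.min() == yb.max():
            continue
        aucs[i] = _auc_fast(s[rows], yb)
        i += 1
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


# ----------------------------------------------------------------------
# paired-model tests
# ----------------------------------------------------------------------
def mcnemar_midp(correct_a, correct_b) -> float:
    """Two-sided mid-P McNemar test on paired per-observation correctness.

    With discordant counts b (A correct, B wrong) and c (the reverse),
    n = b + c and k = max(b, c):
    p = 2 [P(X >= k) - P(X = k)/2], X ~ Binomial(n, 1/2), capped at 1.
    """
    a = np.asarray(correct_a, dtype=bool)
    b_arr = np.asarray(correct_b, dtype=bool)
    if a.size != b_arr.size:
        raise ValueError("correctness vectors must have equal length")
    b = int(np.sum(a & ~b_arr))
    c = int(np.sum(~a & b_arr))
    n = b + c
    if n == 0:
        return 1.0
    k = max(b, c)
    tail = float(sps.binom.sf(k - 1, n, 0.5))       # P(X >= k)
    point = float(sps.binom.pmf(k, n, 0.5))
    return min(1.0, 2.0 * (tail - 0.5 * point))


def delong_paired_test(scores_a, scores_b, truth
                       ) -> tuple[float, float, float, float]:
    """DeLong's test for two correlated AUCs on the same observations.

    Returns ``(auc_a, auc_b, z, p)`` where the variance of the AUC
    difference is estimated from the structural components (placement
    values), accounting for the correlation between the two score sets.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = _as_binary(truth)
    if not sa.size == sb.size == y.size:
        raise ValueError("score sets and truth must have equal length")
    m = int(y.sum())
    n = y.size - m
    if m < 2 or n < 2:
        raise ValueError("need at least two observations in each class")

    def placements(s):
        pos, neg = s[y == 1], s[y == 0]
        all_r = sps.rankdata(np.concatenate([pos, neg]))
        pos_r = sps.rankdata(pos)
        neg_r = sps.rankdata(neg)
        v10 = (all_r[:m] - pos_r) / n          # per-positive placements
        v01 = 1.0 - (all_r[m:] - neg_r) / m    # per-negative placements
        return v10, v01, float(v10.mean())

    v10a, v01a, auc_a = placements(sa)
    v10b, v01b, auc_b = placements(sb)
    d10 = v10a - v10b
    d01 = v01a - v01b
    var = d10.var(ddof=1) / m + d01.var(ddof=1) / n
    diff = auc_a - auc_b
    if var <= 0:
        return auc_a, auc_b, 0.0, 1.0 if diff == 0 else 0.0
    z = diff / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(min(1.0, p))


def delong_auc_variance(scores, truth) -> float:
    """DeLong variance of a single AUC (used for calibration checks)."""
    s = np.asarray(scores, dtype=float)
    y = _as_binary(truth)
    m = int(y.sum())
    n = y.size - m
    pos, neg = s[y == 1], s[y == 0]
    all_r = sps.rankdata(np.concatenate([pos, neg]))
    v10 = (all_r[:m] - sps.rankdata(pos)) / n
    v01 = 1.0 - (all_r[m:] - sps.rankdata(neg)) / m
    return float(v10.var(ddof=1) / m + v01.var(ddof=1) / n)


def exact_binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial test: the sum of P(X = i) over all i with
    P(X = i) <= P(X = k), X ~ Binomial(n, p0); capped at 1."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid k={k}, n={n}")
    pmf = sps.binom.pmf(np.arange(n + 1), n, p0)
    # the tolerance keeps exactly-equal probabilities (e.g. the symmetric
    # point at n - k for p0 = 1/2) inside the sum despite float rounding
    p = float(pmf[pmf <= pmf[k] * (1.0 + 1e-9)].sum())
    if p >= 1.0 - 1e-12:  # every term included: the sum is exactly 1
        return 1.0
    return p


def chi_square_accuracy(correct1: int, n1: int, correct2: int, n2: int
                        ) -> tuple[float, float, bool]:
    """Yates-corrected chi-square comparison of two accuracies (2 x 2
    correct/incorrect x group table, df = 1).

    Returns ``(statistic, p, small_sample)``; the flag marks an expected
    cell below 5.
    """
    table = np.array([[correct1, n1 - correct1], [correct2, n2 - correct2]],
                     dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square table has a zero margin")
    res = sps.chi2_contingency(table, correction=True)
    small = bool(np.any(res.expected_freq < 5))
    return float(res.statistic), float(res.pvalue), small


# ----------------------------------------------------------------------
# correlation structure
# ----------------------------------------------------------------------
def spearman_matrix(table: pd.DataFrame, alpha: float = 0.05
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Spearman correlations between measures.

    Returns ``(rho, p, ns)`` DataFrames; ``ns`` masks nonsignificant pairs
    (p >= ``alpha``).  Pairs with fewer than 3 complete rows are missing.
    Ties get mid-ranks; p-values use the t approximation.
    """
    cols = list(table.columns)
    k = len(cols)
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    for i in range(k):
        rho[i, i] = 1.0
        pval[i, i] = 0.0
        for j in range(i + 1, k):
            x = table[cols[i]].to_numpy(dtype=float)
            y = table[cols[j]].to_numpy(dtype=float)
            mask = np.isfinite(x) & np.isfinite(y)
            if mask.sum() < 3:
                continue
            res = sps.spearmanr(x[mask], y[mask])
            rho[i, j] = rho[j, i] = res.statistic
            pval[i, j] = pval[j, i] = res.pvalue
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    p_df = pd.DataFrame(pval, index=cols, columns=cols)
    ns_df = pd.DataFrame((pval >= alpha) | ~np.isfinite(pval),
                         index=cols, columns=cols)
    np.fill_diagonal(ns_df.values, False)
    return rho_df, p_df, ns_df


def evaluate_model(scores, predicted, truth, subject_ids,
                   n_boot: int = 2000, alpha: float = 0.05, seed: int = 0
                   ) -> ModelMetrics:
    """Full metric bundle for one model: confusion metrics with Wilson
    intervals plus AUC with a subject-level bootstrap interval."""
    metrics = confusion_metrics(predicted, truth, alpha)
    y = _as_binary(truth)
    if y.size and 0 < y.sum() < y.size:
        _, auc = roc_and_auc(scores, truth)
        metrics.auc = auc
        metrics.auc_ci = bootstrap_auc_ci(scores, truth, subject_ids,
                                          n_boot=n_boot, alpha=alpha, seed=seed)
    else:
        metrics.undefined.append("auc")
    return metrics
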