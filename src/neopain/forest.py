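"""Random-forest classifier with subject-level bootstrapping.

This is a from-scratch implementation of Breiman-style classification
forests with one structural modification: because each subject contributes
a *pair* of observations (one noxious, one control), each tree's bootstrap
resamples whole subjects rather than observations.  A subject drawn k
times contributes every one of its observations k times to the tree's
training rows, and out-of-bag (OOB) predictions for an observation use
only trees whose bag excludes that observation's *subject*, keeping the
OOB estimate honest under pairing.

Missing values are handled by per-tree in-bag median imputation: each tree
stores the medians of its own in-bag rows at fit time and reuses them at
prediction time.

Trees use Gini-impurity splits with midpoint thresholds, per-node feature
subsampling of size ``mtry`` (default ceil(sqrt(p))), and are grown to
purity (minimum leaf size 1, no pruning).
"""
from __future__ import annotations

import json
import math
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASSES = ("control", "noxious")  # class 1 ("noxious") is the positive class


# ----------------------------------------------------------------------
# impurity and splitting
# ----------------------------------------------------------------------
def gini_impurity(class_counts) -> float:
    """Gini diversity index 1 - sum(p_i^2) of a node's class counts."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be nonnegative")
    total = counts.sum()
    if total < 1:
        raise ValueError("class counts must sum to at least 1")
    p = counts / total
    return float(1.0 - np.sum(p ** 2))


def _feature_best_cut(v: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """Best (impurity decrease, threshold) for one feature; None when no
    cut reduces impurity.  Thresholds are midpoints between consecutive
    distinct values; ties within a feature go to the lower threshold."""
    order = np.argsort(v, kind="stable")
    vs = v[order]
    ys = y[order]
    n = vs.size
    cum1 = np.cumsum(ys)
    n1 = cum1[-1]
    cuts = np.nonzero(vs[:-1] < vs[1:])[0]
    if cuts.size == 0:
        return None
    nL = (cuts + 1).astype(float)
    nR = n - nL
    n1L = cum1[cuts].astype(float)
    n0L = nL - n1L
    n1R = n1 - n1L
    n0R = nR - n1R
    giniL = 1.0 - (n1L / nL) ** 2 - (n0L / nL) ** 2
    giniR = 1.0 - (n1R / nR) ** 2 - (n0R / nR) ** 2
    parent = 1.0 - (n1 / n) ** 2 - ((n - n1) / n) ** 2
    dec = parent - (nL * giniL + nR * giniR) / n
    j = int(np.argmax(dec))  # first max -> lowest threshold on ties
    if dec[j] <= 0:
        return None
    thr = (vs[cuts[j]] + vs[cuts[j] + 1]) / 2.0
    return float(dec[j]), float(thr)


def best_split(X: np.ndarray, y: np.ndarray, feature_names: list[str],
               feature_subset: list[int] | None = None
               ) -> tuple[str, float, float] | None:
    """Best (feature name, midpoint threshold, impurity decrease) over a
    feature subset, or None when no split reduces impurity.

    Rows must already be imputed (no NaN among candidate features).  Ties
    across features are broken by feature-name order, then by the lower
    threshold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < 2 or np.unique(y).size < 2:
        return None
    cand = list(range(X.shape[1])) if feature_subset is None else list(feature_subset)
    cand.sort(key=lambda j: feature_names[j])
    best: tuple[float, str, float] | None = None
    for j in cand:
        res = _feature_best_cut(X[:, j], y)
        if res is None:
            continue
        dec, thr = res
        if best is None or dec > best[0]:
            best = (dec, feature_names[j], thr)
    if best is None:
        return None
    return best[1], best[2], best[0]


# ----------------------------------------------------------------------
# trees
# ----------------------------------------------------------------------
@dataclass
class Tree:
    """One decision tree in flat-array form.

    ``feature[i] < 0`` marks node i as a leaf; internal nodes send rows
    with value <= ``threshold`` left.  ``counts`` holds the in-bag class
    counts at every node; ``medians`` the per-feature in-bag imputation
    values (NaN = feature unusable in this tree).
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    counts: np.ndarray
    medians: np.ndarray

    def predict_class(self, X: np.ndarray) -> np.ndarray:
        """Predicted class (0/1) per row; rows are imputed with this
        tree's stored medians first."""
        Ximp = X.copy()
        fill = np.where(np.isnan(self.medians), 0.0, self.medians)
        nan_mask = np.isnan(Ximp)
        Ximp[nan_mask] = np.broadcast_to(fill, Ximp.shape)[nan_mask]
        idx = np.zeros(Ximp.shape[0], dtype=np.int64)
        while True:
            f = self.feature[idx]
            inner = f >= 0
            if not inner.any():
                break
            rows = np.nonzero(inner)[0]
            vals = Ximp[rows, f[rows]]
            go_left = vals <= self.threshold[idx[rows]]
            idx[rows] = np.where(go_left, self.left[idx[rows]], self.right[idx[rows]])
        c = self.counts[idx]
        # leaf majority vote; exact ties go to the control class
        return (c[:, 1] > c[:, 0]).astype(np.int64)

    def n_nodes(self) -> int:
        return self.feature.size


class _TreeBuilder:
    def __init__(self, X: np.ndarray, y: np.ndarray, usable: np.ndarray,
                 name_order: np.ndarray, mtry: int, rng: np.random.Generator,
                 min_leaf: int = 1) -> None:
        self.X, self.y = X, y
        self.usable = np.nonzero(usable)[0]
        self.name_order = name_order  # rank of each feature name, lexicographic
        self.mtry = mtry
        self.rng = rng
        self.min_leaf = min_leaf
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.counts: list[tuple[int, int]] = []

    def _new_node(self, rows: np.ndarray) -> int:
        node = len(self.feature)
        c = np.bincount(self.y[rows], minlength=2)
        self.feature.append(-1)
        self.threshold.append(np.nan)
        self.left.append(-1)
        self.right.append(-1)
        self.counts.append((int(c[0]), int(c[1])))
        return node

    def build(self, rows: np.ndarray) -> int:
        node = self._new_node(rows)
        c0, c1 = self.counts[node]
        if c0 == 0 or c1 == 0 or rows.size < 2 * self.min_leaf \
                or self.usable.size == 0:
            return node
        k = min(self.mtry, self.usable.size)
        feats = self.rng.choice(self.usable, size=k, replace=False)
        split = self._best_split(rows, feats)
        if split is None:
            return node
        f, thr = split
        go_left = self.X[rows, f] <= thr
        self.feature[node] = f
        self.threshold[node] = thr
        left = self.build(rows[go_left])
        right = self.build(rows[~go_left])
        self.left[node] = left
        self.right[node] = right
        return node

    def _best_split(self, rows: np.ndarray, feats: np.ndarray
                    ) -> tuple[int, float] | None:
        y = self.y[rows]
        order = feats[np.argsort(self.name_order[feats], kind="stable")]
        best: tuple[float, int, float] | None = None
        for f in order:
            res = _feature_best_cut(self.X[rows, f], y)
            if res is None:
                continue
            dec, thr = res
            if best is None or dec > best[0]:
                best = (dec, int(f), thr)
        if best is None:
            return None
        return best[1], best[2]

    def finish(self) -> tuple[np.ndarray, ...]:
        return (np.array(self.feature, dtype=np.int64),
                np.array(self.threshold, dtype=float),
                np.array(self.left, dtype=np.int64),
                np.array(self.right, dtype=np.int64),
                np.array(self.counts, dtype=np.int64))


# ----------------------------------------------------------------------
# forest
# ----------------------------------------------------------------------
def subject_bootstrap(subjects: list, rng: np.random.Generator) -> np.ndarray:
    """One in-bag multiset: S draws with replacement from the S distinct
    subjects, returned as a per-subject inclusion count vector."""
    S = len(subjects)
    if S < 1:
        raise ValueError("need at least one subject")
    draws = rng.integers(0, S, size=S)
    return np.bincount(draws, minlength=S)


@dataclass
class SubjectForest:
    """A fitted subject-bootstrapped forest."""

    trees: list[Tree]
    inbag: np.ndarray            # (n_trees, S) per-subject multiplicities
    subjects: list               # distinct training subjects, in first-seen order
    feature_names: list[str]
    mtry: int
    n_trees: int
    seed: int

    # ------------------------------------------------------------------
    def subject_index(self, subject_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.subjects)}
        try:
            return np.array([lookup[s] for s in subject_ids], dtype=np.int64)
        except KeyError as err:
            raise KeyError(f"unknown training subject: {err.args[0]}") from None

    def to_json(self) -> str:
        payload = {
            "feature_names": self.feature_names,
            "subjects": list(self.subjects),
            "mtry": self.mtry, "n_trees": self.n_trees, "seed": self.seed,
            "inbag": self.inbag.tolist(),
            "trees": [
                {"feature": t.feature.tolist(),
                 "threshold": [None if math.isnan(v) else v
                               for v in t.threshold.tolist()],
                 "left": t.left.tolist(), "right": t.right.tolist(),
                 "counts": t.counts.tolist(),
                 "medians": [None if math.isnan(v) else v
                             for v in t.medians.tolist()]}
                for t in self.trees
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SubjectForest":
        payload = json.loads(text)

        def arr(vals):
            return np.array([math.nan if v is None else v for v in vals],
                            dtype=float)

        trees = [Tree(feature=np.array(t["feature"], dtype=np.int64),
                      threshold=arr(t["threshold"]),
                      left=np.array(t["left"], dtype=np.int64),
                      right=np.array(t["right"], dtype=np.int64),
                      counts=np.array(t["counts"], dtype=np.int64),
                      medians=arr(t["medians"]))
                 for t in payload["trees"]]
        return cls(trees=trees,
                   inbag=np.array(payload["inbag"], dtype=np.int64),
                   subjects=payload["subjects"],
                   feature_names=payload["feature_names"],
                   mtry=payload["mtry"], n_trees=payload["n_trees"],
                   seed=payload["seed"])


@dataclass
class VoteResult:
    """Per-observation vote aggregation.

    ``score`` is the fraction of eligible trees voting "noxious";
    ``label`` is "noxious" iff score > 0.5 (an exact 0.5 tie is labelled
    "control" and flagged)."""

    score: np.ndarray
    label: np.ndarray
    n_eligible: np.ndarray
    tie: np.ndarray

    @property
    def n(self) -> int:
        return self.score.size


def _coerce_table(features, feature_names=None
                  ) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), list(features.columns)
    X = np.asarray(features, dtype=float)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    return X, list(feature_names)


def _encode_labels(labels) -> np.ndarray:
    y = np.zeros(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if isinstance(lab, str):
            if lab not in CLASSES:
                raise ValueError(f"unknown class label {lab!r}")
            y[i] = CLASSES.index(lab)
        else:
            v = int(lab)
            if v not in (0, 1):
                raise ValueError(f"integer labels must be 0/1, got {lab!r}")
            y[i] = v
    return y


def fit_forest(features, labels, subject_ids, n_trees: int = 1000,
               mtry: int | None = None, seed: int = 0, min_leaf: int = 1,
               feature_names: list[str] | None = None) -> SubjectForest:
    """Fit a subject-bootstrapped Gini forest.

    ``features`` is a DataFrame (columns = measure names) or 2-D array;
    NaN marks missing values.  ``labels`` are "noxious"/"control" (or
    1/0); ``subject_ids`` assigns each observation (row) to a subject.
    Deterministic given ``seed``.
    """
    X, names = _coerce_table(features, feature_names)
    y = _encode_labels(labels)
    subject_ids = list(subject_ids)
    if not (len(subject_ids) == len(y) == X.shape[0]):
        raise ValueError("features, labels and subject_ids disagree on length")
    subjects: list = []
    seen: dict = {}
    for s in subject_ids:
        if s not in seen:
            seen[s] = len(subjects)
            subjects.append(s)
    if len(subjects) < 2:
        raise ValueError("need at least two distinct subjects")
    if np.unique(y).size < 2:
        raise ValueError("need both classes present in the training labels")
    subj_idx = np.array([seen[s] for s in subject_ids], dtype=np.int64)
    S = len(subjects)
    rows_by_subject = [np.nonzero(subj_idx == s)[0] for s in range(S)]

    p = X.shape[1]
    if mtry is None:
        mtry = max(1, math.ceil(math.sqrt(p)))
    name_order = np.empty(p, dtype=np.int64)
    name_order[np.argsort(np.array(names, dtype=object))] = np.arange(p)

    trees: list[Tree] = []
    inbag = np.zeros((n_trees, S), dtype=np.int64)
    for t in range(n_trees):
        rng = np.random.default_rng(np.random.SeedSequence((seed, t)))
        bag = subject_bootstrap(subjects, rng)
        inbag[t] = bag
        rows = np.concatenate([
            np.tile(rows_by_subject[s], bag[s]) for s in range(S) if bag[s] > 0
        ])
        with np.errstate(all="ignore"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                medians = np.nanmedian(X[rows], axis=0)
        usable = ~np.isnan(medians)
        if not usable.all():
            bad = [names[j] for j in np.nonzero(~usable)[0]]
            logger.info("tree %d: features %s missing for all in-bag rows",
                        t, bad)
        Ximp = X[rows].copy()
        fill = np.where(usable, medians, 0.0)
        nan_mask = np.isnan(Ximp)
        Ximp[nan_mask] = np.broadcast_to(fill, Ximp.shape)[nan_mask]
        builder = _TreeBuilder(Ximp, y[rows], usable, name_order, mtry, rng,
                               min_leaf)
        builder.build(np.arange(rows.size))
        f_arr, thr_arr, l_arr, r_arr, c_arr = builder.finish()
        trees.append(Tree(f_arr, thr_arr, l_arr, r_arr, c_arr,
                          medians.astype(float)))

    if n_trees >= 50:
        never_oob = np.nonzero((inbag > 0).all(axis=0))[0]
        if never_oob.size:
            raise RuntimeError(
                f"subjects {[subjects[s] for s in never_oob]} are in-bag for "
                f"every tree; increase n_trees")
    return SubjectForest(trees=trees, inbag=inbag, subjects=subjects,
                         feature_names=names, mtry=mtry, n_trees=n_trees,
                         seed=seed)


def _aggregate_votes(forest: SubjectForest, X: np.ndarray,
                     eligible: np.ndarray) -> VoteResult:
    n = X.shape[0]
    votes = np.zeros(n, dtype=np.int64)
    n_elig = eligible.sum(axis=0)
    if np.any(n_elig == 0):
        bad = int(np.nonzero(n_elig == 0)[0][0])
        raise RuntimeError(
            f"observation {bad} has no eligible (out-of-bag) trees; "
            f"increase n_trees")
    for t, tree in enumerate(forest.trees):
        mask = eligible[t]
        if not mask.any():
            continue
        pred = tree.predict_class(X[mask])
        votes[mask] += pred
    score = votes / n_elig
    tie = score == 0.5
    label = np.where(score > 0.5, "noxious", "control")
    return VoteResult(score=score, label=label, n_eligible=n_elig, tie=tie)


def oob_votes(forest: SubjectForest, features, subject_ids) -> VoteResult:
    """Out-of-bag votes for the training observations: each observation is
    scored only by trees whose bag excludes its subject."""
    X, names = _coerce_table(features)
    if names != forest.feature_names and not isinstance(features, np.ndarray):
        raise ValueError("feature columns do not match the training features")
    subj_idx = forest.subject_index(subject_ids)
    eligible = forest.inbag[:, subj_idx] == 0  # (n_trees, n_obs)
    return _aggregate_votes(forest, X, eligible)


def predict_votes(forest: SubjectForest, features) -> VoteResult:
    """Votes for new observations: every tree is eligible; missing values
    are imputed per tree with the stored in-bag medians."""
    X, names = _coerce_table(features)
    if isinstance(features, pd.DataFrame) and names != forest.feature_names:
        unknown = [n for n in names if n not in forest.feature_names]
        if unknown:
            raise ValueError(f"unknown feature name(s): {unknown}")
        X = features[forest.feature_names].to_numpy(dtype=float)
    if X.shape[0] == 0:
        empty = np.array([])
        return VoteResult(score=empty, label=np.array([], dtype=object),
                          n_eligible=np.array([], dtype=np.int64),
                          tie=np.array([], dtype=bool))
    if X.shape[1] != len(forest.feature_names):
        raise ValueError("feature count does not match the training features")
    eligible = np.ones((forest.n_trees, X.shape[0]), dtype=bool)
    return _aggregate_votes(forest, X, eligible)
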