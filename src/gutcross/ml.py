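"""Nested cross-validated tree-ensemble classification and rank aggregation.

Three tree-ensemble families (random forest, extremely randomized trees,
AdaBoost) are tuned strictly inside the inner cross-validation loop and
evaluated by ROC AUC on outer folds they never saw. Feature importances from
every fitted best model are converted to ranks (1 = most important) and
summarized per feature by the median across all model families and
repetitions — at the defaults, 3 families x 40 repetitions = 120 ranks per
feature.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import StratifiedKFold

from .tables import CohortMetadata, RelAbundTable

__all__ = [
    "FAMILIES",
    "LearnerSpec",
    "NestedCVResult",
    "RankAggregation",
    "default_grids",
    "roc_auc",
    "nested_cv",
    "nested_cv_multi",
    "aggregate_ranks",
]

FAMILIES = ("random_forest", "extra_trees", "adaboost")


def default_grids() -> dict[str, dict[str, list]]:
    """Small documented hyperparameter grids, one per family."""
    return {
        "random_forest": {"n_estimators": [100, 300], "max_depth": [None, 8]},
        "extra_trees": {"n_estimators": [100, 300], "max_depth": [None, 8]},
        "adaboost": {"n_estimators": [50, 200], "learning_rate": [0.1, 1.0]},
    }


@dataclass(frozen=True)
class LearnerSpec:
    """One tree-ensemble family plus its hyperparameter grid."""

    family: str
    grid: dict[str, list] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(
            self, "grid", dict(self.grid) or default_grids()[self.family]
        )
        if any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("grid values must be non-empty")

    def candidates(self) -> list[dict]:
        keys = sorted(self.grid)
        return [dict(zip(keys, combo))
                for combo in itertools.product(*(self.grid[k] for k in keys))]


def build_estimator(family: str, params: dict, seed: int):
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if family == "extra_trees":
        return ExtraTreesClassifier(random_state=seed, **params)
    if family == "adaboost":
        return AdaBoostClassifier(random_state=seed, **params)
    raise ValueError(f"unknown family {family!r}")


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney formulation.

    Probability that a random positive outranks a random negative, ties
    counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = scipy.stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _importances(model) -> np.ndarray:
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    if total <= 0:  # a model that never split: flat importance
        return np.full_like(imp, 1.0 / imp.size)
    return imp / total


@dataclass
class FoldRecord:
    """Bookkeeping for one outer fold of one repetition."""

    repeat: int
    fold: int
    outer_train_idx: np.ndarray
    outer_test_idx: np.ndarray
    inner_splits: list[tuple[np.ndarray, np.ndarray]]
    best_params: dict[str, dict]
    models: dict[str, object]  # family -> fitted best estimator
    aucs: dict[str, float]  # family -> outer-fold AUC


@dataclass
class NestedCVResult:
    """Outcome of repeated nested CV for one or more families."""

    families: list[str]
    feature_ids: list[str]
    fold_records: list[FoldRecord]
    repeat_aucs: dict[str, np.ndarray]  # family -> (n_repeats, outer_k)
    repeat_importances: dict[str, np.ndarray]  # family -> (n_repeats, m)

    def mean_auc(self, family: str) -> float:
        return float(self.repeat_aucs[family].mean())

    def sd_auc(self, family: str) -> float:
        """SD of per-repetition mean AUCs (across repetitions)."""
        per_rep = self.repeat_aucs[family].mean(axis=1)
        return float(per_rep.std(ddof=1)) if len(per_rep) > 1 else 0.0

    def importance_vectors(self) -> list[np.ndarray]:
        """One normalized vector per (family, repetition), spec order."""
        out = []
        for fam in self.families:
            out.extend(list(self.repeat_importances[fam]))
        return out


def _as_xy(features, meta: CohortMetadata):
    x = features.data.to_numpy(dtype=float).T  # samples x features
    y = meta.exposure_for(features.sample_ids)
    return x, y


def nested_cv_multi(features, meta: CohortMetadata,
                    specs: dict[str, LearnerSpec] | None = None,
                    outer_k: int = 5, inner_k: int = 3, n_repeats: int = 40,
                    seed: int = 0) -> NestedCVResult:
    """Repeated nested CV with shared fold partitions across families.

    Per repetition: fresh stratified outer folds; within each outer fold,
    each family's grid is scored by mean inner-CV AUC only, the winner is
    refit on the full outer-train split and evaluated once on the held-out
    outer-test fold. Model selection never sees outer-test samples. Per
    repetition and family, the importance vector is the normalized mean of
    the outer-fold best models' impurity importances.
    """
    if specs is None:
        specs = {fam: LearnerSpec(fam) for fam in FAMILIES}
    x, y = _as_xy(features, meta)
    n = len(y)
    if min((y == 0).sum(), (y == 1).sum()) < outer_k:
        raise ValueError("each class needs at least outer_k samples")
    fams = list(specs)
    rng = np.random.default_rng(seed)
    records: list[FoldRecord] = []
    repeat_aucs = {f: np.zeros((n_repeats, outer_k)) for f in fams}
    repeat_imps = {f: np.zeros((n_repeats, x.shape[1])) for f in fams}

    for rep in range(n_repeats):
        rep_seed = int(rng.integers(2 ** 31 - 1))
        outer = StratifiedKFold(outer_k, shuffle=True, random_state=rep_seed)
        rep_imp = {f: np.zeros(x.shape[1]) for f in fams}
        for fold, (tr, te) in enumerate(outer.split(x, y)):
            inner = StratifiedKFold(inner_k, shuffle=True,
                                    random_state=rep_seed + fold + 1)
            inner_splits = [(tr[i], tr[j]) for i, j in inner.split(x[tr], y[tr])]
            best_params, models, aucs = {}, {}, {}
            for fam in fams:
                spec = specs[fam]
                cands = spec.candidates()
                if len(cands) == 1:
                    best = cands[0]
                else:
                    scores = []
                    for params in cands:
                        fold_scores = []
                        for itr, ite in inner_splits:
                            est = build_estimator(fam, params, spec.seed)
                            est.fit(x[itr], y[itr])
                            prob = est.predict_proba(x[ite])[:, 1]
                            fold_scores.append(roc_auc(prob, y[ite]))
                        scores.append(np.mean(fold_scores))
                    best = cands[int(np.argmax(scores))]
                est = build_estimator(fam, best, spec.seed)
                est.fit(x[tr], y[tr])
                prob = est.predict_proba(x[te])[:, 1]
                best_params[fam] = best
                models[fam] = est
                aucs[fam] = roc_auc(prob, y[te])
                repeat_aucs[fam][rep, fold] = aucs[fam]
                rep_imp[fam] += _importances(est)
            records.append(FoldRecord(rep, fold, tr, te, inner_splits,
                                      best_params, models, aucs))
        for fam in fams:
            v = rep_imp[fam] / outer_k
            repeat_imps[fam][rep] = v / v.sum()

    return NestedCVResult(
        families=fams,
        feature_ids=features.feature_ids,
        fold_records=records,
        repeat_aucs=repeat_aucs,
        repeat_importances=repeat_imps,
    )


def nested_cv(features, meta: CohortMetadata, spec: LearnerSpec,
              outer_k: int = 5, inner_k: int = 3, n_repeats: int = 40,
              seed: int = 0) -> NestedCVResult:
    """Nested CV for a single learner family (see :func:`nested_cv_multi`)."""
    return nested_cv_multi(features, meta, {spec.family: spec},
                           outer_k=outer_k, inner_k=inner_k,
                           n_repeats=n_repeats, seed=seed)


@dataclass
class RankAggregation:
    """Per-feature importance ranks pooled over fits, summarized by median."""

    ranks: pd.DataFrame  # features x fits, each column a permutation of 1..m
    median_rank: pd.Series  # sorted ascending: most important first

    @property
    def n_fits(self) -> int:
        return self.ranks.shape[1]


def aggregate_ranks(importance_vectors, feature_ids) -> RankAggregation:
    """Convert importance vectors to ranks and take per-feature medians.

    Within each fit, rank 1 is the largest importance; ties receive average
    ranks. The output ordering is by ascending median rank (most to least
    important).
    """
    vectors = [np.asarray(v, dtype=float) for v in importance_vectors]
    m = len(feature_ids)
    if any(v.shape != (m,) for v in vectors):
        raise ValueError("importance vectors must match the feature set")
    rank_cols = {
        f"fit{j + 1}": scipy.stats.rankdata(-v, method="average")
        for j, v in enumerate(vectors)
    }
    ranks = pd.DataFrame(rank_cols, index=list(feature_ids))
    med = ranks.median(axis=1)
    order = med.sort_values(kind="stable").index
    return RankAggregation(ranks=ranks.loc[order], median_rank=med.loc[order])
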