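"""Cross-study transfer: train on one cohort, predict the other.

After each outer iteration of the nested CV on the training cohort, the best
model of each family is combined into an unweighted soft-vote ensemble that
predicts a fresh stratified random subset of the *other* cohort, which no
model ever saw. The transfer is audited with per-feature permutation
importance (AUC drop when one feature's values are shuffled across test
samples) and a pooled stratified-AUC bias check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ml import FAMILIES, LearnerSpec, NestedCVResult, nested_cv_multi, roc_auc
from .tables import CohortMetadata, CountTable, RelAbundTable, TableError, prevalence_filter

__all__ = [
    "EnsembleModel",
    "TransferReport",
    "align_features",
    "transfer_predict",
    "permutation_importance",
    "pooled_stratified_auc",
]


def align_features(table_a, table_b, threshold: float):
    """Harmonize two cohorts onto a jointly prevalent feature set.

    Intersects feature ids (order of the first table preserved) and applies
    the joint prevalence filter: a feature must be present in at least
    ``threshold`` of samples in *both* cohorts. The study-style defaults are
    0.30 for taxa and 0.50 for pathways.
    """
    shared = [f for f in table_a.feature_ids if f in set(table_b.feature_ids)]
    if not shared:
        raise TableError("cohorts share no feature ids")
    a = type(table_a)(table_a.data.loc[shared])
    b = type(table_b)(table_b.data.loc[shared])
    return prevalence_filter([a, b], threshold)


@dataclass
class EnsembleModel:
    """Unweighted soft vote over one best model per tree-ensemble family."""

    members: dict[str, object]

    def __post_init__(self) -> None:
        if len(self.members) != 3 or set(self.members) != set(FAMILIES):
            raise ValueError("ensemble needs exactly one model per family")

    def predict_proba1(self, x: np.ndarray) -> np.ndarray:
        """Mean class-1 probability across the three members."""
        probs = [m.predict_proba(x)[:, 1] for m in self.members.values()]
        return np.mean(probs, axis=0)


@dataclass
class TransferReport:
    """One direction of the cross-study experiment."""

    direction: str
    per_iteration_auc: np.ndarray
    overall_auc: float  # AUC of all pooled predictions
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    pooled_sample_ids: list[str]
    ensembles: list[EnsembleModel]
    cv_result: NestedCVResult

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "overall_auc": float(self.overall_auc),
            "per_iteration_auc": [float(a) for a in self.per_iteration_auc],
        }


def _stratified_subsample(y: np.ndarray, frac: float, rng) -> np.ndarray:
    idx = []
    for cls in (0, 1):
        members = np.where(y == cls)[0]
        k = max(2, int(round(frac * len(members))))
        k = min(k, len(members))
        idx.append(rng.choice(members, size=k, replace=False))
    return np.sort(np.concatenate(idx))


def transfer_predict(train_features, train_meta: CohortMetadata,
                     test_features, test_meta: CohortMetadata,
                     specs: dict[str, LearnerSpec] | None = None,
                     outer_k: int = 5, inner_k: int = 3, n_repeats: int = 1,
                     subsample_frac: float = 0.8, seed: int = 0,
                     direction: str = "A->B") -> TransferReport:
    """Nested-CV-trained per-iteration ensembles predict the other cohort.

    ``train_features`` and ``test_features`` must already be harmonized
    (:func:`align_features`): same feature ids, same order. Per outer
    iteration, the three families' best models form an ensemble that scores
    a fresh stratified subsample (fraction ``subsample_frac``) of the test
    cohort; the overall AUC pools every prediction across iterations.
    """
    if train_features.feature_ids != test_features.feature_ids:
        raise TableError("train/test feature sets are not harmonized")
    cv = nested_cv_multi(train_features, train_meta, specs,
                         outer_k=outer_k, inner_k=inner_k,
                         n_repeats=n_repeats, seed=seed)
    x_test = test_features.data.to_numpy(dtype=float).T
    y_test = test_meta.exposure_for(test_features.sample_ids)
    sample_ids = np.array(test_features.sample_ids)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    ensembles, it_aucs = [], []
    scores_all, labels_all, ids_all = [], [], []
    for rec in cv.fold_records:
        ens = EnsembleModel(dict(rec.models))
        idx = _stratified_subsample(y_test, subsample_frac, rng)
        prob = ens.predict_proba1(x_test[idx])
        it_aucs.append(roc_auc(prob, y_test[idx]))
        ensembles.append(ens)
        scores_all.append(prob)
        labels_all.append(y_test[idx])
        ids_all.extend(sample_ids[idx])
    pooled_scores = np.concatenate(scores_all)
    pooled_labels = np.concatenate(labels_all)
    return TransferReport(
        direction=direction,
        per_iteration_auc=np.array(it_aucs),
        overall_auc=roc_auc(pooled_scores, pooled_labels),
        pooled_scores=pooled_scores,
        pooled_labels=pooled_labels,
        pooled_sample_ids=ids_all,
        ensembles=ensembles,
        cv_result=cv,
    )


def permutation_importance(ensembles, test_features, test_meta: CohortMetadata,
                           n_shuffles: int = 10, seed: int = 0) -> pd.DataFrame:
    """Per-feature mean +/- SD AUC reduction under value shuffling.

    For each fitted ensemble the baseline AUC on the full test cohort is
    computed once; then, one feature at a time, that feature's values are
    permuted across test samples (all others fixed) and the AUC drop
    baseline - shuffled is recorded, ``n_shuffles`` times per ensemble.
    """
    if n_shuffles < 5:
        raise ValueError("n_shuffles must be >= 5")
    if isinstance(ensembles, EnsembleModel):
        ensembles = [ensembles]
    x = test_features.data.to_numpy(dtype=float).T
    y = test_meta.exposure_for(test_features.sample_ids)
    rng = np.random.default_rng(seed)
    n, m = x.shape
    drops = np.zeros((len(ensembles) * n_shuffles, m))
    for e, ens in enumerate(ensembles):
        baseline = roc_auc(ens.predict_proba1(x), y)
        for j in range(m):
            # all shuffles of feature j scored in one stacked predict call
            stacked = np.tile(x, (n_shuffles, 1))
            for k in range(n_shuffles):
                stacked[k * n: (k + 1) * n, j] = rng.permutation(x[:, j])
            prob = ens.predict_proba1(stacked)
            for k in range(n_shuffles):
                drops[e * n_shuffles + k, j] = baseline - roc_auc(
                    prob[k * n: (k + 1) * n], y)
    return pd.DataFrame(
        {
            "mean_drop": drops.mean(axis=0),
            "sd": drops.std(axis=0, ddof=1) if drops.shape[0] > 1
                  else np.zeros(m),
        },
        index=test_features.feature_ids,
    ).sort_values("mean_drop", ascending=False)


def pooled_stratified_auc(scores, labels, strata) -> dict:
    """AUC within each stratum of the pooled predictions.

    Returns {stratum: auc or None}; a stratum with a single class is
    flagged (None), not computed. With exactly two computable strata the
    absolute AUC difference is included under ``"abs_difference"``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    strata = np.asarray(strata)
    out: dict = {}
    for s in pd.unique(strata):
        mask = strata == s
        if len(np.unique(labels[mask])) < 2:
            out[str(s)] = None
        else:
            out[str(s)] = roc_auc(scores[mask], labels[mask])
    computable = [v for v in out.values() if v is not None]
    if len(computable) == 2:
        out["abs_difference"] = abs(computable[0] - computable[1])
    return out
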