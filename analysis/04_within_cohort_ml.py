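"""Within-cohort nested-CV classification and importance rank aggregation.

Random forest, extremely randomized trees and AdaBoost are tuned in the
inner CV loop only and scored by ROC AUC on held-out outer folds, repeated
over fresh fold seeds; impurity importances from every best model are
rank-aggregated (median rank, 1 = most important). Repetition count here is
10 per cohort/representation (the library default is 40), a problem size
chosen to keep this driver quick; the rank table layout is identical.
"""

import json
import sys
from pathlib import Path

from gutcross.ml import LearnerSpec, aggregate_ranks, nested_cv_multi
from gutcross.tables import prevalence_filter, read_metadata, read_table, to_relative

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"
OUT = ROOT / "ml"
OUT.mkdir(parents=True, exist_ok=True)

N_REPEATS = int(sys.argv[1]) if len(sys.argv) > 1 else 10
GRIDS = {
    "random_forest": {"n_estimators": [100], "max_depth": [None, 8]},
    "extra_trees": {"n_estimators": [100], "max_depth": [None, 8]},
    "adaboost": {"n_estimators": [50], "learning_rate": [0.1, 1.0]},
}
specs = {f: LearnerSpec(f, g, seed=0) for f, g in GRIDS.items()}

report = {}
for name in ("dm", "pa"):
    meta = read_metadata(DATA / f"{name}_metadata.tsv")
    for rep in ("taxa", "pathways"):
        rel = to_relative(prevalence_filter(
            read_table(DATA / f"{name}_{rep}.tsv"), 0.10))
        cv = nested_cv_multi(rel, meta, specs, outer_k=5, inner_k=3,
                             n_repeats=N_REPEATS, seed=19)
        agg = aggregate_ranks(cv.importance_vectors(), rel.feature_ids)
        agg.median_rank.rename("median_rank").to_csv(
            OUT / f"ranks_{name}_{rep}.tsv", sep="\t")
        key = f"{name}_{rep}"
        report[key] = {
            f: {"mean_auc": cv.mean_auc(f), "sd": cv.sd_auc(f)}
            for f in cv.families
        }
        best = max(cv.families, key=cv.mean_auc)
        print(f"{key}: best {best} AUC {cv.mean_auc(best):.2f} "
              f"(SD {cv.sd_auc(best):.2f}); top features "
              f"{list(agg.median_rank.index[:3])} "
              f"({agg.n_fits} ranks per feature)")

(OUT / "ml.json").write_text(json.dumps(report, indent=1, sort_keys=True))
print(f"report written to {OUT / 'ml.json'}")
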