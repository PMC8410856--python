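"""Alpha and beta diversity of both cohorts.

Shannon diversity (rarefied to 1000 reads for taxa, 10000 for pathways) is
compared between exposure groups with Kruskal-Wallis; community structure is
tested with PERMANOVA on Bray-Curtis distances (two-factor sequential in the
DM cohort, whose metadata carries the antibiotics covariate) and ordinated
with PCoA plus per-group correlation ellipses.
"""

import json
from pathlib import Path

from gutcross.diversity import (
    alpha_diversity,
    bray_curtis,
    correlation_ellipse,
    kruskal_wallis,
    pcoa,
    permanova,
)
from gutcross.tables import min_depth_filter, rarefy, read_metadata, read_table

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"
OUT = ROOT / "diversity"
OUT.mkdir(parents=True, exist_ok=True)

report = {}
for name, depths in (("dm", (1000, 10000)), ("pa", (1000, 10000))):
    meta = read_metadata(DATA / f"{name}_metadata.tsv")
    for rep, depth in zip(("taxa", "pathways"), depths):
        table = min_depth_filter(read_table(DATA / f"{name}_{rep}.tsv"), 1000)
        rare = rarefy(table, depth, seed=11)
        sub = meta.subset(rare.sample_ids)
        y = sub.exposure_for(rare.sample_ids)

        alpha = alpha_diversity(rare)
        h, p_kw = kruskal_wallis(alpha.to_numpy(), y)

        dm_mat = bray_curtis(rare)
        design = {"exposure": y}
        cov = sub.covariate_for(rare.sample_ids)
        if cov is not None:
            design["covariate"] = cov
        perm = permanova(dm_mat, design, n_perm=999, seed=13)
        ordn = pcoa(dm_mat)
        ellipses = correlation_ellipse(ordn.coordinates.iloc[:, :2], y)
        ordn.coordinates.to_csv(OUT / f"pcoa_{name}_{rep}.tsv", sep="\t")

        key = f"{name}_{rep}"
        report[key] = {
            "kruskal": {"H": h, "p": p_kw},
            "permanova": perm.to_dict(),
            "pc1_var": float(ordn.proportion_explained[0]),
            "ellipse_r": {str(g): e.pearson_r for g, e in ellipses.items()},
        }
        r2 = perm.terms.loc["exposure", "R2"]
        p = perm.terms.loc["exposure", "p"]
        print(f"{key}: Shannon KW H={h:.2f} (p={p_kw:.3f}); "
              f"PERMANOVA exposure R2={r2:.4f}, Pr(>F)={p:.3f}")

(OUT / "diversity.json").write_text(json.dumps(report, indent=1, sort_keys=True))
print(f"report written to {OUT / 'diversity.json'}")
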