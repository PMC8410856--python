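"""Compositional differential abundance in both cohorts.

Features present in at least 10% of samples are tested with the ANCOM-style
W proportion (significant at W >= 0.7; covariate-adjusted in the DM cohort)
and the ALDEx-style CLR Monte-Carlo Welch test (significant at expected
q < 0.05; positive effect = more abundant in the exposed group). The focal
taxon's stratified share of the block pathways is reported per group.
"""

import sys
from pathlib import Path

from gutcross.diffabund import aldex_clr, ancom_w
from gutcross.simulate import derive_pathway_table, random_genome_content
from gutcross.tables import (
    prevalence_filter,
    read_metadata,
    read_table,
    taxon_attribution,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"
OUT = ROOT / "diffabund"
OUT.mkdir(parents=True, exist_ok=True)

for name, focal, adjust in (("dm", "G0001", True), ("pa", "G0002", False)):
    meta = read_metadata(DATA / f"{name}_metadata.tsv")
    for rep in ("taxa", "pathways"):
        table = prevalence_filter(read_table(DATA / f"{name}_{rep}.tsv"), 0.10)
        use_adjust = adjust and meta.covariate_for(table.sample_ids) is not None
        ancom = ancom_w(table, meta, covariate_adjust=use_adjust)
        aldex = aldex_clr(table, meta, n_mc=128, seed=17)
        merged = ancom.frame.join(aldex.frame, rsuffix="_aldex")
        merged.to_csv(OUT / f"{name}_{rep}.tsv", sep="\t")
        sig = ancom.significant_features()
        print(f"{name} {rep}: {len(sig)} ANCOM-significant features "
              f"(W >= 0.7): {sig[:6]}")
        if rep == "taxa" and focal in ancom.frame.index:
            w = ancom.frame.loc[focal, "w_proportion"]
            eff = aldex.frame.loc[focal, "effect"]
            print(f"  focal {focal}: W = {w:.2f}, ALDEx effect = {eff:+.2f} "
                  f"(negative = depleted in exposed)")

# stratified attribution: how much of each block pathway comes from the
# DM focal taxon, per exposure group
taxa = read_table(DATA / "dm_taxa.tsv")
meta = read_metadata(DATA / "dm_metadata.tsv")
# must match the seed given to 01_simulate_cohorts.py so the genome-content
# matrix is the one the saved pathway tables were mixed through
seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
gcm = random_genome_content(20, 60, focal_taxon_index=0, block=range(10),
                            seed=seed + 1)
_, strat = derive_pathway_table(taxa, gcm)
y = meta.exposure_for(taxa.sample_ids)
_, groups = taxon_attribution(strat, "G0001", exposure=y)
block_rows = groups.iloc[:10]
print("DM focal-taxon share of block pathways: "
      f"{block_rows['exposed_mean'].min():.0%}-"
      f"{block_rows['exposed_mean'].max():.0%} exposed, "
      f"{block_rows['control_mean'].min():.0%}-"
      f"{block_rows['control_mean'].max():.0%} control")
groups.to_csv(OUT / "dm_focal_attribution.tsv", sep="\t")
print(f"tables written to {OUT}")
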