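"""Generate the two synthetic study cohorts and write their tables.

Cohort DM emulates a delivery-mode cohort: 83 infants (23 exposed /
60 control) whose dominant Bacteroides-like genus falls from 58% to 36%
mean relative abundance in the exposed group, with an independent binary
perinatal-antibiotics covariate. Cohort PA emulates a perinatal-antibiotics
cohort: 97 infants (70 / 27) with the same kind of focal depletion carried
by a different taxon. Both cohorts share a 10-pathway block loaded on their
focal taxa, so the pathway signal is concordant across cohorts while the
taxon signal is not.
"""

import sys
from pathlib import Path

from gutcross.simulate import (
    SimulationConfig,
    derive_pathway_table,
    random_genome_content,
    simulate_paired_cohorts,
)
from gutcross.tables import to_relative, write_metadata, write_table

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

cfg_dm = SimulationConfig(n_exposed=23, n_control=60, seed=SEED,
                          covariate_rate=0.3, replacement_taxon_index=2,
                          sample_prefix="DM")
cfg_pa = SimulationConfig(n_exposed=70, n_control=27, seed=SEED + 1000,
                          focal_taxon_index=1, replacement_taxon_index=3,
                          sample_prefix="PA")
block = range(10)
gcm_dm = random_genome_content(20, 60, focal_taxon_index=0, block=block,
                               seed=SEED + 1)
gcm_pa = random_genome_content(20, 60, focal_taxon_index=1, block=block,
                               seed=SEED + 2)
dm, pa = simulate_paired_cohorts(cfg_dm, cfg_pa, gcm_dm, gcm_pa, block)

for name, bundle in (("dm", dm), ("pa", pa)):
    write_table(bundle.taxa, OUT / f"{name}_taxa.tsv")
    write_table(bundle.pathways, OUT / f"{name}_pathways.tsv")
    write_metadata(bundle.metadata, OUT / f"{name}_metadata.tsv")

for name, bundle, focal in (("DM", dm, 0), ("PA", pa, 1)):
    rel = to_relative(bundle.taxa)
    y = bundle.metadata.exposure_for(bundle.taxa.sample_ids)
    exp = rel.matrix[focal, y == 1].mean()
    ctl = rel.matrix[focal, y == 0].mean()
    print(f"{name}: {bundle.taxa.matrix.shape[1]} samples, focal taxon "
          f"G{focal + 1:04d} mean relative abundance "
          f"{exp:.1%} exposed vs {ctl:.1%} control")
print(f"tables written to {OUT}")
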