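import numpy as np
import pandas as pd
import pytest

from gutcross.simulate import (
    CohortBundle,
    ConfigError,
    GenomeContentMatrix,
    SimulationConfig,
    default_baseline,
    derive_pathway_table,
    focal_effect_for_target,
    random_genome_content,
    simulate_cohort,
    simulate_paired_cohorts,
)
from gutcross.tables import CountTable, to_relative


def group_focal_means(table, meta, focal=0):
    rel = to_relative(table)
    y = meta.exposure_for(table.sample_ids)
    return rel.matrix[focal, y == 1].mean(), rel.matrix[focal, y == 0].mean()


class TestSimulateCohort:
    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(n_exposed=10, n_control=10, seed=99)
        t1, m1 = simulate_cohort(cfg)
        t2, m2 = simulate_cohort(cfg)
        assert np.array_equal(t1.matrix, t2.matrix)
        assert m1.frame.equals(m2.frame)

    def test_shape_and_depths(self):
        cfg = SimulationConfig(n_exposed=12, n_control=18, seed=4,
                               depth_range=(1500, 4000))
        table, meta = simulate_cohort(cfg)
        assert table.matrix.shape == (cfg.n_taxa, 30)
        sums = table.sample_sums().to_numpy()
        assert (sums >= 1500).all() and (sums <= 4000).all()
        y = meta.exposure_for(table.sample_ids)
        assert (y == 1).sum() == 12 and (y == 0).sum() == 18

    def test_null_effect_groups_match(self):
        cfg = SimulationConfig(n_exposed=200, n_control=200,
                               focal_effect=1.0, seed=11)
        exp, ctl = group_focal_means(*simulate_cohort(cfg))
        assert abs(exp - ctl) < 0.03

    def test_bacteroides_like_contrast(self):
        # focal 58% baseline depleted to ~36% in the exposed group
        cfg = SimulationConfig(
            n_exposed=500, n_control=500, seed=12,
            focal_effect=focal_effect_for_target(0.58, 0.36))
        exp, ctl = group_focal_means(*simulate_cohort(cfg))
        assert abs(ctl - 0.58) < 0.05
        assert abs(exp - 0.36) < 0.05

    def test_concentration_limit_recovers_mean(self):
        base = default_baseline(10)
        cfg = SimulationConfig(n_exposed=1, n_control=19, n_taxa=10,
                               baseline_mean_relabund=base, focal_effect=1.0,
                               concentration=1e6, depth_range=(100000, 100000),
                               seed=13)
        table, _ = simulate_cohort(cfg)
        props = table.matrix / table.matrix.sum(axis=0)
        assert np.abs(props - base[:, None]).max() < 0.01

    def test_invalid_configs_rejected(self):
        bad = [
            dict(n_exposed=0, n_control=5),
            dict(n_exposed=5, n_control=5, focal_effect=-1.0),
            dict(n_exposed=5, n_control=5, concentration=0.0),
            dict(n_exposed=5, n_control=5, depth_range=(0, 10)),
            dict(n_exposed=5, n_control=5,
                 baseline_mean_relabund=np.full(20, 0.1)),
        ]
        for kwargs in bad:
            with pytest.raises(ConfigError):
                simulate_cohort(SimulationConfig(seed=0, **kwargs))

    def test_replacement_taxon_absorbs_lost_mass(self):
        cfg = SimulationConfig(n_exposed=400, n_control=400, seed=21,
                               replacement_taxon_index=2)
        table, meta = simulate_cohort(cfg)
        rel = to_relative(table)
        y = meta.exposure_for(table.sample_ids)
        gain = rel.matrix[2, y == 1].mean() - rel.matrix[2, y == 0].mean()
        loss = rel.matrix[0, y == 0].mean() - rel.matrix[0, y == 1].mean()
        assert gain > 0.1
        assert abs(gain - loss) < 0.04
        # other taxa keep their mean abundance
        others = np.delete(np.arange(cfg.n_taxa), [0, 2])
        diff = (rel.matrix[others][:, y == 1].mean(axis=1)
                - rel.matrix[others][:, y == 0].mean(axis=1))
        assert np.abs(diff).max() < 0.02


class TestDerivePathways:
    def test_identity_mixing(self, toy_table):
        gcm = GenomeContentMatrix(np.eye(3), toy_table.feature_ids,
                                  ["p1", "p2", "p3"])
        pwy, strat = derive_pathway_table(toy_table, gcm)
        assert np.array_equal(pwy.matrix, toy_table.matrix)
        assert np.allclose(strat.pathway_totals(), toy_table.matrix)

    def test_single_taxon_copy_number(self):
        table = CountTable(pd.DataFrame({"s": [10]}, index=["t"]))
        gcm = GenomeContentMatrix(np.array([[2.0]]), ["t"], ["p"])
        pwy, strat = derive_pathway_table(table, gcm)
        assert pwy.matrix[0, 0] == 20
        frac = strat.values[0, 0, 0] / strat.pathway_totals()[0, 0]
        assert frac == 1.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 30, size=(5, 1))
        contrib = rng.gamma(1.0, size=(5, 3))
        table = CountTable(pd.DataFrame(
            counts, index=[f"t{i}" for i in range(5)], columns=["s"]))
        gcm = GenomeContentMatrix(contrib, table.feature_ids,
                                  [f"p{j}" for j in range(3)])
        pwy, strat = derive_pathway_table(table, gcm)
        for p in range(3):
            total = sum(counts[t, 0] * contrib[t, p] for t in range(5))
            assert pwy.matrix[p, 0] == round(total)
            assert abs(strat.pathway_totals()[p, 0] - total) < 1e-9
            for t in range(5):
                assert strat.values[t, p, 0] == pytest.approx(
                    counts[t, 0] * contrib[t, p])

    def test_stratified_sums_reproduce_totals(self, planted_cohort):
        taxa, _ = planted_cohort
        gcm = random_genome_content(20, 30, block=range(5), seed=2)
        _, strat = derive_pathway_table(taxa, gcm)
        expected = gcm.contributions.T @ taxa.matrix.astype(float)
        rel_err = np.abs(strat.pathway_totals() - expected) / np.maximum(
            expected, 1e-12)
        assert rel_err.max() <= 1e-6

    def test_id_mismatch_rejected(self, toy_table):
        gcm = GenomeContentMatrix(np.eye(3), ["x", "y", "z"], ["p1", "p2", "p3"])
        with pytest.raises(Exception, match="ids"):
            derive_pathway_table(toy_table, gcm)

    def test_empty_pathway_column_rejected(self):
        with pytest.raises(ConfigError, match="contributing"):
            GenomeContentMatrix(np.array([[1.0, 0.0]]), ["t"], ["p1", "p2"])


class TestPairedCohorts:
    def _pair(self, seed, block, focal_b=1):
        ca = SimulationConfig(n_exposed=30, n_control=30, n_pathways=20,
                              seed=seed, replacement_taxon_index=2)
        cb = SimulationConfig(n_exposed=30, n_control=30, n_pathways=20,
                              focal_taxon_index=focal_b, seed=seed + 5000,
                              replacement_taxon_index=3)
        ga = random_genome_content(20, 20, focal_taxon_index=0, block=block,
                                   seed=seed + 1)
        gb = random_genome_content(20, 20, focal_taxon_index=focal_b,
                                   block=block, seed=seed + 2)
        return simulate_paired_cohorts(ca, cb, ga, gb, block)

    @staticmethod
    def _pathway_diffs(bundle: CohortBundle):
        rel = to_relative(bundle.pathways)
        y = bundle.metadata.exposure_for(bundle.pathways.sample_ids)
        return rel.matrix[:, y == 1].mean(axis=1) - \
            rel.matrix[:, y == 0].mean(axis=1)

    def test_identical_inputs_identical_cohorts(self):
        cfg = SimulationConfig(n_exposed=10, n_control=10, n_pathways=15,
                               seed=3)
        gcm = random_genome_content(20, 15, block=range(3), seed=4)
        a, b = simulate_paired_cohorts(cfg, cfg, gcm, gcm, range(3))
        assert np.array_equal(a.taxa.matrix, b.taxa.matrix)
        assert np.array_equal(a.pathways.matrix, b.pathways.matrix)

    def test_shared_block_concordant_signal(self):
        block = range(5)
        a, b = self._pair(seed=31, block=block)
        da, db = self._pathway_diffs(a), self._pathway_diffs(b)
        for p in block:
            assert np.sign(da[p]) == np.sign(db[p]) == -1.0

    def test_no_shared_block_signals_independent(self):
        # without a shared block, per-pathway signal directions in the two
        # cohorts agree at roughly chance rate
        concordant, total = 0, 0
        for seed in range(50):
            a, b = self._pair(seed=1000 + seed * 7, block=())
            da, db = self._pathway_diffs(a), self._pathway_diffs(b)
            concordant += (np.sign(da) == np.sign(db)).sum()
            total += len(da)
        rate = concordant / total
        assert 0.4 < rate < 0.6

    def test_block_out_of_range_rejected(self):
        cfg = SimulationConfig(n_exposed=5, n_control=5, n_pathways=10, seed=1)
        gcm = random_genome_content(20, 10, block=range(3), seed=1)
        with pytest.raises(ConfigError):
            simulate_paired_cohorts(cfg, cfg, gcm, gcm, [99])

    def test_focal_must_load_on_block(self):
        cfg = SimulationConfig(n_exposed=5, n_control=5, n_pathways=10, seed=1)
        gcm = random_genome_content(20, 10, focal_taxon_index=0,
                                    block=range(3), seed=1)
        contrib = gcm.contributions.copy()
        contrib[0, 0] = 0.0
        contrib[1, 0] = 1.0  # keep the column non-empty
        broken = GenomeContentMatrix(contrib, gcm.taxon_ids, gcm.pathway_ids)
        with pytest.raises(ConfigError, match="load"):
            simulate_paired_cohorts(cfg, cfg, broken, broken, range(3))
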