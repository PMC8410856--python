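import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from gutcross.diversity import (
    bray_curtis,
    correlation_ellipse,
    kruskal_wallis,
    pcoa,
    permanova,
    shannon,
)
from gutcross.tables import CountTable


def random_table(seed, shape=(10, 8)):
    rng = np.random.default_rng(seed)
    data = rng.integers(0, 40, size=shape)
    data[:, data.sum(axis=0) == 0] += 1
    return CountTable(pd.DataFrame(
        data, index=[f"f{i}" for i in range(shape[0])],
        columns=[f"s{j}" for j in range(shape[1])]))


class TestShannon:
    @pytest.mark.parametrize("counts,expected", [
        ((1, 1, 1, 1), 2.0),
        ((5, 0, 0), 0.0),
        ((2, 1, 1), 1.5),
    ])
    def test_known_values(self, counts, expected):
        assert shannon(np.array(counts)) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon(np.zeros(3))


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        table = CountTable(pd.DataFrame(
            {"a": [3, 1, 0], "b": [3, 1, 0], "c": [0, 0, 7]},
            index=["f1", "f2", "f3"]))
        dm = bray_curtis(table)
        assert dm["a", "b"] == 0.0
        assert dm["a", "c"] == 1.0

    def test_hand_example(self):
        table = CountTable(pd.DataFrame(
            {"x": [2, 0, 1], "y": [1, 1, 0]}, index=["f1", "f2", "f3"]))
        assert bray_curtis(table)["x", "y"] == pytest.approx(0.6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        table = random_table(seed)
        dm = bray_curtis(table)
        mat = table.matrix.astype(float)
        for i, j in itertools.combinations(range(mat.shape[1]), 2):
            x, y = mat[:, i], mat[:, j]
            expected = np.abs(x - y).sum() / (x + y).sum()
            assert abs(dm[table.sample_ids[i], table.sample_ids[j]]
                       - expected) <= 1e-12


class TestPcoa:
    def test_points_on_a_line(self):
        pts = np.array([0.0, 1.0, 3.0, 7.0])
        d = np.abs(pts[:, None] - pts[None, :])
        res = pcoa(DistanceMatrix(d, ids=list("abcd")))
        assert len(res.eigenvalues) == 1
        c = res.coordinates["PC1"].to_numpy()
        assert np.allclose(np.abs(c[:, None] - c[None, :]), d, atol=1e-10)

    def test_euclidean_reconstruction(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(9, 4))
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(d, ids=[f"s{i}" for i in range(9)]))
        rec = squareform(pdist(res.coordinates.to_numpy()))
        assert np.abs(rec - d).max() < 1e-8

    def test_duplicated_sample_same_coordinates(self):
        table = CountTable(pd.DataFrame(
            {"a": [5, 1, 2], "a2": [5, 1, 2], "b": [0, 4, 4], "c": [1, 1, 9]},
            index=["f1", "f2", "f3"]))
        res = pcoa(bray_curtis(table))
        assert np.allclose(res.coordinates.loc["a"], res.coordinates.loc["a2"],
                           atol=1e-10)

    def test_structure_and_skbio_agreement(self):
        table = random_table(11)
        dm = bray_curtis(table)
        res = pcoa(dm)
        assert np.all(np.diff(res.proportion_explained) <= 1e-12)
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-9)
        sk = skbio_pcoa(dm, number_of_dimensions=2)
        mine = res.coordinates.to_numpy()[:, :2]
        theirs = sk.samples.to_numpy()[:, :2]
        for k in range(2):  # eigenvector sign is arbitrary
            assert min(np.abs(mine[:, k] - theirs[:, k]).max(),
                       np.abs(mine[:, k] + theirs[:, k]).max()) < 1e-8


class TestCorrelationEllipse:
    def test_isotropic_cloud_round(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(500, 2))
        coords = pd.DataFrame(pts, columns=["PC1", "PC2"])
        e = correlation_ellipse(coords, np.zeros(500, dtype=int))[0]
        assert e.semi_major / e.semi_minor < 1.2
        assert abs(e.pearson_r) < 0.15
        assert not e.degenerate

    def test_perfect_correlation_degenerate(self):
        x = np.linspace(0, 1, 30)
        coords = pd.DataFrame({"PC1": x, "PC2": 2 * x})
        e = correlation_ellipse(coords, np.zeros(30, dtype=int))[0]
        assert e.degenerate
        assert e.semi_minor == pytest.approx(0.0, abs=1e-6)

    def test_matches_closed_form_covariance(self):
        rng = np.random.default_rng(8)
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        pts = rng.multivariate_normal([0, 0], cov, size=200)
        coords = pd.DataFrame(pts, columns=["PC1", "PC2"])
        e = correlation_ellipse(coords, np.zeros(200, dtype=int))[0]
        sample_cov = np.cov(pts, rowvar=False)
        evals = np.linalg.eigvalsh(sample_cov)
        assert e.semi_major == pytest.approx(2 * math.sqrt(evals[1]))
        assert e.semi_minor == pytest.approx(2 * math.sqrt(evals[0]))
        r = sample_cov[0, 1] / math.sqrt(sample_cov[0, 0] * sample_cov[1, 1])
        assert e.pearson_r == pytest.approx(r)

    def test_small_group_rejected(self):
        coords = pd.DataFrame({"PC1": [0, 1], "PC2": [0, 1]})
        with pytest.raises(ValueError):
            correlation_ellipse(coords, [0, 0])


class TestKruskalWallis:
    def test_hand_computed_example(self):
        h, p = kruskal_wallis([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
        assert h == pytest.approx(3.857, abs=1e-3)

    def test_all_equal(self):
        h, _ = kruskal_wallis([2.0] * 6, [0, 0, 0, 1, 1, 1])
        assert h == 0.0

    def test_monotone_invariance(self):
        vals = np.array([0.3, 1.2, 0.7, 2.5, 3.1, 2.9])
        groups = [0, 0, 0, 1, 1, 1]
        h1, p1 = kruskal_wallis(vals, groups)
        h2, p2 = kruskal_wallis(np.exp(vals), groups)
        assert h1 == pytest.approx(h2)
        assert p1 == pytest.approx(p2)


def one_way_pseudo_f(d, labels):
    """Independent one-way pseudo-F from the group-sum formulation."""
    n = len(labels)
    labels = np.asarray(labels)
    d2 = d ** 2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.where(labels == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    a = len(np.unique(labels))
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def test_two_clean_clusters(self):
        d = np.zeros((6, 6))
        d[:3, 3:] = 0.9
        d[3:, :3] = 0.9
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])
        res = permanova(dm, {"exposure": [1, 1, 1, 0, 0, 0]},
                        permutations="exact")
        assert res.terms.loc["exposure", "R2"] == pytest.approx(1.0)
        # minimum attainable exact p: the 3|3 split has 20 label arrangements
        assert res.terms.loc["exposure", "p"] == pytest.approx(
            math.factorial(3) ** 2 * 2 / math.factorial(6))

    def test_matches_vegan_adonis2_sequential(self):
        # frozen oracle: vegan::adonis2(d ~ exposure + covariate, by="terms")
        # on this exact table printed F = 0.27387 / 2.17335 and
        # R2 = 0.023924510501 / 0.189858384124 (residual 0.786217105375)
        rng = np.random.default_rng(42)
        counts = rng.poisson(20, size=(12, 8)).astype(float)
        d = squareform(pdist(counts, "braycurtis"))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(12)])
        res = permanova(
            dm,
            {"exposure": [1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0],
             "covariate": [1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0]},
            n_perm=999, seed=0)
        assert res.terms.loc["exposure", "F"] == pytest.approx(0.27387, abs=5e-6)
        assert res.terms.loc["covariate", "F"] == pytest.approx(2.17335, abs=5e-6)
        assert res.terms.loc["exposure", "R2"] == pytest.approx(0.023924510501)
        assert res.terms.loc["covariate", "R2"] == pytest.approx(0.189858384124)
        assert res.residual_r2 == pytest.approx(0.786217105375)
        assert res.terms["R2"].sum() + res.residual_r2 == pytest.approx(1.0)

    def test_one_way_f_matches_skbio(self):
        table = random_table(17, shape=(12, 10))
        dm = bray_curtis(table)
        labels = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        res = permanova(dm, {"exposure": labels}, n_perm=99, seed=0)
        sk = skbio_permanova(dm, grouping=[str(v) for v in labels],
                             permutations=99)
        assert res.terms.loc["exposure", "F"] == pytest.approx(
            sk["test statistic"])

    def test_exact_enumeration_matches_brute_force(self):
        rng = np.random.default_rng(23)
        pts = rng.normal(size=(6, 3))
        d = squareform(pdist(pts))
        labels = np.array([1, 1, 1, 0, 0, 0])
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])
        res = permanova(dm, {"exposure": labels}, permutations="exact")
        f_obs = one_way_pseudo_f(d, labels)
        assert res.terms.loc["exposure", "F"] == pytest.approx(f_obs)
        count = 0
        total = 0
        for perm in itertools.permutations(range(6)):
            f_p = one_way_pseudo_f(d, labels[list(perm)])
            count += f_p >= f_obs - 1e-12
            total += 1
        assert res.terms.loc["exposure", "p"] == pytest.approx(count / total)

    def test_relabel_invariance_and_reproducibility(self):
        table = random_table(29, shape=(12, 10))
        dm = bray_curtis(table)
        labels = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        r1 = permanova(dm, {"g": labels}, n_perm=199, seed=5)
        r2 = permanova(dm, {"g": 1 - labels}, n_perm=199, seed=5)
        assert r1.terms.loc["g", "R2"] == pytest.approx(r2.terms.loc["g", "R2"])
        r3 = permanova(dm, {"g": labels}, n_perm=199, seed=5)
        assert r1.terms.loc["g", "p"] == r3.terms.loc["g", "p"]

    def test_constant_factor_rejected(self):
        table = random_table(31, shape=(5, 6))
        dm = bray_curtis(table)
        with pytest.raises(ValueError, match="constant"):
            permanova(dm, {"g": [1, 1, 1, 1, 1, 1]}, n_perm=99)
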