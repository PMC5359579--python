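import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import phyloecol as pe
from conftest import make_random_tree, make_star
from oracles import permanova_f, unifrac_bruteforce


def table_from(counts, columns, sites=None):
    sites = sites or [f"s{i + 1}" for i in range(len(counts))]
    return pe.OtuTable(pd.DataFrame(counts, index=sites, columns=columns))


class TestWeightedUnifrac:
    def test_identical_profiles_zero(self, tiny_tree):
        t = table_from([[2, 4, 6], [1, 2, 3]], ["A", "B", "C"])
        dm = pe.weighted_unifrac(t, tiny_tree)
        assert dm["s1", "s2"] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_star_communities(self):
        star = make_star(4)
        t = table_from([[1, 1, 0, 0], [0, 0, 1, 1]],
                       ["T1", "T2", "T3", "T4"])
        norm = pe.weighted_unifrac(t, star, normalized=True)
        raw = pe.weighted_unifrac(t, star, normalized=False)
        assert norm["s1", "s2"] == pytest.approx(1.0)
        assert raw["s1", "s2"] == pytest.approx(2.0)

    def test_otu_missing_from_tree_errors(self, tiny_tree):
        t = table_from([[1, 1], [1, 1]], ["A", "ZZ"])
        with pytest.raises(KeyError, match="ZZ"):
            pe.weighted_unifrac(t, tiny_tree)

    def test_empty_site_excluded_with_warning(self, tiny_tree):
        t = table_from([[1, 1, 1], [0, 0, 0]], ["A", "B", "C"])
        with pytest.warns(UserWarning, match="empty"):
            dm = pe.weighted_unifrac(t, tiny_tree)
        assert list(dm.ids) == ["s1"]

    @pytest.mark.parametrize("normalized", [True, False])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_branch_enumeration_oracle(self, seed, normalized):
        rng = np.random.default_rng(200 + seed)
        tree = make_random_tree(rng, 10)
        names = sorted(t.name for t in tree.tips())
        counts = rng.integers(0, 30, size=(4, 10))
        counts[:, 0] += 1  # no empty site
        t = table_from(counts, names)
        dm = pe.weighted_unifrac(t, tree, normalized=normalized)
        for i, j in itertools.combinations(range(4), 2):
            expect = unifrac_bruteforce(
                tree, dict(zip(names, counts[i])), dict(zip(names, counts[j])),
                normalized=normalized)
            assert dm[f"s{i + 1}", f"s{j + 1}"] == pytest.approx(
                expect, abs=1e-10)

    def test_normalized_bounded_and_metric_axioms(self, default_dataset):
        _, tree, _, _, table = default_dataset
        dm = pe.weighted_unifrac(table, tree)
        d = dm.data
        assert d.min() >= 0 and d.max() <= 1 + 1e-12
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_agrees_with_skbio_reference(self):
        # independent cross-check against the scikit-bio implementation
        from skbio.diversity import beta_diversity
        rng = np.random.default_rng(42)
        tree = make_random_tree(rng, 8)
        names = sorted(t.name for t in tree.tips())
        counts = rng.integers(0, 20, size=(3, 8)) + 1
        t = table_from(counts, names)
        ours = pe.weighted_unifrac(t, tree, normalized=False)
        ref = beta_diversity("weighted_unifrac", counts, ids=t.sites,
                             taxa=names, tree=tree, normalized=False)
        assert np.allclose(ours.data, ref.data, atol=1e-10)


class TestPcoa:
    def test_two_sites_forced_geometry(self):
        res = pe.pcoa(np.array([[0.0, 0.8], [0.8, 0.0]]))
        assert res.coords.shape[1] == 1
        assert sorted(res.coords["PC1"]) == pytest.approx([-0.4, 0.4])
        assert res.explained[0] == pytest.approx(1.0)

    def test_three_collinear_points_one_axis(self):
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = pe.pcoa(D)
        assert res.explained[0] == pytest.approx(1.0, abs=1e-12)
        assert res.coords.shape[1] == 1

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(9, 2))
        D = squareform(pdist(pts))
        res = pe.pcoa(D)
        assert res.explained[:2].sum() == pytest.approx(1.0, abs=1e-9)
        back = squareform(pdist(res.coords.to_numpy()[:, :2]))
        assert np.allclose(back, D, atol=1e-9)
        assert res.negative_mass == pytest.approx(0.0, abs=1e-9)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            pe.pcoa(np.array([[0.0, 1.0], [0.5, 0.0]]))


class TestPermanova:
    def block_distance(self):
        # two tight groups of 2 at distance 1
        D = np.ones((4, 4)) - np.eye(4)
        D[0, 1] = D[1, 0] = 0.05
        D[2, 3] = D[3, 2] = 0.05
        return D

    def test_single_group_error(self):
        labels = pd.Series(["a"] * 4, index=list("wxyz"))
        with pytest.raises(ValueError):
            pe.permanova(self.block_distance(), labels)

    def test_exhaustive_label_enumeration_oracle(self):
        D = self.block_distance()
        labels = pd.Series(["g1", "g1", "g2", "g2"], index=list("wxyz"))
        res = pe.permanova(D, labels, n_perm=999, seed=0)
        f_obs = res.table.loc["factor", "pseudo_F"] if "factor" in res.table.index \
            else res.table.iloc[0]["pseudo_F"]
        # oracle: enumerate all 24 orderings; distinct 2+2 labelings
        fs = []
        for perm in itertools.permutations(range(4)):
            lab = np.array(["g1", "g1", "g2", "g2"])[list(perm)]
            fs.append(permanova_f(D, lab))
        fs = np.array(fs)
        assert f_obs == pytest.approx(permanova_f(D, labels.to_numpy()),
                                      rel=1e-6)
        assert f_obs == pytest.approx(fs.max(), rel=1e-6)  # true labeling maximal
        p_exact = fs[fs >= f_obs - 1e-9].size / fs.size   # = 1/3
        assert p_exact == pytest.approx(1 / 3)
        assert res.table.iloc[0]["p"] == pytest.approx(p_exact, abs=0.05)

    def test_r2_plus_residual_is_one(self, default_dataset):
        _, tree, _, metadata, table = default_dataset
        dm = pe.weighted_unifrac(table, tree)
        res = pe.permanova(dm, metadata.habitat.reindex(list(dm.ids)),
                           n_perm=99, seed=1)
        assert res.table["R2"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_skbio_pseudo_f(self):
        # independent cross-check on the categorical path
        from skbio.stats.distance import permanova as skbio_permanova
        from skbio import DistanceMatrix
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(10, 3))
        D = squareform(pdist(pts))
        ids = [f"s{i}" for i in range(10)]
        labels = pd.Series(["a"] * 5 + ["b"] * 5, index=ids)
        ours = pe.permanova(D, labels, n_perm=99, seed=2)
        ref = skbio_permanova(DistanceMatrix(D, ids), labels.to_numpy(),
                              permutations=99)
        assert ours.table.iloc[0]["pseudo_F"] == pytest.approx(
            ref["test statistic"], rel=1e-9)

    def test_numeric_covariate_and_sequential_mode(self):
        rng = np.random.default_rng(13)
        x = pd.Series(rng.normal(size=12), index=[f"s{i}" for i in range(12)],
                      name="salinity")
        pts = x.to_numpy()[:, None] + rng.normal(scale=0.3, size=(12, 1))
        D = squareform(pdist(pts))
        covs = pd.DataFrame({"salinity": x,
                             "noise": rng.normal(size=12)}, index=x.index)
        res = pe.permanova(D, covs, n_perm=199, seed=3, mode="sequential")
        assert res.table.loc["salinity", "p"] <= 0.05
        assert res.table.loc["salinity", "R2"] > res.table.loc["noise", "R2"]
        total = res.table["SS"].sum()
        assert total == pytest.approx(res.table["SS"].sum(), rel=1e-9)

    def test_invalid_n_perm(self):
        labels = pd.Series(["a", "a", "b", "b"], index=list("wxyz"))
        with pytest.raises(ValueError):
            pe.permanova(self.block_distance(), labels, n_perm=0)
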