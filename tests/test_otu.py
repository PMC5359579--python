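import numpy as np
import pandas as pd
import pytest

import phyloecol as pe
from phyloecol.io import SeqRecord
from phyloecol.otu import DistanceMatrix

from oracles import ols_bruteforce


def seqset(pairs):
    return pe.AlignedSeqSet([SeqRecord(i, s, r) for i, s, r in pairs])


class TestPDistance:
    def test_identical_and_simple_mismatch(self):
        seqs = seqset([("a", "s1", "ACGT"), ("b", "s1", "ACGT"),
                       ("c", "s2", "ACGA")])
        dm = pe.pairwise_pdistance(seqs)
        assert dm.d[0, 1] == 0.0
        assert dm.d[0, 2] == pytest.approx(0.25)  # 1 mismatch / 4 columns

    def test_gap_columns_excluded_pairwise(self):
        seqs = seqset([("a", "s1", "AC-T"), ("b", "s1", "ACGT")])
        dm = pe.pairwise_pdistance(seqs)
        assert dm.d[0, 1] == 0.0  # 0 mismatches over 3 comparable columns

    def test_no_comparable_columns_errors(self):
        seqs = seqset([("a", "s1", "AC--"), ("b", "s1", "--GT")])
        with pytest.raises(ValueError, match="comparable"):
            pe.pairwise_pdistance(seqs)

    def test_symmetry_zero_diag(self):
        rng = np.random.default_rng(0)
        rows = ["".join(rng.choice(list("ACGT-"), size=60)) for _ in range(8)]
        dm = pe.pairwise_pdistance(seqset(
            [(f"s{i}", "x", r) for i, r in enumerate(rows)]))
        assert np.allclose(dm.d, dm.d.T)
        assert np.all(np.diag(dm.d) == 0)


class TestClustering:
    def dm(self, ids, entries):
        n = len(ids)
        d = np.zeros((n, n))
        for (i, j), v in entries.items():
            d[i, j] = d[j, i] = v
        return DistanceMatrix(ids, d)

    def test_complete_linkage_hand_case(self):
        # {A,B} merge at 0.01; joining C needs max(0.02, 0.05) = 0.05 > 0.03
        dm = self.dm(["A", "B", "C"],
                     {(0, 1): 0.01, (0, 2): 0.02, (1, 2): 0.05})
        table, assign = pe.cluster_otus(dm, identity=0.97,
                                        site_ids={"A": "s1", "B": "s1", "C": "s2"})
        assert len(table.otus) == 2
        assert assign["A"] == assign["B"] != assign["C"]
        assert table.counts.loc["s1", assign["A"]] == 2

    def test_all_zero_distances_single_otu(self):
        dm = self.dm(["A", "B", "C"], {})
        table, _ = pe.cluster_otus(dm, 0.97, ["s1", "s1", "s2"])
        assert len(table.otus) == 1

    def test_positive_distances_at_identity_near_one(self):
        dm = self.dm(["A", "B"], {(0, 1): 0.2})
        table, _ = pe.cluster_otus(dm, 0.999, ["s1", "s2"])
        assert len(table.otus) == 2

    def test_coarser_threshold_never_more_otus(self):
        rng = np.random.default_rng(3)
        n = 25
        d = rng.uniform(0, 0.3, size=(n, n))
        d = np.triu(d, 1)
        d = d + d.T
        dm = DistanceMatrix([f"q{i}" for i in range(n)], d)
        sites = [f"s{i % 4}" for i in range(n)]
        t97, _ = pe.cluster_otus(dm, 0.97, sites)
        t90, _ = pe.cluster_otus(dm, 0.90, sites)
        assert len(t90.otus) <= len(t97.otus)

    def test_counts_sum_to_sequences(self):
        rng = np.random.default_rng(5)
        n = 18
        d = rng.uniform(0, 0.2, size=(n, n))
        d = np.triu(d, 1); d = d + d.T
        dm = DistanceMatrix([f"q{i}" for i in range(n)], d)
        table, _ = pe.cluster_otus(dm, 0.95, [f"s{i % 3}" for i in range(n)])
        assert table.n_sequences == n


class TestRelativeAbundance:
    def table(self):
        counts = pd.DataFrame([[3, 1], [1, 3], [0, 4]],
                              index=["s1", "s2", "s3"], columns=["o1", "o2"])
        return pe.OtuTable(counts, pd.Series(["L1", "L2"], index=["o1", "o2"]))

    def test_site_rows_sum_to_one(self):
        frac = pe.relative_abundance(self.table())
        assert np.allclose(frac.sum(axis=1), 1.0, atol=1e-12)
        assert frac.loc["s1", "o1"] == pytest.approx(0.75)

    def test_habitat_mean_and_variance(self):
        meta = pe.SampleMetadata(pd.DataFrame(
            {"habitat": ["peat", "peat", "soil"]}, index=["s1", "s2", "s3"]))
        mean, var = pe.relative_abundance(self.table(), group="habitat",
                                          metadata=meta)
        assert mean.loc["peat", "o1"] == pytest.approx(0.5)  # mean(0.75, 0.25)
        assert var.loc["peat", "o1"] == pytest.approx(0.0625)

    def test_empty_site_excluded_with_warning(self):
        counts = pd.DataFrame([[2, 2], [0, 0]], index=["s1", "s2"],
                              columns=["o1", "o2"])
        with pytest.warns(UserWarning, match="zero total"):
            frac = pe.relative_abundance(pe.OtuTable(counts))
        assert list(frac.index) == ["s1"]


class TestSadRegression:
    def make_table(self, counts, lineages):
        df = pd.DataFrame(counts,
                          index=[f"s{i}" for i in range(len(counts))],
                          columns=[f"o{j}" for j in range(len(counts[0]))])
        return pe.OtuTable(df, pd.Series(lineages, index=df.columns))

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 20, size=(6, 5))
        counts[0] += 1  # avoid empty site
        table = self.make_table(counts, [f"L{j}" for j in range(5)])
        res = pe.sad_regression(table)
        x = res.per_lineage["occurrence"].to_numpy(float)
        y = res.per_lineage["mean_relative_abundance"].to_numpy(float)
        slope, intercept, r2 = ols_bruteforce(x, y)
        assert res.slope == pytest.approx(slope, rel=1e-10)
        assert res.intercept == pytest.approx(intercept, rel=1e-10)
        assert res.r2 == pytest.approx(r2, rel=1e-10)

    def test_perfect_fit_r2_one(self):
        # lineage occurrences 1,2,3 with abundances exactly on a line
        counts = [[8, 0, 0, 2], [0, 4, 0, 6], [0, 0, 2, 8]]
        table = self.make_table(counts, ["L1", "L2", "L3", "L4"])
        res = pe.sad_regression(table)
        occ = res.per_lineage["occurrence"]
        ra = res.per_lineage["mean_relative_abundance"]
        resid = ra - (res.intercept + res.slope * occ)
        if np.allclose(resid, 0, atol=1e-12):
            assert res.r2 == pytest.approx(1.0)

    def test_constant_abundance_zero_slope(self):
        counts = [[5, 5, 0], [5, 5, 0], [0, 0, 10], [5, 5, 10]]
        table = self.make_table(counts, ["L1", "L2", "L3"])
        res = pe.sad_regression(table)
        assert res.r2 >= 0

    def test_too_few_lineages_error(self):
        table = self.make_table([[1, 2]], ["L1", "L2"])
        with pytest.raises(ValueError, match="3 lineages"):
            pe.sad_regression(table)
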