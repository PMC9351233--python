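"""Coverage processing: destrand, filter, normalize, unite, classify."""

import warnings

import numpy as np
import pandas as pd
import pytest

import dmlpipe.methylation as me
from dmlpipe.methylation import MethylMatrix
from dmlpipe.snps import SnpSet


def records(rows):
    """rows: (chrom, pos, strand, meth, unmeth)."""
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand",
                                       "count_meth", "count_unmeth"])


def matrix_from(loci_rows, meth, unmeth, treatments=None, stages=None):
    meth = np.asarray(meth)
    n_s = meth.shape[1]
    treatments = treatments or ["low_pH"] * (n_s // 2) + ["ambient"] * (
        n_s - n_s // 2)
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n_s)],
        "treatment": treatments,
        "stage": stages or list(range(n_s))})
    loci = pd.DataFrame(loci_rows, columns=["chrom", "pos"])
    return MethylMatrix(loci, samples, meth.astype(np.int64),
                        np.asarray(unmeth).astype(np.int64))


class TestDestrand:
    def test_strand_pair_summed_at_plus_position(self):
        out = me.destrand(records([("c", 5, "+", 3, 2), ("c", 6, "-", 1, 4)]))
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["pos"], row["count_meth"], row["count_unmeth"]) == (5, 4, 6)

    def test_plus_only_unchanged(self):
        out = me.destrand(records([("c", 5, "+", 3, 2)]))
        assert out.iloc[0]["pos"] == 5 and out.iloc[0]["count_meth"] == 3

    def test_orphan_minus_reported_at_cpg_start(self):
        out = me.destrand(records([("c", 6, "-", 1, 4)]))
        assert out.iloc[0]["pos"] == 5

    def test_requires_strand(self):
        with pytest.raises(ValueError):
            me.destrand(records([("c", 5, "+", 1, 1)]).drop(columns="strand"))


class TestFilterCoverage:
    def test_low_coverage_voided_per_sample(self):
        m = matrix_from([("c", 1), ("c", 3)],
                        meth=[[2, 5], [5, 5]], unmeth=[[2, 5], [5, 5]])
        out = me.filter_coverage(m, lo=5)
        assert out.coverage[0, 0] == 0       # coverage 4 dropped there
        assert out.coverage[0, 1] == 10      # untouched elsewhere

    def test_extreme_outlier_above_percentile_dropped(self):
        n = 1000
        meth = np.full((n, 2), 5)
        meth[0, 0] = 50  # 10x the rest in sample 0
        m = matrix_from([("c", i + 1) for i in range(n)], meth, meth)
        out = me.filter_coverage(m, lo=5, high_percentile=99.9)
        assert out.coverage[0, 0] == 0
        assert (out.coverage[1:, :] == 10).all()

    def test_uniform_coverage_untouched(self):
        m = matrix_from([("c", i + 1) for i in range(10)],
                        np.full((10, 2), 3), np.full((10, 2), 2))
        out = me.filter_coverage(m, lo=5)
        assert (out.coverage == 5).all()


class TestNormalizeCoverage:
    def test_scales_to_median_of_medians(self):
        # sample medians 10 and 20 -> factors 1.5 and 0.75;
        # a (10,10) cell in sample 1 becomes (8,8) (round half away)
        meth = np.array([[5, 10]] * 5)
        unmeth = np.array([[5, 10]] * 5)
        m = matrix_from([("c", i + 1) for i in range(5)], meth, unmeth)
        out = me.normalize_coverage(m)
        assert (out.meth[:, 1] == 8).all() and (out.unmeth[:, 1] == 8).all()
        # sample 0 scaled up: 5 * 1.5 = 7.5 -> 8
        assert (out.meth[:, 0] == 8).all()

    def test_identical_medians_identity(self):
        meth = np.array([[3, 3], [4, 4], [5, 5]])
        m = matrix_from([("c", 1), ("c", 2), ("c", 3)], meth, meth)
        out = me.normalize_coverage(m)
        assert (out.meth == meth).all() and (out.unmeth == meth).all()

    def test_coverage_floored_at_one(self):
        meth = np.array([[0, 0], [0, 0], [1, 30]])
        unmeth = np.array([[1, 30], [1, 30], [0, 0]])
        m = matrix_from([("c", 1), ("c", 2), ("c", 3)], meth, unmeth)
        out = me.normalize_coverage(m)
        assert (out.coverage[out.coverage > 0] >= 1).all()
        assert (m.coverage > 0).sum() == (out.coverage > 0).sum()

    def test_zero_median_errors(self):
        m = matrix_from([("c", 1)], [[0, 5]], [[0, 5]])
        with pytest.raises(ValueError):
            me.normalize_coverage(m)


class TestUnite:
    def test_locus_missing_in_one_sample_dropped(self):
        meth = np.array([[5, 5, 5, 5, 5, 5, 5, 0],
                         [5, 5, 5, 5, 5, 5, 5, 5]])
        m = matrix_from([("c", 1), ("c", 2)], meth, meth)
        out = me.unite(m, min_cov=5)
        assert list(out.loci["pos"]) == [2]

    def test_empty_intersection_warns(self):
        m = matrix_from([("c", 1)], [[1, 1]], [[1, 1]])
        with pytest.warns(UserWarning, match="empty"):
            out = me.unite(m, min_cov=5)
        assert len(out.loci) == 0


class TestSnpExclusion:
    def test_either_strand_position_excludes(self):
        m = matrix_from([("c", 10), ("c", 20), ("c", 30)],
                        np.full((3, 2), 5), np.full((3, 2), 5))
        # SNP at the minus-strand C (pos 21) of the destranded locus 20
        s = SnpSet(pd.DataFrame({"chrom": ["c", "c"], "pos": [10, 21],
                                 "genotype": ["hom_CT", "hom_CT"]}))
        out, removed = me.apply_snp_exclusion(m, s)
        assert removed == 2 and list(out.loci["pos"]) == [30]

    def test_empty_set_identity_and_full_set_empties(self):
        m = matrix_from([("c", 10)], [[5, 5]], [[5, 5]])
        out, removed = me.apply_snp_exclusion(
            m, SnpSet(pd.DataFrame(columns=["chrom", "pos", "genotype"])))
        assert removed == 0 and len(out.loci) == 1
        s = SnpSet(pd.DataFrame({"chrom": ["c"], "pos": [10],
                                 "genotype": ["hom_CT"]}))
        out, removed = me.apply_snp_exclusion(m, s)
        assert removed == 1 and len(out.loci) == 0


class TestClassification:
    def test_boundaries(self):
        # 50.0% -> high (>=), 10.0% -> low (<=), 10.1% -> moderate
        pct = np.array([50.0, 10.0, 10.1, 49.9, 0.0, 100.0])
        assert list(me.classify_percent(pct)) == [
            "high", "low", "moderate", "moderate", "low", "high"]

    def test_all_zero_matrix_is_all_low(self):
        m = matrix_from([("c", 1), ("c", 2)], np.zeros((2, 2)),
                        np.full((2, 2), 10))
        per_locus, summary = me.classify_loci(m)
        assert (per_locus["meth_class"] == "low").all()
        assert summary.set_index("meth_class").loc["low", "percent"] == 100.0

    def test_counts_sum_to_locus_count(self, small_dataset):
        from dmlpipe import destrand, build_matrix, unite
        des = {sid: destrand(t) for sid, t in small_dataset["counts"].items()}
        mat = unite(build_matrix(des, small_dataset["samples"]), 5)
        _, summary = me.classify_loci(mat)
        assert summary["count"].sum() == len(mat.loci)

    def test_weighted_vs_unweighted_pooling(self):
        # one deep unmethylated sample dominates the weighted pool only
        m = matrix_from([("c", 1)], [[90, 0]], [[10, 900]])
        assert me.classify_loci(m, weighted=True)[0]["percent"][0] == \
            pytest.approx(9.0)
        assert me.classify_loci(m, weighted=False)[0]["percent"][0] == \
            pytest.approx(45.0)


class TestCorrelationsAndPca:
    def test_duplicated_sample_correlates_perfectly(self):
        rng = np.random.default_rng(0)
        meth = rng.integers(0, 10, (50, 1))
        meth = np.hstack([meth, meth, rng.integers(0, 10, (50, 1))])
        unmeth = np.full((50, 3), 10) - meth
        m = matrix_from([("c", i + 1) for i in range(50)], meth, unmeth,
                        treatments=["low_pH", "low_pH", "ambient"])
        corr = me.sample_correlations(m)
        assert corr.iloc[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(corr), 1.0)

    def test_pc1_separates_offset_groups(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.3, 0.4, 100)
        meth = np.empty((100, 8), dtype=np.int64)
        for j in range(8):
            p = base + (0.5 if j < 4 else 0.0)
            meth[:, j] = rng.binomial(100, p)
        m = matrix_from([("c", i + 1) for i in range(100)], meth,
                        100 - meth)
        scores, evr = me.sample_pca(m)
        pc1 = scores["PC1"].to_numpy()
        assert (np.sign(pc1[:4]) != np.sign(pc1[4:])).all()
        assert evr.sum() <= 1.0 + 1e-9
        assert evr[0] > 0.8

    def test_constant_column_reported_missing(self):
        m = matrix_from([("c", 1), ("c", 2)],
                        [[5, 3], [5, 4]], [[5, 7], [5, 6]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corr = me.sample_correlations(m)
        assert np.isnan(corr.iloc[0, 1])


class TestPipelineOrder:
    """Golden-run: canonical destrand->filter->normalize->unite order on
    seeded data; permuting filter/normalize changes the result."""

    def test_canonical_order_golden(self, small_dataset, small_config):
        des = {sid: me.destrand(t)
               for sid, t in small_dataset["counts"].items()}
        raw = me.build_matrix(des, small_dataset["samples"])
        canonical = me.unite(me.normalize_coverage(me.filter_coverage(raw)), 5)
        permuted = me.unite(me.filter_coverage(me.normalize_coverage(raw)), 5)
        # frozen from the first canonical run at seed 11 (regression guard)
        assert len(raw.loci) == 800
        assert len(canonical.loci) == 781
        assert int(canonical.meth.sum()) == 34154
        different = (len(permuted.loci) != len(canonical.loci)
                     or int(permuted.meth.sum()) != int(canonical.meth.sum()))
        assert different


def test_bedgraph_and_matrix_writers(tmp_path, small_dataset):
    from dmlpipe import destrand, build_matrix, unite
    des = {sid: destrand(t) for sid, t in small_dataset["counts"].items()}
    mat = unite(build_matrix(des, small_dataset["samples"]), 5)
    me.write_matrix_tsv(mat, tmp_path / "m.tsv")
    me.write_bedgraph(mat, tmp_path / "m.bedgraph")
    back = pd.read_csv(tmp_path / "m.tsv", sep="\t")
    assert len(back) == len(mat.loci)
    bg = pd.read_csv(tmp_path / "m.bedgraph", sep="\t", header=None)
    assert ((bg[2] - bg[1]) == 2).all()
    assert bg[3].between(0, 100).all()
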