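"""Synthetic-data generator: determinism, planted structure, conservation."""

import io

import numpy as np
import pandas as pd
import pytest

import dmlpipe.simulate as sim
from dmlpipe import SimConfig
from dmlpipe.intervals import find_cg_motifs, intersect, merge, subtract


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"dml_fraction": 1.5},
        {"dml_effect": 0.0},
        {"dml_effect": 150.0},
        {"mean_coverage": 0.5},
        {"dispersion_rho": 0.0},
        {"genome_length_per_chrom": -5},
        {"snp_fraction": -0.1},
    ])
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestGenome:
    def test_cpg_density(self):
        cfg = SimConfig(genome_length_per_chrom=10_000, n_chroms=1,
                        cpg_density_per_kb=10.0, seed=3)
        seqs, sizes = sim.simulate_genome(cfg)
        assert sizes == {"chr1": 10_000}
        n_cg = seqs["chr1"].count("CG")
        assert n_cg == 100  # all CpGs are planted; background is scrubbed

    def test_deterministic_fasta_bytes(self, tmp_path):
        cfg = SimConfig(genome_length_per_chrom=5_000, n_chroms=2, seed=9)
        for name in ("a.fa", "b.fa"):
            seqs, _ = sim.simulate_genome(cfg)
            sim.write_fasta(seqs, tmp_path / name)
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_fasta_roundtrip(self, tmp_path):
        cfg = SimConfig(genome_length_per_chrom=2_000, n_chroms=1, seed=1)
        seqs, sizes = sim.simulate_genome(cfg)
        sim.write_fasta(seqs, tmp_path / "g.fa")
        back, back_sizes = sim.read_fasta(tmp_path / "g.fa")
        assert back == seqs and back_sizes == sizes


class TestAnnotation:
    def test_structure_is_valid(self, small_dataset):
        ann = small_dataset["annotation"]
        gene, exon, cds = ann["gene"], ann["exon"], ann["CDS"]
        # CDS ⊆ exon ⊆ gene base-wise
        assert len(subtract(cds, exon)) == 0
        assert len(subtract(exon, gene)) == 0
        # genes disjoint: merged base count equals summed lengths
        assert gene.total_bases() == int(
            (gene.df["end"] - gene.df["start"]).sum())
        # at least one multi-exon gene so introns are derivable
        assert exon.df["name"].value_counts().max() >= 2
        # exons within each gene are disjoint
        for name, sub in exon.df.groupby("name"):
            assert (sub.sort_values("start")["start"].to_numpy()[1:]
                    >= sub.sort_values("start")["end"].to_numpy()[:-1]).all()


class TestCounts:
    def test_conservation_and_determinism(self, small_config):
        seqs, _ = sim.simulate_genome(small_config)
        c1, t1 = sim.simulate_counts(seqs, None, small_config)
        c2, t2 = sim.simulate_counts(seqs, None, small_config)
        for sid in c1:
            pd.testing.assert_frame_equal(c1[sid], c2[sid])
        pd.testing.assert_frame_equal(t1.loci, t2.loci)
        # counts are nonnegative and coverage >= 1 for emitted rows
        for df in c1.values():
            assert (df["count_meth"] >= 0).all()
            assert (df["count_meth"] + df["count_unmeth"] >= 1).all()

    def test_all_counts_at_planted_cpgs(self, small_config, small_dataset):
        cg = find_cg_motifs(small_dataset["sequences"])
        valid = set(zip(cg.df["chrom"], cg.df["start"] + 1)) | set(
            zip(cg.df["chrom"], cg.df["start"] + 2))
        df = small_dataset["counts"]["L1"]
        assert set(zip(df["chrom"], df["pos"])) <= valid

    def test_hom_snp_reads_unmethylated(self):
        # plant aggressively so hom SNPs land on high-methylation loci
        cfg = SimConfig(genome_length_per_chrom=30_000, n_chroms=1,
                        snp_fraction=0.3, het_fraction=0.0,
                        baseline_meth_mixture=(0, 0, 1), seed=21,
                        error_rate=0.0)
        seqs, _ = sim.simulate_genome(cfg)
        counts, truth = sim.simulate_counts(seqs, None, cfg)
        hom = truth.loci[truth.loci["genotype"] == "hom_CT"]
        assert len(hom) > 20
        df = counts["L1"]
        plus = df[df["strand"] == "+"].set_index(["chrom", "pos"])
        rows = plus.loc[list(zip(hom["chrom"], hom["pos"]))]
        # plus-strand C carries the SNP: every read converted to T
        assert (rows["count_meth"] == 0).all()
        # minus strand unaffected by default: still highly methylated
        minus = df[df["strand"] == "-"].set_index(["chrom", "pos"])
        mrows = minus.loc[list(zip(hom["chrom"], hom["pos"] + 1))]
        frac = mrows["count_meth"].sum() / (
            mrows["count_meth"] + mrows["count_unmeth"]).sum()
        assert frac > 0.7

    def test_null_world_has_small_group_difference(self):
        cfg = SimConfig(genome_length_per_chrom=50_000, n_chroms=1,
                        dml_fraction=0.0, snp_fraction=0.0,
                        baseline_meth_mixture=(0, 1, 0), mean_coverage=60,
                        dispersion_rho=0.01, seed=4, error_rate=0.0,
                        covariate_effect=0.0, sample_depth_sd=0.0)
        seqs, _ = sim.simulate_genome(cfg)
        counts, truth = sim.simulate_counts(seqs, None, cfg)
        samples = cfg.sample_table()
        pooled = {}
        for grp in ("low_pH", "ambient"):
            sids = samples[samples["treatment"] == grp]["sample_id"]
            tot_m = tot_c = 0
            for sid in sids:
                df = counts[sid]
                tot_m += df["count_meth"].sum()
                tot_c += (df["count_meth"] + df["count_unmeth"]).sum()
            pooled[grp] = 100.0 * tot_m / tot_c
        assert abs(pooled["low_pH"] - pooled["ambient"]) < 2.0

    def test_planted_effect_recovered_in_expectation(self):
        """Pooled percent difference at planted loci tracks the planted
        +/-60-point effect to within 10 points, averaged over >200
        independently simulated DML."""
        cfg = SimConfig(genome_length_per_chrom=30_000, n_chroms=1,
                        dml_fraction=0.5, dml_effect=60.0, snp_fraction=0.0,
                        mean_coverage=30, seed=17, error_rate=0.0)
        seqs, _ = sim.simulate_genome(cfg)
        counts, truth = sim.simulate_counts(seqs, None, cfg)
        samples = cfg.sample_table()
        dml = truth.dml_truth
        assert len(dml) >= 200
        # pooled per-group counts at each planted locus (both strands)
        diffs = {}
        group_m = {g: {} for g in ("low_pH", "ambient")}
        group_c = {g: {} for g in ("low_pH", "ambient")}
        for sid, df in counts.items():
            grp = samples.set_index("sample_id").loc[sid, "treatment"]
            plus = df.copy()
            plus.loc[plus["strand"] == "-", "pos"] -= 1
            agg = plus.groupby(["chrom", "pos"])[
                ["count_meth", "count_unmeth"]].sum()
            for key, row in agg.iterrows():
                group_m[grp][key] = group_m[grp].get(key, 0) + row.iloc[0]
                group_c[grp][key] = group_c[grp].get(key, 0) + row.sum()
        err = []
        for row in dml.itertuples(index=False):
            key = (row.chrom, row.pos)
            d = 100.0 * (group_m["low_pH"][key] / group_c["low_pH"][key]
                         - group_m["ambient"][key] / group_c["ambient"][key])
            err.append(d - row.effect)
        assert abs(np.mean(err)) < 10.0


class TestPileups:
    def make(self, **kwargs):
        cfg = SimConfig(genome_length_per_chrom=30_000, n_chroms=1,
                        error_rate=0.0, seed=23, **kwargs)
        seqs, _ = sim.simulate_genome(cfg)
        truth = sim._plant_truth(seqs, cfg)
        pileups = sim.simulate_pileups(seqs, cfg)
        return truth, pileups

    def test_hom_snp_opposite_strand_all_A(self):
        truth, pileups = self.make(snp_fraction=0.3, het_fraction=0.0)
        hom = truth[truth["genotype"] == "hom_CT"]
        df = pileups["L1"]
        plus = df[df["strand"] == "+"].set_index("pos")
        rows = plus.loc[hom["pos"]]
        assert (rows["opp_G"] == 0).all()
        assert (rows["opp_A"] > 0).any()
        # this-strand reads are all T (converted, never methylated)
        assert (rows["this_C"] == 0).all()

    def test_non_snp_opposite_strand_all_G(self):
        truth, pileups = self.make(snp_fraction=0.0)
        df = pileups["L1"]
        assert (df["opp_A"] == 0).all()
        assert (df["opp_G"] > 0).all()

    def test_het_snp_balanced_alleles(self):
        truth, pileups = self.make(snp_fraction=0.3, het_fraction=1.0,
                                   mean_coverage=200)
        het = truth[truth["genotype"] == "het_CT"]
        df = pileups["L1"]
        plus = df[df["strand"] == "+"].set_index("pos")
        rows = plus.loc[het["pos"]]
        a, g = rows["opp_A"].sum(), rows["opp_G"].sum()
        assert a + g > 1000
        assert 0.45 <= a / (a + g) <= 0.55

    def test_counts_and_pileups_share_truth(self, small_config):
        seqs, _ = sim.simulate_genome(small_config)
        _, truth_counts = sim.simulate_counts(seqs, None, small_config)
        truth_pileups = sim._plant_truth(seqs, small_config)
        pd.testing.assert_frame_equal(truth_counts.loci, truth_pileups)


def test_coverage_writer_format(tmp_path, small_dataset):
    path = tmp_path / "s.cov.tsv"
    sim.write_coverage(small_dataset["counts"]["A1"], path)
    df = pd.read_csv(path, sep="\t", header=None)
    assert df.shape[1] == 6
    # percent column consistent with counts
    pct = 100.0 * df[4] / (df[4] + df[5])
    assert np.allclose(df[3], pct, atol=1e-4)


def test_gene2go_simulation(small_dataset):
    g2g = small_dataset["gene2go"]
    genes = set(small_dataset["annotation"]["gene"].df["name"])
    assert set(g2g["gene_id"]) <= genes
    assert all(go.startswith("GO:") for row in g2g["go_ids"]
               for go in row.split(","))
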