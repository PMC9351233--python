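"""Synthetic WGBS world: toy genome, annotation, CpG counts and pileups.

The generator emulates the post-alignment data of a two-treatment whole
genome bisulfite experiment — 4 low-pH and 4 ambient-pH samples with an
ordinal gonad-maturation covariate (0 = indeterminate .. 3 = spawn-ready
mature female) — and emits the matching ground truth so downstream
recovery can be scored:

* per-sample, per-strand CpG methylation counts (Bismark-coverage-style),
  with coverage drawn negative-binomially and methylated counts drawn
  beta-binomially (intra-site correlation ``dispersion_rho``) so the
  overdispersion correction in the test stage has something to correct;
* planted treatment effects (``dml_fraction`` of loci, ``dml_effect``
  percentage points) and planted homozygous/heterozygous C→T SNPs, which
  read as unmethylated cytosines on the affected strand;
* strand-resolved base pileups in which a C→T SNP is visible only through
  the opposite strand (A paired with the SNP's T, G paired with a true C).

Counts are simulated directly at the post-alignment level; read-level
FASTQ simulation is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .intervals import FeatureTrack, INTERVAL_COLUMNS, find_cg_motifs

BASES = np.array(list("ACGT"))

# fixed RNG stream keys so independently-called operations agree on truth
(_KEY_GENOME, _KEY_ANNOT, _KEY_TRUTH, _KEY_COUNTS, _KEY_PILEUP, _KEY_GO,
 _KEY_DEPTH) = range(7)


@dataclass
class SimConfig:
    """Parameters of the simulated experiment.

    Defaults state the emulated design: 2 treatments x 4 samples, ordinal
    maturation stages 0-3 balanced across treatments, mean coverage 30x,
    beta-binomial intra-site correlation 0.05, and a genome-wide baseline
    methylation mixture dominated by lowly methylated CpGs as in molluscan
    genomes (~80% low / ~10% moderate / ~10% high).
    """

    genome_length_per_chrom: int = 60_000
    n_chroms: int = 5
    cpg_density_per_kb: float = 20.0
    n_samples_per_group: int = 4
    covariate_levels: tuple = (0, 1, 2, 3)
    baseline_meth_mixture: tuple = (0.80, 0.10, 0.10)  # low / mid / high
    dml_fraction: float = 0.02
    dml_effect: float = 60.0          # percentage points, signed at random
    snp_fraction: float = 0.02
    het_fraction: float = 0.3
    mean_coverage: float = 30.0
    coverage_dispersion: float = 8.0  # negative-binomial size parameter
    sample_depth_sd: float = 0.2      # lognormal sd of per-sample depth
    dispersion_rho: float = 0.05
    covariate_effect: float = 0.3     # logit shift per maturation stage
    error_rate: float = 0.001         # per-read uniform miscall rate (pileups)
    snp_both_strands: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dml_fraction", "snp_fraction", "het_fraction",
                     "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.dml_effect <= 100.0:
            raise ValueError("dml_effect must be in (0, 100]")
        if self.mean_coverage < 1:
            raise ValueError("mean_coverage must be >= 1")
        if not 0.0 < self.dispersion_rho < 1.0:
            raise ValueError("dispersion_rho must be in (0, 1)")
        if self.genome_length_per_chrom <= 0 or self.n_chroms <= 0:
            raise ValueError("genome dimensions must be positive")
        if sum(self.baseline_meth_mixture) <= 0:
            raise ValueError("baseline_meth_mixture must have positive mass")

    def rng(self, key: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), key])

    def sample_table(self) -> pd.DataFrame:
        """Sample ids, treatments and maturation stages (balanced)."""
        n = self.n_samples_per_group
        stages = [self.covariate_levels[i % len(self.covariate_levels)]
                  for i in range(n)]
        rows = [(f"L{i + 1}", "low_pH", stages[i]) for i in range(n)]
        rows += [(f"A{i + 1}", "ambient", stages[i]) for i in range(n)]
        return pd.DataFrame(rows, columns=["sample_id", "treatment", "stage"])


@dataclass
class TruthSet:
    """Planted ground truth emitted alongside the simulated data.

    ``loci`` has one row per destranded CpG (1-based position of the
    plus-strand C) with its baseline methylation probability, planted
    effect in percentage points (0 where null) and SNP genotype
    (ref / hom_CT / het_CT). Planted DML and SNP sets may overlap — that
    overlap is what the SNP screen must catch.
    """

    loci: pd.DataFrame
    config: SimConfig

    @property
    def dml_truth(self) -> pd.DataFrame:
        return self.loci[self.loci["effect"] != 0.0][
            ["chrom", "pos", "effect"]].reset_index(drop=True)

    @property
    def snp_truth(self) -> pd.DataFrame:
        return self.loci[self.loci["genotype"] != "ref"][
            ["chrom", "pos", "genotype"]].reset_index(drop=True)

    def feature_membership(self, tracks: dict[str, FeatureTrack],
                           order=("CDS", "exon_UTR", "intron", "flank_up",
                                  "flank_down", "intergenic")) -> pd.DataFrame:
        from .annotate import partition_loci
        labels = partition_loci(self.loci[["chrom", "pos"]], tracks, order)
        out = self.loci[["chrom", "pos"]].copy()
        out["feature_class"] = labels
        return out

    def write(self, path) -> None:
        self.loci.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> tuple[dict[str, str], dict[str, int]]:
    """Random genome with CG dinucleotides planted at the configured density.

    The background sequence is scrubbed of accidental CG so every CpG is a
    deliberately planted, truth-tracked locus.
    """
    rng = config.rng(_KEY_GENOME)
    length = config.genome_length_per_chrom
    sequences: dict[str, str] = {}
    sizes: dict[str, int] = {}
    n_cpg = int(round(length * config.cpg_density_per_kb / 1000.0))
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        arr = rng.choice(BASES, size=length, p=[0.31, 0.19, 0.19, 0.31])
        cg = (arr[:-1] == "C") & (arr[1:] == "G")
        arr[1:][cg] = "A"  # scrub accidental CpGs
        if n_cpg > 0 and length >= 2:
            # place CpG starts on even offsets to guarantee >= 2 bp spacing
            slots = np.arange(0, length - 1, 2)
            starts = np.sort(rng.choice(slots, size=min(n_cpg, len(slots)),
                                        replace=False))
            arr[starts] = "C"
            arr[starts + 1] = "G"
            # planting cannot create extra CpGs: background has no G after C
            before = starts - 1
            bad = before[before >= 0][arr[before[before >= 0]] == "C"]
            arr[bad] = "A"
        sequences[chrom] = "".join(arr)
        sizes[chrom] = length
    return sequences, sizes


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=chrom, description="")
               for chrom, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> tuple[dict[str, str], dict[str, int]]:
    from Bio import SeqIO

    sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return sequences, {chrom: len(s) for chrom, s in sequences.items()}


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(chrom_sizes: dict[str, int], config: SimConfig
                        ) -> dict[str, FeatureTrack]:
    """Gene/exon/CDS (+ TE, lncRNA) tracks with valid nesting.

    Genes are disjoint, strands alternate, and the first gene of each
    chromosome is multi-exon so introns are always derivable. TE intervals
    are scattered independently of genes (they may land in introns);
    lncRNA genes are placed in gene-free gaps.
    """
    rng = config.rng(_KEY_ANNOT)
    gene_rows, exon_rows, cds_rows = [], [], []
    te_rows, lnc_rows = [], []
    g_idx = 0
    for chrom, size in chrom_sizes.items():
        pos = int(rng.integers(1200, 2500))
        first = True
        while pos + 1500 < size - 1200:
            glen = int(rng.integers(1500, min(4000, size - pos - 1200)))
            strand = "+" if rng.random() < 0.5 else "-"
            g_idx += 1
            name = f"gene{g_idx:04d}"
            gs, ge = pos, pos + glen
            n_ex = int(rng.integers(2, 5)) if (first or rng.random() < 0.7) else 1
            first = False
            bounds = np.sort(rng.choice(
                np.arange(gs + 100, ge - 100), size=2 * (n_ex - 1),
                replace=False)) if n_ex > 1 else np.array([], dtype=int)
            edges = np.concatenate([[gs], bounds, [ge]])
            gene_rows.append((chrom, gs, ge, strand, name))
            for i in range(n_ex):
                es, ee = int(edges[2 * i]), int(edges[2 * i + 1])
                if ee - es < 30:
                    ee = es + 30
                exon_rows.append((chrom, es, ee, strand, name))
                # CDS trimmed by a UTR margin in first/last exon
                cs = es + (int(rng.integers(10, 25)) if i == 0 else 0)
                ce = ee - (int(rng.integers(10, 25)) if i == n_ex - 1 else 0)
                if cs < ce:
                    cds_rows.append((chrom, cs, ce, strand, name))
            pos = ge + int(rng.integers(1500, 4000))
        # transposable elements: scattered short intervals
        n_te = max(1, size // 12_000)
        for _ in range(n_te):
            ts = int(rng.integers(0, size - 1000))
            te_rows.append((chrom, ts, ts + int(rng.integers(200, 1000)),
                            ".", ""))
        # one lncRNA per chromosome in the leading gene-free gap
        if gene_rows and pos < size - 400:
            ls = int(rng.integers(pos, size - 300))
            lnc_rows.append((chrom, ls, min(ls + 300, size), "+",
                             f"lnc_{chrom}"))

    def track(cls, rows):
        return FeatureTrack(cls, pd.DataFrame(rows, columns=INTERVAL_COLUMNS))

    return {"gene": track("gene", gene_rows), "exon": track("exon", exon_rows),
            "CDS": track("CDS", cds_rows), "TE": track("TE", te_rows),
            "lncRNA": track("lncRNA", lnc_rows)}


# ---------------------------------------------------------------------------
# Truth: baseline methylation, planted DML and SNPs
# ---------------------------------------------------------------------------

def _plant_truth(sequences: dict[str, str], config: SimConfig) -> pd.DataFrame:
    """One row per destranded CpG locus with planted parameters."""
    cg = find_cg_motifs(sequences)
    chroms = cg.df["chrom"].to_numpy()
    pos = cg.df["start"].to_numpy() + 1  # 1-based plus-strand C
    n = len(pos)
    rng = config.rng(_KEY_TRUTH)

    mix = np.asarray(config.baseline_meth_mixture, dtype=float)
    mix = mix / mix.sum()
    stratum = rng.choice(3, size=n, p=mix)
    base_p = np.empty(n)
    base_p[stratum == 0] = rng.uniform(0.005, 0.10, (stratum == 0).sum())
    base_p[stratum == 1] = rng.uniform(0.30, 0.70, (stratum == 1).sum())
    base_p[stratum == 2] = rng.uniform(0.80, 0.97, (stratum == 2).sum())

    effect = np.zeros(n)
    is_dml = rng.random(n) < config.dml_fraction
    d = config.dml_effect / 100.0
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    lo, hi = 0.02, 0.98
    for i in np.flatnonzero(is_dml):
        if sign[i] > 0:
            base_p[i] = rng.uniform(lo, max(lo + 1e-6, hi - d))
        else:
            base_p[i] = rng.uniform(min(hi - 1e-6, lo + d), hi)
        effect[i] = sign[i] * config.dml_effect

    genotype = np.full(n, "ref", dtype=object)
    is_snp = rng.random(n) < config.snp_fraction
    het = rng.random(n) < config.het_fraction
    genotype[is_snp & ~het] = "hom_CT"
    genotype[is_snp & het] = "het_CT"

    return pd.DataFrame({"chrom": chroms, "pos": pos, "base_p": base_p,
                         "effect": effect, "genotype": genotype})


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _nb_coverage(rng, mean, size_param, shape):
    mean = np.broadcast_to(np.asarray(mean, dtype=float), shape)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, shape)


def _sample_depths(config: SimConfig) -> np.ndarray:
    """Per-sample library-depth multipliers (lognormal, mean 1).

    Real libraries never sequence to identical depth; this is what the
    cross-sample coverage normalization step exists to undo.
    """
    rng = config.rng(_KEY_DEPTH)
    n = 2 * config.n_samples_per_group
    sd = config.sample_depth_sd
    if sd <= 0:
        return np.ones(n)
    return rng.lognormal(-sd ** 2 / 2.0, sd, n)


def _site_probs(truth: pd.DataFrame, config: SimConfig) -> np.ndarray:
    """Per-(locus, sample) true methylation probability (loci x samples)."""
    samples = config.sample_table()
    treat = (samples["treatment"] == "low_pH").to_numpy(float)
    stage = samples["stage"].to_numpy(float)
    base = np.clip(truth["base_p"].to_numpy(), 1e-6, 1 - 1e-6)
    target = np.clip(base + truth["effect"].to_numpy() / 100.0, 1e-6, 1 - 1e-6)
    delta = logit(target) - logit(base)  # 0 for null loci
    eta = (logit(base)[:, None] + delta[:, None] * treat[None, :]
           + config.covariate_effect * (stage - stage.mean())[None, :])
    return expit(eta)


def simulate_counts(sequences: dict[str, str],
                    annotation: dict[str, FeatureTrack] | None,
                    config: SimConfig
                    ) -> tuple[dict[str, pd.DataFrame], TruthSet]:
    """Per-sample strand-resolved CpG count tables plus the truth set.

    For each destranded locus and sample, coverage is negative binomial
    with mean ``mean_coverage``; a site-level methylation probability is
    drawn Beta(p, rho) and reads are binomial around it (i.e. destranded
    counts are beta-binomial). Reads are split between the two strands of
    the CpG at random; a hom C→T SNP zeroes methylation on the affected
    strand, a het SNP halves it in expectation. Zero-coverage strand rows
    are absent, matching Bismark coverage-file semantics.
    """
    truth = _plant_truth(sequences, config)
    rng = config.rng(_KEY_COUNTS)
    samples = config.sample_table()
    n_loci, n_s = len(truth), len(samples)

    p_true = _site_probs(truth, config)
    rho = config.dispersion_rho
    a = p_true * (1 - rho) / rho
    b = (1 - p_true) * (1 - rho) / rho
    p_site = rng.beta(np.maximum(a, 1e-8), np.maximum(b, 1e-8))

    depths = _sample_depths(config)
    cov = _nb_coverage(rng, config.mean_coverage * depths[None, :],
                       config.coverage_dispersion, (n_loci, n_s))
    plus_cov = rng.binomial(cov, 0.5)
    minus_cov = cov - plus_cov

    geno = truth["genotype"].to_numpy()
    # effective per-strand methylation probability given the genotype
    p_plus = p_site.copy()
    p_plus[geno == "hom_CT"] = 0.0
    p_plus[geno == "het_CT"] *= 0.5
    p_minus = p_site.copy()
    if config.snp_both_strands:
        p_minus[geno == "hom_CT"] = 0.0
        p_minus[geno == "het_CT"] *= 0.5
    plus_meth = rng.binomial(plus_cov, p_plus)
    minus_meth = rng.binomial(minus_cov, p_minus)

    chrom = truth["chrom"].to_numpy()
    pos_plus = truth["pos"].to_numpy()
    tables: dict[str, pd.DataFrame] = {}
    for j, sid in enumerate(samples["sample_id"]):
        parts = []
        for strand, c, m, offset in (("+", plus_cov[:, j], plus_meth[:, j], 0),
                                     ("-", minus_cov[:, j], minus_meth[:, j], 1)):
            keep = c >= 1
            parts.append(pd.DataFrame({
                "chrom": chrom[keep], "pos": pos_plus[keep] + offset,
                "strand": strand, "count_meth": m[keep],
                "count_unmeth": (c - m)[keep],
            }))
        df = pd.concat(parts, ignore_index=True)
        tables[sid] = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return tables, TruthSet(truth, config)


def write_coverage(table: pd.DataFrame, path) -> None:
    """Bismark-coverage-style TSV: chrom, pos, pos, %meth, meth, unmeth."""
    cov = table["count_meth"] + table["count_unmeth"]
    out = pd.DataFrame({
        "chrom": table["chrom"], "start": table["pos"], "end": table["pos"],
        "pct": np.round(100.0 * table["count_meth"] / cov, 6),
        "meth": table["count_meth"], "unmeth": table["count_unmeth"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Pileups
# ---------------------------------------------------------------------------

def simulate_pileups(sequences: dict[str, str], config: SimConfig
                     ) -> dict[str, pd.DataFrame]:
    """Strand-resolved base counts at every CpG cytosine, per sample.

    Each record carries this-strand A/C/G/T counts (methylated C reads as
    C, converted unmethylated C as T) and opposite-strand counts (G paired
    with a true C, A paired with a C→T SNP allele). Truth draws share the
    seed-keyed stream used by :func:`simulate_counts`, so pileups and
    count tables agree on planted SNPs and effects.
    """
    truth = _plant_truth(sequences, config)
    rng = config.rng(_KEY_PILEUP)
    samples = config.sample_table()
    p_true = _site_probs(truth, config)
    rho = config.dispersion_rho
    a = p_true * (1 - rho) / rho
    b = (1 - p_true) * (1 - rho) / rho
    geno = truth["genotype"].to_numpy()
    n = len(truth)
    e = config.error_rate
    depths = _sample_depths(config)

    A, C, G, T = 0, 1, 2, 3
    out: dict[str, pd.DataFrame] = {}
    for j, sid in enumerate(samples["sample_id"]):
        p_site = rng.beta(np.maximum(a[:, j], 1e-8), np.maximum(b[:, j], 1e-8))
        frames = []
        for strand, offset in (("+", 0), ("-", 1)):
            snp_here = (geno != "ref") if (strand == "+"
                                           or config.snp_both_strands) else \
                np.zeros(n, dtype=bool)
            alt_frac = np.where(snp_here & (geno == "hom_CT"), 1.0,
                                np.where(snp_here & (geno == "het_CT"), 0.5,
                                         0.0))
            this_cov = _nb_coverage(rng, config.mean_coverage * depths[j],
                                    config.coverage_dispersion, n)
            opp_cov = _nb_coverage(rng, config.mean_coverage * depths[j],
                                   config.coverage_dispersion, n)
            # this strand: T-allele reads -> T; C-allele reads -> C (meth) / T
            alt_reads = rng.binomial(this_cov, alt_frac)
            meth_reads = rng.binomial(this_cov - alt_reads, p_site)
            this = np.zeros((n, 4), dtype=np.int64)
            this[:, C] = meth_reads
            this[:, T] = this_cov - meth_reads
            # opposite strand: A pairs with the SNP's T, G with a true C
            opp_alt = rng.binomial(opp_cov, alt_frac)
            opp = np.zeros((n, 4), dtype=np.int64)
            opp[:, A] = opp_alt
            opp[:, G] = opp_cov - opp_alt
            if e > 0:
                this = _redistribute_errors(rng, this, e)
                opp = _redistribute_errors(rng, opp, e)
            frames.append(pd.DataFrame({
                "chrom": truth["chrom"], "pos": truth["pos"] + offset,
                "strand": strand,
                "this_A": this[:, A], "this_C": this[:, C],
                "this_G": this[:, G], "this_T": this[:, T],
                "opp_A": opp[:, A], "opp_C": opp[:, C],
                "opp_G": opp[:, G], "opp_T": opp[:, T],
            }))
        df = pd.concat(frames, ignore_index=True)
        out[sid] = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return out


def _redistribute_errors(rng, counts: np.ndarray, error: float) -> np.ndarray:
    """Move a binomial(error) share of each base's reads to the other bases."""
    out = counts.copy()
    for b in range(4):
        wrong = rng.binomial(counts[:, b], error)
        out[:, b] -= wrong
        others = [t for t in range(4) if t != b]
        r1 = rng.binomial(wrong, 1 / 3)
        r2 = rng.binomial(wrong - r1, 1 / 2)
        r3 = wrong - r1 - r2
        for t, add in zip(others, (r1, r2, r3)):
            out[:, t] += add
    return out


def write_pileups(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_pileups(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# gene -> GO mapping
# ---------------------------------------------------------------------------

def simulate_gene2go(gene_track: FeatureTrack, config: SimConfig,
                     n_terms: int = 50, mean_terms_per_gene: float = 3.0
                     ) -> pd.DataFrame:
    """Random gene→GO-term assignments (TSV-writable, topGO-style)."""
    rng = config.rng(_KEY_GO)
    genes = sorted(set(gene_track.df["name"]) - {""})
    terms = [f"GO:{7000000 + i:07d}" for i in range(n_terms)]
    rows = []
    for g in genes:
        k = min(n_terms, rng.poisson(mean_terms_per_gene) + 1)
        chosen = rng.choice(terms, size=k, replace=False)
        rows.append((g, ",".join(sorted(chosen))))
    return pd.DataFrame(rows, columns=["gene_id", "go_ids"])


def write_gene2go(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# One-call dataset
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig) -> dict:
    """Generate the complete synthetic world in one consistent call."""
    sequences, sizes = simulate_genome(config)
    annotation = simulate_annotation(sizes, config)
    counts, truth = simulate_counts(sequences, annotation, config)
    pileups = simulate_pileups(sequences, config)
    gene2go = simulate_gene2go(annotation["gene"], config)
    return {
        "sequences": sequences, "chrom_sizes": sizes,
        "annotation": annotation, "counts": counts, "pileups": pileups,
        "truth": truth, "gene2go": gene2go,
        "samples": config.sample_table(),
    }
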