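"""DML and methylation-class characterization against genome features,
plus chi-squared location tests and GO-term enrichment.

Feature overlap is reported two ways: an overlapping-class table (a CpG
in a transposable element inside an intron counts for both, so columns
can sum past 100%) and a mutually exclusive partition used by the
contingency tests, with precedence CDS > exon_UTR > intron > flank_up >
flank_down > intergenic (genic-first). Enrichment is gene-level Fisher's
exact against the universe of genes containing >= 5x-covered CpGs, with
no multiple-testing correction — deliberately matching topGO defaults.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import FeatureTrack, overlaps_track

PARTITION_ORDER = ("CDS", "exon_UTR", "intron", "flank_up", "flank_down",
                   "intergenic")
OVERLAP_CLASSES = ("gene", "exon_UTR", "CDS", "intron", "flank_up",
                   "flank_down", "intergenic", "TE", "lncRNA")


def _loci_track(loci: pd.DataFrame) -> FeatureTrack:
    """A destranded 1-based CpG at p occupies bases [p-1, p+1)."""
    return FeatureTrack("loci", pd.DataFrame({
        "chrom": loci["chrom"], "start": loci["pos"] - 1,
        "end": loci["pos"] + 1}))


def overlap_features(loci: pd.DataFrame, tracks: dict[str, FeatureTrack]
                     ) -> pd.DataFrame:
    """Per feature class: loci overlapping (>= 1 base) and percent of total.

    Classes are not mutually exclusive; use :func:`partition_loci` for
    contingency-test counts.
    """
    query = _loci_track(loci)
    total = max(len(loci), 1)
    rows = []
    for cls in OVERLAP_CLASSES:
        if cls not in tracks:
            continue
        n = int(overlaps_track(query, tracks[cls]).sum())
        rows.append((cls, n, round(100.0 * n / total, 1)))
    return pd.DataFrame(rows, columns=["feature_class", "count", "percent"])


def partition_loci(loci: pd.DataFrame, tracks: dict[str, FeatureTrack],
                   order=PARTITION_ORDER) -> np.ndarray:
    """Assign every locus exactly one feature label by precedence."""
    query = _loci_track(loci)
    labels = np.full(len(loci), "unassigned", dtype=object)
    unset = np.ones(len(loci), dtype=bool)
    for cls in order:
        if cls not in tracks:
            continue
        hit = overlaps_track(query, tracks[cls]) & unset
        labels[hit] = cls
        unset &= ~hit
    return labels


def partition_counts(loci: pd.DataFrame, tracks: dict[str, FeatureTrack],
                     order=PARTITION_ORDER) -> pd.Series:
    labels = partition_loci(loci, tracks, order)
    return pd.Series(labels).value_counts().reindex(
        list(order) + ["unassigned"], fill_value=0)


def contingency_test(background_counts: pd.Series, query_counts: pd.Series
                     ) -> dict:
    """2 x k chi-squared test of feature-location association.

    Inputs are mutually exclusive partition counts for the background
    (all 5x CpGs) and the query (e.g. highly methylated CpGs or DML).
    No continuity correction, matching R's chisq.test on 2 x k tables.
    Zero-margin categories are dropped with a warning in the result.
    """
    cats = background_counts.index.union(query_counts.index)
    bg = background_counts.reindex(cats, fill_value=0)
    qr = query_counts.reindex(cats, fill_value=0)
    keep = (bg + qr) > 0
    dropped = list(cats[~keep])
    table = np.vstack([bg[keep].to_numpy(), qr[keep].to_numpy()])
    res = stats.chi2_contingency(table, correction=False)
    warn_small = bool((res.expected_freq < 5).any())
    return {
        "statistic": float(res.statistic), "df": int(res.dof),
        "p_value": float(res.pvalue), "expected": res.expected_freq,
        "dropped_categories": dropped, "small_expected_warning": warn_small,
    }


def chromosome_density(dml: pd.DataFrame, cpg_loci: pd.DataFrame,
                       gene_track: FeatureTrack,
                       placed_chroms: list[str] | None = None) -> pd.DataFrame:
    """Per-chromosome DML counts normalized by CpG and gene counts.

    Chromosomes not in ``placed_chroms`` are aggregated into one
    "unplaced" row (scaffolds without a chromosome assignment).
    """
    def label(c):
        return c if placed_chroms is None or c in placed_chroms else "unplaced"

    dml_n = dml["chrom"].map(label).value_counts()
    cpg_n = cpg_loci["chrom"].map(label).value_counts()
    gene_n = gene_track.df["chrom"].map(label).value_counts()
    chroms = cpg_n.index.tolist()
    rows = []
    for c in chroms:
        n_dml = int(dml_n.get(c, 0))
        n_cpg = int(cpg_n.get(c, 0))
        rows.append((c, n_dml, n_cpg, int(gene_n.get(c, 0)),
                     n_dml / n_cpg if n_cpg else 0.0))
    return pd.DataFrame(rows, columns=["chrom", "dml", "cpgs", "genes",
                                       "dml_per_cpg"])


def dml_per_gene(dml: pd.DataFrame, gene_track: FeatureTrack) -> pd.Series:
    """DML count per gene (genes with zero DML omitted).

    A DML inside two overlapping genes counts once for each.
    """
    counts: dict[str, int] = {}
    query = _loci_track(dml)
    for name, sub in gene_track.df.groupby("name", sort=True):
        if not name:
            continue
        n = int(overlaps_track(query, FeatureTrack("gene", sub)).sum())
        if n:
            counts[name] = n
    return pd.Series(counts, dtype=np.int64).sort_values(ascending=False)


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------

def read_gene2go(path) -> dict[str, set[str]]:
    """TSV of gene id and comma-separated GO ids (topGO geneID2GO style)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "go_ids"])
    return {str(r.gene_id): set(str(r.go_ids).split(","))
            for r in df.itertuples(index=False) if pd.notna(r.go_ids)}


def go_enrichment(interest_genes, universe_genes,
                  gene2go: dict[str, set[str]],
                  p_threshold: float = 0.01) -> pd.DataFrame:
    """One-sided Fisher's exact test per GO term, uncorrected.

    For each term the 2x2 table is (in-term vs not) x (interest vs rest
    of universe); p = P[X >= observed] under the hypergeometric null.
    ``interest_genes`` must be a subset of ``universe_genes``; genes
    whose only DML overlapped SNPs must already have been filtered out
    upstream.
    """
    universe = sorted(set(universe_genes) & set(gene2go))
    interest = set(interest_genes) & set(universe)
    if not universe or not set(interest_genes):
        raise ValueError("empty universe or interest gene set")
    if not set(interest_genes) <= set(universe_genes):
        raise ValueError("interest genes must be a subset of the universe")
    n_univ = len(universe)
    n_int = len(interest)
    term_genes: dict[str, set[str]] = {}
    for g in universe:
        for t in gene2go[g]:
            term_genes.setdefault(t, set()).add(g)
    rows = []
    for term, members in sorted(term_genes.items()):
        k_univ = len(members)
        k_int = len(members & interest)
        # upper tail of Hypergeometric(N=n_univ, K=k_univ, n=n_int) at k_int
        p = float(stats.hypergeom.sf(k_int - 1, n_univ, k_univ, n_int))
        rows.append((term, k_univ, k_int, p, p < p_threshold,
                     ",".join(sorted(members & interest))))
    return pd.DataFrame(rows, columns=[
        "go_id", "annotated_in_universe", "annotated_in_interest",
        "p_value", "significant", "interest_genes"])


def genes_with_dml(records: pd.DataFrame, gene_track: FeatureTrack,
                   exclude_snp_only: bool = True) -> set[str]:
    """Gene ids containing >= 1 retained DML (SNP-overlap DML never count)."""
    dml = records[records["is_dml"]]
    return set(dml_per_gene(dml, gene_track).index)


def write_enrichment_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
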