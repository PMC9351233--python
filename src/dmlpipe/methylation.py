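"""From per-sample CpG coverage records to a united methylation matrix.

The processing order is fixed and mirrors the canonical methylKit-style
recipe: destrand → per-sample coverage filter (low count and 99.9th
percentile) → cross-sample coverage normalization → unite (loci ≥5x in
every sample) → C→T SNP exclusion. Also provides the global landscape
summaries: high/moderate/low classification, pairwise Pearson
correlations and a PCA of the percent-methylation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .snps import SnpSet

TREATMENTS = ("low_pH", "ambient")


@dataclass
class MethylMatrix:
    """Destranded CpG loci x samples matrix of (meth, unmeth) counts.

    ``loci`` is a (chrom, pos) frame of 1-based destranded CpG positions;
    ``meth``/``unmeth`` are int arrays of shape (n_loci, n_samples);
    ``samples`` carries sample_id, treatment and maturation stage.
    Missing (sample, locus) cells are coded coverage 0 until ``unite``
    removes them.
    """

    loci: pd.DataFrame
    samples: pd.DataFrame
    meth: np.ndarray
    unmeth: np.ndarray

    def __post_init__(self) -> None:
        assert self.meth.shape == self.unmeth.shape == (
            len(self.loci), len(self.samples))

    @property
    def coverage(self) -> np.ndarray:
        return self.meth + self.unmeth

    def percent(self) -> np.ndarray:
        """Per-cell percent methylation (NaN where coverage is 0)."""
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, 100.0 * self.meth / np.maximum(cov, 1),
                            np.nan)

    def pooled_percent(self, weighted: bool = True) -> np.ndarray:
        """Per-locus percent methylation across samples.

        Coverage-weighted pooling (sum of meth over sum of coverage) by
        default; ``weighted=False`` averages per-sample percentages.
        """
        if weighted:
            cov = self.coverage.sum(axis=1)
            return 100.0 * self.meth.sum(axis=1) / np.maximum(cov, 1)
        return np.nanmean(self.percent(), axis=1)

    def subset(self, mask: np.ndarray) -> "MethylMatrix":
        return MethylMatrix(self.loci[mask].reset_index(drop=True),
                            self.samples, self.meth[mask], self.unmeth[mask])

    def treatment_masks(self) -> tuple[np.ndarray, np.ndarray]:
        t = self.samples["treatment"].to_numpy()
        return t == TREATMENTS[0], t == TREATMENTS[1]


# ---------------------------------------------------------------------------
# Reading and destranding
# ---------------------------------------------------------------------------

def read_bismark_coverage(path) -> pd.DataFrame:
    """Read a Bismark coverage file (chrom, pos, pos, %, meth, unmeth)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "pos", "end", "pct", "count_meth",
                            "count_unmeth"])
    return df[["chrom", "pos", "count_meth", "count_unmeth"]].astype(
        {"chrom": str, "pos": np.int64})


def assign_strand(records: pd.DataFrame, cg_track) -> pd.DataFrame:
    """Label records +/− by matching CG motif starts (Bismark files carry
    no strand; the genome's CG positions disambiguate)."""
    plus_pos = set(zip(cg_track.df["chrom"], cg_track.df["start"] + 1))
    out = records.copy()
    keys = list(zip(out["chrom"], out["pos"]))
    out["strand"] = ["+" if k in plus_pos else "-" for k in keys]
    return out


def destrand(records: pd.DataFrame) -> pd.DataFrame:
    """Sum the two strand records of each CpG at the plus-strand position.

    A minus-strand C at 1-based position p+1 joins the plus-strand C at
    p; orphan minus records are simply reported at their own CpG start.
    Input needs columns chrom, pos, strand, count_meth, count_unmeth.
    """
    if "strand" not in records.columns:
        raise ValueError("destrand needs a strand column "
                         "(see assign_strand)")
    df = records.copy()
    minus = df["strand"] == "-"
    df.loc[minus, "pos"] = df.loc[minus, "pos"] - 1
    out = df.groupby(["chrom", "pos"], as_index=False)[
        ["count_meth", "count_unmeth"]].sum()
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


def build_matrix(destranded: dict[str, pd.DataFrame],
                 samples: pd.DataFrame) -> MethylMatrix:
    """Assemble per-sample destranded records into one loci x samples grid."""
    keys = sorted(
        {(c, p) for df in destranded.values()
         for c, p in zip(df["chrom"], df["pos"])})
    loci = pd.DataFrame(keys, columns=["chrom", "pos"])
    index = {k: i for i, k in enumerate(keys)}
    n, s = len(keys), len(samples)
    meth = np.zeros((n, s), dtype=np.int64)
    unmeth = np.zeros((n, s), dtype=np.int64)
    for j, sid in enumerate(samples["sample_id"]):
        df = destranded[sid]
        rows = [index[k] for k in zip(df["chrom"], df["pos"])]
        meth[rows, j] = df["count_meth"].to_numpy()
        unmeth[rows, j] = df["count_unmeth"].to_numpy()
    return MethylMatrix(loci, samples.reset_index(drop=True), meth, unmeth)


# ---------------------------------------------------------------------------
# Filtering, normalization, uniting
# ---------------------------------------------------------------------------

def filter_coverage(matrix: MethylMatrix, lo: int = 5,
                    high_percentile: float = 99.9) -> MethylMatrix:
    """Per sample, void loci below ``lo`` or above that sample's coverage
    percentile (PCR-duplicate guard). Voided cells become coverage 0; the
    locus stays until :func:`unite` requires presence in all samples."""
    meth, unmeth = matrix.meth.copy(), matrix.unmeth.copy()
    cov = matrix.coverage
    for j in range(cov.shape[1]):
        present = cov[:, j] > 0
        if not present.any():
            continue
        cut_hi = np.percentile(cov[present, j], high_percentile)
        drop = present & ((cov[:, j] < lo) | (cov[:, j] > cut_hi))
        meth[drop, j] = 0
        unmeth[drop, j] = 0
    out = MethylMatrix(matrix.loci, matrix.samples, meth, unmeth)
    if not (out.coverage.sum(axis=1) > 0).any():
        warnings.warn("coverage filter removed every locus")
    return out


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def normalize_coverage(matrix: MethylMatrix) -> MethylMatrix:
    """Equalize sample median coverages (scale to the median-of-medians).

    Both counts are scaled and rounded half away from zero; covered cells
    are floored at total coverage 1 so normalization never erases a site.
    """
    cov = matrix.coverage
    medians = np.array([
        np.median(cov[cov[:, j] > 0, j]) if (cov[:, j] > 0).any() else 0.0
        for j in range(cov.shape[1])])
    if (medians <= 0).any():
        raise ValueError("zero median coverage in at least one sample")
    target = np.median(medians)
    factors = target / medians
    meth = _round_half_away(matrix.meth * factors[None, :]).astype(np.int64)
    unmeth = _round_half_away(matrix.unmeth * factors[None, :]).astype(np.int64)
    was_covered = cov > 0
    zeroed = was_covered & ((meth + unmeth) == 0)
    unmeth[zeroed] = 1
    return MethylMatrix(matrix.loci, matrix.samples, meth, unmeth)


def unite(matrix: MethylMatrix, min_cov: int = 5) -> MethylMatrix:
    """Keep loci covered >= ``min_cov`` in every sample (the CpG
    background for DML testing and the enrichment gene universe)."""
    keep = (matrix.coverage >= min_cov).all(axis=1)
    if not keep.any():
        warnings.warn("unite produced an empty matrix")
    return matrix.subset(keep)


def apply_snp_exclusion(matrix: MethylMatrix, snp_set: SnpSet
                        ) -> tuple[MethylMatrix, int]:
    """Remove destranded loci whose either strand position (p or p+1) is
    in the C→T exclusion set; returns (matrix, number removed)."""
    if len(snp_set) == 0:
        return matrix, 0
    snp = set(zip(snp_set.positions["chrom"], snp_set.positions["pos"]))
    chrom = matrix.loci["chrom"].to_numpy()
    pos = matrix.loci["pos"].to_numpy()
    hit = np.fromiter(
        (((c, p) in snp) or ((c, p + 1) in snp)
         for c, p in zip(chrom, pos)), dtype=bool, count=len(pos))
    return matrix.subset(~hit), int(hit.sum())


# ---------------------------------------------------------------------------
# Global landscape
# ---------------------------------------------------------------------------

CLASS_LABELS = ("low", "moderate", "high")


def classify_percent(percent: np.ndarray) -> np.ndarray:
    """high if >= 50%, low if <= 10%, moderate in between."""
    out = np.full(len(percent), "moderate", dtype=object)
    out[percent >= 50.0] = "high"
    out[percent <= 10.0] = "low"
    return out


def classify_loci(matrix: MethylMatrix, weighted: bool = True
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-locus methylation class plus a count/percentage summary.

    Percent methylation is the coverage-weighted pooled mean across
    samples by default (matches count-level uniting); ``weighted=False``
    uses the unweighted mean of per-sample percentages.
    """
    pct = matrix.pooled_percent(weighted=weighted)
    labels = classify_percent(pct)
    per_locus = matrix.loci.copy()
    per_locus["percent"] = pct
    per_locus["meth_class"] = labels
    counts = {c: int((labels == c).sum()) for c in CLASS_LABELS}
    total = max(len(labels), 1)
    summary = pd.DataFrame({
        "meth_class": CLASS_LABELS,
        "count": [counts[c] for c in CLASS_LABELS],
        "percent": [100.0 * counts[c] / total for c in CLASS_LABELS],
    })
    return per_locus, summary


def sample_correlations(matrix: MethylMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-sample percent methylation."""
    pct = pd.DataFrame(matrix.percent(),
                       columns=matrix.samples["sample_id"])
    return pct.corr(method="pearson")


def sample_pca(matrix: MethylMatrix, n_components: int | None = None
               ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the centered percent-methylation matrix (samples as points).

    Returns (scores frame with one row per sample, explained-variance
    fractions). Implemented by SVD of the locus-centered matrix.
    """
    pct = matrix.percent()
    x = pct.T  # samples x loci
    x = np.where(np.isnan(x), np.nanmean(x, axis=0, keepdims=True), x)
    x = x - x.mean(axis=0, keepdims=True)
    n = x.shape[0]
    k = n_components or min(n - 1, x.shape[1])
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k] * s[:k]
    total_var = (s ** 2).sum()
    evr = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    frame = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(k)])
    frame.insert(0, "sample_id", matrix.samples["sample_id"].to_numpy())
    return frame, evr


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_matrix_tsv(matrix: MethylMatrix, path) -> None:
    out = matrix.loci.copy()
    for j, sid in enumerate(matrix.samples["sample_id"]):
        out[f"{sid}_meth"] = matrix.meth[:, j]
        out[f"{sid}_unmeth"] = matrix.unmeth[:, j]
    out.to_csv(path, sep="\t", index=False)


def write_bedgraph(matrix: MethylMatrix, path) -> None:
    """5x-CpG track: destranded loci with pooled percent methylation."""
    pct = matrix.pooled_percent()
    out = pd.DataFrame({"chrom": matrix.loci["chrom"],
                        "start": matrix.loci["pos"] - 1,
                        "end": matrix.loci["pos"] + 1,
                        "value": np.round(pct, 4)})
    out.to_csv(path, sep="\t", header=False, index=False)
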