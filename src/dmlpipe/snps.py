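"""Bisulfite-aware C→T SNP screening from strand-resolved pileups.

Bisulfite conversion turns unmethylated C into T, so on the read strand a
T at a reference-C position is ambiguous: converted cytosine or C→T SNP.
The opposite strand disambiguates — a T paired with an adenine is a C→T
SNP, a T paired with a guanine is a converted unmethylated cytosine.
Calls therefore use only the opposite-strand A/(A+G) fraction; this-strand
T counts are never evidence of a variant.

The full Bayesian genotyper of BS-SNP callers is not reproduced: the
het/hom allele-fraction thresholds (0.1 / 0.85) mirror documented
defaults and coverage is taken on the informative (opposite) strand.
What matters downstream is the exclusion set of destranded CpG loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GENOTYPES = ("ref", "het_CT", "hom_CT")


@dataclass(frozen=True)
class SnpCall:
    chrom: str
    pos: int  # 1-based position of the reference C
    genotype: str
    alt_allele_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alt_allele_fraction <= 1.0:
            raise ValueError("alt_allele_fraction must be in [0, 1]")


@dataclass
class SnpSet:
    """C→T exclusion set: deduplicated 1-based cytosine positions."""

    positions: pd.DataFrame  # chrom, pos, genotype
    mode: str = "merged"

    def __post_init__(self) -> None:
        df = self.positions
        if len(df) == 0:
            self.positions = pd.DataFrame(
                {"chrom": pd.Series(dtype=str),
                 "pos": pd.Series(dtype=np.int64),
                 "genotype": pd.Series(dtype=str)})
            return
        df = df.drop_duplicates(["chrom", "pos"]).sort_values(
            ["chrom", "pos"]).reset_index(drop=True)
        self.positions = df

    def __len__(self) -> int:
        return len(self.positions)

    def position_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.positions[["chrom", "pos"]])


def call_site(opp_a: int, opp_g: int, min_cov: int = 5,
              het_min: float = 0.1, hom_min: float = 0.85) -> tuple[str, float]:
    """Genotype one reference-C site from opposite-strand A/G counts.

    Returns ``(genotype, alt_allele_fraction)``. Sites with informative
    coverage (A+G) below ``min_cov`` are left as ``ref`` — no call.
    """
    if opp_a < 0 or opp_g < 0:
        raise ValueError("negative base counts")
    cov = opp_a + opp_g
    if cov == 0:
        return "ref", 0.0
    f = opp_a / cov
    if cov < min_cov:
        return "ref", f
    if f >= hom_min:
        return "hom_CT", f
    if f >= het_min:
        return "het_CT", f
    return "ref", f


def call_pileup_table(pileups: pd.DataFrame, min_cov: int = 5,
                      het_min: float = 0.1, hom_min: float = 0.85
                      ) -> pd.DataFrame:
    """Vectorized :func:`call_site` over a pileup table."""
    a = pileups["opp_A"].to_numpy(np.int64)
    g = pileups["opp_G"].to_numpy(np.int64)
    if (a < 0).any() or (g < 0).any():
        raise ValueError("negative base counts")
    cov = a + g
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(cov > 0, a / np.maximum(cov, 1), 0.0)
    geno = np.full(len(pileups), "ref", dtype=object)
    callable_ = cov >= min_cov
    geno[callable_ & (f >= het_min)] = "het_CT"
    geno[callable_ & (f >= hom_min)] = "hom_CT"
    out = pileups[["chrom", "pos", "strand"]].copy()
    out["genotype"] = geno
    out["alt_allele_fraction"] = f
    out["informative_coverage"] = cov
    return out


def screen_genome(pileups_per_sample: dict[str, pd.DataFrame],
                  mode: str = "merged", min_cov: int = 5,
                  het_min: float = 0.1, hom_min: float = 0.85) -> SnpSet:
    """Screen all samples for C→T SNPs, merged or per sample.

    ``merged`` sums opposite-strand counts across samples before calling
    (deep coverage, but heterozygotes private to one sample are diluted);
    ``per_sample`` calls each sample independently and keeps any non-ref
    call. The returned set records its mode.
    """
    if mode not in ("merged", "per_sample"):
        raise ValueError(f"unknown mode {mode!r}")
    tables = list(pileups_per_sample.values())
    key = ["chrom", "pos", "strand"]
    base = tables[0][key]
    for t in tables[1:]:
        if len(t) != len(base) or not t[key].reset_index(drop=True).equals(
                base.reset_index(drop=True)):
            raise ValueError("pileup positions differ across samples")
    if mode == "merged":
        summed = base.copy()
        summed["opp_A"] = sum(t["opp_A"].to_numpy() for t in tables)
        summed["opp_G"] = sum(t["opp_G"].to_numpy() for t in tables)
        calls = call_pileup_table(summed, min_cov, het_min, hom_min)
        hits = calls[calls["genotype"] != "ref"]
    else:
        parts = []
        for t in tables:
            calls = call_pileup_table(t, min_cov, het_min, hom_min)
            parts.append(calls[calls["genotype"] != "ref"])
        hits = pd.concat(parts, ignore_index=True)
        # prefer the stronger genotype when samples disagree at a position
        hits = hits.sort_values("genotype").drop_duplicates(
            ["chrom", "pos"], keep="last")
    return SnpSet(hits[["chrom", "pos", "genotype"]].reset_index(drop=True),
                  mode=mode)


def union_snp_sets(*sets: SnpSet) -> SnpSet:
    """Position-wise union of C→T call sets (the exclusion set).

    When genotypes disagree at a position (het in one sample, hom when
    merged) a single exclusion entry is kept — hom wins, arbitrarily but
    reproducibly; exclusion only needs the position.
    """
    frames = [s.positions for s in sets if len(s)]
    modes = "+".join(dict.fromkeys(s.mode for s in sets))
    if not frames:
        return SnpSet(pd.DataFrame(columns=["chrom", "pos", "genotype"]),
                      mode=modes or "union")
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values("genotype").drop_duplicates(["chrom", "pos"],
                                                    keep="last")
    return SnpSet(df.reset_index(drop=True), mode=modes)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_snp_bed(snp_set: SnpSet, path) -> None:
    df = snp_set.positions
    out = pd.DataFrame({"chrom": df["chrom"], "start": df["pos"] - 1,
                        "end": df["pos"], "name": df["genotype"]})
    out.to_csv(path, sep="\t", header=False, index=False)


def write_snp_vcf(snp_set: SnpSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=dmlpipe snp_screen mode={snp_set.mode}\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in snp_set.positions.itertuples(index=False):
            gt = "1/1" if row.genotype == "hom_CT" else "0/1"
            fh.write(f"{row.chrom}\t{row.pos}\t.\tC\tT\t.\tPASS\tGT={gt}\n")


def read_snp_bed(path) -> SnpSet:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "genotype"])
    out = pd.DataFrame({"chrom": df["chrom"].astype(str),
                        "pos": df["end"].astype(np.int64),
                        "genotype": df["genotype"].astype(str)})
    return SnpSet(out)
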