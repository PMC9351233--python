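"""Strand-aware genomic interval algebra and feature-track derivation.

Coordinates are 0-based half-open internally (BED convention); GFF3 I/O
converts to/from 1-based closed. The derived tracks mirror the classic
bedtools recipe for building intron / exon-UTR / flank / intergenic
annotations from gene, exon and CDS tracks:

* intron      = gene ∩ complement(exon)
* exon_UTR    = exon ∖ CDS
* flank_up    = 1 kb upstream of each gene (strand-aware), minus gene bases
* flank_down  = 1 kb downstream, likewise
* intergenic  = complement(gene) ∖ (flank_up ∪ flank_down)
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start", "end", "strand", "name"]

FEATURE_CLASSES = (
    "gene", "exon", "CDS", "exon_UTR", "intron",
    "flank_up", "flank_down", "intergenic", "TE", "lncRNA", "mito",
)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open [start, end) interval on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "name": pd.Series(dtype=str),
        }
    )


@dataclass
class FeatureTrack:
    """A named collection of intervals of one feature class."""

    feature_class: str
    df: pd.DataFrame = field(default_factory=_empty_frame)

    def __post_init__(self) -> None:
        df = self.df
        if df is None or len(df) == 0:
            self.df = _empty_frame()
            return
        df = df.copy()
        if "strand" not in df.columns:
            df["strand"] = "."
        if "name" not in df.columns:
            df["name"] = ""
        df = df[INTERVAL_COLUMNS].astype(
            {"start": np.int64, "end": np.int64, "chrom": str}
        )
        if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
            bad = df[(df["start"] < 0) | (df["end"] <= df["start"])].iloc[0]
            raise ValueError(
                f"invalid interval {bad.chrom}:{bad.start}-{bad.end} "
                f"in {self.feature_class} track"
            )
        self.df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(row.chrom, int(row.start), int(row.end),
                                  row.strand, row.name)

    @classmethod
    def from_intervals(cls, feature_class: str, intervals) -> "FeatureTrack":
        rows = [
            (iv.chrom, iv.start, iv.end, iv.strand, iv.name) for iv in intervals
        ]
        return cls(feature_class, pd.DataFrame(rows, columns=INTERVAL_COLUMNS))

    def total_bases(self) -> int:
        m = merge(self)
        return int((m.df["end"] - m.df["start"]).sum())


def _check_bounds(track: FeatureTrack, chrom_sizes: dict[str, int]) -> None:
    for chrom, sub in track.df.groupby("chrom", sort=False):
        if chrom not in chrom_sizes:
            raise ValueError(f"chromosome {chrom!r} absent from size table")
        if (sub["end"] > chrom_sizes[chrom]).any():
            bad = sub[sub["end"] > chrom_sizes[chrom]].iloc[0]
            raise ValueError(
                f"interval {chrom}:{bad.start}-{bad.end} exceeds "
                f"chromosome length {chrom_sizes[chrom]}"
            )


# ---------------------------------------------------------------------------
# Core set algebra
# ---------------------------------------------------------------------------

def _merge_arrays(starts: np.ndarray, ends: np.ndarray):
    """Merge overlapping/adjacent sorted intervals; returns (starts, ends)."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def merge(track: FeatureTrack) -> FeatureTrack:
    """Union of a track's intervals: merged, sorted, strand discarded."""
    frames = []
    for chrom, sub in track.df.groupby("chrom", sort=True):
        s, e = _merge_arrays(sub["start"].to_numpy(), sub["end"].to_numpy())
        frames.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e}))
    if not frames:
        return FeatureTrack(track.feature_class)
    return FeatureTrack(track.feature_class, pd.concat(frames, ignore_index=True))


def complement(track: FeatureTrack, chrom_sizes: dict[str, int]) -> FeatureTrack:
    """Maximal intervals covering every base not in the merged input."""
    _check_bounds(track, chrom_sizes)
    merged = merge(track)
    frames = []
    for chrom, size in chrom_sizes.items():
        sub = merged.df[merged.df["chrom"] == chrom]
        bounds = np.concatenate([[0], sub[["start", "end"]].to_numpy().ravel(), [size]])
        starts, ends = bounds[::2], bounds[1::2]
        keep = starts < ends
        frames.append(
            pd.DataFrame({"chrom": chrom, "start": starts[keep], "end": ends[keep]})
        )
    out = pd.concat(frames, ignore_index=True) if frames else None
    return FeatureTrack(f"complement({track.feature_class})", out)


def _pairwise_op(a: FeatureTrack, b: FeatureTrack, keep_outside_b: bool,
                 name: str) -> FeatureTrack:
    """Base-wise a∩b (keep_outside_b=False) or a∖b (True), merged output."""
    a_m, b_m = merge(a), merge(b)
    frames = []
    for chrom, sub_a in a_m.df.groupby("chrom", sort=True):
        sub_b = b_m.df[b_m.df["chrom"] == chrom]
        # sweep over boundary points of b within each a interval
        bs = sub_b["start"].to_numpy()
        be = sub_b["end"].to_numpy()
        rows_s, rows_e = [], []
        for s, e in zip(sub_a["start"].to_numpy(), sub_a["end"].to_numpy()):
            lo = np.searchsorted(be, s, side="right")
            hi = np.searchsorted(bs, e, side="left")
            if keep_outside_b:
                cur = s
                for i in range(lo, hi):
                    if bs[i] > cur:
                        rows_s.append(cur)
                        rows_e.append(min(bs[i], e))
                    cur = max(cur, be[i])
                if cur < e:
                    rows_s.append(cur)
                    rows_e.append(e)
            else:
                for i in range(lo, hi):
                    rows_s.append(max(s, bs[i]))
                    rows_e.append(min(e, be[i]))
        if rows_s:
            frames.append(pd.DataFrame({"chrom": chrom, "start": rows_s,
                                        "end": rows_e}))
    out = pd.concat(frames, ignore_index=True) if frames else None
    return merge(FeatureTrack(name, out))


def intersect(a: FeatureTrack, b: FeatureTrack) -> FeatureTrack:
    """Base-wise set intersection of two tracks."""
    return _pairwise_op(a, b, False, f"{a.feature_class}&{b.feature_class}")


def subtract(a: FeatureTrack, b: FeatureTrack) -> FeatureTrack:
    """Base-wise a minus b."""
    return _pairwise_op(a, b, True, a.feature_class)


def union(*tracks: FeatureTrack, feature_class: str = "union") -> FeatureTrack:
    frames = [t.df for t in tracks if len(t)]
    if not frames:
        return FeatureTrack(feature_class)
    return merge(FeatureTrack(feature_class, pd.concat(frames, ignore_index=True)))


def flank(genes: FeatureTrack, chrom_sizes: dict[str, int], width: int = 1000,
          side: str = "up") -> FeatureTrack:
    """Strand-aware flanking windows of each gene, minus all gene bases.

    ``side="up"`` gives the window upstream of the transcription start
    (before start on + genes, after end on − genes); ``side="down"`` the
    opposite. Windows are clipped to chromosome bounds and gene bases are
    subtracted, so flanks never overlap genes (they may overlap each other
    and are merged within the class).
    """
    if width <= 0:
        raise ValueError("flank width must be positive")
    if side not in ("up", "down"):
        raise ValueError("side must be 'up' or 'down'")
    rows = []
    for row in genes.df.itertuples(index=False):
        before = (side == "up") == (row.strand != "-")
        if before:
            s, e = row.start - width, row.start
        else:
            s, e = row.end, row.end + width
        s = max(s, 0)
        e = min(e, chrom_sizes[row.chrom])
        if s < e:
            rows.append((row.chrom, s, e, row.strand, row.name))
    raw = FeatureTrack(f"flank_{side}",
                       pd.DataFrame(rows, columns=INTERVAL_COLUMNS))
    out = subtract(raw, genes)
    out.feature_class = f"flank_{side}"
    return out


# ---------------------------------------------------------------------------
# CG motifs
# ---------------------------------------------------------------------------

def find_cg_motifs(sequences: dict[str, str]) -> FeatureTrack:
    """Locate every CG dinucleotide on the plus strand, case-insensitive.

    Each motif is a [i, i+2) interval; a destranded CpG locus is the
    1-based position i+1 of the C.
    """
    frames = []
    for chrom, seq in sequences.items():
        starts = [m.start() for m in re.finditer("CG", seq.upper())]
        if starts:
            s = np.asarray(starts, dtype=np.int64)
            frames.append(pd.DataFrame({"chrom": chrom, "start": s, "end": s + 2}))
    out = pd.concat(frames, ignore_index=True) if frames else None
    return FeatureTrack("CG", out)


def count_cpgs_in_track(cg_track: FeatureTrack, feature: FeatureTrack) -> int:
    """Number of CG motifs overlapping the feature track by >= 1 base."""
    return int(overlaps_track(cg_track, feature).sum())


def overlaps_track(query: FeatureTrack, feature: FeatureTrack) -> np.ndarray:
    """Boolean mask: which query intervals overlap the feature by >= 1 base."""
    merged = merge(feature)
    mask = np.zeros(len(query), dtype=bool)
    df = query.df
    for chrom, sub in merged.df.groupby("chrom", sort=False):
        sel = (df["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        qs = df.loc[sel, "start"].to_numpy()
        qe = df.loc[sel, "end"].to_numpy()
        fs, fe = sub["start"].to_numpy(), sub["end"].to_numpy()
        # overlap iff some feature interval has start < qe and end > qs
        idx = np.searchsorted(fs, qe, side="left")  # features starting before qe
        hit = np.zeros(len(qs), dtype=bool)
        nonzero = idx > 0
        cummax_end = np.maximum.accumulate(fe)
        hit[nonzero] = cummax_end[idx[nonzero] - 1] > qs[nonzero]
        mask[np.flatnonzero(sel)] = hit
    return mask


# ---------------------------------------------------------------------------
# Derived feature tracks
# ---------------------------------------------------------------------------

def build_feature_tracks(gene: FeatureTrack, exon: FeatureTrack,
                         cds: FeatureTrack, chrom_sizes: dict[str, int],
                         flank_width: int = 1000,
                         extra: dict[str, FeatureTrack] | None = None,
                         ) -> dict[str, FeatureTrack]:
    """Derive the full feature-track set from gene/exon/CDS annotation.

    Raises ``ValueError`` naming the offending interval when the nesting
    CDS ⊆ exon ⊆ gene is violated.
    """
    for inner, outer, what in ((exon, gene, "exon within gene"),
                               (cds, exon, "CDS within exon")):
        stray = subtract(inner, outer)
        if len(stray):
            bad = stray.df.iloc[0]
            raise ValueError(
                f"nesting violated ({what}): {bad.chrom}:{bad.start}-{bad.end}"
            )
    intron = intersect(gene, complement(exon, chrom_sizes))
    intron.feature_class = "intron"
    exon_utr = subtract(exon, cds)
    exon_utr.feature_class = "exon_UTR"
    flank_up = flank(gene, chrom_sizes, flank_width, "up")
    flank_down = flank(gene, chrom_sizes, flank_width, "down")
    intergenic = subtract(complement(gene, chrom_sizes),
                          union(flank_up, flank_down))
    intergenic.feature_class = "intergenic"
    tracks = {
        "gene": gene, "exon": exon, "CDS": cds, "intron": intron,
        "exon_UTR": exon_utr, "flank_up": flank_up, "flank_down": flank_down,
        "intergenic": intergenic,
    }
    if extra:
        tracks.update(extra)
    return tracks


# ---------------------------------------------------------------------------
# I/O: BED, GFF3, chromosome sizes
# ---------------------------------------------------------------------------

def read_bed(path, feature_class: str = "bed") -> FeatureTrack:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    df["name"] = df[3] if 3 in df.columns else ""
    df["strand"] = df[5] if 5 in df.columns else "."
    return FeatureTrack(feature_class, df[INTERVAL_COLUMNS])


def write_bed(track: FeatureTrack, path) -> None:
    df = track.df.copy()
    df["name"] = df["name"].replace("", ".")
    df["score"] = 0
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


_ATTR_RE = re.compile(r"(\w+)=([^;]+)")


def read_gff3(path) -> dict[str, FeatureTrack]:
    """Read gene/exon/CDS/lnc_RNA features from a GFF3 file.

    Returns tracks keyed by feature class; ``name`` holds the feature ID
    (gene) or Parent (exon/CDS), so derived tables can group by gene.
    """
    rows: dict[str, list] = {"gene": [], "exon": [], "CDS": [], "lncRNA": []}
    type_map = {"gene": "gene", "exon": "exon", "CDS": "CDS",
                "lnc_RNA": "lncRNA", "lncRNA": "lncRNA"}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in type_map:
                continue
            attrs = dict(_ATTR_RE.findall(f[8]))
            name = attrs.get("ID") if f[2] == "gene" else attrs.get(
                "Parent", attrs.get("ID", ""))
            rows[type_map[f[2]]].append(
                (f[0], int(f[3]) - 1, int(f[4]), f[6], name or "")
            )
    return {
        cls: FeatureTrack(cls, pd.DataFrame(r, columns=INTERVAL_COLUMNS))
        for cls, r in rows.items()
    }


def write_gff3(tracks: dict[str, FeatureTrack], path) -> None:
    type_map = {"gene": "gene", "exon": "exon", "CDS": "CDS", "lncRNA": "lnc_RNA"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cls, track in tracks.items():
            gff_type = type_map.get(cls, cls)
            for row in track.df.itertuples(index=False):
                key = "ID" if cls == "gene" else "Parent"
                attr = f"{key}={row.name}" if row.name else "."
                fh.write(
                    f"{row.chrom}\tdmlpipe\t{gff_type}\t{row.start + 1}\t"
                    f"{row.end}\t.\t{row.strand}\t.\t{attr}\n"
                )


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_chrom_sizes(chrom_sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
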