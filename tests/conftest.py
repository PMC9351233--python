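import numpy as np
import pandas as pd
import pytest

from dmlpipe import SimConfig, simulate_dataset
from dmlpipe.intervals import FeatureTrack, INTERVAL_COLUMNS


def make_track(cls, rows):
    """rows: (chrom, start, end[, strand[, name]]) tuples."""
    full = [tuple(r) + (".", "")[len(r) - 3:] if len(r) < 5 else tuple(r)
            for r in rows]
    return FeatureTrack(cls, pd.DataFrame(full, columns=INTERVAL_COLUMNS))


@pytest.fixture(scope="session")
def toy_annotation():
    """The worked example: one + strand gene [100, 400) with two exons
    [100,200), [300,400) and CDS [150,200), [300,350)."""
    gene = make_track("gene", [("chr1", 100, 400, "+", "geneA")])
    exon = make_track("exon", [("chr1", 100, 200, "+", "geneA"),
                               ("chr1", 300, 400, "+", "geneA")])
    cds = make_track("CDS", [("chr1", 150, 200, "+", "geneA"),
                             ("chr1", 300, 350, "+", "geneA")])
    return {"gene": gene, "exon": exon, "CDS": cds,
            "sizes": {"chr1": 10_000}}


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(genome_length_per_chrom=20_000, n_chroms=2, seed=11,
                     error_rate=0.0)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


def brute_force_mask(track, chrom_sizes):
    """Independent base-wise oracle: one boolean array per chromosome."""
    masks = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    for row in track.df.itertuples(index=False):
        masks[row.chrom][row.start:row.end] = True
    return masks


def mask_to_intervals(masks):
    """Maximal intervals of each mask, as a sorted (chrom,start,end) list."""
    out = []
    for chrom in sorted(masks):
        m = masks[chrom]
        padded = np.concatenate([[False], m, [False]]).astype(np.int8)
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return out


def track_tuples(track):
    return [(r.chrom, int(r.start), int(r.end))
            for r in track.df.itertuples(index=False)]
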