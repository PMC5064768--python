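"""Repeat-class expression quantitation (RPKM) with gene-proximity exclusion.

Repeat instances within 2 kb of an annotated gene body are removed so
genic transcription does not bleed into TE expression estimates. Reads
are then assigned to repeat classes by non-directional (>=1 bp) overlap;
class counts are corrected for the total length of all instances of the
class and the library size, giving RPKM.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import intervals
from .core_io import GeneModel, RepeatInstance, repeats_to_frame


def exclude_near_genes(
    repeats: Sequence[RepeatInstance],
    genes: Sequence[GeneModel],
    distance_bp: int = 2000,
) -> list[RepeatInstance]:
    """Drop repeat instances within `distance_bp` of any gene body.

    The distance is the gap between the repeat interval and the gene tx
    span (overlap counts as distance 0, hence within). An instance
    exactly `distance_bp` away is removed; one bp further is kept.
    """
    repeats = list(repeats)
    if not repeats or not genes:
        return repeats
    rdf = repeats_to_frame(repeats)
    bodies = pd.DataFrame(
        [(g.chrom, g.tx_start, g.tx_end) for g in genes],
        columns=["chrom", "start", "end"],
    )
    merged = {
        c: intervals.merge(sub["start"].to_numpy(), sub["end"].to_numpy())
        for c, sub in bodies.groupby("chrom", sort=False)
    }
    keep = np.ones(len(rdf), dtype=bool)
    row_idx = np.arange(len(rdf))
    for chrom, sub in rdf.assign(_row=row_idx).groupby("chrom", sort=False):
        if chrom not in merged:
            continue
        ts, te = merged[chrom]
        gap = intervals.gap_to_nearest(
            sub["start"].to_numpy(), sub["end"].to_numpy(), ts, te
        )
        keep[sub["_row"].to_numpy()] = gap > distance_bp
    return [r for r, k in zip(repeats, keep) if k]


def repeat_rpkm(
    reads: pd.DataFrame,
    repeats: Sequence[RepeatInstance],
    library_size: int,
) -> pd.DataFrame:
    """Repeat-class RPKM from mapped reads.

    `reads` is a BED6-like frame (chrom, start, end[, name, score,
    strand]); strand is ignored. A read counts once toward every class it
    overlaps (>=1 bp with any instance of that class), but only once per
    class however many instances it touches. RPKM = count /
    (class_length_kb * library_millions) with class length the summed
    length of all instances.
    """
    repeats = list(repeats)
    if not repeats:
        raise ValueError("empty repeat list")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    rdf = repeats_to_frame(repeats)
    rows = []
    for cls, sub in rdf.groupby("repeat_class", sort=True):
        hit = intervals.overlap_mask(reads, sub[["chrom", "start", "end"]])
        count = int(hit.sum())
        length = int((sub["end"] - sub["start"]).sum())
        rpkm = count / (length / 1000.0) / (library_size / 1e6)
        rows.append((cls, count, length, library_size, rpkm))
    return pd.DataFrame(
        rows, columns=["repeat_class", "count", "length_bp", "library_size", "rpkm"]
    )
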