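"""Vectorized interval primitives on 0-based half-open coordinates.

All functions operate on numpy arrays of starts/ends for a single
chromosome. Callers are expected to group by chromosome first (see
:func:`by_chrom`). Merged-interval queries rely on the target set being
sorted and non-overlapping, which :func:`merge` guarantees.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
import pandas as pd


def merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping or bookended intervals; returns sorted disjoint set."""
    if len(starts) == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    s = np.asarray(starts, dtype=np.int64)[order]
    e = np.asarray(ends, dtype=np.int64)[order]
    out_s = [s[0]]
    out_e = [e[0]]
    for i in range(1, len(s)):
        if s[i] <= out_e[-1]:
            if e[i] > out_e[-1]:
                out_e[-1] = e[i]
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def overlaps_any(
    q_starts: np.ndarray,
    q_ends: np.ndarray,
    t_starts: np.ndarray,
    t_ends: np.ndarray,
) -> np.ndarray:
    """Boolean array: does each query overlap (>=1 bp) any target interval?

    Targets must be merged (sorted, disjoint).
    """
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    if len(t_starts) == 0 or len(q_starts) == 0:
        return np.zeros(len(q_starts), dtype=bool)
    # candidate target: the last one starting before the query end
    idx = np.searchsorted(t_starts, q_ends, side="left") - 1
    hit = idx >= 0
    safe = np.where(hit, idx, 0)
    hit &= t_ends[safe] > q_starts
    return hit


def gap_to_nearest(
    q_starts: np.ndarray,
    q_ends: np.ndarray,
    t_starts: np.ndarray,
    t_ends: np.ndarray,
) -> np.ndarray:
    """Gap in bp between each query and its nearest target interval.

    Overlapping intervals have gap 0; adjacent half-open intervals
    ([0,10) vs [10,20)) also have gap 0. Targets must be merged. Returns
    a large sentinel (2**62) when there are no targets on the chromosome.
    """
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    n = len(q_starts)
    if len(t_starts) == 0:
        return np.full(n, 2**62, dtype=np.int64)
    # gap to the nearest target on the left (target end <= query start side)
    idx_l = np.searchsorted(t_ends, q_starts, side="right") - 1
    left = np.where(idx_l >= 0, q_starts - t_ends[np.maximum(idx_l, 0)], 2**62)
    # gap to the nearest target on the right
    idx_r = np.searchsorted(t_starts, q_ends, side="left")
    right = np.where(
        idx_r < len(t_starts),
        t_starts[np.minimum(idx_r, len(t_starts) - 1)] - q_ends,
        2**62,
    )
    gap = np.minimum(np.maximum(left, 0), np.maximum(right, 0))
    gap[overlaps_any(q_starts, q_ends, t_starts, t_ends)] = 0
    return gap


def by_chrom(df: pd.DataFrame) -> Iterator[tuple[str, pd.DataFrame]]:
    """Group an interval DataFrame by its 'chrom' column."""
    for chrom, sub in df.groupby("chrom", sort=True):
        yield str(chrom), sub


def overlap_mask(query: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Per-row boolean overlap (>=1 bp) of `query` against `targets`.

    Both are DataFrames with chrom/start/end columns. Targets are merged
    per chromosome internally.
    """
    mask = np.zeros(len(query), dtype=bool)
    if len(targets) == 0 or len(query) == 0:
        return mask
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in by_chrom(targets):
        merged[chrom] = merge(sub["start"].to_numpy(), sub["end"].to_numpy())
    positions = np.arange(len(query))
    for chrom, sub in query.assign(_row=positions).groupby("chrom", sort=False):
        if chrom not in merged:
            continue
        ts, te = merged[chrom]
        hit = overlaps_any(sub["start"].to_numpy(), sub["end"].to_numpy(), ts, te)
        mask[sub["_row"].to_numpy()] = hit
    return mask
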