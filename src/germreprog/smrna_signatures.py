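"""piRNA signature statistics on mapped small-RNA reads.

Reads are first partitioned by a fixed annotation hierarchy
(rRNA > miRNA > piRNA_gene > repeat > gene > unannotated), emulating the
usual sequential exclusion mapping (rRNA and miRNA removed first, the
remainder matched against repeats) in a single labeling pass. Signature
statistics then run on the repeat-derived fraction:

* length spectra (18-35 nt), optionally split by sense/antisense relative
  to the annotated repeat strand;
* 5'-end nucleotide composition in a +/-30 nt genomic window, where
  position +1 is the read's first nucleotide (minus-strand reads are
  reverse-complemented);
* the ping-pong signature — the histogram of 5'-5' overlap distances
  between opposite-strand read pairs, summarized by the z-score of the
  10-nt bin against all other bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import intervals
from .core_io import FeatureSet, SmallRNAReadSet

CLASS_HIERARCHY = ["rRNA", "miRNA", "piRNA_gene", "repeat", "gene"]
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_reads(
    reads: SmallRNAReadSet,
    annotations: Mapping[str, FeatureSet],
) -> SmallRNAReadSet:
    """Assign each read the first class in the hierarchy it overlaps.

    `annotations` maps class names (any subset of rRNA, miRNA,
    piRNA_gene, repeat, gene) to interval sets; a missing or empty set
    simply leaves that class unused. Reads overlapping nothing are
    'unannotated'. Match = >=1 bp overlap, strand-agnostic.
    """
    df = reads.reads.copy()
    labels = np.full(len(df), "unannotated", dtype=object)
    unassigned = np.ones(len(df), dtype=bool)
    for cls in CLASS_HIERARCHY:
        fs = annotations.get(cls)
        if fs is None or len(fs) == 0 or not unassigned.any():
            continue
        hit = intervals.overlap_mask(df[["chrom", "start", "end"]], fs.df)
        take = hit & unassigned
        labels[take] = cls
        unassigned &= ~hit
    df["class_label"] = labels
    return SmallRNAReadSet(reads=df)


def length_distribution(
    classified: SmallRNAReadSet,
    exclude: set[str] = frozenset({"rRNA"}),
    unique_only: bool = True,
    by_repeat_strand: bool = False,
    repeats: FeatureSet | None = None,
    min_len: int = 18,
    max_len: int = 35,
) -> pd.DataFrame:
    """Read-length histogram over `min_len`..`max_len` nt.

    With by_repeat_strand=True only repeat-class reads are counted, split
    into sense/antisense by comparing the read strand to the strand of
    the overlapped repeat (largest-overlap repeat wins when several
    overlap; same strand = sense). Requires `repeats` in that mode.
    """
    df = classified.reads
    df = df[~df["class_label"].isin(exclude)]
    if unique_only:
        df = df[df["unique"]]
    lengths = np.arange(min_len, max_len + 1)
    if not by_repeat_strand:
        counts = df["seq"].str.len().value_counts()
        out = pd.DataFrame(
            {"length": lengths, "count": [int(counts.get(l, 0)) for l in lengths]}
        )
        return out
    if repeats is None:
        raise ValueError("by_repeat_strand requires the repeat annotation")
    df = df[df["class_label"] == "repeat"]
    sense = np.zeros(len(lengths), dtype=np.int64)
    anti = np.zeros(len(lengths), dtype=np.int64)
    rep_by_chrom = {c: sub.sort_values("start") for c, sub in repeats.df.groupby("chrom")}
    for r in df.itertuples(index=False):
        sub = rep_by_chrom.get(r.chrom)
        if sub is None:
            continue
        ov_start = np.maximum(sub["start"].to_numpy(), r.start)
        ov_end = np.minimum(sub["end"].to_numpy(), r.end)
        ov = ov_end - ov_start
        if ov.max() <= 0:
            continue
        rep_strand = sub["strand"].to_numpy()[int(np.argmax(ov))]
        L = len(r.seq)
        if L < min_len or L > max_len:
            continue
        if rep_strand == r.strand:
            sense[L - min_len] += 1
        else:
            anti[L - min_len] += 1
    return pd.DataFrame({"length": lengths, "sense": sense, "antisense": anti})


def five_prime_composition(
    classified: SmallRNAReadSet,
    genome: Mapping[str, str],
    window: int = 30,
    class_label: str = "repeat",
    unique_only: bool = True,
) -> pd.DataFrame:
    """Base frequencies around read 5' ends (+/-`window` nt).

    Position +1 is the read's first nucleotide; upstream positions are
    -1..-window (no position 0). Minus-strand reads use the reverse
    complement so the window reads in the read's own orientation.
    Positions truncated at chromosome ends are excluded from that
    column's normalization. Returns a frame indexed by position with
    columns A, C, G, T.
    """
    df = classified.reads
    df = df[df["class_label"] == class_label]
    if unique_only:
        df = df[df["unique"]]
    positions = [p for p in range(-window, window + 1) if p != 0]
    counts = {b: np.zeros(len(positions), dtype=np.int64) for b in "ACGT"}
    denom = np.zeros(len(positions), dtype=np.int64)
    for r in df.itertuples(index=False):
        if r.chrom not in genome:
            raise KeyError(f"missing chromosome sequence: {r.chrom}")
        seq = genome[r.chrom]
        clen = len(seq)
        if r.strand == "+":
            p5 = r.start
            lo, hi = p5 - window, p5 + window  # genomic [lo, hi)
            frag = seq[max(0, lo) : min(clen, hi)].upper()
            pad_l = max(0, -lo)
            pad_r = max(0, hi - clen)
            win = "N" * pad_l + frag + "N" * pad_r
        else:
            p5 = r.end - 1
            lo, hi = p5 - window + 1, p5 + window + 1
            frag = seq[max(0, lo) : min(clen, hi)].upper()
            pad_l = max(0, -lo)
            pad_r = max(0, hi - clen)
            win = _revcomp("N" * pad_l + frag + "N" * pad_r)
        # win has 2*window chars: window upstream then window from the 5' end
        for i, base in enumerate(win):
            if base in counts:
                counts[base][i] += 1
                denom[i] += 1
    out = pd.DataFrame({b: counts[b] for b in "ACGT"}, index=positions)
    out.index.name = "position"
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = out.div(pd.Series(denom, index=positions).where(lambda s: s > 0), axis=0)
    freq["n"] = denom
    return freq


@dataclass
class PingPongProfile:
    """5'-5' overlap histogram between opposite-strand reads."""

    counts: pd.Series  # index d=1..d_max
    n_pairs: int

    @property
    def z10(self) -> float:
        """z-score of the 10-nt bin against all other bins (their mean/sd)."""
        c = self.counts
        others = c[c.index != 10].to_numpy(dtype=float)
        sd = others.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            return float("nan")
        return float((c.loc[10] - others.mean()) / sd)

    def cpm(self) -> pd.Series:
        """Counts per million pairs (histogram normalization)."""
        total = self.counts.sum()
        if total == 0:
            return self.counts.astype(float)
        return 1e6 * self.counts / total


def pingpong_profile(
    classified: SmallRNAReadSet,
    d_max: int = 30,
    class_label: str = "repeat",
    unique_only: bool = True,
    weighted: bool = False,
) -> PingPongProfile:
    """Ping-pong 5'-5' overlap histogram for repeat-derived reads.

    Pairs are opposite-strand reads on the same chromosome; the 5' end of
    a minus-strand read is its highest genomic coordinate. For a plus
    read with 5' at p+ and a minus read with 5' at p-, the overlap is
    d = p- - p+ + 1; pairs with 1 <= d <= d_max are counted. By default
    each distinct genomic position pair of reads counts once per read
    pair (unweighted by multiplicity); weighted=True multiplies by the
    number of reads sharing each 5' position.
    """
    df = classified.reads
    if class_label is not None:
        df = df[df["class_label"] == class_label]
    if unique_only:
        df = df[df["unique"]]
    counts = np.zeros(d_max, dtype=np.int64)
    n_pairs = 0
    for chrom, sub in df.groupby("chrom", sort=False):
        plus = sub.loc[sub["strand"] == "+", "start"].to_numpy()
        minus = (sub.loc[sub["strand"] == "-", "end"].to_numpy()) - 1
        if len(plus) == 0 or len(minus) == 0:
            continue
        if weighted:
            m_pos, m_mult = np.unique(minus, return_counts=True)
            p_pos, p_mult = np.unique(plus, return_counts=True)
        else:
            m_pos = np.unique(minus)
            m_mult = np.ones(len(m_pos), dtype=np.int64)
            p_pos = np.unique(plus)
            p_mult = np.ones(len(p_pos), dtype=np.int64)
        lookup = dict(zip(m_pos.tolist(), m_mult.tolist()))
        for p, pm in zip(p_pos.tolist(), p_mult.tolist()):
            for d in range(1, d_max + 1):
                mm = lookup.get(p + d - 1)
                if mm:
                    counts[d - 1] += pm * mm
                    n_pairs += pm * mm
    series = pd.Series(counts, index=pd.RangeIndex(1, d_max + 1, name="overlap"))
    return PingPongProfile(counts=series, n_pairs=int(n_pairs))


def class_counts(classified: SmallRNAReadSet) -> pd.Series:
    """Reads per class (partition check: sums to the total)."""
    return classified.reads["class_label"].value_counts()
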