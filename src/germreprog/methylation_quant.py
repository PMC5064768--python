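"""Probe construction and weighted methylation quantitation.

Methylation over a region is the *weighted* (call-pooled) fraction:
sum of methylated calls over all covered CpGs divided by the sum of all
calls, so deeply covered CpGs contribute proportionally more. An
unweighted mean-of-CpG-fractions variant is available via
``weighted=False`` where noted.

Probes come in two flavors mirroring common WGBS practice:

* tiling — fixed-width windows laid consecutively along each chromosome
  (e.g. 20-kb global probes, 2-kb clustering probes, 1-kb/500-bp metagene
  windows); trailing partial windows are dropped so probe length stays
  constant;
* cpg_count — windows spanning consecutive runs of exactly ``n_cpg`` CpGs
  (e.g. 50-CpG scatter probes), built from the union of CpG positions
  covered in all compared samples so probe definitions are shared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import intervals
from .core_io import CpGCallSet, FeatureSet, GeneModel, GenomeIndex, RepeatInstance, repeats_to_frame

logger = logging.getLogger(__name__)


@dataclass
class ProbeSet:
    """Genomic windows over which methylation is quantitated."""

    mode: str  # 'tiling' | 'cpg_count'
    params: dict
    df: pd.DataFrame  # probe_id, chrom, start, end
    note: str = ""

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class MethMatrix:
    """Probe x sample weighted methylation fractions with coverage metadata.

    Fractions are NaN (missing) where a probe has fewer covered CpGs than
    the quantitation threshold in that sample.
    """

    probes: pd.DataFrame
    samples: list[str]
    fractions: pd.DataFrame  # index probe_id, columns samples
    total_calls: pd.DataFrame
    covered_cpgs: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        out = self.probes.set_index("probe_id").copy()
        for s in self.samples:
            out[s] = self.fractions[s]
            out[f"{s}_cpgs"] = self.covered_cpgs[s]
        return out


def make_probes(
    genome: GenomeIndex,
    calls: Sequence[CpGCallSet] | None = None,
    mode: str = "tiling",
    width: int = 20_000,
    step: int | None = None,
    n_cpg: int = 50,
    exclude: FeatureSet | None = None,
) -> ProbeSet:
    """Build a ProbeSet.

    tiling: windows [i*step, i*step+width) wholly inside each chromosome
    (trailing partial windows dropped). cpg_count: consecutive blocks of
    exactly n_cpg CpGs from the union of positions across `calls`; a
    window spans first CpG to last CpG inclusive (half-open end =
    last_pos + 1); the final partial block is dropped. Probes overlapping
    `exclude` by >=1 bp are removed.
    """
    rows = []
    if mode == "tiling":
        if width <= 0:
            raise ValueError("probe width must be positive")
        step = width if step is None else step
        if step <= 0:
            raise ValueError("probe step must be positive")
        for chrom in genome.chroms:
            length = genome[chrom]
            starts = np.arange(0, length - width + 1, step, dtype=np.int64)
            for s in starts:
                rows.append((chrom, int(s), int(s + width)))
    elif mode == "cpg_count":
        if n_cpg <= 0:
            raise ValueError("n_cpg must be positive")
        if not calls:
            raise ValueError("cpg_count probes require CpG call sets")
        union: dict[str, np.ndarray] = {}
        for cs in calls:
            for chrom, sub in cs.records.groupby("chrom", sort=True):
                pos = sub["pos"].to_numpy()
                union[chrom] = (
                    np.union1d(union[chrom], pos) if chrom in union else np.asarray(pos)
                )
        for chrom in genome.chroms:
            pos = union.get(chrom)
            if pos is None:
                continue
            n_full = len(pos) // n_cpg
            for i in range(n_full):
                block = pos[i * n_cpg : (i + 1) * n_cpg]
                rows.append((chrom, int(block[0]), int(block[-1]) + 1))
    else:
        raise ValueError(f"unknown probe mode {mode!r}")

    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    note = ""
    if exclude is not None and len(exclude) and len(df):
        hit = intervals.overlap_mask(df, exclude.df)
        df = df[~hit].reset_index(drop=True)
        note = f"excluded {int(hit.sum())} probes overlapping {len(exclude)} intervals"
    df.insert(0, "probe_id", [f"p{i:07d}" for i in range(len(df))])
    params = {"width": width, "step": step} if mode == "tiling" else {"n_cpg": n_cpg}
    return ProbeSet(mode=mode, params=params, df=df, note=note)


def _probe_sums(
    probes: pd.DataFrame, calls: CpGCallSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-probe (meth, total, n_cpg) sums via cumulative-sum range queries."""
    meth_out = np.zeros(len(probes), dtype=np.int64)
    total_out = np.zeros(len(probes), dtype=np.int64)
    ncpg_out = np.zeros(len(probes), dtype=np.int64)
    grouped = {c: sub for c, sub in calls.records.groupby("chrom", sort=False)}
    row_idx = np.arange(len(probes))
    for chrom, sub in probes.assign(_row=row_idx).groupby("chrom", sort=False):
        rec = grouped.get(chrom)
        if rec is None:
            continue
        pos = rec["pos"].to_numpy()
        cmeth = np.concatenate([[0], np.cumsum(rec["meth"].to_numpy())])
        ctot = np.concatenate([[0], np.cumsum((rec["meth"] + rec["unmeth"]).to_numpy())])
        lo = np.searchsorted(pos, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, sub["end"].to_numpy(), side="left")
        r = sub["_row"].to_numpy()
        meth_out[r] = cmeth[hi] - cmeth[lo]
        total_out[r] = ctot[hi] - ctot[lo]
        ncpg_out[r] = hi - lo
    return meth_out, total_out, ncpg_out


def quantify_probes(
    probes: ProbeSet,
    calls: Sequence[CpGCallSet],
    min_cpg: int = 10,
    weighted: bool = True,
) -> MethMatrix:
    """Quantitate weighted methylation of every probe in every sample.

    A CpG belongs to a probe iff pos in [start, end). Probes with fewer
    than `min_cpg` covered CpGs in a sample are missing (NaN) there.
    """
    if len(probes) == 0:
        raise ValueError("empty probe set")
    if min_cpg < 1:
        raise ValueError("min_cpg must be >= 1")
    idx = probes.df["probe_id"]
    fractions = {}
    totals = {}
    covered = {}
    for cs in calls:
        if weighted:
            meth, total, ncpg = _probe_sums(probes.df, cs)
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(total > 0, meth / np.maximum(total, 1), np.nan)
        else:
            frac, total, ncpg = _unweighted_probe_fracs(probes.df, cs)
        frac = np.where(ncpg >= min_cpg, frac, np.nan)
        fractions[cs.sample_id] = frac
        totals[cs.sample_id] = total
        covered[cs.sample_id] = ncpg
    samples = [cs.sample_id for cs in calls]
    return MethMatrix(
        probes=probes.df,
        samples=samples,
        fractions=pd.DataFrame(fractions, index=idx),
        total_calls=pd.DataFrame(totals, index=idx),
        covered_cpgs=pd.DataFrame(covered, index=idx),
    )


def _unweighted_probe_fracs(probes: pd.DataFrame, calls: CpGCallSet):
    """Mean of per-CpG fractions per probe (coverage-unweighted variant)."""
    frac_out = np.full(len(probes), np.nan)
    total_out = np.zeros(len(probes), dtype=np.int64)
    ncpg_out = np.zeros(len(probes), dtype=np.int64)
    grouped = {c: sub for c, sub in calls.records.groupby("chrom", sort=False)}
    row_idx = np.arange(len(probes))
    for chrom, sub in probes.assign(_row=row_idx).groupby("chrom", sort=False):
        rec = grouped.get(chrom)
        if rec is None:
            continue
        pos = rec["pos"].to_numpy()
        tot = (rec["meth"] + rec["unmeth"]).to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(tot > 0, rec["meth"].to_numpy() / np.maximum(tot, 1), np.nan)
        cfrac = np.concatenate([[0.0], np.cumsum(np.nan_to_num(f))])
        cn = np.concatenate([[0], np.cumsum(~np.isnan(f))])
        ctot = np.concatenate([[0], np.cumsum(tot)])
        lo = np.searchsorted(pos, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, sub["end"].to_numpy(), side="left")
        r = sub["_row"].to_numpy()
        n = cn[hi] - cn[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_out[r] = np.where(n > 0, (cfrac[hi] - cfrac[lo]) / np.maximum(n, 1), np.nan)
        total_out[r] = ctot[hi] - ctot[lo]
        ncpg_out[r] = hi - lo
    return frac_out, total_out, ncpg_out


def classify_promoters(
    genes: Sequence[GeneModel],
    cgis: FeatureSet,
    upstream_bp: int = 1000,
    cgi_margin_bp: int = 250,
) -> FeatureSet:
    """Strand-aware promoters labeled CGI_promoter / nonCGI_promoter.

    The promoter is the `upstream_bp` window upstream of the TSS. It is a
    CGI promoter if it contains, overlaps, or lies within `cgi_margin_bp`
    of any CpG island.
    """
    rows = []
    for g in genes:
        if g.strand == "+":
            start, end = max(0, g.tss - upstream_bp), g.tss
        else:
            start, end = g.tss, g.tss + upstream_bp
        if start >= end:
            continue
        rows.append((g.chrom, start, end, g.strand, g.gene_id))
    prom = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "name"])
    labels = np.full(len(prom), "nonCGI_promoter", dtype=object)
    cgi_by_chrom = {c: sub for c, sub in cgis.df.groupby("chrom", sort=False)}
    for i, r in enumerate(prom.itertuples(index=False)):
        sub = cgi_by_chrom.get(r.chrom)
        if sub is None:
            continue
        gap = intervals.gap_to_nearest(
            np.array([r.start]),
            np.array([r.end]),
            *intervals.merge(sub["start"].to_numpy(), sub["end"].to_numpy()),
        )[0]
        if gap <= cgi_margin_bp:
            labels[i] = "CGI_promoter"
    prom["feature_class"] = labels
    return FeatureSet(prom)


def gene_body_complement(genes: Sequence[GeneModel], genome: GenomeIndex) -> FeatureSet:
    """Intergenic space: complement of gene bodies (tx spans) only."""
    rows = []
    bodies = pd.DataFrame(
        [(g.chrom, g.tx_start, g.tx_end) for g in genes], columns=["chrom", "start", "end"]
    )
    for chrom in genome.chroms:
        sub = bodies[bodies["chrom"] == chrom]
        ms, me = intervals.merge(sub["start"].to_numpy(), sub["end"].to_numpy())
        prev = 0
        for s, e in zip(ms, me):
            if s > prev:
                rows.append((chrom, prev, int(s)))
            prev = int(e)
        if prev < genome[chrom]:
            rows.append((chrom, prev, genome[chrom]))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["feature_class"] = "intergenic"
    return FeatureSet(df)


def _pooled_fraction(feat_df: pd.DataFrame, calls: CpGCallSet) -> tuple[float, int, int]:
    """Call-weighted fraction over the union of a feature set's intervals."""
    merged_rows = []
    for chrom, sub in feat_df.groupby("chrom", sort=False):
        ms, me = intervals.merge(sub["start"].to_numpy(), sub["end"].to_numpy())
        for s, e in zip(ms, me):
            merged_rows.append((chrom, int(s), int(e)))
    mdf = pd.DataFrame(merged_rows, columns=["chrom", "start", "end"])
    meth, total, ncpg = _probe_sums(mdf, calls)
    tot = int(total.sum())
    if tot == 0:
        return float("nan"), 0, int(ncpg.sum())
    return float(meth.sum() / tot), tot, int(ncpg.sum())


def feature_methylation(
    feature_sets: dict[str, FeatureSet], calls: Sequence[CpGCallSet]
) -> pd.DataFrame:
    """Pooled methylation per feature class per sample.

    Overlapping intervals within a class are merged first so no CpG is
    double counted. Classes with zero covered calls are reported as NaN,
    not zero. Returns a tidy frame: feature_class, sample, meth_fraction,
    total_calls, covered_cpgs.
    """
    rows = []
    for cls, fs in feature_sets.items():
        for cs in calls:
            frac, tot, ncpg = _pooled_fraction(fs.df, cs)
            rows.append((cls, cs.sample_id, frac, tot, ncpg))
    return pd.DataFrame(
        rows, columns=["feature_class", "sample", "meth_fraction", "total_calls", "covered_cpgs"]
    )


def dmr_panel_methylation(dmrs: FeatureSet, calls: Sequence[CpGCallSet]) -> pd.DataFrame:
    """Imprinted-DMR panel methylation: maternal, paternal and combined.

    The combined value pools calls over the whole panel, so a panel with
    fully methylated maternal and unmethylated paternal DMRs sits near 0.5
    until erasure.
    """
    panels = {
        "DMR_maternal": dmrs.subset(dmrs.df["feature_class"] == "maternal"),
        "DMR_paternal": dmrs.subset(dmrs.df["feature_class"] == "paternal"),
        "DMR_combined": dmrs,
    }
    panels = {k: v for k, v in panels.items() if len(v)}
    return feature_methylation(panels, calls)


def metagene_profile(
    genes: Sequence[GeneModel],
    calls: CpGCallSet,
    flank_bp: int = 5000,
    win_bp: int = 1000,
    step_bp: int = 500,
    body_bins: int = 40,
) -> pd.DataFrame:
    """Average methylation profile over flanks and scaled gene bodies.

    Flanks are tiled with `win_bp` windows at `step_bp` steps (9 windows
    per side at the 5-kb/1-kb/500-bp defaults); gene bodies are scaled to
    `body_bins` equal bins. Genes shorter than `body_bins` bp are skipped.
    All genes are oriented TSS->TES, so minus-strand genes are flipped.
    Per-bin values are call-weighted fractions pooled across genes.
    """
    n_flank = (flank_bp - win_bp) // step_bp + 1
    meth = np.zeros(2 * n_flank + body_bins, dtype=np.int64)
    total = np.zeros_like(meth)
    used = 0
    grouped = {c: sub for c, sub in calls.records.groupby("chrom", sort=False)}
    for g in genes:
        if g.length < body_bins:
            logger.debug("skipping gene %s: shorter than %d bp", g.gene_id, body_bins)
            continue
        rec = grouped.get(g.chrom)
        if rec is None:
            continue
        pos = rec["pos"].to_numpy()
        cmeth = np.concatenate([[0], np.cumsum(rec["meth"].to_numpy())])
        ctot = np.concatenate([[0], np.cumsum((rec["meth"] + rec["unmeth"]).to_numpy())])

        def window_sum(s: int, e: int) -> tuple[int, int]:
            lo = np.searchsorted(pos, s, side="left")
            hi = np.searchsorted(pos, e, side="left")
            return int(cmeth[hi] - cmeth[lo]), int(ctot[hi] - ctot[lo])

        bins: list[tuple[int, int]] = []
        # genomic 5' flank windows for a plus-strand gene, upstream->TSS
        for i in range(n_flank):
            s = g.tx_start - flank_bp + i * step_bp
            bins.append((s, s + win_bp))
        body_edges = np.linspace(g.tx_start, g.tx_end, body_bins + 1).astype(np.int64)
        for i in range(body_bins):
            bins.append((int(body_edges[i]), int(body_edges[i + 1])))
        for i in range(n_flank):
            s = g.tx_end + i * step_bp
            bins.append((s, s + win_bp))
        sums = [window_sum(max(0, s), max(0, e)) if e > 0 else (0, 0) for s, e in bins]
        if g.strand == "-":
            sums = sums[::-1]
        for j, (m, t) in enumerate(sums):
            meth[j] += m
            total[j] += t
        used += 1
    if used == 0:
        raise ValueError("no eligible genes for metagene profile")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, meth / np.maximum(total, 1), np.nan)
    labels = (
        [f"up_{i}" for i in range(n_flank)]
        + [f"body_{i}" for i in range(body_bins)]
        + [f"down_{i}" for i in range(n_flank)]
    )
    return pd.DataFrame(
        {
            "bin_index": np.arange(len(labels)),
            "bin_label": labels,
            "mean_fraction": frac,
            "n_genes": used,
        }
    )


def repeat_class_methylation(
    repeats: Sequence[RepeatInstance], calls: Sequence[CpGCallSet]
) -> pd.DataFrame:
    """Pooled methylation per repeat class: sum all (un)methylated calls
    over every instance of the class and take the methylated share."""
    rdf = repeats_to_frame(repeats)
    rows = []
    for cls, sub in rdf.groupby("repeat_class", sort=True):
        for cs in calls:
            meth, total, ncpg = _probe_sums(sub[["chrom", "start", "end"]], cs)
            tot = int(total.sum())
            frac = float(meth.sum() / tot) if tot > 0 else float("nan")
            rows.append((cls, cs.sample_id, frac, tot, int(ncpg.sum())))
    return pd.DataFrame(
        rows, columns=["feature_class", "sample", "meth_fraction", "total_calls", "covered_cpgs"]
    )
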