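"""Demethylation background model, escapee calling, trajectory clustering.

The background model captures the genome-wide demethylation trend between
two stages without assuming a parametric form: probes are binned into
equal-occupancy bins by their starting methylation, and each probe's end
methylation is ranked against its bin peers. The two-sided empirical tail
probability (with add-one continuity) flags probes that retain
significantly more ("higher" — escapees) or less ("lower") methylation
than their peers. This reproduces the scatter-band logic of visual
background-model overlays while remaining distribution-free.

The add-one empirical p is conservative by construction: with n peers the
smallest attainable p is 2/(n+1), and the null rejection rate at level
alpha is slightly below alpha (by about 2/(n+1)); bins must therefore be
reasonably populated (min_bin_n, default 50) for calibration to be tight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from . import intervals
from .core_io import FeatureSet
from .methylation_quant import MethMatrix, ProbeSet

logger = logging.getLogger(__name__)


@dataclass
class BackgroundModel:
    """Equal-occupancy bins over start methylation with per-bin empirical
    distributions of end methylation."""

    start_sample: str
    end_sample: str
    bin_edges: np.ndarray  # len n_bins+1, on start-fraction scale
    probe_ids: np.ndarray
    start: np.ndarray
    end: np.ndarray
    bin_id: np.ndarray  # per probe
    bin_members: list[np.ndarray]  # per bin: sorted end fractions
    bin_median: np.ndarray
    bin_mad: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_members)


@dataclass
class OutlierCalls:
    """Per-probe two-sided empirical p and higher/lower/ns class."""

    alpha: float
    correction: str
    table: pd.DataFrame  # probe_id, start, end, bin, p, p_adj, class

    @property
    def higher_ids(self) -> set[str]:
        t = self.table
        return set(t.loc[t["class"] == "higher", "probe_id"])

    @property
    def lower_ids(self) -> set[str]:
        t = self.table
        return set(t.loc[t["class"] == "lower", "probe_id"])


def fit_background(
    meth_matrix: MethMatrix,
    start_sample: str,
    end_sample: str,
    n_bins: int = 20,
    min_bin_n: int = 50,
) -> BackgroundModel:
    """Fit the background model of demethylation between two samples.

    Probes missing in either sample are excluded. Bin count is reduced
    (logged) when fewer than n_bins*min_bin_n probes remain; identical
    start values collapse bins further. Raises if fewer than 2 usable
    bins remain for a non-degenerate start distribution.
    """
    start = meth_matrix.fractions[start_sample].to_numpy(dtype=float)
    end = meth_matrix.fractions[end_sample].to_numpy(dtype=float)
    ids = meth_matrix.fractions.index.to_numpy()
    ok = ~(np.isnan(start) | np.isnan(end))
    start, end, ids = start[ok], end[ok], ids[ok]
    n = len(start)
    if n == 0:
        raise ValueError("no probes covered in both samples")
    eff_bins = min(n_bins, max(1, n // min_bin_n))
    if eff_bins < n_bins:
        logger.warning("reducing bins from %d to %d (%d usable probes)", n_bins, eff_bins, n)
    quantiles = np.linspace(0, 1, eff_bins + 1)
    edges = np.unique(np.quantile(start, quantiles))
    degenerate = len(edges) < 2
    if degenerate:
        # all start values identical: single bin holding everything
        logger.warning("start values all identical; collapsing to a single bin")
        edges = np.array([edges[0], edges[0] + 1e-9])
    n_eff = len(edges) - 1
    if n_eff < 2 and not degenerate and n_bins >= 2:
        raise ValueError("fewer than 2 usable bins; not enough probes")
    bin_id = np.clip(np.searchsorted(edges, start, side="right") - 1, 0, n_eff - 1)
    members = [np.sort(end[bin_id == b]) for b in range(n_eff)]
    median = np.array([np.median(m) if len(m) else np.nan for m in members])
    mad = np.array(
        [np.median(np.abs(m - np.median(m))) if len(m) else np.nan for m in members]
    )
    return BackgroundModel(
        start_sample=start_sample,
        end_sample=end_sample,
        bin_edges=edges,
        probe_ids=ids,
        start=start,
        end=end,
        bin_id=bin_id,
        bin_members=members,
        bin_median=median,
        bin_mad=mad,
    )


def call_outliers(
    model: BackgroundModel,
    alpha: float = 0.05,
    correction: str = "none",
    method: str = "empirical",
) -> OutlierCalls:
    """Call probes with higher/lower end methylation than their bin peers.

    method='empirical' (default): p = 2*min(r+1, n-r+1)/(n+1) capped at
    1, where r is the probe's rank (ties mid-ranked) among the n
    end-methylation values of its bin — distribution-free, but its
    smallest attainable p is 2/(n+1), so its power is bounded by bin
    occupancy. method='mad_z': a robust two-sided normal tail using the
    bin median and 1.4826*MAD as location/scale, which stays calibrated
    when a minority of genuinely resistant probes contaminates the bin
    and is the recommended setting for escapee discovery (typically with
    correction='bh').

    A probe is 'higher' if significant and above its bin median, 'lower'
    if significant and below, else 'ns'. correction='bh' applies
    Benjamini-Hochberg across all probes before thresholding.
    """
    if correction not in {"none", "bh"}:
        raise ValueError(f"unknown correction {correction!r}")
    if method not in {"empirical", "mad_z"}:
        raise ValueError(f"unknown method {method!r}")
    n_probes = len(model.end)
    p = np.empty(n_probes)
    for b in range(model.n_bins):
        mask = model.bin_id == b
        vals = model.end[mask]
        peers = model.bin_members[b]
        nb = len(peers)
        if method == "empirical":
            lt = np.searchsorted(peers, vals, side="left")
            le = np.searchsorted(peers, vals, side="right")
            rank = (lt + le - 1) / 2.0  # mid-rank, 0-based
            p[mask] = np.minimum(
                1.0, 2.0 * np.minimum(rank + 1, nb - rank) / (nb + 1)
            )
        else:
            sigma = 1.4826 * model.bin_mad[b]
            if sigma == 0:
                p[mask] = np.where(vals == model.bin_median[b], 1.0, 0.0)
            else:
                z = (vals - model.bin_median[b]) / sigma
                p[mask] = 2.0 * stats.norm.sf(np.abs(z))
    p_adj = p.copy()
    if correction == "bh":
        p_adj = _bh(p)
    side_high = model.end > model.bin_median[model.bin_id]
    side_low = model.end < model.bin_median[model.bin_id]
    sig = p_adj < alpha
    cls = np.where(sig & side_high, "higher", np.where(sig & side_low, "lower", "ns"))
    table = pd.DataFrame(
        {
            "probe_id": model.probe_ids,
            "start": model.start,
            "end": model.end,
            "bin": model.bin_id,
            "p": p,
            "p_adj": p_adj,
            "class": cls,
        }
    )
    return OutlierCalls(alpha=alpha, correction=correction, table=table)


def _bh(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def enrich_features(
    group: set[str],
    universe: ProbeSet,
    features: dict[str, FeatureSet],
) -> pd.DataFrame:
    """Feature enrichment of a probe group vs the whole probe universe.

    For each feature class: percentage of group probes overlapping (>=1
    bp), the genome-wide (universe) percentage, the log2 ratio (NaN when
    the background is 0) and a hypergeometric upper-tail p.
    """
    if not group:
        raise ValueError("empty probe group")
    udf = universe.df
    unknown = group - set(udf["probe_id"])
    if unknown:
        raise ValueError(f"group probes not in universe: {sorted(unknown)[:3]}")
    in_group = udf["probe_id"].isin(group).to_numpy()
    M = len(udf)
    N = int(in_group.sum())
    rows = []
    for cls, fs in features.items():
        hit = intervals.overlap_mask(udf, fs.df)
        n_univ = int(hit.sum())
        k = int((hit & in_group).sum())
        pct_group = 100.0 * k / N
        pct_univ = 100.0 * n_univ / M
        if pct_univ > 0 and pct_group > 0:
            ratio = float(np.log2(pct_group / pct_univ))
        elif pct_univ > 0:
            ratio = float("-inf")
        else:
            ratio = float("nan")
        pval = float(stats.hypergeom.sf(k - 1, M, n_univ, N))
        rows.append((cls, k, pct_group, pct_univ, ratio, pval))
    return pd.DataFrame(
        rows,
        columns=["feature_class", "n_group", "pct_group", "pct_universe", "log2_ratio", "p"],
    )


@dataclass
class TrajectoryClusters:
    """k-means clusters of per-probe methylation trajectories."""

    k: int
    seed: int
    n_restarts: int
    labels: pd.Series  # index probe_id -> cluster id (0..k-1, descending size)
    centroids: pd.DataFrame  # index cluster id, columns time points
    inertia: float


def kmeans_trajectories(
    meth_matrix: MethMatrix,
    k: int = 7,
    seed: int = 0,
    n_restarts: int = 25,
) -> TrajectoryClusters:
    """Cluster probe methylation trajectories with k-means.

    Probes with any missing time point are excluded; values stay on the
    fraction scale (unstandardized). Lloyd iterations from k-means++
    starts, best of n_restarts by within-cluster sum of squares,
    deterministic given seed. Clusters are renumbered in descending size
    order.
    """
    X = meth_matrix.fractions.dropna(axis=0, how="any")
    if len(X) < k:
        raise ValueError(f"only {len(X)} complete probes for k={k}")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        random_state=seed,
        algorithm="lloyd",
    ).fit(X.to_numpy())
    raw = km.labels_
    sizes = np.bincount(raw, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = pd.Series(relabel[raw], index=X.index, name="cluster")
    centroids = pd.DataFrame(
        km.cluster_centers_[order], columns=meth_matrix.samples
    )
    centroids.index.name = "cluster"
    return TrajectoryClusters(
        k=k,
        seed=seed,
        n_restarts=n_restarts,
        labels=labels,
        centroids=centroids,
        inertia=float(km.inertia_),
    )


def overlay_chip(
    universe: ProbeSet,
    chip: FeatureSet,
    total_reads: int | None = None,
    top_quantile: float = 0.9,
) -> pd.DataFrame:
    """Per-probe ChIP read-count enrichment (RPKM-style score).

    `chip` holds read intervals; each probe's score is reads overlapping
    (>=1 bp) per probe kb per million reads. 'enriched' marks probes with
    score at or above the `top_quantile` quantile of the universe (ties
    at the threshold are all included).
    """
    if len(chip) == 0:
        raise ValueError("zero total chip signal")
    total = total_reads if total_reads is not None else len(chip)
    udf = universe.df
    counts = np.zeros(len(udf), dtype=np.int64)
    # count read midpoint-agnostic overlaps: any >=1 bp intersection
    reads_by_chrom = {c: sub for c, sub in chip.df.groupby("chrom", sort=False)}
    row_idx = np.arange(len(udf))
    for chrom, sub in udf.assign(_row=row_idx).groupby("chrom", sort=False):
        reads = reads_by_chrom.get(chrom)
        if reads is None:
            continue
        rs = np.sort(reads["start"].to_numpy())
        re_ = np.sort(reads["end"].to_numpy())
        ps = sub["start"].to_numpy()
        pe = sub["end"].to_numpy()
        # reads with start < probe_end minus reads with end <= probe_start
        n_start_before_end = np.searchsorted(rs, pe, side="left")
        n_end_before_start = np.searchsorted(re_, ps, side="right")
        counts[sub["_row"].to_numpy()] = n_start_before_end - n_end_before_start
    kb = (udf["end"] - udf["start"]).to_numpy() / 1000.0
    score = counts / kb / (total / 1e6)
    thresh = np.quantile(score, top_quantile)
    out = udf[["probe_id", "chrom", "start", "end"]].copy()
    out["reads"] = counts
    out["score"] = score
    out["enriched"] = score >= thresh
    return out


def correlate_meth_expr(
    gene_body_meth: pd.Series,
    expression: pd.Series,
    method: str = "pearson",
    log_transform: bool = True,
) -> tuple[float, int]:
    """Correlate gene-body methylation with expression.

    Genes are intersected by id; expression is log2(x+1)-transformed by
    default. Returns (r, n). Raises when fewer than 3 genes overlap.
    """
    joined = pd.concat(
        {"meth": gene_body_meth, "expr": expression}, axis=1, join="inner"
    ).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError(f"only {n} genes shared between methylation and expression")
    x = joined["meth"].to_numpy(dtype=float)
    y = joined["expr"].to_numpy(dtype=float)
    if log_transform:
        y = np.log2(y + 1.0)
    if method == "pearson":
        r = stats.pearsonr(x, y).statistic
    elif method == "spearman":
        r = stats.spearmanr(x, y).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), n
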