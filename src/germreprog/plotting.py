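"""Optional summary plots over the pipeline's TSV outputs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def summary_plots(outdir: Path) -> list[Path]:
    """Render centroid trajectories, ping-pong histogram and length spectra
    from an analysis output directory; returns the files written."""
    written = []
    cent = outdir / "centroids.tsv"
    if cent.exists():
        df = pd.read_csv(cent, sep="\t")
        df.columns = [c.lstrip("#") for c in df.columns]
        fig, ax = plt.subplots(figsize=(5, 4))
        for _, row in df.iterrows():
            ax.plot(row.iloc[1:].to_numpy(dtype=float), marker="o", label=f"c{int(row.iloc[0])}")
        ax.set_xlabel("stage")
        ax.set_ylabel("methylation fraction")
        ax.legend(fontsize=7)
        path = outdir / "centroids.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    pp = outdir / "pingpong.tsv"
    if pp.exists():
        df = pd.read_csv(pp, sep="\t")
        df.columns = [c.lstrip("#") for c in df.columns]
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.bar(df["overlap"], df["count"])
        ax.set_xlabel("5'-5' overlap (nt)")
        ax.set_ylabel("pairs")
        path = outdir / "pingpong.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    ld = outdir / "smrna_lengths.tsv"
    if ld.exists():
        df = pd.read_csv(ld, sep="\t")
        df.columns = [c.lstrip("#") for c in df.columns]
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.bar(df["length"], df["count"])
        ax.set_xlabel("read length (nt)")
        ax.set_ylabel("reads")
        path = outdir / "smrna_lengths.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
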