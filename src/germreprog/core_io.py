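"""Readers, writers and the shared genomic data model.

All internal coordinates are 0-based half-open. Bismark coverage files are
1-based inclusive and are shifted on read; bedGraph-with-counts files are
already 0-based. The percent column of call files is never trusted —
methylation fractions are always recomputed from the call counts.

CpGs are keyed by the plus-strand C position; input call files are assumed
to carry strand-merged counts (the usual coverage-file convention).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenomeIndex",
    "CpGCallSet",
    "FeatureSet",
    "GeneModel",
    "RepeatInstance",
    "SmallRNAReadSet",
    "read_genome_index",
    "read_cpg_calls",
    "write_cpg_calls",
    "read_intervals",
    "write_bed",
    "read_gene_models",
    "write_gene_models",
    "read_smrna",
    "write_smrna",
]

CALL_COLUMNS = ["chrom", "pos", "meth", "unmeth"]
FEATURE_COLUMNS = ["chrom", "start", "end", "strand", "name", "feature_class"]
READ_COLUMNS = ["read_id", "seq", "chrom", "start", "end", "strand", "unique", "class_label"]


class FormatError(ValueError):
    """Raised for malformed input files; message names the offending line."""


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered chromosome name -> length (bp) table."""

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(set(self.lengths)) != len(self.lengths):
            raise ValueError("duplicate chromosome names")
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())


@dataclass
class CpGCallSet:
    """Per-CpG methylated/unmethylated call counts for one sample.

    `records` has columns chrom, pos (0-based plus-strand C), meth, unmeth,
    sorted by (chrom, pos) with unique positions per chromosome.
    """

    sample_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        self.records = normalize_calls(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def fractions(self) -> pd.Series:
        total = self.records["meth"] + self.records["unmeth"]
        return self.records["meth"] / total.where(total > 0)

    def global_fraction(self) -> float:
        """Call-weighted genome-wide methylation fraction."""
        total = int(self.records["meth"].sum() + self.records["unmeth"].sum())
        if total == 0:
            return float("nan")
        return float(self.records["meth"].sum() / total)


def normalize_calls(df: pd.DataFrame) -> pd.DataFrame:
    df = df[CALL_COLUMNS].copy()
    df["pos"] = df["pos"].astype(np.int64)
    df["meth"] = df["meth"].astype(np.int64)
    df["unmeth"] = df["unmeth"].astype(np.int64)
    if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
        raise FormatError("negative call counts")
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        row = df[dup].iloc[0]
        raise FormatError(f"duplicate CpG position {row['chrom']}:{row['pos']}")
    return df


class FeatureSet:
    """Genomic intervals with strand, name and a feature-class label."""

    def __init__(self, df: pd.DataFrame, genome: GenomeIndex | None = None):
        df = df.copy()
        for col, default in (("strand", "."), ("name", "."), ("feature_class", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[[c for c in FEATURE_COLUMNS if c in df.columns] + [c for c in df.columns if c not in FEATURE_COLUMNS]]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        bad = df["start"] >= df["end"]
        if bad.any():
            row = df[bad].iloc[0]
            raise FormatError(
                f"interval with start >= end: {row['chrom']}:{row['start']}-{row['end']}"
            )
        if genome is not None:
            unknown = sorted(set(df["chrom"]) - set(genome.chroms))
            if unknown:
                raise FormatError(f"unknown chromosome(s): {', '.join(unknown)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "FeatureSet":
        return FeatureSet(self.df[mask])

    def classes(self) -> list[str]:
        return sorted(self.df["feature_class"].unique())


@dataclass
class GeneModel:
    """One gene: tx span plus exon blocks; TSS/TES are strand-aware."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        prev_end = self.tx_start
        for s, e in self.exons:
            if s < prev_end or e > self.tx_end or s >= e:
                raise FormatError(
                    f"gene {self.gene_id}: exon block [{s},{e}) outside tx bounds "
                    f"or out of order"
                )
            prev_end = e

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tes(self) -> int:
        return self.tx_end if self.strand == "+" else self.tx_start

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1, s2))
        return out

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start


@dataclass(frozen=True)
class RepeatInstance:
    chrom: str
    start: int
    end: int
    strand: str
    repeat_class: str
    family: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"repeat with start >= end: {self.chrom}:{self.start}-{self.end}"
            )
        if not self.repeat_class:
            raise FormatError("repeat with empty class")


def repeats_to_frame(repeats: Iterable[RepeatInstance]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in repeats]
    if not rows:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "strand", "repeat_class", "family"]
        )
    return pd.DataFrame(rows)


@dataclass
class SmallRNAReadSet:
    """Strand-aware aligned short reads with sequences.

    `reads` has columns read_id, seq, chrom, start, end, strand, unique
    (bool), class_label (assigned by smrna_signatures.classify_reads,
    initially 'unset'). Alignment interval length equals sequence length.
    """

    reads: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.reads.copy()
        if "class_label" not in df.columns:
            df["class_label"] = "unset"
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        lens = df["seq"].str.len()
        bad = (df["end"] - df["start"]) != lens
        if bad.any():
            rid = df[bad].iloc[0]["read_id"]
            raise FormatError(f"read {rid}: alignment length != sequence length")
        if ((lens < 15) | (lens > 50)).any():
            rid = df[(lens < 15) | (lens > 50)].iloc[0]["read_id"]
            raise FormatError(f"read {rid}: sequence length outside 15-50 nt")
        self.reads = df[READ_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_genome_index(path: str | Path) -> GenomeIndex:
    """Read a chrom.sizes table (name, length)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
    return GenomeIndex(dict(zip(df["chrom"].astype(str), df["length"].astype(int))))


def write_genome_index(genome: GenomeIndex, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.lengths.items():
            fh.write(f"{name}\t{length}\n")


def read_cpg_calls(path: str | Path, dialect: str, sample_id: str) -> CpGCallSet:
    """Read per-CpG call counts.

    dialect 'bismark_cov': chrom, start(1-based), end, percent, meth, unmeth.
    dialect 'bedgraph_counts': chrom, start(0-based), end, percent, meth, unmeth.
    The percent column is ignored; fractions are recomputed from counts.
    """
    if dialect not in {"bismark_cov", "bedgraph_counts"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"{path}: malformed line {lineno}: expected 6 columns")
            chrom, start, _end, _pct, meth, unmeth = parts[:6]
            try:
                pos = int(start)
                meth_n = int(meth)
                unmeth_n = int(unmeth)
            except ValueError as exc:
                raise FormatError(f"{path}: malformed line {lineno}: {exc}") from exc
            if dialect == "bismark_cov":
                pos -= 1
            if meth_n < 0 or unmeth_n < 0:
                raise FormatError(f"{path}: negative counts at line {lineno}")
            rows.append((chrom, pos, meth_n, unmeth_n))
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return CpGCallSet(sample_id=sample_id, records=df)


def write_cpg_calls(calls: CpGCallSet, path: str | Path, dialect: str = "bismark_cov") -> None:
    df = calls.records
    total = (df["meth"] + df["unmeth"]).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * df["meth"].to_numpy() / total, 0.0)
    shift = 1 if dialect == "bismark_cov" else 0
    with open(path, "w") as fh:
        for (chrom, pos, meth, unmeth), p in zip(df.itertuples(index=False), pct):
            start = pos + shift
            end = pos + 1
            fh.write(f"{chrom}\t{start}\t{end}\t{p:.6g}\t{meth}\t{unmeth}\n")


def read_intervals(
    path: str | Path,
    kind: str = "bed",
    genome: GenomeIndex | None = None,
    feature_class: str | None = None,
):
    """Read BED (>=3 cols), a repeat TSV, or an imprinted-DMR TSV.

    kind='bed' -> FeatureSet (col 4 = name, col 6 = strand if present);
    kind='repeat_tsv' -> list[RepeatInstance] (chrom, start, end, strand,
    class, family); kind='dmr_tsv' -> FeatureSet with the parent of origin
    ('maternal'/'paternal') stored in feature_class.
    """
    if kind == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        ncol = df.shape[1]
        out = pd.DataFrame(
            {
                "chrom": df[0].astype(str),
                "start": df[1].astype(np.int64),
                "end": df[2].astype(np.int64),
                "name": df[3].astype(str) if ncol > 3 else ".",
                "strand": df[5].astype(str) if ncol > 5 else ".",
                "feature_class": feature_class or ".",
            }
        )
        return FeatureSet(out, genome=genome)
    if kind == "repeat_tsv":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "strand", "repeat_class", "family"],
        )
        if genome is not None:
            unknown = sorted(set(df["chrom"].astype(str)) - set(genome.chroms))
            if unknown:
                raise FormatError(f"unknown chromosome(s): {', '.join(unknown)}")
        return [
            RepeatInstance(
                chrom=str(r.chrom),
                start=int(r.start),
                end=int(r.end),
                strand=str(r.strand),
                repeat_class=str(r.repeat_class),
                family=str(r.family),
            )
            for r in df.itertuples(index=False)
        ]
    if kind == "dmr_tsv":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "name", "parent"],
        )
        bad = ~df["parent"].isin(["maternal", "paternal"])
        if bad.any():
            raise FormatError(
                f"DMR parent must be maternal/paternal, got {df[bad].iloc[0]['parent']!r}"
            )
        out = df.rename(columns={"parent": "feature_class"})
        out["strand"] = "."
        return FeatureSet(out, genome=genome)
    raise ValueError(f"unknown kind {kind!r}")


def write_bed(features: FeatureSet, path: str | Path) -> None:
    df = features.df
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for r in df.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\n")


def write_repeats(repeats: Iterable[RepeatInstance], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tstrand\trepeat_class\tfamily\n")
        for r in repeats:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t{r.repeat_class}\t{r.family}\n")


def write_dmr_tsv(features: FeatureSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tparent\n")
        for r in features.df.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.feature_class}\n")


def read_gene_models(path_bed12: str | Path, genome: GenomeIndex | None = None) -> list[GeneModel]:
    """Read gene models from BED12; exons reconstructed from blocks."""
    genes: list[GeneModel] = []
    with open(path_bed12) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise FormatError(f"{path_bed12}: line {lineno}: BED12 needs 12 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5]
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            if genome is not None and chrom not in genome:
                raise FormatError(f"{path_bed12}: line {lineno}: unknown chromosome {chrom}")
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                    exons=exons,
                )
            )
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.tx_start) for s, e in g.exons)
            fh.write(
                f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.tx_start}\t{g.tx_end}\t0\t{len(g.exons)}\t{sizes},\t{offsets},\n"
            )


def read_smrna(fasta_path: str | Path, bed6_path: str | Path) -> SmallRNAReadSet:
    """Join mapped small-RNA intervals (BED6) with read sequences (FASTA).

    The BED score column carries the unique-mapping flag (1=unique,
    0=multi-mapping). Every BED name must have a FASTA entry whose length
    equals the interval length.
    """
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    bed = pd.read_csv(
        bed6_path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "read_id", "score", "strand"],
    )
    missing = set(bed["read_id"].astype(str)) - set(seqs)
    if missing:
        raise FormatError(f"BED read id(s) missing from FASTA: {sorted(missing)[:3]}")
    df = pd.DataFrame(
        {
            "read_id": bed["read_id"].astype(str),
            "seq": bed["read_id"].astype(str).map(seqs),
            "chrom": bed["chrom"].astype(str),
            "start": bed["start"].astype(np.int64),
            "end": bed["end"].astype(np.int64),
            "strand": bed["strand"].astype(str),
            "unique": bed["score"].astype(int) == 1,
        }
    )
    return SmallRNAReadSet(reads=df)


def write_smrna(reads: SmallRNAReadSet, fasta_path: str | Path, bed6_path: str | Path) -> None:
    df = reads.reads
    with open(fasta_path, "w") as fa, open(bed6_path, "w") as bed:
        for r in df.itertuples(index=False):
            fa.write(f">{r.read_id}\n{r.seq}\n")
            score = 1 if r.unique else 0
            bed.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.read_id}\t{score}\t{r.strand}\n")
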