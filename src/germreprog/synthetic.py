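"""Synthetic genomes, methylomes, chromatin and small-RNA reads with truth.

The generator emulates the structure of a PGC-like-cell specification
time course: the genome is tiled into region classes (CpG islands,
young/old transposable elements, gene bodies, imprinted DMRs,
intergenic), each class follows its own stage-wise methylation
trajectory (CGIs hypomethylated throughout, young TEs resistant to the
global demethylation wave, imprinted DMRs at intermediate levels and
then erased), per-CpG calls are binomial draws under a negative-binomial
coverage model, and small-RNA libraries mix repeat-derived piRNA-like
reads (24-31 nt, 5'U-biased, ping-pong paired by a slicer-cleavage
rule), miRNA-like reads (22-23 nt) and rRNA background.

Ping-pong pairs arise mechanistically: a secondary read is placed on the
opposite strand with its 5' end across from nucleotide 10 of its primary
partner, so the 10-nt 5'-5' overlap is emergent in the reads, not
hard-coded into any statistic.

Every draw derives from the config seed; identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core_io
from .core_io import (
    CpGCallSet,
    FeatureSet,
    GeneModel,
    GenomeIndex,
    RepeatInstance,
    SmallRNAReadSet,
)

REGION_CLASSES = ["cgi", "young_TE", "old_TE", "gene_body", "imprinted_DMR", "intergenic"]
STAGES = ["naive", "EpiLC", "PGCLC_early", "PGCLC_late"]

# repeat-class labels for simulated TE regions (young = IAP/SVA-like)
REPEAT_LABELS = {"young_TE": ("LTR/ERVK", "IAPEz"), "old_TE": ("LINE/L1", "L1Md")}


@dataclass
class SmallRNAParams:
    n_reads: int = 5000
    pirna_frac: float = 0.55
    mirna_frac: float = 0.25
    rrna_frac: float = 0.15
    # remainder of the library originates from gene bodies
    five_prime_u: float = 0.8
    pingpong_frac: float = 0.3
    pirna_len: tuple[int, int] = (24, 31)
    mirna_len: tuple[int, int] = (22, 23)
    rrna_len: tuple[int, int] = (28, 35)
    unique_frac: float = 0.95


@dataclass
class ChipParams:
    n_reads: int = 20000
    read_len: int = 100
    k9_enrichment: float = 8.0  # fold weight on demethylation-resistant regions
    k4_enrichment: float = 8.0  # fold weight on CGI regions


@dataclass
class RnaSeqParams:
    n_reads: int = 20000
    read_len: int = 75
    # sampling weight per region class (arbitrary units, gene expression high)
    weights: dict = field(
        default_factory=lambda: {
            "gene_body": 5.0,
            "young_TE": 3.0,
            "old_TE": 0.5,
            "cgi": 0.2,
            "imprinted_DMR": 0.2,
            "intergenic": 0.2,
        }
    )


@dataclass
class SimulationConfig:
    """All knobs of the simulator; the defaults define the study conditions."""

    seed: int = 0
    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000})
    region_bp: int = 5000
    cpg_per_kb: float = 3.5
    cgi_cpg_factor: float = 10.0
    class_proportions: dict = field(
        default_factory=lambda: {
            "cgi": 0.03,
            "young_TE": 0.05,
            "old_TE": 0.12,
            "gene_body": 0.30,
            "imprinted_DMR": 0.02,
            "intergenic": 0.48,
        }
    )
    # per-class stage-mean methylation: naive ~0.30 globally, de novo
    # methylation to ~0.65 on priming, stepwise PGCLC decline; young TEs
    # resistant; CGIs low throughout; imprinted DMRs at 0.5 then erased
    stage_means: dict = field(
        default_factory=lambda: {
            "cgi": (0.05, 0.05, 0.05, 0.05),
            "young_TE": (0.30, 0.70, 0.65, 0.60),
            "old_TE": (0.30, 0.65, 0.35, 0.15),
            "gene_body": (0.30, 0.65, 0.35, 0.15),
            "imprinted_DMR": (0.50, 0.50, 0.25, 0.05),
            "intergenic": (0.30, 0.65, 0.35, 0.15),
        }
    )
    beta_precision: float = 50.0
    coverage_mean: float = 10.0
    coverage_shape: float = 5.0  # NB overdispersion (gamma shape)
    n_rrna_loci_per_chrom: int = 2
    n_mirna_loci: int = 40
    smrna: SmallRNAParams = field(default_factory=SmallRNAParams)
    chip: ChipParams = field(default_factory=ChipParams)
    rnaseq: RnaSeqParams = field(default_factory=RnaSeqParams)

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        for cls, means in self.stage_means.items():
            if any(not (0.0 <= m <= 1.0) for m in means):
                raise ValueError(f"stage means for {cls} outside [0,1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), int(stream)])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub_cls in (("smrna", SmallRNAParams), ("chip", ChipParams), ("rnaseq", RnaSeqParams)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub_cls(**raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class SimulatedAnnotation:
    """Genome, annotation tracks and per-region truth from one simulation."""

    genome: GenomeIndex
    sequences: dict  # chrom -> bytearray (mutable until reads are placed)
    regions: pd.DataFrame  # region_id, chrom, start, end, class, resistant, dmr_parent
    cpg_positions: dict  # chrom -> int64 array
    cgis: FeatureSet
    dmrs: FeatureSet
    genes: list
    repeats: list
    rrna_loci: FeatureSet
    mirna_loci: FeatureSet

    def sequences_str(self) -> dict[str, str]:
        return {c: bytes(s).decode("ascii") for c, s in self.sequences.items()}


def simulate_genome_and_annotation(config: SimulationConfig) -> SimulatedAnnotation:
    """Tile the genome into region classes and draw sequence + annotation.

    Region classes are non-overlapping and cover every chromosome. CpG
    positions follow a Poisson process with a `cgi_cpg_factor`-fold
    higher rate inside CGI regions; a CG dinucleotide is written into the
    sequence at every CpG site.
    """
    rng = config.rng(1)
    genome = GenomeIndex(dict(config.chrom_sizes))
    classes = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes])

    region_rows = []
    cpg_positions: dict[str, np.ndarray] = {}
    sequences: dict[str, bytearray] = {}
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    rid = 0
    for chrom in genome.chroms:
        length = genome[chrom]
        seq = bytearray(alphabet[rng.integers(0, 4, size=length)].tobytes())
        starts = np.arange(0, length, config.region_bp, dtype=np.int64)
        ends = np.minimum(starts + config.region_bp, length)
        assigned = rng.choice(len(classes), size=len(starts), p=probs)
        chrom_cpgs = []
        for s, e, ci in zip(starts, ends, assigned):
            cls = classes[ci]
            parent = ""
            if cls == "imprinted_DMR":
                parent = "maternal" if rng.random() < 0.5 else "paternal"
            region_rows.append((f"r{rid:06d}", chrom, int(s), int(e), cls, cls == "young_TE", parent))
            rid += 1
            rate = config.cpg_per_kb / 1000.0
            if cls == "cgi":
                rate *= config.cgi_cpg_factor
            n_cpg = rng.poisson((e - s) * rate)
            n_cpg = min(n_cpg, max(0, (e - s - 1) // 2))
            if n_cpg > 0:
                pos = rng.choice(np.arange(s, e - 1), size=n_cpg, replace=False)
                chrom_cpgs.append(np.sort(pos))
        pos_all = np.unique(np.concatenate(chrom_cpgs)) if chrom_cpgs else np.array([], dtype=np.int64)
        # drop adjacent positions so the planted CG dinucleotides never collide
        if len(pos_all) > 1:
            keep = np.concatenate([[True], np.diff(pos_all) > 1])
            pos_all = pos_all[keep]
        for p in pos_all:
            seq[p] = ord("C")
            seq[p + 1] = ord("G")
        cpg_positions[chrom] = pos_all
        sequences[chrom] = seq

    regions = pd.DataFrame(
        region_rows,
        columns=["region_id", "chrom", "start", "end", "class", "resistant", "dmr_parent"],
    )

    def class_features(cls: str, feature_class_col: str | None = None) -> pd.DataFrame:
        sub = regions[regions["class"] == cls]
        return pd.DataFrame(
            {
                "chrom": sub["chrom"],
                "start": sub["start"],
                "end": sub["end"],
                "name": sub["region_id"],
                "strand": ".",
                "feature_class": sub[feature_class_col] if feature_class_col else cls,
            }
        )

    cgis = FeatureSet(class_features("cgi")) if (regions["class"] == "cgi").any() else FeatureSet(
        pd.DataFrame(columns=["chrom", "start", "end", "strand", "name", "feature_class"]).astype(
            {"start": np.int64, "end": np.int64}
        )
    )
    dmr_df = class_features("imprinted_DMR", feature_class_col="dmr_parent")
    dmrs = FeatureSet(dmr_df) if len(dmr_df) else FeatureSet(
        pd.DataFrame(columns=["chrom", "start", "end", "strand", "name", "feature_class"]).astype(
            {"start": np.int64, "end": np.int64}
        )
    )

    genes = []
    for r in regions[regions["class"] == "gene_body"].itertuples(index=False):
        strand = "+" if rng.random() < 0.5 else "-"
        L = r.end - r.start
        # three exons with two introns at fixed relative positions
        exons = [
            (r.start, r.start + int(0.3 * L)),
            (r.start + int(0.4 * L), r.start + int(0.7 * L)),
            (r.start + int(0.8 * L), r.end),
        ]
        genes.append(
            GeneModel(
                gene_id=f"gene_{r.region_id}",
                chrom=r.chrom,
                strand=strand,
                tx_start=r.start,
                tx_end=r.end,
                exons=exons,
            )
        )

    repeats = []
    for cls, (rep_class, family) in REPEAT_LABELS.items():
        for r in regions[regions["class"] == cls].itertuples(index=False):
            strand = "+" if rng.random() < 0.5 else "-"
            repeats.append(
                RepeatInstance(
                    chrom=r.chrom,
                    start=int(r.start),
                    end=int(r.end),
                    strand=strand,
                    repeat_class=rep_class,
                    family=family,
                )
            )

    # carve rRNA and miRNA source loci out of intergenic regions
    inter = regions[regions["class"] == "intergenic"].reset_index(drop=True)
    rrna_rows = []
    mirna_rows = []
    used = set()
    for chrom in genome.chroms:
        cand = inter[inter["chrom"] == chrom]
        take = cand.head(config.n_rrna_loci_per_chrom)
        for r in take.itertuples(index=False):
            rrna_rows.append((r.chrom, r.start, r.end, f"rrna_{r.region_id}", "+", "rRNA"))
            used.add(r.region_id)
    pool = inter[~inter["region_id"].isin(used)].reset_index(drop=True)
    n_mirna = min(config.n_mirna_loci, len(pool))
    if n_mirna > 0:
        picks = rng.choice(len(pool), size=n_mirna, replace=False)
        for i in sorted(picks.tolist()):
            r = pool.iloc[i]
            s = int(r["start"]) + 100
            mirna_rows.append((r["chrom"], s, s + 70, f"mirna_{r['region_id']}", "+", "miRNA"))
    rrna_loci = FeatureSet(
        pd.DataFrame(rrna_rows, columns=["chrom", "start", "end", "name", "strand", "feature_class"])
    )
    mirna_loci = FeatureSet(
        pd.DataFrame(mirna_rows, columns=["chrom", "start", "end", "name", "strand", "feature_class"])
    )

    return SimulatedAnnotation(
        genome=genome,
        sequences=sequences,
        regions=regions,
        cpg_positions=cpg_positions,
        cgis=cgis,
        dmrs=dmrs,
        genes=genes,
        repeats=repeats,
        rrna_loci=rrna_loci,
        mirna_loci=mirna_loci,
    )


def simulate_methylomes(
    config: SimulationConfig, annotation: SimulatedAnnotation
) -> dict[str, CpGCallSet]:
    """Draw per-stage per-CpG call counts.

    Each region gets a beta-distributed latent methylation level around
    its class's stage mean (precision = beta_precision); each CpG draws
    coverage from a negative binomial (mean coverage_mean, shape
    coverage_shape) and methylated calls from Binomial(coverage, latent).
    CpGs with zero drawn coverage are omitted from that stage's call set.
    """
    rng = config.rng(2)
    regions = annotation.regions
    n_regions = len(regions)
    class_idx = regions["class"].to_numpy()
    latent = np.zeros((n_regions, len(STAGES)))
    for j, stage in enumerate(STAGES):
        means = np.array([config.stage_means[c][j] for c in class_idx])
        prec = config.beta_precision
        interior = (means > 0) & (means < 1)
        vals = means.copy()
        if interior.any() and prec > 0:
            vals[interior] = rng.beta(means[interior] * prec, (1 - means[interior]) * prec)
        latent[:, j] = vals

    out: dict[str, CpGCallSet] = {}
    p_nb = config.coverage_shape / (config.coverage_shape + config.coverage_mean)
    region_by_chrom = {c: sub.reset_index() for c, sub in regions.groupby("chrom", sort=False)}
    for j, stage in enumerate(STAGES):
        frames = []
        for chrom in annotation.genome.chroms:
            pos = annotation.cpg_positions[chrom]
            if len(pos) == 0:
                continue
            sub = region_by_chrom[chrom]
            ridx = np.searchsorted(sub["start"].to_numpy(), pos, side="right") - 1
            lam = latent[sub["index"].to_numpy()[ridx], j]
            cov = rng.negative_binomial(config.coverage_shape, p_nb, size=len(pos))
            meth = rng.binomial(cov, lam)
            keep = cov > 0
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos[keep],
                        "meth": meth[keep],
                        "unmeth": (cov - meth)[keep],
                    }
                )
            )
        records = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=core_io.CALL_COLUMNS
        )
        out[stage] = CpGCallSet(sample_id=stage, records=records)
    return out


def simulate_smrna(
    config: SimulationConfig, annotation: SimulatedAnnotation
) -> tuple[SmallRNAReadSet, pd.DataFrame]:
    """Draw a small-RNA library with per-read truth labels.

    Primary piRNA-like reads are sampled from TE instances with a 5'U
    probability written into the genome sequence before extraction;
    secondary reads (pingpong_frac of piRNA reads) sit on the opposite
    strand with their 5' end across from nucleotide 10 of their primary.
    miRNA-like reads come from miRNA loci, rRNA background from rRNA
    loci, and the remainder from gene bodies. Read sequences are exact
    genome substrings (reverse-complemented on the minus strand).
    """
    rng = config.rng(3)
    p = config.smrna
    n = p.n_reads
    n_pirna = int(round(p.pirna_frac * n))
    n_secondary = int(round(p.pingpong_frac * n_pirna))
    n_primary = n_pirna - n_secondary
    n_mirna = int(round(p.mirna_frac * n))
    n_rrna = int(round(p.rrna_frac * n))
    n_gene = max(0, n - n_pirna - n_mirna - n_rrna)

    if n_pirna > 0 and not annotation.repeats:
        raise ValueError("piRNA fraction > 0 but no repeat instances in annotation")

    seqs = annotation.sequences
    genome = annotation.genome
    rows = []  # chrom, start, end, strand, origin, partner
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    # primary piRNAs from TE instances
    reps = annotation.repeats
    primaries = []
    for _ in range(n_primary):
        inst = reps[int(rng.integers(0, len(reps)))]
        L = int(rng.integers(p.pirna_len[0], p.pirna_len[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        lo = inst.start + p.pirna_len[1]
        hi = inst.end - p.pirna_len[1]
        if hi <= lo:
            lo, hi = inst.start, max(inst.start + 1, inst.end - L)
        if strand == "+":
            start = int(rng.integers(lo, hi))
            end = start + L
            p5 = start
        else:
            p5 = int(rng.integers(lo, hi))
            start, end = p5 - L + 1, p5 + 1
        # plant the 5' nucleotide: U (T on the read strand) with prob five_prime_u;
        # on the minus strand the genomic base is the complement of the read base
        base = "T" if rng.random() < p.five_prime_u else "ACG"[int(rng.integers(0, 3))]
        if strand == "-":
            base = comp[base]
        seqs[inst.chrom][p5] = ord(base)
        rows.append([inst.chrom, start, end, strand, "piRNA_primary", ""])
        primaries.append((len(rows) - 1, inst.chrom, strand, p5))

    # secondary piRNAs: 5' end opposite nucleotide 10 of a primary partner
    for _ in range(n_secondary):
        idx = int(rng.integers(0, len(primaries)))
        pi_row, chrom, strand, p5 = primaries[idx]
        L = int(rng.integers(p.pirna_len[0], p.pirna_len[1] + 1))
        if strand == "+":
            s5 = p5 + 9  # secondary minus-strand 5' across from nt 10
            start, end = s5 - L + 1, s5 + 1
            sec_strand = "-"
        else:
            s5 = p5 - 9
            start, end = s5, s5 + L
            sec_strand = "+"
        if start < 0 or end > genome[chrom]:
            continue
        rows.append([chrom, start, end, sec_strand, "piRNA_secondary", f"read_{pi_row:06d}"])

    # miRNA-like reads from miRNA locus starts
    mloci = annotation.mirna_loci.df
    for _ in range(n_mirna):
        if len(mloci) == 0:
            break
        r = mloci.iloc[int(rng.integers(0, len(mloci)))]
        L = int(rng.integers(p.mirna_len[0], p.mirna_len[1] + 1))
        rows.append([r["chrom"], int(r["start"]), int(r["start"]) + L, "+", "miRNA", ""])

    # rRNA fragments
    rloci = annotation.rrna_loci.df
    for _ in range(n_rrna):
        if len(rloci) == 0:
            break
        r = rloci.iloc[int(rng.integers(0, len(rloci)))]
        L = int(rng.integers(p.rrna_len[0], p.rrna_len[1] + 1))
        start = int(rng.integers(r["start"], r["end"] - L))
        rows.append([r["chrom"], start, start + L, "+" if rng.random() < 0.5 else "-", "rRNA", ""])

    # residual gene-derived fragments
    gene_regions = annotation.regions[annotation.regions["class"] == "gene_body"]
    for _ in range(n_gene):
        if len(gene_regions) == 0:
            break
        r = gene_regions.iloc[int(rng.integers(0, len(gene_regions)))]
        L = int(rng.integers(p.mirna_len[0], p.rrna_len[1] + 1))
        start = int(rng.integers(r["start"], r["end"] - L))
        rows.append([r["chrom"], start, start + L, "+" if rng.random() < 0.5 else "-", "gene", ""])

    # extract sequences (after all 5' planting) and assemble the read set
    read_rows = []
    truth_rows = []
    for i, (chrom, start, end, strand, origin, partner) in enumerate(rows):
        seq = bytes(seqs[chrom][start:end]).decode("ascii")
        if strand == "-":
            seq = _revcomp(seq)
        rid = f"read_{i:06d}"
        unique = bool(rng.random() < p.unique_frac)
        read_rows.append((rid, seq, chrom, start, end, strand, unique, "unset"))
        truth_rows.append((rid, origin, partner))
    reads = SmallRNAReadSet(
        reads=pd.DataFrame(read_rows, columns=core_io.READ_COLUMNS)
    )
    truth = pd.DataFrame(truth_rows, columns=["read_id", "origin", "partner_id"])
    return reads, truth


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_chip(
    config: SimulationConfig, annotation: SimulatedAnnotation
) -> dict[str, FeatureSet]:
    """Draw ChIP-like read interval tracks for two marks.

    H3K9me3-like reads are enriched (k9_enrichment-fold sampling weight)
    on demethylation-resistant regions; H3K4me3-like reads on CGI
    regions. Reads are uniform within their chosen region.
    """
    rng = config.rng(4)
    regions = annotation.regions
    lengths = (regions["end"] - regions["start"]).to_numpy(dtype=float)
    out = {}
    for mark, (flag_col, fold) in {
        "H3K9me3": ("resistant", config.chip.k9_enrichment),
        "H3K4me3": (None, config.chip.k4_enrichment),
    }.items():
        if flag_col == "resistant":
            boost = regions["resistant"].to_numpy()
        else:
            boost = (regions["class"] == "cgi").to_numpy()
        w = lengths * np.where(boost, fold, 1.0)
        w = w / w.sum()
        picks = rng.choice(len(regions), size=config.chip.n_reads, p=w)
        starts = regions["start"].to_numpy()[picks]
        ends = regions["end"].to_numpy()[picks]
        span = np.maximum(ends - starts - config.chip.read_len, 1)
        offs = rng.integers(0, span)
        rs = starts + offs
        df = pd.DataFrame(
            {
                "chrom": regions["chrom"].to_numpy()[picks],
                "start": rs,
                "end": rs + config.chip.read_len,
                "name": [f"{mark}_{i}" for i in range(config.chip.n_reads)],
                "strand": ".",
                "feature_class": mark,
            }
        )
        out[mark] = FeatureSet(df)
    return out


def simulate_rnaseq(
    config: SimulationConfig, annotation: SimulatedAnnotation
) -> pd.DataFrame:
    """Draw RNA-seq-like read intervals (BED6 frame) for repeat RPKM.

    Regions are sampled with class-specific weights (genes high, young
    TEs expressed, background low) and reads placed uniformly within.
    """
    rng = config.rng(5)
    regions = annotation.regions
    lengths = (regions["end"] - regions["start"]).to_numpy(dtype=float)
    w = lengths * regions["class"].map(config.rnaseq.weights).to_numpy(dtype=float)
    w = w / w.sum()
    picks = rng.choice(len(regions), size=config.rnaseq.n_reads, p=w)
    starts = regions["start"].to_numpy()[picks]
    ends = regions["end"].to_numpy()[picks]
    span = np.maximum(ends - starts - config.rnaseq.read_len, 1)
    offs = rng.integers(0, span)
    rs = starts + offs
    return pd.DataFrame(
        {
            "chrom": regions["chrom"].to_numpy()[picks],
            "start": rs,
            "end": rs + config.rnaseq.read_len,
            "name": [f"rna_{i}" for i in range(config.rnaseq.n_reads)],
            "score": 0,
            "strand": np.where(rng.random(len(picks)) < 0.5, "+", "-"),
        }
    )


def write_fasta(sequences: dict, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            s = bytes(seq).decode("ascii") if not isinstance(seq, str) else seq
            fh.write(f">{chrom}\n")
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_simulation(
    config: SimulationConfig,
    outdir: str | Path,
) -> dict[str, str]:
    """Run the full simulation and write every output; returns a manifest
    of logical name -> file path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann = simulate_genome_and_annotation(config)
    methylomes = simulate_methylomes(config, ann)
    reads, read_truth = simulate_smrna(config, ann)
    chip = simulate_chip(config, ann)
    rnaseq = simulate_rnaseq(config, ann)

    manifest: dict[str, str] = {}

    def reg(name: str, path: Path) -> Path:
        manifest[name] = str(path)
        return path

    write_fasta(ann.sequences, reg("genome_fasta", outdir / "genome.fa"))
    core_io.write_genome_index(ann.genome, reg("chrom_sizes", outdir / "genome.chrom.sizes"))
    core_io.write_bed(ann.cgis, reg("cgi_bed", outdir / "cgi.bed"))
    core_io.write_dmr_tsv(ann.dmrs, reg("dmr_tsv", outdir / "dmr.tsv"))
    core_io.write_gene_models(ann.genes, reg("genes_bed12", outdir / "genes.bed12"))
    core_io.write_repeats(ann.repeats, reg("repeats_tsv", outdir / "repeats.tsv"))
    core_io.write_bed(ann.rrna_loci, reg("rrna_bed", outdir / "rrna.bed"))
    core_io.write_bed(ann.mirna_loci, reg("mirna_bed", outdir / "mirna.bed"))
    for stage, calls in methylomes.items():
        core_io.write_cpg_calls(calls, reg(f"calls_{stage}", outdir / f"{stage}.cov"))
    core_io.write_smrna(
        reads,
        reg("smrna_fasta", outdir / "smrna.fa"),
        reg("smrna_bed", outdir / "smrna.bed"),
    )
    for mark, fs in chip.items():
        core_io.write_bed(fs, reg(f"chip_{mark}", outdir / f"chip_{mark}.bed"))
    rnaseq.to_csv(
        reg("rnaseq_bed", outdir / "rnaseq.bed"), sep="\t", header=False, index=False
    )
    ann.regions.to_csv(
        reg("truth_regions", outdir / "truth_regions.tsv"), sep="\t", index=False
    )
    read_truth.to_csv(
        reg("truth_reads", outdir / "truth_reads.tsv"), sep="\t", index=False
    )
    config.to_yaml(reg("config", outdir / "config.yaml"))
    return manifest
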