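# Methods

## Scope and data model

`germreprog` analyzes the DNA-methylation resetting that accompanies the
specification of primordial-germ-cell-like cells (PGCLCs) from
pluripotent stem cells, together with the small-RNA (piRNA) signatures
that appear as transposable elements (TEs) lose methylation. It consumes
per-CpG methylation call counts (Bismark coverage or
bedGraph-with-counts dialects), interval annotations (BED, repeat TSV,
imprinted-DMR TSV with parent of origin), gene models (BED12) and mapped
small-RNA reads (BED6 + FASTA). All internal coordinates are 0-based
half-open; Bismark coverage input is shifted from its 1-based convention
on read. CpGs are keyed by the plus-strand C position and input counts
are assumed strand-merged, the usual coverage-file semantics; the
percent column of call files is ignored and fractions are always
recomputed from counts.

## Methylation quantitation

Regional methylation is the *weighted* fraction: summed methylated calls
over summed total calls across covered CpGs, so deep CpGs carry
proportionally more weight. An unweighted mean-of-CpG-fractions variant
is available (`quantify_probes(..., weighted=False)`); weighted is the
default and is used throughout the pipeline.

Probes:

* **20-kb tiling probes** (default step = width; trailing partial
  windows dropped so probe length stays constant), quantitated with a
  ≥10-CpG coverage floor — the global-methylation view.
* **2-kb tiling probes**, excluding any probe overlapping a repeat
  instance by ≥1 bp — the trajectory-clustering universe.
* **50-CpG probes**: consecutive blocks of exactly 50 CpGs from the
  union of positions covered in all compared samples, so probe
  definitions are shared across stages; each probe spans first to last
  CpG of its block (half-open end = last position + 1), with the final
  partial block dropped — the scatter/background-model universe.

Feature classes follow standard definitions: exons and introns from gene
models; promoters are the 1,000 bp strand-aware upstream of the TSS,
split into CGI promoters (containing or within 250 bp of a CpG island)
and non-CGI promoters; intergenic is the complement of gene bodies only
(promoters are not subtracted). Imprinted-DMR panels are reported
per-parent and combined; the combined value pools calls across the whole
panel, so a panel of fully methylated maternal and unmethylated paternal
DMRs sits near 50% until erasure. Overlapping intervals within a feature
class are merged before pooling so no CpG is double counted — except for
repeat classes, where calls are summed over every instance as such
(an instance-level pooled percentage), matching the way repeat-class
methylation matrices are conventionally built.

Metagene profiles tile 5-kb flanks with 1-kb windows at 500-bp steps
(nine windows per side) and scale each gene body into `body_bins` equal
bins (default 40 — smooth at typical gene lengths while keeping tens of
CpGs per bin); genes shorter than `body_bins` bp are skipped and all
genes are oriented TSS→TES.

## Background model of demethylation and escapee calling

To ask which regions resist the global demethylation wave between two
stages, probes present in both stages are ranked into equal-occupancy
bins by start methylation (default 20 bins, ≥50 probes per bin; the bin
count is reduced and logged when probes are scarce, and a degenerate
single-valued start distribution collapses to one bin). Each bin retains
the empirical distribution of end methylation plus its median and MAD.

Two tail statistics are offered:

* `method="empirical"` (default): the two-sided add-one rank probability
  p = 2·min(r+1, n−r)/(n+1), r the probe's mid-rank among its n bin
  peers. It is distribution-free and calibrated under the null, but
  discretely conservative — the smallest attainable p is 2/(n+1), and
  the null rejection rate at α sits ≈2/(n+1) below α. A consequence
  worth knowing: at raw two-sided α it can never flag more than ~α/2 of
  a bin per tail, so when genuinely resistant probes are a sizable
  minority (several percent), rank-based calls saturate well below full
  sensitivity.
* `method="mad_z"`: a robust normal tail, z = (end − median)/(1.4826·MAD),
  p = 2Φ(−|z|). Because median and MAD ignore a minority of outliers,
  this retains calibration under contamination and separates strong
  escapees completely. For escapee discovery we recommend
  `method="mad_z", correction="bh"`; with a 7-σ planted offset this
  yields ~100% sensitivity at an observed false-discovery proportion of
  ~1–2%, whereas a raw α=0.05 threshold would admit the full 2.5% upper
  null tail and push the FDP above 30%.

Significant probes above their bin median are "higher" (escapees),
below it "lower"; Benjamini–Hochberg correction is optional (default
none, reproducing a raw p < 0.05 readout).

## Trajectory clustering, enrichment, ChIP overlay, expression

k-means on complete (no missing time point) probe trajectories, on the
raw fraction scale, k = 7 by default, k-means++ starts, Lloyd
iterations, best of 25 restarts by within-cluster sum of squares,
deterministic under the seed (scikit-learn backend); clusters are
renumbered in descending size order. Cluster–feature enrichment compares
the percentage of cluster probes overlapping a feature class (≥1 bp)
with the universe percentage, reporting the log2 ratio (undefined when
the background is zero) and a hypergeometric upper-tail p.

ChIP tracks are overlaid as reads-per-probe-kb-per-million scores; a
probe is "enriched" when its score reaches the top decile of the
universe, ties at the threshold included. Gene-body methylation is
correlated with expression as Pearson r (Spearman optional) after
log2(x+1) transform of expression.

## Repeat expression

Repeat instances within 2 kb of any gene body (gap ≤ 2,000 bp; overlap
counts as within; distance measured to tx bounds, not exons) are removed
before quantitation so genic transcription does not contaminate TE
signal. Reads are assigned by non-directional ≥1 bp overlap; a read
counts once per repeat class however many instances of that class it
touches, and once for *each* distinct class it touches (the simplest
reading of class-pooled counting; no fractional splitting). RPKM =
count / (summed instance length in kb × library size in millions), with
the library size supplied by the caller (all mapped reads by default).

## Small-RNA signatures

Reads are labeled by a fixed hierarchy — rRNA > miRNA > piRNA gene >
repeat > gene > unannotated, ≥1 bp overlap — which reproduces the usual
sequential exclusion mapping in one pass given interval annotations.
Length spectra cover 18–35 nt over uniquely mapped non-rRNA reads;
sense/antisense splitting compares the read strand with the strand of
the overlapped repeat (largest overlap wins). The 5′-end composition
matrix spans ±30 nt with +1 defined as the read's first nucleotide (no
position 0); minus-strand reads are reverse-complemented, and positions
truncated at chromosome ends are dropped from that column's
normalization. The ping-pong profile counts opposite-strand 5′–5′
overlap distances d = p⁻ − p⁺ + 1 for d = 1…30, unweighted by read
multiplicity by default (each distinct 5′-position pair counts once; a
weighted option multiplies by multiplicities), and summarizes the 10-nt
bin as z10 = (c₁₀ − mean(c_{d≠10}))/sd(c_{d≠10}) (sample sd; undefined
and reported missing when the off-peak bins have zero spread). Histogram
normalization, where requested, is counts per million pairs.

## The simulator

The generator defines the study conditions for all tests. Each
chromosome (default 2 × 5 Mb) is tiled into 5-kb regions assigned to
classes — CGI 3%, young TE 5% (IAP/SVA-like, demethylation-resistant),
old TE 12%, gene body 30%, imprinted DMR 2%, intergenic 48%. CpGs
follow a Poisson process at 3.5/kb, 10-fold denser in CGIs (~44,000
CpGs at the defaults), with a CG dinucleotide written into the sequence
at every site. Stage means (naive → EpiLC → early PGCLC → late PGCLC)
encode the biology being modeled: a globally hypomethylated naive state
(~0.30), strong de novo methylation on priming (~0.65), stepwise
PGCLC demethylation (0.35, 0.15), young TEs resistant (0.70 → 0.60),
CGIs low throughout (0.05), imprinted DMRs intermediate then erased
(0.50, 0.50, 0.25, 0.05). Per region and stage a latent level is drawn
from a Beta around the class mean (precision 50); per CpG, coverage is
negative binomial (mean 10, shape 5) and methylated calls binomial,
with zero-coverage CpGs omitted from that stage.

Small-RNA libraries (default 5,000 reads: 55% piRNA-like, 25% miRNA-like
22–23 nt, 15% rRNA, remainder genic) sample primary piRNA reads
(24–31 nt) from TE instances; the 5′ base is written into the genome as
read-strand T with probability 0.8 before sequence extraction, so every
read remains an exact genome substring while the 5′U bias is emergent.
Secondary reads (30% of piRNA reads) are placed on the opposite strand
with their 5′ end across from nucleotide 10 of their primary partner —
the slicer-cleavage rule — so the 10-nt ping-pong peak is a mechanistic
consequence in the reads, never hard-coded in the statistic that
detects it. ChIP-like tracks sample reads with 8-fold weight on
resistant regions (H3K9me3-like) or CGIs (H3K4me3-like); RNA-seq-like
reads sample regions with genes high and young TEs expressed. All draws
derive from the config seed; identical configs are byte-identical.

What the simulator does **not** emulate — and hence what passing tests
do not demonstrate about real data: realistic sequence composition
beyond CG placement, bisulfite conversion failure, M-bias, strand
asymmetries, copy-number and mappability structure, locus-level TE
heterogeneity, and the smooth genome-wide correlation structure of real
methylomes. Recovery results on planted structure bound the method's
behavior under the stated noise model only.

## Numerical and design choices

* Equal-occupancy bin edges come from quantiles; duplicate edges are
  collapsed, and a fully degenerate start distribution becomes a single
  logged bin. Requesting ≥2 bins with too few probes for 2 bins is an
  error.
* Ties in the empirical rank p are mid-ranked; ties at the ChIP
  enrichment threshold are all included; k-means empty clusters are
  handled by the backend's deterministic relocation.
* Null calibration of the empirical p is verified as the mean flagged
  fraction across 10 seeded replicates lying inside the 99% binomial
  band at a single replicate's size — the statistic's own ≈2/(n+1)
  conservatism is a property, not a bug, and is documented above.
* The imprint-panel erasure check allows each stage step to rise by at
  most 3 sd of the step estimate, since the first two generator means
  are equal and a strict non-increase would fail on noise alone.
* TSV outputs use fixed %.6g float formatting so identical seeds give
  byte-identical files.
* Problem sizes used by the bundled checks: the default 10-Mb genome
  for oracle equivalence and imprint tracking; 10,000-probe synthetic
  matrices for calibration and escapee recovery; 3,500 trajectories for
  cluster recovery; 5,000 piRNA reads for ping-pong; 2,000 for 5′U
  recovery. These sizes give comfortable statistical margins while
  keeping the whole suite in seconds.

## Known limitations

Non-CpG methylation, 5hmC, per-read epialleles, HMM/regression DMR
callers, ChIP peak calling, piRNA cluster discovery, phasing signatures
and multi-mapper EM reassignment are out of scope. The background model
assumes probes within a start-methylation bin are exchangeable under the
null; strong residual covariates (CpG density, chromatin state) violate
this and should be assessed via the enrichment and overlay tools rather
than absorbed into the test.
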