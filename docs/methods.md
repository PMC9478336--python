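# Methods

This note documents the models and procedures `admixpress` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not establish
about real data.

## Study design being modelled

Two pure ancestral citrus species — pummelo (PU) and mandarin (MA) — are
separated by fixed homozygous SNP differences. Hybrid segregants derived
from admixed parents carry genomes that are mosaics of MA/MA, PU/MA and
PU/PU tracts produced by meiotic crossovers. Expression is measured by
bulk RNA-seq in five groups (a wild outgroup ICH, the reference mandarin
SCM, and three segregants S1–S3) with three biological replicates each,
and by qPCR with two reference genes.

## Species-informative markers

A SIM is a biallelic site at which panel A is homozygous for one allele
and panel B homozygous for a different one, with read depth ≥ `min_depth`
(default 20) in **both** panels. The both-panels reading of the depth rule
is a design choice: a marker unreliable in either species cannot
diagnose ancestry. Heterozygous or missing genotypes disqualify a site
(fixation cannot be established from them); multi-allelic sites are
skipped and counted. Swapping the panels swaps the allele columns but
never the site set, and raising the depth threshold can only remove
markers — both properties are tested.

## Ancestry painting

Per genotyped SIM the copy number of the pummelo allele (2, 1, 0) is
recorded; genotypes carrying an allele matching neither diagnostic allele
are excluded and tallied. Chromosomes are tiled into consecutive,
non-overlapping windows of `window_size` markers (default 1000). Tiling
rather than sliding is an assumption; it makes window labels independent
and the smoothing rule well defined. The trailing partial window is kept
when it holds ≥ half a window of markers and merged into its predecessor
otherwise — a compromise between spurious short windows and lost
telomeric signal.

Each window takes the most frequent pattern as its label; an exact tie is
labelled AMBIGUOUS rather than resolved arbitrarily, deferring the
decision to the smoothing pass. Runs of ≥ `min_stable` (default 5)
identically labelled windows become stable blocks; every remaining window
— including AMBIGUOUS ones — receives the label of the nearest stable
block, nearest in window-index distance with ties to the left (5′)
neighbour, which is deterministic and orientation-stable. A chromosome
with no stable run collapses to a single unstable segment carrying its
most frequent window label. Segment coordinates span first-to-last member
marker: the method asserts nothing beyond the markers it saw.

Genes take the label of the segment overlapping most of the gene body
(1-based inclusive bp); an overlap tie goes to the segment containing the
gene start; genes on markerless scaffolds are UNASSIGNED.

The resolution limit of this estimator is the window: a crossover inside
a window misassigns at most the minority side of that window (≈ 250
markers on average), and tracts shorter than `min_stable` windows are
absorbed by design. Recovery benchmarks therefore run in the long-tract
regime (every tract ≥ 10 windows of markers, enforced in the generator by
redrawing breakpoint configurations), where marker-level accuracy
exceeds 99% and every true breakpoint falls within one window-span of an
inferred boundary.

## Differential expression

Library sizes are median-of-ratios factors: for genes with nonzero counts
in every sample, a sample's factor is the median ratio of its counts to
the per-gene geometric mean. The per-gene NB dispersion α is estimated by
method of moments from within-group variation pooled across the two
contrasted groups (σ̂² vs mean on the normalized scale), floored at 1e-8,
then shrunk 50/50 toward a trend α(μ) = a₀ + a₁/μ fitted across genes —
the standard asymptotic shape of the mean–dispersion relation. The
deliberate choice of moments-plus-trend over an external package's
empirical-Bayes machinery keeps the stage self-contained; the contract is
statistical (error control and recovery), not package identity.

Group abundance is q = Σ counts / Σ size factors (the Poisson score
estimator, consistent under the NB model), with a half-read continuity
term so a group with zero counts yields a finite, strongly signed log₂FC.
The Wald statistic is log₂(q₁/q₂) over its delta-method standard error
under Var(Y) = μ + αμ². Because the per-gene dispersion rests on only
n₁+n₂−2 residual degrees of freedom, the statistic is referred to a
moderated t distribution with df = residual + prior, the prior taken as
twice the residual df to credit the information contributed by the
cross-gene trend through the shrinkage (the quasi-likelihood moderation
argument); with 3 + 3 replicates this gives 12 df, and the reference
approaches the normal as replication grows. Under the package's own null
simulation (5,000 genes, dispersion 0.1, 3 vs 3) the empirical size at
nominal 0.05 is measured by the test suite; a plain normal reference is
measurably anti-conservative in this regime. Genes with all-zero counts
in both groups are excluded from testing and from the BH denominator.

DEG selection applies |log₂FC| ≥ threshold (boundary inclusive) and
padj < α (strict) — the presets are `soft` (0.58, 0.05) and `strict`
(1, 0.01). The consensus rule intersects the three segregant contrasts on
identical direction and then applies the 100-read filter on **raw**
counts ("reads" means read counts, not normalized values) over the
replicates of the compared groups, boundary inclusive.

The TPM-like output divides by size factors and rescales each sample to
sum to one million. It deliberately has no gene-length term: it is a
size-factor normalization presented per million, which suffices for
within-gene cross-sample comparison, not for cross-gene comparison.

## Pathway tri-state

A node whose member DEGs share one direction takes it. With both
directions present and read-credible genes (≥ 100 reads in some
replicate) on both sides, the node is undetermined — unless one direction
has strictly more genes **and** strictly more summed raw reads, in which
case it dominates ("unequivocally higher" operationalized as a double
strict inequality). When only one side has a read-credible gene, that
side wins; when neither does, the dominance comparison decides, with
undetermined on ties. The rule is label-symmetric: flipping every
direction flips up↔down and preserves undetermined.

## Allele-specific expression

The RNA genotype at a SIM in one replicate is called homozygous for the
major allele when the minor allele has < 2 reads **and** < 5% of the
site's reads, heterozygous otherwise, and no-call at zero coverage. This
count rule is a self-contained stand-in for a full RNA variant-calling
pass; its thresholds make single stray reads (sequencing error scale)
tolerable at depth while never absorbing genuine biallelic signal at 10x+.
A SIM passes when mean depth across replicates ≥ 10 and all replicates
agree on the genotype; a gene is eligible when ≥ 80% of its SIMs pass
(the "approximately 80%" criterion fixed at ≥ 0.80 exactly,
configurable). Classification over passing SIMs: all homozygous pummelo →
PU-only; all homozygous mandarin → MA-only; otherwise biallelic. The
pummelo-allele fraction pools reads over passing SIMs and replicates
(depth weighting, rather than averaging per-replicate fractions).

Haplotype summaries count a gene as expressed when some replicate reaches
10 raw reads; proportions are over assigned expressed genes and the DEG
frequency of a haplotype is DEGs / expressed genes within it.

## ΔΔCt

ΔCt = Ct_target − mean(Ct_ref1, Ct_ref2) — the arithmetic mean of the two
reference Cts, equivalent to the geometric mean of their linear
quantities, which is standard practice with two reference genes.
ΔΔCt subtracts the calibrator sample's ΔCt; relative expression is
2^(−ΔΔCt), so the calibrator reads exactly 1.

## Synthetic data generator

The generator emulates: two panels separated by an exact number
(`round(fixed_diff_fraction × sites)`) of fixed differences; per-site
Poisson read depth; segregants built from two gametes whose crossover
counts are Poisson per chromosome with uniform positions and no
interference (no genetic map is assumed); NB counts with a per-gene
log-normal baseline (default mean 100, sdlog 1), group fold changes of
±`lfc_magnitude` applied to every non-reference group for a fraction
`frac_de_genes` of genes (the concordant design the consensus rule
targets); and allelic reads at SIMs inside PU/MA genes split
Binomial(total, p) with p ∈ {1, 0, 0.5} according to a gene-intrinsic
monoallelic/biallelic truth. Defaults follow the study design: 3
replicates × 5 groups, NB dispersion 0.1 (a typical bulk RNA-seq
biological-replicate value), 30x DNA depth, 30% fixed differences.
Random streams are split per stage and per segregant from the master
seed, so adding a segregant never perturbs earlier output, and a fixed
seed fixes every table bit for bit.

`min_tract_markers` optionally redraws breakpoint configurations until
every tract holds at least that many diagnostic markers; recovery
benchmarks use it to pin the long-tract regime described above.

What the generator does **not** model: read-level artefacts (FASTQ,
sequencing error, mapping bias toward the reference allele), linked
genotyping error, crossover interference, dispersion that varies by gene
beyond the mean trend, or correlated replicates. Passing recovery tests
therefore demonstrate the correctness and calibration of the inference
chain under its own assumptions, not robustness to mapping bias or batch
structure in real libraries — mapping-bias correction is explicitly out
of scope for the ASE stage.

## Benchmark problem sizes

The shipped benchmarks use: three segregants on two 100,000-site
chromosomes (≈ 57,000 called SIMs) for ancestry recovery; 5,000 genes,
3 vs 3 at dispersion 0.1 for the null calibration; 5,000 genes with 10%
planted |log₂FC| = 2 at mean 500 and dispersion 0.01 for consensus
recovery (the low-dispersion regime in which a fourfold change is
unambiguous, so recall measures the pipeline rather than the noise
floor); 400 genes at ≈ 25x allelic depth for ASE recovery. These sizes
give stable Monte-Carlo estimates in well under a minute per benchmark on
one core.

## Numerical and degenerate-input conventions

Coordinates are 1-based, end-inclusive everywhere (VCF convention);
BED-like outputs carry a header comment saying so. Dispersion floor 1e-8;
all-identical count matrices give size factors of exactly 1; a count
matrix with no universally expressed gene raises a normalization error; a
contrast with a single-replicate group raises a design error; an empty
pathway membership raises; a gene with zero RNA reads at passing SIMs
raises (it cannot have passed the depth filter). Window-vote ties are
AMBIGUOUS; smoothing distance ties go left; gene-overlap ties go to the
segment containing the gene start.

## Known limitations

Two-way admixture only; no probabilistic/HMM ancestry model (hard window
votes lose information near breakpoints); no phasing beyond the
diagnostic alleles; the DE engine is intentionally simpler than
empirical-Bayes packages and should not be expected to reproduce their
per-gene p-values; the ASE stage tests exclusivity, not graded allelic
imbalance (no beta-binomial test).
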