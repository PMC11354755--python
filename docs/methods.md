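# Methods

## Coordinate conventions

All internal coordinates are 0-based, half-open `[start, end)`. GFF3
(1-based inclusive) is converted on read; BED and bedGraph are taken
as-is. A gene's poly(A) site defaults to its strand-aware last
transcribed nucleotide (`end − 1` on `+`, `start` on `−`) and can be
overridden per gene from a sidecar TSV, since curated poly(A) cleavage
sites generally differ from annotated CDS/transcript ends. Window
offsets are always in the transcription sense: negative = upstream,
positive = downstream, and signal vectors for `−` strand genes are
reversed so index 0 is the most 5′ requested offset.

Coverage represents the 3′ end of each nascent read once, per nucleotide
and strand. When ingesting SAM/BAM the 3′-terminal aligned base of each
read is counted on the read's strand; bedGraph pairs are taken as
already-reduced 3′-end densities. No between-library normalization is
applied at load: every downstream statistic is either a within-sample
ratio (RTI, BNSAF, ChIP occupancy) or CDS-normalized, so library size
cancels — the test suite asserts this scale invariance explicitly.

## Gene inclusion filters

Three inclusive thresholds define the analyzed set:

| filter | default | reason |
|---|---|---|
| neighbor distance | ≥ 500 nt | yeast genes are packed; a close downstream same-strand gene would contaminate the readthrough window with its own transcription |
| gene length | ≥ 500 nt | the upstream reference window must sit in the gene body |
| expression | ≥ 1 read/nt over the CDS in ≥ 3 replicates | RTI is a ratio; it is meaningless for silent genes |

"Neighbor" means the nearest same-strand gene edge downstream of the 3′
end (the readthrough direction), not the nearest gene in either
direction; a gene with no downstream neighbor on its strand gets an
infinite distance and passes any threshold. The expression criterion
pools replicates across both genotypes (6 in a 3+3 design) and counts
how many meet the threshold. The funnel counts are reported in the order
distance → length → expression; the final set is a pure intersection and
order-independent.

## Readthrough index

For each gene and replicate,
`RTI = Σ reads(+50..+500) / Σ reads(−500..−50)` around the poly(A) site,
i.e. two half-open 450-nt windows with a 50-nt exclusion zone on either
side of the cleavage site (the zone absorbs positional uncertainty of
the annotated site and pileups at cleavage itself). Windows that run off
a chromosome end are flagged and excluded rather than zero-padded, which
would bias the ratio. An RTI with zero upstream reads is undefined and
that replicate is dropped, not imputed; the expression filter makes this
rare.

Differential readthrough per gene is a one-sided Welch (unequal
variance) t-test, alternative mutant > WT, on the replicate RTI values
(raw, not log-transformed), requiring ≥5 defined replicates in total and
≥2 per genotype; genes failing the minimums are reported unsounded with
a reason code. Significance requires p < 0.05 and a log2 mutant/WT ratio
of mean RTIs > 1 (a 2-fold increase); both thresholds are configurable
(e.g. log2 > 2 for a stricter 4-fold call). When both genotypes have
zero within-group variance the Welch statistic is undefined and the
limit is reported — p = 0.5 for equal means, otherwise 0 or 1 — with a
degeneracy flag. No multiple-testing correction gates the default call;
a Benjamini–Hochberg q-value column is emitted alongside for users who
want it.

Genome-wide summaries use the unweighted mean over genes of per-gene
replicate-mean RTIs (the alternative — pooling replicates before
averaging — weighs genes by replicate count and is available by
computing from the per-replicate table). The mean comparison between
genotypes is a two-sided paired t-test across genes; an unpaired Welch
p-value is reported alongside the medians.

## Metagene and heat map

Each gene's signal in −200..+200 nt around the poly(A) site is divided
by that gene's mean CDS read density in the same replicate, so the
profile is in units of "fraction of gene-body polymerase density" and a
perfectly uniform gene sits at exactly 1 (asserted per gene). Only full
windows enter. The profile is the per-offset mean over the pooled
(gene × replicate) vectors of a genotype; the standard error is the
sample SD over that pool divided by √count. Pooling (rather than SE
across genes of per-gene means) was chosen because one band per genotype
is drawn from all replicates; the distinction only changes the band
width, not the mean. Heat-map rows are ordered by ascending per-gene
mean mutant RTI with lexicographic tie-breaks; genes lacking a defined
mutant RTI are placed last and flagged. The row order is identical
across all samples so the matrices are visually comparable.

## BNSAF proteomics

SAF = spectral counts / protein length in amino acids; BNSAF =
SAF(protein) / SAF(bait) within the same purification, which pins the
bait at exactly 1 and makes the measure invariant to per-sample scaling.
Length normalization uses amino-acid length; a counts-only mode
(`bnsaf = counts/counts_bait`) exists for tables without lengths and is
labeled distinctly in the output. A sample in which the bait has zero
counts carries no internal reference and is rejected with an error.
Genotypes are compared per protein with a two-sided paired t-test across
replicate purifications (replicate indices must match one-to-one);
chromatin and soluble fractions are analyzed separately and never
merged. Complex-level summaries (CF1: Rna14, Rna15, Pcf11, Clp1, Hrp1;
Rat1: Rat1, Rai1; CPF; general transcription factors) aggregate member
percent changes; the complex mean always lies between the member
extremes.

## ChIP and TRO

ChIP occupancy = (factor ChIP / input) / (RNAPII ChIP / input) at the
same amplicon — a double ratio invariant to rescaling either pair, so
differences in immunoprecipitation efficiency or input amount cancel.
TRO nascent signal is the RT-PCR signal divided by the 18S control.
Genotype comparisons use percent change of group means with a Welch
t-test, two-tailed by default (configurable to one-sided); percent
decline is undefined (flagged) when the reference mean is zero. Both
operations start from per-amplicon signal tables; raw qPCR curve
processing is out of scope.

## The simulator

The generator emulates the features of nascent 3′-end coverage that the
statistics actually see: a flat Poisson polymerase density over the gene
body (`body_rate`, default 10 reads/nt), a drop at the poly(A) site, and
downstream density `body_rate · r` from a readthrough fraction `r` —
constant over `readthrough_extent_nt` (default 500) and zero beyond, or
decaying as `2^(−d/halflife)` when a half-life is set. Defaults plant
`r = 0.05` in wild type and `0.15` in the mutant with 3 replicates per
genotype over 200 genes. Gene lengths are drawn from 1000–2000 nt and
inter-gene spacings from 600–1200 nt so the inclusion filters pass by
construction and both RTI windows sit inside gene body/readthrough
zones; chromosome ends are padded so no window truncates. Counts are
Poisson per nucleotide with no overdispersion parameter (an extension
point); replicate-to-replicate variation in the coverage model is purely
counting noise. The proteomics generator draws Poisson counts around
`abundance × length × scale` with a per-replicate lognormal factor
shared between genotypes, making the paired design real; ChIP and TRO
tables use lognormal replicate noise (CV 15–20%) around planted effects
(90% occupancy decline; 3-fold downstream TRO increase in the mutant).
Everything derives from `numpy.random.default_rng` seeded with the
user's seed plus fixed stream offsets, so the full fixture set is
byte-reproducible.

What the simulator deliberately omits — mappability gaps, promoter
pausing peaks, antisense transcription, 3′-end heterogeneity, library-
size differences between replicates, overdispersed counts — means that
passing tests demonstrate correctness of the window arithmetic,
filtering logic and statistical machinery, and estimator calibration
under the stated noise model; they do not certify performance on real
libraries, where the expression filter and the exclusion zone do the
corresponding work.

## Problem sizes and numerics

The test suite and the acceptance script run simulations of 200–500
genes (≈0.3–1 Mb of dense coverage, 6 replicates), which is where the
estimator's standard errors are small enough for 3-SE recovery checks
while the whole suite stays fast. The brute-force oracles (per-position
window sums, exhaustive neighbor scans, elementwise normalization)
recompute results independently of the vectorized paths. Ties in
heat-map ordering break lexicographically by gene id; filter thresholds
are inclusive at the boundary; undefined quantities (RTI with empty
upstream window, decline with zero reference mean) are propagated as
explicit flags rather than NaN arithmetic.
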