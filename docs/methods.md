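# Methods

This note documents the models and procedures `mirweave` implements, the
defaults and why they were chosen, what the synthetic study generator does
and does not emulate, and the numerical decisions that matter when reading
its outputs.

## Study design emulated

The pipeline targets a common design in non-model plant stress genomics:
eight sampling durations S1..S8 after treatment onset (a control plus seven
stress durations), one collapsed small-RNA library per duration, a single
pooled degradome library, and per-gene digital expression counts on a
de-novo assembled transcript set that stands in for a genome. The number of
time points is a parameter (k ≥ 2) with 8 as the default.

## Small-RNA catalogue

Tags are collapsed per library into unique sequences with per-library
counts, stored in the DNA alphabet (U→T) and rendered back as needed. The
analysis window is 17–25 nt inclusive. Contaminant removal is exact
substring matching of each tag against the supplied rRNA/tRNA/snRNA/snoRNA
set on both strands — a deterministic stand-in for a BLAST screen that is
exact at desk scale and has no scoring heuristics to tune.

Matching against a reference mature set allows up to 2 end-shift nucleotides
per side and up to 2 substitutions, the span of variation the field's
`L±n/R±n/kss` suffix grammar encodes. Among admissible explanations of a tag
the match minimising (substitutions, total shift) wins, with ties broken by
(reference id, left shift, right shift); the field-standard name is rendered as
`refid[_L±n][_R±n][_kss<pos><ref><alt>…]` with substitution positions
1-based on the reference. On random references this naming is invertible
(apply-then-derive is the identity); pathological periodic references could
in principle admit two minimal explanations, which the deterministic
tie-break resolves reproducibly.

Abundance tiers follow the catalogue convention: low < 10 total reads;
high > catalogue mean; middle otherwise (a total exactly at the mean is
middle, since "high" is defined as strictly over the average).

## Hairpin discovery and validation

Candidates are excised around each seeding tag with flank windows of 80,
150 and 250 nt on either arm hypothesis, covering typical plant precursor
lengths. Folding delegates to the ViennaRNA nearest-neighbour MFE model
through an injectable engine interface; a base-pair-maximisation stub exists
for structure-only tests and is clearly non-thermodynamic. AMFE is
|MFE|/length×100 (kcal/mol per 100 nt) and MFEI is AMFE divided by GC
percentage, a dimensionless hairpin-quality index. MFEI is reported, not
gated, by default (`--min-mfei` exists): published precursor sets describe
an observed MFEI range rather than a hard cutoff.

Validation implements the plant-annotation consensus quantitatively:

- (a) ≥ 75 % of mature bases paired;
- (b) those pairs must land in one compact window on a single side of the
  mature — the star arm.  The window may exceed the mature length by at most
  2 nt (`max_bulge`), the usual limit on asymmetric bulges; pairing across
  the terminal loop or scattered over both arms fails.  Judging compactness
  on the densest window rather than on all partners makes the check robust
  to stray long-range pairs involving a few mature bases;
- (c) ≥ 80 % of precursor-mapped read counts must start within ±2 nt of the
  mature or star 5' ends (Dicer-consistent read stacking);
- (d) MFE/AMFE/MFEI are recorded on every candidate.

Specificity is assessed against Altschul–Erickson dinucleotide shuffles
(exact dinucleotide counts preserved) carrying the same read stack; across
seeds ≈ 96–98 % of shuffled controls fail, essentially always on duplex
geometry. The residual passes are short random RNAs that genuinely fold
into a hairpin with the mature span in one arm — a structural
false-positive class that read-coverage evidence cannot remove when the
mature stack dominates the library, which is why confident novel calls also
require star-read presence.

The star strand of a planted duplex is defined with a 2-nt 3' overhang on
both strands (the canonical Dicer product geometry).

## Degradome target calling

Complementarity scoring uses the Allen-style plant rubric over antiparallel
duplexes: Watson–Crick 0, G:U wobble 0.5, mismatch 1, gap 2, all penalties
doubled at miRNA positions 2–13 from the 5' end; at most one bulged base on
either strand. The default cutoff is 4.0 penalty units. The implementation
is vectorised over all transcript offsets and is tested for exact equality
against a plain all-offset scorer.

The canonical cleavage site is the transcript base paired to miRNA position
10 (cleavage between the bases paired to positions 10 and 11); it is read
off the per-position pairing map, so a single bulge 5' of position 10
shifts the site by the gap offset automatically, and a duplex whose position
10 is itself bulged yields no call.

Degradome tags (20–21 nt, the read lengths a PARE protocol produces) are
placed by exact sense-strand matching; multi-mapping tags count at every
locus, the conservative choice for redundant de-novo assemblies. Cleavage
signatures are classified on the transcript's 5'-end profile:

- 4 — a single raw read at the site;
- 0 — count > 1 equal to the transcript's unique maximum;
- 1 — count > 1 equal to a tied maximum;
- 2 — above the profile median;
- 3 — at or below the median.

"Over one raw read" is read as count > 1; the alternative (≥ 1) would make
category 4 unreachable. The median is computed over positions carrying at
least one read (`--median-mode nonzero`), because the median over all
transcript positions of a sparse profile is ~0 and would make category 3
unreachable; `--median-mode all` implements the literal alternative. A hit
is emitted when the canonical site carries signal (window ±0 by default,
up to ±1 via `--cleave-window`); all categories are retained, with one
best-scoring hit per (miRNA, transcript, site).

## Differential expression

Expression is RPKM = count / (length/10³) / (library/10⁶). The two-library
test is the Audic–Claverie exact test: given x reads in a library of size
N1, the count y in a library of size N2 follows a negative binomial with
r = x+1 and success probability N1/(N1+N2); the two-sided p doubles the
smaller tail, capped at 1. Tail sums are evaluated through scipy's
log-scale negative-binomial routines and verified against direct log-gamma
summation to 1e-10. Under matched Poisson nulls the empirical type-I rate
at 0.05 is ≈ 0.045 — the test's well-known slight conservatism from
discreteness. Note the two-sided statistic is exchange-symmetric in
(x,N1)↔(y,N2) only up to discrete boundary terms of the tail sums (within a
factor 2 deep in the tails); significance calls at usual levels are
unaffected.

Gene significance is the conjunction p < 0.005 AND BH-FDR ≤ 0.001 AND
|log2 ratio| ≥ 1, with FDR computed per pairwise comparison and the log2
ratio taken on RPKM with a 0.01 pseudocount (zero handling is otherwise
undefined). miRNAs use the looser p < 0.05 per comparison on raw
per-library counts with library-size totals passed to the test; the strict
tier additionally requires total raw abundance > 10 across libraries (the
abundance gate is deliberately un-normalised — it is a read-support filter,
not an expression estimate). Z-scores are per-feature (x−mean)/sd with
constant profiles mapped to zeros.

## Integration

A pair (m, t) is reported when m is strict-DE, (m, t) is a degradome hit,
and t passes the gene thresholds in at least one comparison. Direction is
classified by the Pearson correlation of the pair's Z-scored profiles:
negative at r ≤ −0.5, positive at r ≥ 0.5, else uncorrelated; a constant
profile gets r = 0. The −0.5 default is a judgement call — visual
"reversed heatmap pattern" criteria have no published numeric equivalent —
and is exposed as `--neg-r`. Z-scoring does not change Pearson r; it is
kept to mirror how such profiles are displayed. Term enrichment is the
one-sided hypergeometric upper tail (identical to one-sided Fisher),
gating on raw p < 0.05 with a BH column reported but not gating; the
background defaults to all annotated genes.

## Coexpression network

Genes with more than four zero counts across the eight samples are removed
(the count filter that "selected" genes in the original phrasing is read as
exclusion, which the surrounding text confirms) and survivors are
log2(x+1)-transformed. The unsigned adjacency is |Pearson|⁶ — power 6 is
the conventional default for unsigned networks — with unit diagonal and
zero-variance genes given zero correlation. Topological overlap is
TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij).

Modules come from average-linkage hierarchical clustering on 1 − TOM with a
static cut at height 0.95 and a minimum size of 30; clusters below the
minimum fall into "grey". A static cut replaces the dynamic tree cut for
determinism and dependency-lightness at desk scale; both knobs are exposed.
Labels follow the WGCNA colour sequence by size rank. The module eigengene
is the first principal component of the gene-standardised submatrix with
samples as observations, sign-oriented to correlate positively with the
module mean profile; variance explained is reported. Hub subnetworks export
(hub, gene, a_ij) edges at a_ij ≥ 0.1 (a common export default; published
edge counts never state their threshold) plus the neighbour set shared by
all requested hubs.

## Synthetic data: what it emulates, what it does not

The generator plants, under one seed: random transcripts at 45 % GC
(500–1500 nt); 30 miRNAs (21 nt) each with a hairpin precursor
(15-nt flanks, 15-nt loop, 0–2 G:U wobbles in the star arm); 30 target
transcripts carrying an exact reverse-complement site; a degradome with
peak_count = 5 tags exactly at each canonical cleavage site over count-1
uniform background (0.05 tags/kb); eight sRNA libraries holding the mature
(NB, base mean 100) and star (base mean 10) stacks plus a background whose
length law peaks at 24 nt — the signature of an angiosperm sRNA population —
and a few planted contaminant fragments; gene counts (NB, base mean 200,
dispersion 0.05) with 8-fold step trajectories planted so that 20 pairs are
anti-correlated and 10 positively correlated; and four correlated blocks of
100 genes each (pairwise r = 0.8) with one hub per block.

Two constructions are deliberately exact rather than merely expected.
Block factors are mean-centred and QR-orthogonalised across the eight
samples and each gene's noise is projected orthogonal to every factor, so
the planted inter-block correlation of zero is realised in-sample; with
only eight samples, free Gaussian factors would collide (|r| > 0.68 between
two block factors is a ~30 % event per draw) and module recovery would
reflect factor collisions rather than method behaviour. The hub gene is a
noise-free copy of its block factor: at eight samples the sampling spread
of per-gene factor correlations (Fisher-z s.d. 1/√5 ≈ 0.45) means any
noisy hub construction is overtaken by some ordinary member almost surely,
so a "highest-connectivity hub" ground truth is only well-defined for the
noise-free choice (`hub_cor` is exposed for weaker wiring).

Not emulated: sequencing errors, adapters and quality scores (collapsed
tags are the unit of analysis); multi-branched precursors; translational
repression; miRNA families and genomic multi-locus structure; GO DAG
structure (enrichment uses a flat gene→term table). Consequently, passing
tests demonstrate correctness of the implemented rules and recoverability
of planted signal under realistic noise — not robustness to base-calling
artefacts or annotation ambiguity in real libraries.

## Problem sizes and determinism

Default verification sizes: 10 000 random profiles for the category
classifier; 30 planted interactions + 30 decoys for target recovery;
100–200 random pairs for the alignment oracle; 10 000 null pairs for test
calibration; 800 genes (60 planted) for DE sensitivity; 5 seeds × 400 genes
for module recovery; 600 dinucleotide shuffles for hairpin specificity;
1000 sampled names for the nomenclature round trip. These sizes keep the
full verification run in well under a minute per stage on one CPU while
leaving binomial noise far from every decision bound.

All randomness flows from a single seed through `numpy.random.default_rng`;
generators are pure functions of (parameters, seed), the truth manifest is
byte-identical across reruns, and every stochastic stage logs its seed.
Identical configurations produce byte-identical outputs (the run manifest
records parameters and input checksums, no timestamps).
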