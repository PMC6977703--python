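# Methods

## Model-profile clustering over an ordered condition series

The central computation treats the four experimental groups (Sham, PD,
NLID, LID) as an ordered series and clusters genes by the *shape* of
their expression across it, following the short time-series clustering
idea: because replicates are few and the series is short, candidate
cluster centers are not learned from the data but enumerated a priori as
integer-valued shapes.

**Candidate set.** A shape is a length-*T* integer vector starting at 0
whose successive differences lie in [−c, +c]. The set has
(2c+1)^(T−1) members, minus one when the flat (all-zero) shape is
excluded. With T = 4 and c = 1 this gives 3³ − 1 = 26 profiles, the
count used throughout. c = 1 is the unique unit-change bound producing
26 profiles for four conditions, and the flat profile must be excluded
to reach it; both choices are defaults and arguments. Profile ids are
assigned in lexicographic order of the vectors so they are stable across
runs and platforms.

**Gene series.** Replicates are collapsed to condition means before any
transform (each gene contributes one curve across the four groups), and
the series is the log2 ratio against the first condition,
sₜ = log₂((x̄ₜ + ε)/(x̄₀ + ε)) with pseudocount ε = 1 FPKM by default
(s₀ ≡ 0). The pseudocount keeps zero-expression conditions finite; at
FPKM ≫ 1 its effect is negligible.

**Assignment.** Each gene goes to the shape maximizing the Pearson
correlation between its series and the shape vector. Correlation makes
the assignment invariant to positive affine scaling of the series, so a
gene falling 4-fold and one falling 16-fold with the same relative
timing land on the same profile. Zero-variance series are returned
unassigned (`zero-variance`); an optional similarity floor
(`min_similarity`, default 0) unassigns weak matches
(`below-min-similarity`). Ties break to the smallest profile id.

**Permutation significance.** Under the null hypothesis that condition
order carries no information, each gene's T condition values are
exchangeable. The null therefore permutes every gene's series over the
T! orderings (4! = 24, run exhaustively for T = 4), re-references each
permuted series so its first element is 0 (the same transform the
observed data received), and re-assigns. A profile's expected count is
the mean assigned count over permutations, and its p-value is the upper
binomial tail P(X ≥ observed) with X ~ Binom(n_genes, expected/n_genes).
The identity permutation is included in the null average (slightly
conservative; a flag drops it). On flat-noise data roughly none of the
26 profiles reach p < 0.05 (calibration is asserted as a property test
over 20 seeds, threshold ≤ 0.12 on the mean fraction).

**Pattern selection.** The monotone-decreasing shape (0, −1, −1, −2) —
high in Sham, lower in PD and NLID, lowest in LID — is the pattern of
biological interest; `select_pattern_genes` returns the genes assigned
to any given shape together with that profile's significance record.

## Differential expression and enrichment

The screen applies the conjunction |log₂FC| ≥ log₂(fc_threshold) and
BH-FDR q ≤ fdr_threshold (defaults 2 and 0.05). Fold change is computed
from condition means with pseudocount 1 on the FPKM scale. The study's
count-based negative-binomial test is out of scope here; the built-in
p-value source is Welch's t on log₂(x+1) across replicates — a
deliberately simple, clearly labeled stand-in — and a per-gene p-value
table from any external tool can be supplied instead, so the
thresholding logic is exercised either way. With the default three
replicates per group the t stand-in is underpowered relative to a
count-based test; see "Stage order" below. Down-regulation counts
toward the fold-change rule by default (|log₂FC|); a flag restricts to
one side. Enrichment is the one-sided over-representation
(hypergeometric upper-tail) Fisher test per annotation term against a
user-supplied term→gene table; no correction is applied across terms
(selection at raw p < 0.05), and no ontology-graph propagation is done.

## lncRNA candidate filter

A novel transcript is a lncRNA candidate iff all of: spliced length
≥ 200 nt; ≥ 2 exons; longest ORF ≤ 300 nt; CPC score < 0; CNCI-style
coding score < 0; no significant Pfam hit. Thresholds are inclusive
(≥/≤) at the boundary. The coding-potential engines are external and
their scores arrive as inputs; the ORF finder is built in: it scans the
three sense-strand frames for ATG…{TAA, TAG, TGA}, counts the stop
codon in the length, treats codons containing N as matching neither
start nor stop, and returns 0 when no complete ORF exists. Sense-strand
scanning is the default because spliced transcripts are stranded; a
six-frame flag exists for unstranded input. Merging with a known-lncRNA
annotation set de-duplicates by id with known provenance winning.

## ceRNA network inference

Step 1 computes Pearson correlations for every lncRNA × mRNA pair using
all samples across all four groups (the "overall correlation
distribution" is read as this full pool). Step 2 keeps pairs at or
above the pool's 99th percentile, computed by the nearest-rank rule —
the ⌈p/100·n⌉-th order statistic — which is deterministic and
interpolation-free; ties at the threshold are retained. Step 3 keeps a
(lncRNA, miRNA, mRNA) triplet iff both members contain at least one
perfect 6mer seed site of the shared miRNA: an exact occurrence of the
reverse complement of miRNA nucleotides 2–7 (the TargetScan 6mer
convention; the seed window is configurable). G:U wobble does not count
as a match by default (sites are perfect); a flag enables wobble
tolerance. Signed r (not |r|) is used throughout, matching the printed
"≥" threshold. The standalone co-expression network uses a fixed
r ≥ 0.99 cut instead of a percentile. The miRNA set is a required
input: no miRNA assay is modeled, so the sequences must come from an
external catalog (or the synthetic generator).

## Cis and trans target prediction

Coordinates are 1-based inclusive (GTF convention). The gap between two
non-overlapping spans is `later.start − earlier.end − 1`; overlapping
spans are at distance 0. A gene is a cis target of a lncRNA when both
lie on the same chromosome and the gap between their transcript spans
is ≤ 10 kb (window configurable, strand-agnostic, symmetric up/down).
Window ends are the transcript span ends, not the TSS.

Trans prediction is a two-stage screen-then-score: stage 1 keeps
candidates sharing at least one exact reverse-complement k-mer
(default k = 12) with the lncRNA; stage 2 scores the best ungapped
antisense alignment over all offsets, counting paired positions
(Watson–Crick 1, optional G:U 1, mismatch 0). The match-count duplex
score is a transparent surrogate for a thermodynamic duplex energy —
it ranks by base-paired extent, not free energy — and preserves the
screen-then-score architecture. Stage 1 is complete for perfect sites:
any candidate whose best score comes from ≥ k contiguous perfect pairs
necessarily shares a k-mer and survives the screen.

## qPCR quantification and validation correlations

Relative expression follows the comparative-Ct method: per sample,
ΔCt = mean Ct(target) − mean Ct(reference); ΔΔCt = ΔCt − mean ΔCt of
the calibrator condition; RQ = 2^−ΔΔCt. Replicate wells are averaged on
the Ct scale (arithmetic mean), and the calibrator aggregate is the
arithmetic mean ΔCt, which makes the calibrator condition's geometric
mean RQ exactly 1. The calibrator defaults to sham. No
amplification-efficiency correction is applied. Validation correlations
are plain Pearson r with the two-sided t-distribution p-value
(df = n − 2); zero-variance input is an error rather than an NaN.

## Synthetic data: what it emulates and what it does not

The generators produce inputs with the statistical structure the
analysis assumes, plus a machine-readable record of what was planted.

- **Expression**: a planted gene's replicate value in condition t is
  base · 2^(shapeₜ + N(0, σ)); background genes are flat with the same
  lognormal noise. Noise is normal on the log2 scale because the
  profiling operates on log2 ratios, which keeps planted shapes
  unbiased after the transform. Defaults mirror the demonstration
  conditions: 50 genes on (0, −1, −1, −2) at base 10 FPKM with σ = 0.2
  among 1,000 flat genes, 3 replicates per condition (a typical
  small-animal sequencing group size; the study does not state its
  group size).
- **Sequences**: each planted triplet inserts the exact reverse
  complement of its miRNA's seed at a recorded offset into both the
  lncRNA and the mRNA; every sequence is otherwise rejection-sampled
  (retry cap 1,000) to contain no seed site of any miRNA in the set,
  and insertions are re-checked so junction artifacts cannot create
  stray sites. Negatives are therefore clean by construction.
- **ceRNA instance**: 5 planted triplets among 20 lncRNAs × 25 mRNAs
  (495 background pairs). Planted pairs share an identical noise-free
  series (r = 1); with 500 pairs the nearest-rank 99th-percentile
  threshold is the 495th order statistic — a background correlation —
  so all planted pairs clear it without depending on floating-point
  ties at r = 1.
- **Annotation**: cis pairs get gaps uniform in [0, 10 kb], non-cis
  pairs in (10 kb, 20 kb], and successive pairs are separated by more
  than 2 windows so no unintended hit can arise.
- **qPCR**: the target's Ct rises by the planted log2 drop
  (0, 1, 1, 2 cycles across Sham, PD, NLID, LID) over well noise of
  0.1 cycles; dyskinesia scores for LID animals are generated from each
  animal's realized Ct gap so expression and score co-vary.

What the synthetic data does **not** emulate: count noise
(negative-binomial mean–variance coupling), library-size and
gene-length biases, correlated background genes, realistic genome
coordinates or gene density, miRNA expression, partial or wobbled seed
sites, and secondary-structure effects on duplex formation. Passing
tests therefore demonstrate the correctness of the computations under
their stated assumptions, not the biological error rates to expect on
real sequencing data.

## Stage order and the demonstration run

`run_pipeline` defaults to screening first and profiling the surviving
genes, mirroring the narrative order of the original analysis; a flag
profiles all genes. The packaged demonstration (`demo_config`) uses the
profile-all order: on planted-vs-flat data there is nothing a screen
must remove, and profile recovery is a property of the assignment
machinery rather than of the built-in t stand-in, whose low power at
three replicates would otherwise dominate the result. The demo's
problem sizes (1,050 genes × 12 samples, 24-permutation exhaustive
null, 500-pair correlation pool) run in seconds on one CPU.

## Numerical choices and degenerate inputs

- Correlations are computed by centered dot products and clipped into
  [−1, 1]; zero-variance rows propagate as NaN and are skipped with the
  behavior documented per operation (unassigned genes, skipped network
  nodes, errors for validation correlations).
- Nearest-rank percentile, lexicographic profile ids, first-maximum
  tie-breaking, and sorted output edges/triplets make every stage
  deterministic; the pipeline writes no timestamps, so identical
  config + seed reproduces output trees byte-for-byte.
- BH adjustment delegates to the standard step-up implementation in
  statsmodels and is cross-checked in the tests against the explicit
  q_(i) = min_{j ≥ i} m·p_(j)/j definition.
- All generator randomness flows from `numpy.random.default_rng(seed)`;
  derived stage seeds are fixed offsets of the run seed.

## Known limitations

- The Welch-t p-value source is a stand-in, not a count model; supply
  external p-values for real count data.
- The duplex score ignores thermodynamics, loops and bulges.
- Profile significance assumes genes are independent when forming the
  binomial tail; co-expressed gene modules violate this and inflate
  significance, as they do in the original procedure.
- The 26-profile candidate set only distinguishes relative timing, not
  magnitude; genes with identical ordering but different amplitudes are
  indistinguishable by design.
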