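# Methods

## The correction model

The sub-region of interest (the 18S rRNA v4 hypervariable region in the
motivating use case) is modelled with a nucleotide profile HMM estimated
from a multiple alignment of the sub-region across taxa.

**Architecture.** Alignment columns whose non-gap occupancy is at least
`match_fraction` (default 0.5) become match states; the remaining columns
feed the insert state of the preceding node. Emission probabilities per
match/insert state and transition probabilities per node are
maximum-likelihood counts with an additive pseudocount (default 1.0, i.e.
Laplace smoothing: a column of four A's gives P(A) = (4+1)/(4+4) = 0.625).
The background is uniform (0.25 per base). This simple ≥ 50% occupancy rule
replaces the weighted architecture construction of mature HMM suites: it is
transparent, exactly testable, and adequate for alignments without extreme
gap structure.

**Search.** Reads are aligned by Viterbi dynamic programming in log₂-odds
(bits) against the background. The alignment is *glocal*: read sequence
outside the aligned region is free (unscored flanks), while the model is
traversed from an entry match state to an exit match state. Entry and exit
may be internal: a fixed probability mass (0.01) is diverted from the
flush begin→M₁ (and M_K→end) transition and spread evenly over the K−1
internal states, so a read covering only part of the region pays
log₂(0.01/(K−1)) per boundary rather than failing. Both strands are
scored and the better one kept; a hit is reported when the score reaches
`min_bits` (default 20 — at v4-like lengths true amplicons score in the
hundreds of bits while shuffled sequence scores near or below zero, so the
threshold is not delicate). Ambiguous bases (N and other IUPAC codes)
emit at background on both match and insert states, contributing exactly
0 bits — neither rewarded nor penalized. There is no E-value calibration;
bit-score thresholding is the contract, and the empirical null can be
obtained by scoring shuffled reads.

The dynamic program is verified against brute-force enumeration of every
legal glocal path on random small models (K ≤ 4, reads ≤ 6 nt), and its
score rank-order on diverged reads is cross-checked against an independent
profile-HMM engine built from the same alignment.

**Excision.** Each read with a hit is replaced by the hit window, reverse
complemented when the hit was on the minus strand, so corrected reads are
uniformly in model orientation (this also removes the half-and-half strand
mixture that otherwise doubles every taxon's ASVs). Reads whose hit covers
less than `min_coverage` (default 0.5) of the model's match states are
dropped; the default keeps the shortest published v4 windows (−73 bp,
~0.6–0.8 coverage) while discarding fragments that carry too little of the
region to be comparable at all.

## ASV construction

Corrected (or raw) reads are dereplicated exactly; uniques are denoised by
the published UNOISE abundance-skew rule: a unique of size s at Levenshtein
distance d > 0 from an established centroid of current size c is absorbed
iff s/c ≤ β(d) = 1/2^(αd+1), visiting uniques in descending abundance,
joining the nearest eligible centroid (distance ties → larger centroid) and
founding a new centroid only at size ≥ `minsize`. Defaults α = 2,
minsize = 8 are the rule's documented defaults; candidates at d > 10 are
skipped since β(10) < 1e−6 makes joins impossible at plausible sizes.
De-novo chimera filtering is deliberately omitted (the synthetic data
contains no chimeras; see Limitations). Reads are pooled across the samples
of the datasets being compared before denoising and then mapped back per
sample at ≥ 97% identity, identity being 1 − d/max(length) — an end-to-end
definition, so reads of a different window length never map into another
dataset's ASVs (an infix definition would let containment ties shuffle
reads between datasets and blur exactly the incomparability being
measured).

## Evaluation geometry

For a pair of datasets, the pre-correction and post-correction ASV tables
(same samples, both tables covering both datasets) are evaluated as
follows:

1. Bray–Curtis dissimilarity BC(x,y) = 1 − 2Σmin(xᵢ,yᵢ)/(Σx+Σy) between
   sample columns.
2. Non-metric MDS to 2-D for each table (Kruskal stress-1, isotonic
   regression on dissimilarity ranks).
3. Procrustes superimposition of the post configuration onto the pre
   configuration: both centred and scaled to unit sum of squares, optimal
   rotation/reflection from the SVD; M² = 1 − (Σ singular values)² in
   [0,1], with a permutation p-value over row permutations of the post
   configuration (999 permutations; p ≥ 1/(permutations+1)).
4. The medoid m of the *pre-correction* configuration (PAM, k = 1: the
   observed point minimizing summed Euclidean distance; ties → lowest
   index).
5. Per sample, ΔE = d(m, a) − d(m, b) with b/a the sample's pre/post
   position in the standardized aligned space. Negative ΔE = the sample
   converged toward the pre-treatment medoid.
6. A one-sample two-sided t-test of ΔE against 0 (zero-variance vectors
   return p = 1 when the mean is 0, else p → 0, flagged degenerate);
   between two groups, Ē(g₁,g₂) = mean ΔE₁ − mean ΔE₂ with a Welch
   two-sample t-test. Ē is antisymmetric; the package's convention is
   g₁ = the longer-window dataset, so Ē < 0 reads "the longer dataset
   converged more". Stars: *** < 0.001, ** < 0.01, * < 0.05, '.' < 0.1,
   reported raw (a Holm adjustment is available as a flag).
7. Across pairs, the Spearman correlation between |amplicon length
   difference| and Ē; a negative ρ means larger scale differences are
   corrected more.

A literal paired t-test between two groups of unequal size is not defined,
hence Welch for the between-group matrix and the one-sample test for
per-pair panels. ΔE can alternatively be computed directly on Bray–Curtis
distances rather than ordination coordinates; the ordination route is the
default because it matches the medoid-in-NMDS-space description the
evaluation is built around.

### Numerical choices in the NMDS

Non-metric scaling has a well-known degenerate optimum when the
dissimilarity matrix contains disconnected blocks: exact-sequence ASV
tables of two datasets with different window lengths share no features, so
all cross-dataset Bray–Curtis values tie at exactly 1.0, and a randomly
started non-metric fit reaches near-zero stress by collapsing each dataset
to a single point — destroying the within-dataset structure the medoid and
ΔE statistics depend on. The fit is therefore seeded from the classical
metric PCoA configuration and polished by non-metric SMACOF (eps 1e−6,
max 200 iterations, normalized stress-1). On connected data this converges
to the ordinary non-metric solution (planar configurations reach stress
≈ 0; rank-preserving transforms of the input leave the stress unchanged);
on block-tied data it shrinks clusters only partially and preserves their
relative spreads, keeping the medoid and ΔE well defined. The fit is
fully deterministic; the `seed` argument exists for interface uniformity.

## The synthetic generator

`make_family` draws an ancestral sub-region (default 380 nt, the v4-like
scale) with flanks (default 200 nt) and evolves each taxon independently:
substitutions at `divergence` (default 0.10) per site and 1–3 nt indels at
`indel_rate` (default 0.01) per site in the sub-region, substitutions at
`divergence/5` and no indels in the flanks (so sub-region coordinates in
every template are exact, and the true alignment is assembled from the
recorded events). At divergence 0.10 the realized mean pairwise sub-region
identity is 0.80–0.84 (two independent 10% mutation processes with 1/3
back-coincidence). Two optional structures support the category benchmark:
`n_lineages` groups taxa into lineages sharing the ancestor's evolved
sub-region *exactly* while their flanks diverge — so flanking sequence
carries real taxonomic information that trimming removes, which is the
information-scale effect itself — and `flank_margin` keeps the flank
positions immediately adjacent to the sub-region invariant.

`simulate_sample` draws taxon abundances log-normal(σ = 1.5) (heavy-tailed
rank-abundance, typical of community profiles), read counts multinomially
at `depth` (default 10,000, the depth cap used after resampling), per-base
substitution errors at `error_rate` (default 0.005), and
reverse-complements half the reads. `make_category_bundle` observes the
*same* per-sample community realizations through four windows —
Same (0,0), Near (0,−22), Short (+7,−66), Long (−80,+81) relative to the
sub-region, i.e. length deltas 0/−22/−73/+161 matching the published
catalog's categories — with 48 taxa in 16 lineages and a 24 nt conserved
flank margin.

Under this construction, before correction the Long dataset resolves
lineage members (via flank variation) that the baseline cannot, and its
ASVs share nothing with the baseline's; after correction both datasets
collapse to identical lineage-level features. The Long samples therefore
converge toward the baseline medoid (ΔE < 0) while Near — a strict
sub-window of the region, which the correction provably leaves unchanged —
is a true null. The length–effect correlation is evaluated over the
baseline-anchored pairs (Long–Same, Same–Near, Same–Short): corrected
sub-window reads can never share exact features with corrected
full-coverage reads, so non-anchored pairs are structural nulls regardless
of their length difference, and anchoring at the baseline (as the
category design itself does) is what makes the monotone relation
identifiable.

**What passing tests do and do not show.** The generator produces
substitution-only read error (no homopolymer or chimeric artifacts), exact
log-normal communities shared across datasets, and windows at fixed
offsets. Passing the benchmark shows the pipeline corrects a pure
information-scale batch effect under known truth; it does not show
robustness to chimeras, platform-specific indel error, primer-binding
bias, or genuinely different communities between studies.

## Problem sizes

The test suite and benchmark run the bundle at sub-region 200 nt, flanks
100 nt, 300 reads/sample, 20 samples/group (directional statistics) and an
error-free 4-samples/group variant (sensitivity/coordinate checks); these
sizes give the directional tests p-values around 1e−30 and leave generator
defaults (380 nt / 10,000 reads) for full-scale use. The depth
filter/resampler defaults (min 5000, cap 10,000) apply to real-scale data
and are exercised at their boundaries in unit tests.

## Known limitations

- The denoiser omits chimera removal; on real data an upstream or
  downstream chimera filter is required.
- The match-column rule and uniform background are simpler than mature HMM
  suites' weighted counting and Dirichlet mixtures; models built from very
  gappy alignments will differ more from those suites.
- Bit-score thresholding only; no E-values.
- Exact-ASV features make datasets with different corrected lengths
  permanently incomparable; the correction can only harmonize windows that
  cover the modelled region (the shortest datasets stay on their own
  scale, mirroring the erratic behaviour of the shortest published
  windows).
- The NMDS partial-collapse containment (above) keeps medoid/ΔE defined on
  block-tied matrices, but stress values on such data are not comparable
  with stress on connected data.
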