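# Methods

## Scope and design

`neotad` models the chain of reasoning used to explain enhancer reallocation
at a CTCF-organised locus after a structural rearrangement: reconstruct the
mutant chromosome, predict how the boundary landscape re-partitions it into
domains, quantify the resulting contact changes, and test the downstream
expression consequences in single-cell UMI data. Each stage is a standalone
module with explicit in-memory types, so the stages can be recombined on
synthetic fixtures or user data.

## Rearrangement compilation and liftover

Rearrangements are restricted to **disjoint** operations on the wild-type
axis (inversions, deletions, duplications with an insertion point); nested or
overlapping operations are rejected. Compilation produces a `SegmentMap` of
maximal colinear blocks whose mutant intervals tile `[0, mut_length)` — this
tiling is asserted on every compile. Internal coordinates are 0-based
half-open; publication-style 1-based inclusive coordinates are accepted via a
convention tag, converted as `(start−1, end]`. Under that standard conversion
the published inversion breakpoints span 963,247 bp; the printed coordinates
are ambiguous at the ±1 bp level (segment endpoints vs flanking bases) but the
kb-rounded size (963 kb) is insensitive to the choice.

Liftover is purely block arithmetic: a flipped block maps position `p` to
`mut_start + (wt_end − 1 − p)`. Deleted positions lift to nothing;
positions inside duplications lift once per copy (needed for duplication
alleles where a gene copy lands in a new regulatory context). Feature liftover
splits or drops junction-spanning features by policy and flips strand inside
inverted blocks. The correctness oracle used in tests is independent of this
arithmetic: a uniquely marked base is pushed through *sequence* construction
and read back from the mutant string, exhaustively over random small genomes.
Chain export writes one UCSC chain per colinear block (query = mutant axis,
reverse-strand coordinates for flipped blocks) and parses back to an
equivalent map.

## Boundary model

Occupied CTCF sites (position, motif orientation, occupancy weight) are
clustered by single linkage at gap ≤ `max_gap` (default 20 kb at genome
scale, 2 kb on the ~10× scaled-down toy locus). A cluster is *bidirectional*
iff both orientations independently reach `min_weight_per_orientation`
(default 1.0), else biased toward the dominant orientation. Boundary
"strength" is the summed occupancy weight — a deliberate simplification, since
real boundary strength is only qualitatively ranked; the insulation factors
used in simulation are free parameters, not fitted to experimental contact
data.

Domains are the maximal intervals between consecutive boundary-cluster
**midpoints** (midpoints, not edges, so the tiling is deterministic), closed
by the span edges. Adjacent boundary pairs are annotated convergent when the
left cluster has forward-oriented sites facing reverse-oriented sites on the
right. Enhancer→promoter assignment uses the same-domain-by-midpoint rule;
loop-level specificity (which convergent pair actually anchors a loop) is
intentionally out of scope. On the toy fixture, lifting clusters through an
inversion and then partitioning agrees exactly with partitioning the wild
type and lifting the domain edges, because no boundary straddles a breakpoint
there.

The insulation score is the plain diamond mean: `score(i)` averages the
`w × w` block of contacts crossing bin boundary `i`, masked within `w` bins of
the matrix edge; boundaries are local minima with a prominence threshold
(via `scipy.signal.find_peaks`). The multi-scale z-score machinery of
dedicated TAD callers is not reproduced — at simulation scale the plain
diamond is sufficient and exactly analysable.

## Contact-matrix operations

Matrices are dense, symmetric (checked to 1e−9 relative), non-negative, on a
named coordinate system. Genotype comparison uses **equal-total
normalization** (both operands scaled to a common sum, default 1e6) before
subtraction; matrix balancing (ICE/KR) and capture-bias correction are out of
scope, so only relative contact redistribution is interpreted. Remapping a
mutant matrix onto wild-type coordinates assigns each mutant bin to the
wild-type bin containing the lift of its midpoint. When breakpoints are
bin-aligned this is a permutation and conserves mass exactly (asserted in
integer inputs); when they are not, the midpoint rule can merge bins, and any
dropped mass is reported, never silent. Fractional mass splitting was
rejected in favour of determinism. Masked bins (matrix edges for insulation,
viewpoint bins for virtual 4C) are NaN, not zero.

`region_gain` sums the signed matrix over viewpoint × target bins; its
percentile bootstrap resamples **target bins**, so the interval reflects how
uniformly the gain is spread across the target region rather than assay
noise, which the simulation already carries.

## Synthetic fixtures

The toy locus is a 400 kb cartoon (~10× scaled from the ~1 Mb real locus),
with all coordinates declared as constants in one block of `simulate.py`:
five boundary groups B1–B5 left→right (B2/B3 the bidirectional intra-cluster
pair; B1 forward-biased, B5 reverse-biased), the gene cluster between B2 and
B4, distal enhancers (three islands + Prox) centromeric of the cluster, and
proximal enhancers (CS39, CS65, CS68, PLE01–05) telomeric, with CS68/PLE
placed beyond the inversion analogue's telomeric breakpoint so they stay put.
Two allele analogues are provided: an inv2-like inversion `[130 kb, 300 kb)`
(CS65 travels away; CS68/PLE stay with the relocated *Hoxd13*) and an
Ulnaless-like inversion `[145 kb, 250 kb)` (breakpoint centromeric of CS65,
which therefore joins the relocated gene's domain). Occupancy weights and
insulation factors are free fixture parameters.

Contact simulation: `E[c_ij] = C (|i−j|+1)^(−α) ∏ f_b`, with the `+1` as the
distance-0 convention on the diagonal; Poisson noise samples the upper
triangle and mirrors it. Defaults `C = 100`, `α = 0.8`, `f_b = 0.2–0.5`,
5 kb bins over 80 bins, chosen to look like a deeply sequenced capture
experiment at a single locus.

UMI simulation: per cell, depth `s_c ~ LogNormal(log 8000, 0.4)` (a typical
droplet depth distribution); counts are negative binomial with mean
`s_c · r_gk · fold_change` and dispersion `θ_g` (gamma–Poisson sampling;
`θ = ∞` gives Poisson). Planted gene–gene anti-correlation multiplies one
gene's rate by a shared latent factor `exp(κ z_c)` and divides the other's —
a latent-factor construction rather than a copula because it approximately
preserves the NB marginals and is trivially invertible in tests (κ = 0 is
exact independence). The study-like default (`toy_scrna_config`) plants a
2.0-fold gain of *Hoxd13* and partial losses of *Hoxa11* (×0.5) and *Hoxd11*
(×0.78) in two "proximal" clusters of the mutant genotype, ~500 cells per
cluster per genotype — the same order as a dissected-limb 10X experiment
split over clusters. Note the simulator emulates depth variation, cluster
structure and planted effects but not ambient RNA, doublets or batch
effects, so passing tests validate the inference machinery, not robustness
to those artefacts.

Peak-set simulation plants non-overlapping consensus peaks (spacing reserves
room for jitter), jitters them per replicate, and adds replicate-private
peaks placed clear of the planted ones; a paired-factor variant plants a
chosen cross-factor overlap fraction, giving a binomially-exact target for
the overlap percentage.

## Interval algebra

Overlap is ≥1 bp throughout (bedtools default; no reciprocal-fraction option
in v1). The consensus of two replicates reports the replicate-1 intervals
having any overlap in replicate 2, with the reference convention recorded in
metadata, since a single printed overlap count does not determine which side
was counted. Percentages round half-up to integers; with the published counts
this reproduces 37% (6182/16740) and 70% (1359/1955), while 6182/24141 gives
26% by this rule (the source prints 25% for that one figure; the rounding or
count convention there is unknowable from the text, and the implementation
does not force it). Every overlap computation is checked against an O(n²)
brute-force oracle on random instances.

## Zero-proportion inference

Detection is count > 0 (no threshold was stated where the concept is used).
The zero proportion's confidence interval is Wilson at 0.95. Rate inference
inverts `p0 = mean_c P0(s_c r)` by Brent root-finding (relative tolerance
1e−8) with an adaptive upper bracket; `p0 ∈ {0, 1}` returns flagged boundary
results. This deterministic inversion plus a cell-level percentile bootstrap
(default 1000 replicates; 200 in the test suite for speed) stands in for
full posterior deconvolution of the expression distribution, which is a
separate published method and out of scope. Bootstrap replicates whose
resampled `p0` hits 0 or 1 get the continuity correction `1/(2n)` so ratios
stay finite. Dispersion θ is a user parameter; no empirical-Bayes shrinkage.

Depth bias: because `p0` comparisons are only meaningful at matched depth,
depth correction is **exact multivariate-hypergeometric downsampling** (row
sums hit the target exactly; shallower cells are dropped and counted), not
size-factor scaling. The tests demonstrate both halves: a pure 2× depth
difference at equal rates produces clearly separated raw zero proportions,
and after downsampling the fold-change CI covers 1. The depth-aware inversion
itself also absorbs depth differences; downsampling additionally repairs the
model-free proxy comparisons (detection tables, correlations).

`correlation_sign` ranks depth-normalized counts (counts/depth), reports
Spearman rho with a cell-resampling bootstrap CI, and `p_opposite` — the
fraction of bootstrap replicates whose rho falls on the other side of zero —
as a one-sided sign-stability probability.

## Problem sizes and determinism

Simulation studies in the tests and the acceptance script use 50 seeds for
rate-type claims (boundary recovery, region-gain detection, CI coverage),
80-bin matrices, 500–2000 cells per group, and 200 bootstrap replicates —
sizes at which every claim's Monte-Carlo error is far from its threshold
while the whole suite runs in well under a minute per module. Every source of
randomness is an explicit `numpy.random.default_rng(seed)`; no global RNG
state is touched, and all CLI outputs are byte-stable for a fixed seed.

## Known limitations

- Boundary strength is occupancy-weight sum; no learned or fitted strengths.
- Same-domain assignment ignores intra-domain distance and loop specificity.
- Equal-total normalization cannot correct capture or coverage bias.
- The rate model assumes the gene's own contribution to cell depth is
  negligible; for genes carrying a large fraction of depth the inversion is
  slightly biased.
- Real-data effect sizes reported in the source study (e.g. fold-change
  ranges from tissue data) require the deposited sequencing data and are not
  reproduced here; the simulation studies calibrate the same machinery on
  known ground truth instead.
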