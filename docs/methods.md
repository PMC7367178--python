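# Methods

This note documents the models and procedures implemented in `sescape`,
the defaults they use, and the design choices made where several
reasonable options existed.

## Coordinate conventions and interval arithmetic

All coordinates are 0-based half-open (BED convention); any 1-based
display is formatting only.  Overlap is counted at single-base
resolution: two spans overlap iff they share at least one base, so
`[0,10)` and `[10,20)` do not overlap.  Merging treats adjacency (gap 0)
as contiguous, matching union-peak semantics.  Fragment counting uses the
≥ 1 bp overlap rule rather than fragment midpoints; RPKM is
`count × 10⁹ / (library_size × length)`.  bedGraph steps must be
non-overlapping — an overlapping track is rejected rather than silently
summed, so double-counted coverage upstream surfaces immediately.

## Peak filtering and differential binding

Peaks are retained when −log10 *P* strictly exceeds 9 and fold
enrichment strictly exceeds 3; boundary values are excluded by design
(all thresholds in the package are strict).  Differential classification
works on the merged WT/KO union: each union peak's RPKM ratio
`(RPKM_KO + ε)/(RPKM_WT + ε)` is compared to 2 (up) and 1/1.5 (down).
"1.5-fold lower" is read literally as KO < WT/1.5.  The pseudocount
ε = 0.25 RPKM stabilises ratios where WT signal is near zero; it is
configurable.  No significance test is attached to differential peaks —
the classification is pure fold change.

Peak-to-gene assignment uses a ±50 kb window around the TSS, with
distance measured from the TSS to the nearest peak edge (0 when the TSS
lies inside the peak).  A peak may map to several genes and vice versa.

## Co-localization enrichment

For factor coverages cov(a), cov(b) on a genome of L bases, the expected
base-pair overlap under independent placement is cov(a)·cov(b)/L and the
enrichment score is observed/expected.  The tail probability models each
base of the smaller set as an independent uniform trial hitting the
larger set with probability max-coverage/L, i.e.
X ~ Binomial(min cov, max cov/L); taking the smaller coverage as the
trial count is the conservative, symmetric choice.  The test suite
verifies the analytic tail against a Monte-Carlo placement permutation
that scatters the smaller set's bases accordingly.  Effective genome
length defaults to the full assembled length; callers may rescale it for
mappability.

Factor clustering uses average linkage on a correlation distance between
rows of the log2(score+1) matrix.  The self-enrichment diagonal
(score = L/cov, always large) never enters the distance: when comparing
rows i and j, each row's own-column entry is replaced by the mutual pair
score.  This substitution — rather than dropping the columns outright —
matters for two-member factor groups, whose mutual enrichment would
otherwise be invisible to their own distance and leave the pairing to
noise.  Ties in linkage order are broken by factor-name sort.

Chromatin-state enrichment applies the same observed/expected score per
state; states with zero coverage are reported with an undefined score
rather than dropped.

Enrichment is computed on base pairs throughout ("single-nucleotide
resolution"); a peak-count variant was considered and rejected because
it would make the score depend on how fragmented each peak set is.
Signal tracks are treated as unitless depth — the reader is agnostic to
whether a track was RPKM- or CPM-scaled upstream, since every statistic
in the package is either a ratio over the same track or recomputed from
fragment counts.

## Super-enhancer identification

The procedure is Rank Ordering of Super-Enhancers: enhancer peaks whose
gaps are ≤ 12,500 bp (canonical default) merge transitively into
stitched regions; an optional promoter filter removes peaks fully inside
TSS ± 2,500 bp windows before stitching and is off by default.  Each
region is scored `max(0, RPKM_treat − RPKM_input) × length`; the unit
(RPKM·kb) makes ranks invariant to common library rescaling.  Note that
treat and input each use their own library size, so input subtraction is
a background correction, not a paired per-base difference.

The SE/TE cutoff is the geometric inflection point of the ranked curve:
signals are sorted ascending, both axes rescaled to [0, 1], and the
cutoff placed where a line of slope 1 is tangent to the curve — computed
globally as argmax(xᵢ − yᵢ), with ties toward the smaller rank (more
SEs).  The global tangent and the first local slope-1 crossing coincide
on smooth convex and two-regime curves; on sampled curves with sparse
upper tails the local crossing fires on the first large order-statistic
gap, which can sit far below the true elbow, so the global form is used.
A flat curve has no inflection: the cutoff is the maximum, zero regions
pass, and a warning is emitted.  Regions strictly above the cutoff are
super-enhancers.

Across two conditions, every SE's signal is recomputed over its exact
span in both conditions; it is unique to its home condition iff
`(signal_home + ε)/(signal_other + ε) > 2` (ε = 1 RPKM·kb), else common.
Whether the span also overlaps an SE called in the other condition is
recorded for users but deliberately does not enter the rule — the
fold-change-only reading keeps the definition monotone in signal.
`bound_by` lists every factor whose peaks overlap the SE span by ≥ 1 bp.

## Expression analysis

A gene is differentially expressed when max(FPKM_A, FPKM_B) > 1, the
pseudocounted fold `(FPKM_B + 0.1)/(FPKM_A + 0.1)` exceeds 2 in either
direction, and q < 0.01 (all strict).  Applying the FPKM gate to the max
of the two conditions is one of three supported readings (`max`,
`either`, `both`); `max` is the default because a gene silent in one
condition and induced in the other is exactly the interesting case.  The
package does not fit an expression model; q-values must be supplied.

Binding stratification cross-tabulates expression classes against the
classes of assigned differential peaks; genes hit by both up- and
down-classified peaks land in a separate `mixed` stratum rather than
being double-counted.

Group shifts use the two-sample Wilcoxon rank-sum test: exact
enumeration when both groups have ≤ 20 tie-free observations, otherwise
the normal approximation with tie and continuity correction.  The two
modes agree to |Δp| < 0.01 at n = 20 (cross-checked in the suite).
Empirical cumulative-fraction curves are returned for plotting.

## Synthetic data generator

The generator emulates a two-condition (wild type / kinase knockout),
multi-factor ChIP-seq study on a 5 Mb toy genome (2 × 2.5 Mb), with 600
enhancer sites, 30 SE clusters of 4–8 constituents within ≤ 20 kb, and
200 genes.  Its defaults are the study conditions for every recovery
test.

**Placement.**  Sites occupy non-overlapping slots.  SE clusters keep a
margin of > 12.5 kb on both sides so a default stitch recovers each
cluster as exactly one region.  Typical enhancers are laid out in small
groups of 1–3 sites; most groups sit beyond stitching range of each
other, a minority within it, so the ranked signal curve is a continuous
low-signal ramp rather than a set of isolated atoms.

**Co-binding.**  Factor memberships per site come from a latent-Gaussian
(copula) scheme: a correlated standard-normal vector per site is
thresholded at each factor's marginal, with pairwise correlations solved
by bisection on the bivariate normal CDF so the joint binding
probabilities hit requested site-level enrichment ratios.  Requests
outside the Fréchet bounds, or a pairwise-consistent but jointly
impossible matrix, raise an error naming the offending pair.  Because
binding is confined to S sites of width w on an L bp genome, a site-level
ratio ρ corresponds to a genome-scale base-pair enrichment of
ρ·L/(S·w); `site_ratio_for_genome_score` converts, and
`simulate_cobinding_sets` plants genome-scale targets directly (used by
the calibration tests, which recover ratios 1–10 within a few percent).

**Signal.**  Each bound site has a per-factor strength
(log-normal, σ = 0.3 in log, clipped at ±2σ); fragment counts are
Poisson(strength × depth) with depth 100 fragments per unit strength,
fragment length 200 bp, and uniform background at 0.01 fragments/bp.
H3K27ac binds every cluster constituent; active clusters multiply
constituent strengths by the SE boost (×5), which makes cluster
acetylation depth ≈ 5× the typical-enhancer median (verified from the
emitted tracks to ±20%).  Condition-unique clusters carry a weak
pre-mark (×0.3) in their inactive condition — a gained SE arises from
lightly acetylated chromatin, and this keeps inactive clusters inside
the typical-enhancer continuum instead of hovering just below the SE
cutoff.  narrowPeak statistics are produced by the generator itself as a
Poisson upper tail of the site count against the local background
expectation, since peak calling is out of scope.

**Knockout effect.**  20% of ordinary YAP-bound sites are boosted ×4 in
the KO; coupled factors (Oct4/Sox2/Nanog/H3K27ac) at those sites gain
×4^0.8 (coupling 0.8 in log space).  Boosted sites are drawn from
singleton enhancer groups so the coupled acetylation gain strengthens
isolated typical enhancers rather than manufacturing unplanned
multi-site clusters that would blur the SE ground truth.  Constituents
of gained clusters are also KO-boosted YAP sites.  Strengths carry no
per-condition random jitter by default (a zero knockout effect leaves
WT and KO strengths identical); an optional jitter knob exists.  The
resulting YAP and H3K27ac log2 signal changes at planted sites correlate
with r ≈ 0.97 from the emitted tracks.

**Expression.**  Baseline FPKMs are log-normal (median 8); the two genes
planted near each gained cluster are up-regulated ×4 with
q ~ U(0, 0.005), genes near lost clusters down ×4, and background genes
jitter by 2^N(0, 0.15) with q ~ U(0.2, 1).  The q-values are simulated,
not fitted — the package consumes, never produces, DE significance.
Background gene TSSs avoid ±55 kb of condition-unique clusters so the
linked-vs-background comparison has a clean null.

**What the generator does not emulate:** read sequences, mappability and
GC bias, replicate structure, fragment-length variation, broad-domain
marks, and trans effects beyond the planted coupling.  Passing recovery
tests therefore demonstrates the correctness and calibration of the
analysis logic under the planted model, not robustness to every artefact
of real ChIP-seq.

## Numerical and degenerate-input choices

Metaplot bins partition the window left-closed with the remainder in the
last bin; regions whose window crosses a chromosome edge are skipped
with a warning and counted.  Zero-variance log-fold-change vectors yield
an undefined correlation (`None`), never a NaN crash.  Empty interval
sets are rejected by enrichment computations (the score is undefined).
The binomial solver clamps latent correlations to ±0.999; mild
non-positive-definiteness from pairwise fitting (smallest eigenvalue
> −0.05) is projected to the nearest correlation matrix, stronger
violations are errors.  All pipeline randomness derives from a single
seed; reports are JSON with sorted keys and no timestamps, so identical
configurations reproduce byte-identical outputs.

## Problem sizes

The default synthetic scale (5 Mb, 600 sites, ~14 tracks of ~10⁵
fragments) keeps a full simulate-and-analyse cycle under ten seconds on
one CPU, which lets the recovery properties be averaged over five seeds
and the calibration over ten inside a normal test run.
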