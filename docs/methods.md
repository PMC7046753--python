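# Methods

## Colocalization model

ChIP-Seq peak callers report enriched regions a few hundred bp wide, while
the bound site itself spans ~10 bp; the peak summit is typically within a
few dozen bp of the true contact point. The package therefore works on
summit coordinates throughout: two peaks cobind when their summits lie
within `d_s` bp on the same chromosome (default 150, a conventional window
that also matches the width of accessible-chromatin regions in digital
genomic footprinting maps). Coordinates are 0-based half-open (BED); a
summit is a single 0-based position. A narrowPeak summit offset of −1 falls
back to the region midpoint so every peak stays usable.

**Counting convention.** `count_cobinding(a, b)` counts peaks of the *first*
experiment with at least one qualifying summit of the second, pairing each
with its nearest partner (equidistant candidates resolve toward the lower
coordinate). This anchored count is reproducible and bounded by n; the two
orientations can differ by the number of many-to-one matches, which is why
score matrices average the two orientation scores before clustering. In the
pathological case where many-to-one matching pushes k above min(n, m), the
pairwise test caps k there (with a warning) so the null's support is
respected; this cannot occur when each binding event occupies its own
accessible slot.

**Null and significance.** The null places the n and m binding events
independently into N accessible slots of width d_s. N defaults to 250,000
(somatic mammalian cell lines; digital genomic footprinting totals range
≈200,000–250,000) or 500,000 for embryonic stem cells, whose nucleosome
occupancy is roughly half; alternatively N is counted from a user-supplied
accessible-regions BED (one slot per row, warning when widths differ from
d_s). The observed k is tested with the Poisson tail at λ = n·m/N — the
default because its tail probabilities are almost everywhere the more
conservative — or the exact hypergeometric tail. Both distributions are
two-sided in principle; the implementation reports the single tail on the
observed side plus an explicit direction flag (`enriched` when k ≥ λ),
because the downstream score is directional: −log₁₀ p when enriched,
+log₁₀ p when depleted, with p floored at 1e−300 so scores stay finite.
A systematic grid comparison (tests) shows Poisson-tail dominance over the
hypergeometric everywhere except k = 1 and within two standard deviations of
the mode, where the two agree within 3% relative and no test is significant.

**Multiple testing.** All-pairs analyses correct by T² for T experiments
(e.g. 329² = 108,241), the conservative all-ordered-comparisons convention;
T(T−1)/2 is available behind a flag. Conditional analyses correct over the
number of (i, j) pairs tested within the base.

## Conditional (higher-order) tests

Given a base TF_b with k_b peaks, candidate factors i and j cobinding k_i
and k_j of those peaks, the joint count k_ij is tested against
λ = k_i·k_j/k_b with the same Poisson tails. When the base covers every
slot exactly once (k_b = N) this reduces to the pairwise λ. Candidate sets
for the conditional heatmap are pre-filtered to factors whose *raw* pairwise
p with the base is below θ (default 1e−10; 1e−100 is typical for anchor-TF
analyses in dense compendia) — the raw scale is used because that is the
scale on which such pre-filter thresholds are conventionally quoted.

`iterate_module` extends a module by one factor at a time: the peaks of the
first base cobound by every current member form the new region set of size
k_b′, and a candidate with n_c peaks is tested against λ = k_b′·n_c/N — the
pairwise construction with the region set as one pseudo-experiment. (The
triplet λ needs two candidates and does not specialize to one; the chosen
form is the one under which a candidate placed uniformly over the N slots
yields uniform p-values, which simulation confirms.)

## Clustering

Score rows are compared with distance 1 − Pearson r and agglomerated
(average linkage by default; the linkage method is a free choice exposed as
an argument). Matrices are symmetrized by orientation-averaging before
clustering, the diagonal is defined as 0, and zero-variance rows — for which
correlation is undefined — get distance 1 to everything and are flagged
rather than dropped. Flat clusters come from a maxclust or height cut;
heatmap rendering (blue enriched, black/gray depleted) is cosmetic and not
part of any tested contract.

## Motif layer

A motif is a 4×L count matrix; a pseudocount of 0.01× the column total,
split equally over the four bases, is added before column normalization.
An instance at some offset scores the sum of per-position frequencies of
its bases, min/max-normalized so the per-position argmax string (consensus)
scores exactly 1 and the argmin string 0; ambiguous bases contribute the
column mean (0.25). Each 150-bp summit-centered window keeps its best
instance over all offsets and both strands, ties toward the + strand and
then the lower offset. Instance centers are base-resolution integers
(offset + L//2), which keeps planted spacings and measured center-to-center
distances exactly integral.

Three enrichment measures (the concrete statistics are this package's own
choices, approximating the behavior of summit-centered motif tools):

- **Global**: one-tailed two-sample z-test on the mean best score, summit
  windows vs. windows from the accessible background (≥200 background
  regions required; a convenient default is ~5,000 windows sampled from an
  accessible-regions BED).
- **Local**: paired one-tailed z-test of the summit-window best score
  against the mean of the two adjacent equal-width flanking windows.
- **Positional bias**: chi-square goodness-of-fit of best-instance start
  offsets against the *discrete* uniform over the achievable offsets
  (window − L + 1 of them), with expected bin counts following the exact
  number of integer offsets per bin. Testing against a uniform over the
  full window would structurally underfill the edge bins and break null
  calibration. With fewer regions than bins, the bin count drops to
  max(5, n/10).

**Motif-centered analysis.** Regions whose best anchor instance scores
below a quality threshold (default 0.8, configurable; "low quality" is not
quantified by convention) are discarded and counted. Surviving regions are
re-centered on the anchor instance center and flipped so the anchor reads on
the + strand; partner motifs are rescanned in the re-centered 150-bp window,
and signed center-to-center distances (negative = partner upstream of the
anchor) with relative partner strands feed per-strand histograms, modal
distances, and a positional-bias p-value on strand-normalized offsets. A
positional-bias p below 0.01 for a partner indicates a preferential
arrangement of the two binding sites.

## Dataset redundancy filtering

Within each factor (grouped by exact factor-name string; flags come from
the metadata table, not filenames): stimulated-cell experiments are dropped;
tagged-protein experiments are dropped when a wild-type one exists; a
duplicate with under 10,000 peaks *and* under half the peaks of every other
remaining duplicate is dropped as minor; among survivors, if every pairwise
summit-overlap fraction exceeds 0.66 the largest is kept, otherwise all are
discarded as ambiguous. The overlap fraction uses k/min(n, m) with the
smaller experiment as counting anchor (the denominator is not fixed by
convention; min is symmetric and conservative toward keeping data). Rule 3
is evaluated simultaneously against the pre-removal duplicate set and peak
count ties break by smallest id, making the filter order-independent.

## Synthetic fixtures

The generator emulates exactly the conditions the null assumes: `n_slots`
accessible 150-bp slots separated by 300-bp closed gaps on an i.i.d.
uniform-ACGT genome, so two summits in the same slot are always within
150 bp and summits in different slots never are — the cobinding count equals
the shared-slot count and λ = n·m/N is exact up to the Poisson-vs-
hypergeometric approximation. Null experiments place one summit per
uniformly chosen slot without replacement. Planted structure: `cobind`
copies a fraction of summits with ±30 bp jitter (reflecting summit
centrality); `tether` places partners on a common, per-relation-disjoint
subset of a base's peaks; `spacing` writes anchor and partner consensus
strings at a fixed signed center-to-center distance and strand. A truth
table records every planted relation with realized counts, and all emitted
files (FASTA, BED3, narrowPeak, JASPAR, metadata TSV) round-trip through the
package's own readers. The background sequence model is deliberately simple
(no GC structure, no repeats); none of the statistics here model sequence
composition beyond the PWM layer's own background sampling, so passing
tests demonstrate correctness of the statistics under their stated model,
not robustness to compositional biases of real genomes.

## Problem sizes and determinism

The test and acceptance workloads run at the sizes the checks are defined
at — 2,000 replicates for each null-calibration suite (N = 10,000 slots,
n = m = 500 pairwise; k_b = 1,000, k_i = k_j = 300 conditional), 200
replicates for planted-recovery (n = m = 1,000, N = 250,000, 30% planted),
1,000 fixtures for the scan and count oracles, and 100 replicates of 500
regions for spacing recovery — sizes at which every observed rate is stable
to well under the asserted margins. All randomness flows from explicit
seeds (numpy `SeedSequence` spawning for replicate streams, children kept
below 2³¹), and identical seeds reproduce byte-identical fixture bundles
and output tables.

## Known limitations

- The null ignores peak widths, signal strengths, GC/mappability covariates
  and any promoter/enhancer stratification (a user-supplied accessible BED
  is the only hook for restricted universes).
- The anchored counting convention is asymmetric under many-to-one
  matching; orientation-averaged scores absorb this for clustering, but
  single-pair reports should state the anchor.
- The motif statistics are z- and chi-square approximations; they are
  calibrated under the generator's null (simulation-checked) but are not an
  exact replication of any external tool's internals.
- De novo motif discovery, dinucleotide background models, read-level
  processing and peak calling are out of scope.
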