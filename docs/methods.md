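# Methods

This note records the models, conventions and design choices behind
`hicdelta`, in the order the pipeline applies them.

## Scaling and the differential map

Both raw maps are scaled by their *overall sum*: cis contacts within
autosomes, each unordered pixel pair counted once, the main diagonal
excluded, plus autosome–autosome trans contacts when present. The exclusions
matter: diagonal pixels are dominated by self-ligation artefacts in real
data, and sex chromosomes differ systematically between samples of different
karyotype. Non-autosomal chromosomes still receive differential values for
inspection; they simply never contribute to the scaling total.

Zero handling is a genuine free choice, and the default is to *mask*:
a pixel with a zero raw count in either map gets no log2 value and
contributes zero to window sums, with the per-window valid fraction
recorded. The alternative (`pseudocount`) computes
`log2((t+ψ)/(c+ψ))` on the scaled maps with ψ defaulting to
`2/(ΣC + ΣT)`. Masking avoids the sign bias a pseudocount introduces at
shallow depth (a pseudocount pulls all sparse pixels toward the depth
ratio), at the cost of making window scores depend on coverage through the
valid fraction; the `min_valid_fraction` guard (default 0.5) exists exactly
to stop zero-count deserts from producing spuriously extreme window sums.

## Window statistic

The window statistic is the plain sum of differential values over the strict
upper triangle of a `w × w` diagonal-anchored square (default `w = 10` bins,
step 1 bin). Using the upper triangle only avoids double-counting symmetric
pixels, and excluding the window's main diagonal keeps the statistic
consistent with the scaling convention. Summation order within a window is
fixed (row-major, sequential accumulation), so scores are bit-reproducible
and can be checked against a brute-force double loop exactly.

## Threshold selection

The genome-wide score distribution under the null is unimodal and roughly
symmetric; genuinely depleted regions form a heavy lower tail. Two rules are
implemented:

* `mean_sd` (default, param 3): threshold = mean − 3·SD. A 3-SD outlier rule
  adapts its scale to the bulk of the distribution, so the *number* of calls
  is driven by how extreme the tail is, not fixed in advance.
* `quantile` (param 0.01): the empirical 1st-percentile of all scores.

The quantile rule is scale-free but passes, by construction, a fixed share
of windows; when the genuinely affected fraction of the genome exceeds that
share (on the default planted fixture ~10 % of windows touch a depleted
rectangle), it cannot recover every affected region no matter how strong the
signal. The mean−SD rule has no such ceiling, which is why it is the
default; on null data it calls ≈0–1 regions per genome scan. Both rules,
the window size, the direction (decrease/increase) and the valid-fraction
guard are plain parameters of the CLI and `RunConfig`.

Merged regions span from the first passing window's start bin to the last
passing window's start plus `w` bins; overlapping or adjacent windows merge.
Recovery against truth is scored per region as the Jaccard index between a
truth interval and the union of calls overlapping it (recall at J ≥ 0.25 by
default), with precision as the mirror statistic.

## Coverage control

For each region the mean per-bin log2 marginal ratio (treated/control) is
computed on raw and on scaled maps; |scaled ratio| > 0.3 flags the region.
A planted depletion redistributes a small fraction of a bin's contacts, so
on the synthetic fixtures the scaled ratios stay within ±0.05–0.15; a region
whose coverage tracks its call would instead point to a depth artefact.

## Distance decay

P(s) is the arithmetic mean of contacts per *possible* pixel (zeros
included) at each separation, pooled across autosomes, in 50 log-spaced
distance bins from one bin size to the longest autosome. The arithmetic mean
is used because the geometric mean is undefined at zero counts. Curves may
be normalized to unit mass; comparisons are per-bin log2 ratios with probe
values interpolated in log distance at 1 Mb and 10 Mb by default.

## The compaction tilt (generator)

The generator emulates a global compaction change as a one-sided tilt of the
treated expected matrix: `(max(s, s_pivot)/s_pivot)^(−γ)` with pivot 3 Mb
and γ = 0.3 in the study fixture — contacts beyond the pivot are depleted,
sub-pivot contacts untouched. The one-sided form is deliberate. Contact maps
are compared at matched depth, and for a *two-sided* power tilt
`(s/s_pivot)^(−γ)` the depth-normalized ratio curve crosses unity at the
mass-weighted power-mean of s — a quantity independent of the pivot and, for
realistic decay, stuck at a few hundred kb — so the intended
"up at 1 Mb, down at 10 Mb" contrast can never appear. With the one-sided
tilt, depth matching automatically converts the long-range depletion into a
relative short-range gain, and the ratio curve crosses unity at the pivot by
construction. This mirrors the physical reading of compaction at fixed
ligation events: losing long-range contacts means relatively more
short-range ones.

## Pileups and relative insulation

Pileups divide each window by the *map's own* expected-by-distance profile,
so a global decay difference between conditions cannot masquerade as a local
insulation change. Variable-length regions with fixed flanks are rescaled
piecewise — the region onto a central band, each flank onto a side band of
width `round(grid_n · flank/(flank + mean region length))` (recorded in the
result) — so region boundaries align across regions; block means ignore
masked pixels. Point anchors use fixed windows of 2·flank+1 bins with no
rescaling. Grid default 99 × 99.

No standard formula exists for the "relative insulation strength" printed on
pileup plots, so this package defines it transparently: split the central
span at its midpoint into halves A and B and take
`RI = log2( mean o/e over A×A ∪ B×B / mean o/e over A×B )`. The raw
quadrant means are reported next to RI so any alternative definition can be
recomputed from the same numbers. On the planted fixture, RI(treated) −
RI(control) ≈ −log2 δ, slightly attenuated (≈0.93–0.99 for δ = 0.5)
because the treated map's own expected profile absorbs a few percent of the
planted depletion and the grid cell straddling the domain boundary mixes the
two compartments.

## Hypergeometric enrichment

The sampling unit is the analysis bin (default: the calling resolution), so
the population size N is well-defined and regions are exact unions of units:
N autosomal bins, m feature-marked, k inside regions, q both. The upper tail
is computed in log space (log-gamma binomial coefficients, log-sum-exp).
The default tail is *exclusive*, `P(X > q)` — matching the common R idiom
`1 − phyper(q, m, n, k)` — even though it understates significance by one
pmf term; the inclusive tail `P(X ≥ q)` is always reported alongside, and a
peak-level unit (drawing peaks from an explicit background universe) is
available for sensitivity analysis. Under a matched-density null the
exclusive test's false-positive rate at p < 0.05 sits at ≈0.05 on the study
fixture (slightly conservative, as expected for a discrete exclusive tail).

## Synthetic study fixtures

The default fixture is two 20-Mb chromosomes at 100 kb resolution (200 bins
each), tiled into 1-Mb TADs, with α = 1, β = 3, four planted adjacent-TAD
pairs (δ = 0.5) and 2×10⁶ contacts per map — enough depth that near-diagonal
pixels average ~50 counts while long-range pixels are sparse, similar in
spirit to a downsampled mammalian experiment. Feature peaks are 1 kb wide at
10 per Mb inside planted regions and 2 per Mb outside (a 5× density
contrast, typical of active-promoter clustering). Pipeline runs simulate at
10 kb and coarsen 10× for calling, so one simulated dataset serves both the
100-kb calling stage and the 10-kb pileup stage.

What the generator does *not* model: loops/dots, A/B compartment
checkerboards, trans-contact structure, mappability/GC bias, replicate
variance, or balancing artefacts. Passing tests therefore demonstrate the
pipeline's statistical machinery — scaling, scoring, thresholding,
insulation and enrichment arithmetic — not robustness to every systematic
error of real Hi-C; the coverage control and the matrix balancer
(`hicdelta.balance`, iterative correction, provided as plumbing) are the
entry points for such checks on real data.

## Numerical conventions

* Bins are half-open `[k·bin, (k+1)·bin)`; the last partial bin of a
  chromosome is kept short. BED intervals are 0-based half-open.
* Masked values propagate as NaN inside pileups and are excluded from all
  means; an all-masked quadrant yields RI = NA with a reason.
* The window scan skips chromosomes shorter than `w` bins with a warning;
  coarsening requires an integer factor ≥ 2 and conserves the dense matrix
  sum exactly (mirrored off-diagonal fine pixels merge onto the coarse
  diagonal, which the diagonal-excluding totals then ignore).
* All simulation randomness flows from one seed through SeedSequence
  spawning; identical configs give byte-identical outputs, and the pipeline
  report contains no timestamps so identical seeds give identical report
  checksums.

## Problem sizes

The shipped fixtures use 2 × 200 bins (100 kb) for calling-stage analyses
and 2 × 2000 bins (10 kb) for pileup-stage simulation; the test suite and
the acceptance script complete in well under a minute each on one core.
These sizes were chosen to make every statistic's sampling error small
relative to its acceptance band while keeping exact brute-force oracles
(per-window double loops, per-bp overlap scans, exhaustive hypergeometric
enumeration) practical.
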