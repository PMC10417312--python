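# hicdelta

Differential analysis of binned Hi-C contact maps: find genomic regions where
chromatin interactions *decrease* between two conditions (e.g. drug-treated vs
control cells), and back the calls with the standard supporting analyses —
coverage control, distance-decay contrast, aggregate observed/expected pileups
with a relative-insulation score, and hypergeometric feature enrichment.

It is written for chromatin biologists and genomics analysts who have two
binned contact matrices (and optionally BED files of peaks, genes or anchors)
and want a reproducible, parameterised version of the common
"log2-ratio map + sliding window" differential pipeline, together with a
synthetic-data generator that plants ground-truth differential regions so
every step can be validated end to end.

## The method

**Region calling.** Raw contact maps `T` (treated) and `C` (control) are each
scaled by their overall sum of contacts — cis pixels within autosomes with the
main diagonal excluded, plus autosome–autosome trans pixels — so sequencing
depth cancels. The differential map is the per-pixel log2 ratio

    D[i,j] = log2( (T[i,j]/ΣT) / (C[i,j]/ΣC) ),

with pixels where either raw count is zero masked (a pseudocount policy is
available). A square window of `w = 10` bins slides along the diagonal in
steps of one bin; its score is the sum of `D` over the strict upper triangle
of the window (each symmetric pixel once, masked pixels contributing zero).
A threshold is chosen from the genome-wide score distribution — by default
`mean − 3·SD`, with a lower-tail quantile rule as an alternative — and
passing windows are merged into regions.

**Controls and companions.**

* *Coverage*: per-bin marginal sums of both maps; regions whose mean log2
  marginal ratio moves with the call would indicate a depth artefact.
* *Distance decay*: P(s) — mean contacts per possible pixel in log-spaced
  separation bins, pooled over autosomes — compared between conditions as a
  log2-ratio curve with probes at 1 Mb and 10 Mb.
* *Pileups*: regions (plus 1 Mb flanks) are divided by each map's own
  expected-by-distance profile, rescaled onto a fixed grid (region and flanks
  separately, so boundaries stay aligned), and averaged. The relative
  insulation strength of a pileup is
  `RI = log2( mean o/e within the two halves of the region / mean o/e between them )`.
* *Enrichment*: of `N` autosomal bins, `m` carry a feature, `k` lie in the
  query regions and `q` do both; over-representation is the hypergeometric
  upper tail `P(X > q)` (exclusive, the R `1-phyper(q, m, n, k)` convention;
  the inclusive tail is always reported alongside).

**Synthetic truth.** The generator samples independent Poisson pixels from an
expected matrix with power-law decay `(s+1)^(−α)`, block-TAD enrichment `β`,
planted inter-domain depletion `δ` between chosen adjacent TAD pairs in the
treated condition, an optional long-range "compaction" tilt, and clustered
feature peaks inside the planted regions — all reproducible from one seed.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic data
(about 30 s in total):

```sh
python analysis/01_simulate.py
python analysis/02_call_regions.py
python analysis/03_coverage_control.py
python analysis/04_distance_decay.py
python analysis/05_pileups.py
python analysis/06_enrichment.py
```

Output (seed 7, the default planted fixture: 2 chromosomes × 20 Mb at 100 kb,
α=1, β=3, δ=0.5, four planted 2-Mb regions, 2×10⁶ contacts per map):

```
planted: 4 regions at threshold -18.27; recall=1.00 precision=1.00 min Jaccard=0.70
null: 0 regions (quiet as expected)
4 regions checked; max |mean log2 coverage ratio| = 0.050; 0 flagged (bound 0.3)
log2(treated/control) probes: 1 Mb = +0.025, 10 Mb = -0.455
control: RI = 0.809 ...  treated: RI = 1.788 ...  insulation gain = +0.979
peaks in called regions: q=33 of k=56 bins (background m=114/N=400); fold=2.07, p=4.91e-08
null calibration: 12/200 replicates below 0.05 (rate 0.060)
```

Reading: all four planted regions are recovered exactly once each
(precision 1.0) and none of the calls is explained by coverage; the treated
map gains ≈1 unit of relative insulation over the called regions, matching
the planted two-fold inter-domain depletion (−log2 0.5 = 1); the compaction
fixture shows the short-range-up / long-range-down decay contrast; and the
peaks planted inside the regions are strongly over-represented while the
matched-density null keeps the false-positive rate at the nominal level.

The same stages are exposed as a CLI (`hicdelta simulate | diff | call |
coverage | decay | pileup | enrich | coarsen | run-all`); `run-all` executes
everything from a YAML config (or the built-in demo) and writes a
checksummed JSON run report.

## File formats

Contact maps are exchanged as a sparse TSV triple format (header line starts
with `#`; unlisted pixels are zero; cis pixels upper-triangle only):

```
file    ::= header line*
header  ::= "#chrom1" TAB "bin1" TAB "chrom2" TAB "bin2" TAB "count" NL
line    ::= chrom TAB int TAB chrom TAB int TAB number NL
```

Bin indices are 0-based and local to each chromosome. Intervals use BED
(0-based half-open); chromosome tables are `name TAB length [TAB autosome]`.
A minimal reader for single-resolution `.cool` (HDF5) files is included
(`hicdelta.contacts.read_cool`).

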