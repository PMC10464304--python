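# Methods

## Equilibrium binding models

A fluorescently labeled histone-tail peptide is held at total
concentration `c_pep` (default 100 nM) while the reader domain is
titrated; the readout is the anisotropy change Δr. Two binary-binding
models are implemented.

*Simple (hyperbolic) isotherm.* Valid when free protein ≈ total protein:
`Δr = BL + F·c/(c + K_D)`, with baseline `BL` and amplitude `F` in
anisotropy units and `K_D` in nM. The fraction bound is
`Θ = (Δr − BL)/F`; `Θ = 0.5` exactly at `c = K_D`.

*Ligand-depletion isotherm.* When `K_D` is comparable to or below
`c_pep`, complex formation depletes free protein and the exact
two-component mass balance must be solved. With
`A = (K_D + c_pep + c)/(2·c_pep)`, the fraction of peptide bound is the
stable root of the quadratic, `Θ = A − √(A² − c/c_pep)`, and
`Δr = BL + F·Θ`. This solution is verified in the tests against
bisection on the complex concentration in the mass-balance system and
converges to the simple isotherm as `c_pep/K_D → 0` (relative deviation
< 10⁻³ at `c_pep = 10⁻⁴·K_D`).

*Fitting.* Nonlinear least squares (`scipy.optimize.least_squares`) on
(K_D, BL, F), with multi-start initialization: K_D started at the
minimum, geometric mean and maximum of the positive concentrations, BL
at the first point and F at the observed span; the best residual sum of
squares wins. Bounds keep K_D positive. Tolerances: xtol 10⁻¹⁰, at most
10⁴ objective evaluations per start. A curve whose signal span is below
a relative 10⁻¹² noise floor is rejected as degenerate, as are curves
with fewer than 5 points. In `auto` mode the simple model is fitted
first; if its fitted K_D is below 100 nM the curve is refitted with the
depletion model and that fit is reported. The threshold is applied to
the simple-model estimate — a literal reading of the fitting convention
the titration protocol states.

*Replicate pooling.* Reported K_D = arithmetic mean over n ≥ 2
replicates with CI95 = z₀.₉₇₅·σ/√n. By default σ is the population
(divide-by-n) standard deviation of the replicate values — the
spreadsheet STDEV.P/CONFIDENCE.NORM convention the source protocol
names. For *calibration* purposes this convention matters: a z-interval
whose σ is estimated from only two replicates covers the truth ~60 % of
the time, not 95 % (the coverage probability is
P(|Z₁| ≤ 1.386·|Z₂|) ≈ 0.60 for independent standard normals, a
half-normal-ratio argument). CONFIDENCE.NORM itself is defined for a
*known* population σ, so the coverage study in the acceptance layer
estimates the per-fit K_D σ once from a pilot ensemble of 100 fits at
the same noise level and supplies it to the interval
(`pool_replicates(..., sigma=...)`). Under that known-σ reading the
pooled n = 2 interval covers the true K_D at the nominal ~95 % rate
(measured 94–96 % over 500 simulated pairs). The per-fit noise level is
itself calibrated at run time to a ~5 % K_D coefficient of variation by
linear scaling from a pilot ensemble (the K_D estimator's sd is linear
in the anisotropy noise in the small-noise regime).

*Ratio tables.* The double-mark preference is `K_D(single)/K_D(double)`
and the mutation effect is `K_D(WT)/K_D(mutant)` (> 1 = the mutant binds
more strongly). For display both are rounded to two significant figures,
one below 0.1, matching the printed panel's convention; internal
computation is unrounded. Θ in plots is defined per-curve as
`(Δr − BL)/F` with the fitted BL and F (not plateau-normalized).

## Synthetic genome

The generator emulates the statistical structure the genome analyses
assume, not reads: it emits normalized coverage directly.

* Default toy genome: 2 chromosomes × 2.5 Mb at 10 bp track resolution —
  thousands of 1-kb analysis bins, seconds-scale tests.
* **H3K9me2**: broad non-overlapping domains, width uniform in
  0.2–0.6 Mb (scaled down from the megabase scale in proportion to the
  toy genome so several independent domains fit per chromosome),
  covering 40 % of the genome — the mark is the most abundant H3
  methylation in the cell lines concerned. The last domain is trimmed so
  the realized covered fraction equals the target exactly. Signal =
  background 0.2 + level 4.0 × smoothed indicator (5-kb moving average,
  emulating the broad, peakless distribution) + Gaussian noise (sd 0.3),
  floored at 0.
* **H3K4me1**: kilobase peaks (0.5–2 kb, real enhancer scale) covering
  2 % of the genome, level 6.0, background 0.1, 200-bp smoothing. With
  40 % domain coverage, roughly 40 % of peaks land inside K9me2 domains
  by construction.
* **H3K9me3**: intermediate domains (50–200 kb) covering 10 %.
* **TTD (reader) track**: `α·K4me1·1[K9me2 domain] +
  γ·K4me1·1[K9me3 domain] + β·K9me2 + noise`, floored at 0, with
  defaults α = 1.0, β = 0.15, γ = 0.5, noise sd 0.2. The product term
  encodes the double-mark binding rule (reader follows H3K4me1 only
  where a K9-methyl domain provides the anchoring mark); the β term
  adds the weak K9me2-only binding; γ < α reflects the smaller genomic
  share of the K9me3 context.
* Annotations: a gap-free chromatin-state partition
  (Enhancer/FlankingTSS/Quiescent) with enhancers centered on planted
  K4me1 peaks at a configurable placement fidelity; TSSs; an
  enhancer→gene map.
* Expression: probe-level log2 fold changes for two rescue channels
  versus mock. A planted set of 115 genes is non-responsive under the
  WT rescue but upregulated (+2 log2) under the reader-dead (TTD*)
  rescue; disjoint WT-responsive up/down sets (30 + 30 of 400 genes)
  respond in both channels. Planted genes' enhancers carry H3K4me1
  shifted by +δ (default +1.0 = 2 enhancer-sd).

All randomness flows from one top-level seed through named, crc32-tagged
substreams, so every artifact is reproducible bit-for-bit and
independent of Python's per-process hash randomization.

**What passing tests do and do not show.** The generator plants exactly
the structure the analyses look for: piecewise-constant signal plus
i.i.d. Gaussian noise, rectangular domains, no mappability artifacts, no
copy-number variation, no fragment-length or GC effects, no correlated
replicate noise. Recovering the planted pattern therefore validates the
*statistical machinery* (binning, conditioning, clustering, null
calibration), not the biological claim on real data; genome-scale
numbers from real assays (genome-wide r values, real peak counts,
real bin totals) are not reproduced at this desk scale.

## Genome analyses

* Coordinates are 0-based half-open throughout; a shared boundary is
  never an overlap. Coverage tracks are run-length encoded over a
  complete partition of each chromosome, so per-base algebra (pooling =
  per-base mean, log2 ratio with pseudocount) and base-weighted interval
  means are exact (cumulative-integral evaluation, no densification).
* Binning tiles each chromosome from 0; the trailing short bin is kept
  for tiling and fragmentation. Bins overlapping the blacklist by any
  amount are dropped, not clipped, so bin widths stay uniform.
* Quantile split: stable sort by descending ranking signal with ties
  broken by genomic order; group sizes differ by at most one, larger
  groups first; group 1 = highest signal. Conditional correlation is
  plain Pearson on per-bin means within each group, flagged undefined
  for zero-variance groups. No log transform is applied except where a
  log2-ratio track is explicitly requested.
* Fragmentation: genome tiled in 150-bp steps; a fragment is kept iff
  its overlap with the merged peak union is ≥ retention × its width
  (inclusive, so 75 bp at the defaults).
* k-means (scikit-learn, 10 restarts, fixed seed) on per-fragment
  signals with columns standardized to zero mean/unit variance — track
  scales differ by orders of magnitude and unstandardized clustering
  would be dominated by the largest-scale track. Clusters are relabeled
  in decreasing order of the ordering track's mean so cluster 0 is
  always the strongest.
* Shuffle null: each interval keeps its length and is re-placed
  uniformly (chromosome chosen proportional to admissible starts),
  avoiding any blacklist overlap by rejection; shuffled intervals may
  overlap each other, matching the classic shuffle tool. Enrichment
  counts regions overlapping ≥ 1 bp (count-based, not base-pair-based);
  the empirical p-value uses the add-one estimator
  (1 + #{null ≥ obs})/(1 + n) to avoid zero p at small permutation
  counts.
* Region matrices center each region on its midpoint ± flank, split into
  equal windows; off-chromosome windows are missing values and regions
  with off-chromosome midpoints are dropped with a warning.

## Expression stage

Probe-level log2 fold changes are collapsed to genes by the median
(merging duplicate symbols by name). The 1.5-fold threshold is applied
on the linear scale, |log2 FC| ≥ log2 1.5, boundary inclusive — the
deposited data are log2 ratios while the threshold is quoted linear; the
inclusive boundary is this package's documented choice where the
convention is unstated. The reader-dependent set = WT non-responders ∩
TTD* up-set. Association between gene groups and enhancer marks uses
the classical equal-variance one-way ANOVA (the stated method; a Welch
option exists on the pairwise tests' scipy path but classical is the
default), with pairwise pooled-variance t-tests Bonferroni-multiplied
and capped at 1. For two groups, F = t² exactly. Expression-ratio
binning filters genes at ratio ≥ min_fold (or ≤ 1/min_fold) AND
max level ≥ min_level, then splits by ascending ratio into k near-equal
bins, ties broken by gene name.

## Problem sizes and defaults used in the shipped checks

The shipped acceptance checks run the co-occurrence chain on the 5-Mb
toy genome (5,000 × 1-kb bins, ~1,500 fragments), 500 simulated
replicate pairs for the CI calibration, 20–200 shuffles for the
enrichment nulls, and 100/300 seed replicates for the association
power and null-uniformity checks — sizes chosen so the whole suite runs
in well under a minute of compute while keeping Monte-Carlo error small
relative to the asserted margins.

## Known limitations

* The shuffle placer is rejection sampling; a blacklist leaving almost
  no admissible starts fails with an explicit error rather than
  degrading to a biased placement.
* `pool_tracks` and `log2_ratio_track` align breakpoints exactly and are
  O(total runs); dense per-base arrays are only materialized on request.
* The depletion model assumes one binding site and no cooperativity; no
  global multi-curve fitting, no anisotropy intensity-change correction,
  and no thermodynamic decomposition beyond ratios.
* The expression stage consumes pre-normalized fold changes; no Lowess
  normalization of raw two-color arrays.
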