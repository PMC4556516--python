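# Methods

## Problem setting

Heavy pedestrian traffic beside mountain tracks compacts soil, bares
and injures roots, and is expected to depress the annual radial growth
of adjacent trees relative to trees beyond the track's reach. The
natural design compares ring-width series from a **track zone**
(directly trampled) against a **control zone** within each study plot.
Two features make the inference delicate: permits in protected areas
fix small sample sizes in advance, and growth declines with tree age
anyway, so the trampling signal must be separated from an age trend
whose shape is itself uncertain. The package implements the full chain
of analyses this design calls for, each stage testable on synthetic
data with known truth.

## Data model and normalization

A `RingSeries` is one tree's dated widths (mm): the ring labelled year
*Y* is the increment formed in *Y*, years are consecutive, widths are
positive and finite. Trees cored but unusable carry a `flawed` flag;
they are counted in design bookkeeping but excluded from every
statistic. In the wide CSV layout an entirely empty column is the
canonical flawed marker.

Normalization replaces each width by its z-score against the grand
mean and SD of **all** retained measurements pooled across plots
(sample SD, ddof = 1, by default; a per-plot option exists because
pooling across sites with different productivity mixes two scales into
one — the default keeps everything on one comparable scale, which is
also what makes the between-plot heterogeneity test meaningful).
Chronologies are per plot × zone arithmetic means of z-values per
calendar year, each year averaging only the trees alive then; the
control-zone chronology is the reference trend.

## Chronology statistics

* **Mean sensitivity** MS = (1/(n−1)) Σ |2(wₜ−wₜ₋₁)/(wₜ+wₜ₋₁)|,
  computed per series on raw mm and averaged unweighted over series
  (not the MS of the mean chronology, which damps variability).
* **Gleichläufigkeit**: per year-to-year interval, score
  1 − ½|s_a − s_b| with s the sign of the first difference; both-zero
  counts 1, one-zero counts ½. Dataset GLK is the unweighted mean over
  all pairs overlapping ≥ 2 years.
* **r̄ and EPS**: mean pairwise Pearson correlation over common
  overlaps of ≥ 10 years (configurable), by default after per-series
  detrending with a modified negative exponential (ratio indices
  w/fit; fallback to the horizontal mean when the fit fails or the
  curve is not positive), because raw series correlate mostly through
  their shared age trend. EPS = n·r̄/(n·r̄ + (1−r̄)); undefined
  (reported as `None`) when r̄ ≤ 0.

## Representativeness simulation

Pool of *N* virtual trees, *K* flawed. For each sample size the draw
is an explicit without-replacement subset (first *n* positions of a
random permutation), 5000 replications by default, sizes 5..N step 5.
The per-draw flawed count is exactly Hypergeometric(*N*, *K*, *n*);
the closed-form mean *K/N* and SD with finite-population correction
serve as the analytic oracle, and the convergence report includes the
Spearman correlation of the standard error with sample size. Fractions
are also emitted as percentages. Reported "SE" is SD/√reps (the Monte
Carlo error of the mean); the per-draw SD is reported alongside, since
either reading of "standard error of the estimation" may be wanted.

## Trend families and comparisons

Fits operate on the group-mean normalized chronologies (a per-tree
long table is available for the GLM). Families: linear; negative
exponential a·e^(−b(x−x₀)) + k with a, b > 0 and x₀ the first year (k
free in sign, since z-scale chronologies are centred); logarithmic
b₀ + b₁·ln(x−x₀+1); cubic polynomial in (x − x̄); and a scaled
Weibull-density shape a·(u/c)^(b−1)·e^(−(u/c)^b), u = x−x₀+1, all
parameters positive — chosen as the rise-then-decline form matching
tree ontogeny. Note the Weibull shape is non-negative, so it can fit
mm-scale or index chronologies well but not centred z-scale ones; its
poor R² there is informative, not a bug.

Nonlinear fits use bounded multi-start least squares (five seeded
starts: range/level heuristics plus a log-linear pre-fit for the decay
rate; `scipy.optimize.least_squares`, ftol 1e-10, up to 5000 function
evaluations); the best-RSS converged start wins and total failure
raises. F and p are the regression F with (p−1, n−p) df; for the
nonlinear families the identical R²-based statistic is reported as a
descriptive analogue, not an exact test.

* **Best fit**: maximum R²; ties within 1e-8 go to the family with
  fewer parameters.
* **Goodness-of-fit comparison**: two-sided paired t test on absolute
  residuals of two fits on the same data — the simplest test matching
  a "are this curve's residuals smaller?" question.
* **Conservative selection**: keep the line unless a rival family has
  significantly smaller absolute residuals (p < α, default 0.05) and a
  lower mean |residual|; among qualifiers the max-R² family wins. The
  justification p-values ride along on the returned fit.
* **Parallelism**: extra-sum-of-squares F. Full model = separate
  parameter vectors per group; reduced = shared shape parameters with
  free per-group vertical offsets (for families without an intercept an
  additive offset term is introduced in the reduced model only). A
  flag switches the reduced model to one fully common curve.
* **Between-group residuals**: Welch t comparing the two groups'
  residuals under a single pooled fit. Pooled fits may contain tied
  x-values (both zones observed in the same years); fits require x
  sorted non-decreasing rather than strictly increasing for this
  reason.

## Watershed (breakpoint) sensitivity

The onset of mass tourism is not identifiable from visitation records,
so the scan fits linear trends per zone before/after each candidate
year (default 1960, 1970, 1980; the watershed year belongs to "after",
configurable). Zone-slope equality per period is tested by the
year × zone interaction of a combined OLS — one variance estimate,
standard output — rather than a z-comparison of separate fits.
Segments with fewer than 3 points are marked unfit, not errors, so
scans always complete. The summary tabulates slopes, R² and
interaction p side by side and reports the range of after-period track
slopes across watersheds: the divergence induced purely by the
arbitrary split. The whole-span fits are watershed-invariant by
construction and serve as an internal check.

## Joint GLM

Tree-level rings (not per-year means — the information about
tree-to-tree variability would otherwise be discarded; a means option
exists) are modelled as width ~ intercept + plot + zone + year with a
Gaussian family and identity link, which coincides with OLS on the
same design (asserted to 1e-8 in tests). Dummy coding against
configurable reference levels (default: first sorted plot, track
zone), so the zone contrast directly estimates how much wider control
rings are than track rings at fixed plot and year. Wald χ² =
(estimate/SE)² per term; the overall fit is the likelihood-ratio χ²
against the intercept-only model with df = number of non-intercept
terms (3 for two plots, two zones). The raw-mm response is the
default; normalized z is available and only rescales the estimates.

## Synthetic generator

w_i(t) = m_p·[a_p·e^(−b_p(t−B_i)) + k_p] · exp(c_{p,t} + δ·r(t)·1[track])
· e^(ε_it): a negative-exponential age trend from the tree's
recruitment year B_i; a plot-shared AR(1) year effect c (φ = 0.3,
innovation SD 0.15, log scale) standing in for climate; a trampling
deficit δ ≤ 0 (default −0.3, i.e. ≈ 26% growth loss) ramping linearly
over 10 years from onset 1970; and lognormal noise (σ = 0.2).
Multiplicative effects keep widths positive and make δ a constant
percentage suppression, the natural scale for growth. Flawed trees are
drawn Bernoulli(π = 1/6) or, in the `study_shape` preset, as exact
per-group counts (6/7/1/1 across the two plots' zones) so the
90 → 75 bookkeeping is deterministic. The preset's plots differ in
productivity (mature levels ≈ 0.35 vs 0.8 mm above differing juvenile
amplitudes) and recruitment windows (1770–1930, 1830–1950; last ring
2007), emulating a subalpine and a montane stand.

What the generator does **not** emulate: real climate signal structure
(volcanic years, trends), competition/release events, missing or false
rings, measurement error from core preparation, or spatial
autocorrelation within zones. Passing tests therefore demonstrate the
pipeline's statistical machinery is correct and recovers known truth
under the model's assumptions — not that field data satisfy those
assumptions.

## Problem sizes and numerical choices

Tests and the acceptance script run the full design (90 trees,
~11,000 rings, 238-year chronologies), 5000-replicate resampling, and
null-calibration loops of 200–500 replicates per test (each replicate
a small OLS), totalling well under a minute. Type-I-rate assertions
use wide binomial bands around α. All randomness flows through
explicit seeds (`numpy.random.default_rng`); equal seeds give
byte-identical datasets and artifacts, and every CLI output header
records version, seed and a config digest.

## Known limitations

* Crossdating is out of scope: inputs are assumed correctly dated.
* The parallelism F test is exact only for the linear-in-parameters
  families; for negexp/Weibull it is the usual nonlinear-regression
  approximation.
* EPS/GLK are computed over each group's full span; sub-period
  chronology statistics are not implemented.
* No mixed-effects (per-tree random effect) extension of the GLM;
  rings from one tree are treated as independent observations, so its
  SEs are anti-conservative for strongly autocorrelated trees.
* Legacy binary spreadsheet formats are not read; use CSV or xlsx.
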