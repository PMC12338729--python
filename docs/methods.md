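# Methods

## Edge co-fluctuation and amplitudes

For a parcellated scan, each region's timeseries is z-scored (population
SD) over *retained* frames only, after motion censoring; censored frames
are excluded from every downstream step rather than interpolated, so they
can neither bias standardization nor leak into amplitude bins. With
population-SD z-scores the temporal mean of an edge timeseries
`E_ij(t) = z_i(t) z_j(t)` equals the pair's Pearson correlation exactly,
which the tests assert to 1e-10.

Global and regional RSS amplitudes use the algebraic identities

    Σ_{i<j} (z_i z_j)²  =  ((Σ_i z_i²)² − Σ_i z_i⁴) / 2
    Σ_{j≠i} (z_i z_j)²  =  z_i² (Σ_j z_j² − z_i²)

so cost is O(TN) instead of O(TN²) and the edge matrix is never formed.
Tiny negative values from cancellation are clipped to zero before the
square root. The identity `Σ_i RSS_REGION_i² = 2·RSS_GLOBAL²` holds per
frame and is validated continuously.

## Binning and scoring

Retained frames are sorted ascending by global RSS (stable sort, ties
broken by original frame index for reproducibility) and cut into
contiguous near-equal bins (default 20). When T is not divisible by the
bin count, the remainder frames go to the highest-amplitude bins, keeping
the "5% of timepoints per bin" rule as close as possible while staying
deterministic. Scores are exact ratios of within-bin means; they are
invariant to any common positive rescaling of the amplitudes, and equal
`sqrt(2/N)` for all regions when every region carries the same signal.
Binning is per scan; multi-scan subjects should be averaged at the subject
level first, which respects each run's own amplitude distribution.

## Trajectory model

Per region, subject-by-bin observations (score, subject's own per-bin mean
global RSS, sex, mean FD) enter a penalized regression:

* smooth term: cubic B-spline on 10 equally spaced basis functions whose
  knots extend beyond the observed amplitude range (P-spline construction),
  with a second-order difference penalty. On uniform knots the penalty's
  null space corresponds exactly to straight lines, so the model reproduces
  linear trends exactly at any smoothing level — the basis is exact in the
  linear limit by construction, not approximately.
* identifiability: the basis is column-centered and reparametrized onto the
  sum-to-zero subspace next to an explicit intercept.
* smoothing parameter: profiled Gaussian restricted-likelihood criterion
  `(n − M) log σ̂² + log|XᵀX + λS| − rank(S) log λ` minimized over a 57-point
  log grid spanning 1e-6..1e8 (a GCV option exists; REML is the default
  because GCV undersmooths when the amplitude axis is heavily right-skewed,
  letting boundary wiggle corrupt the averaged second derivative). The fit
  is cross-checked in the test suite against mgcv's thin-plate REML GAM on
  identical data; partial R² agrees to ~0.001 and fitted curves to a few
  percent of their range.

The primary amplitude effect is the partial R² of the smooth —
`(SSE_reduced − SSE_full)/SSE_reduced` against a reduced model with only
intercept + covariates — signed by the average first derivative of the
fitted curve; significance is an F-type comparison using the smooth's
effective degrees of freedom (trace of the hat matrix). Derivatives are
central finite differences on a 200-point uniform grid over the observed
amplitude range, averaged over the grid; halving the step changes the
averages by under 1%. A constant response short-circuits to partial R² 0
and p = 1; constant covariates are dropped with a logged warning.

Regime labels: *flat* when the smooth is not significant at α = 0.05;
*inverted-U* when the average second derivative — normalized to curvature
units of score range per squared amplitude range, so the 1e-3 floor is
invariant to axis units — is below −1e-3 and the fitted curve peaks
strictly inside the amplitude range; otherwise *increasing*/*decreasing*
by the sign of the primary effect.

Age effects reuse the same machinery with age as the smooth term, applied
to each subject's mean score over a stated amplitude-bin range. The model
is population-level: no per-subject random smooths, matching the intended
design.

## Spatial alignment and spin testing

Bin-map similarity is Pearson correlation across regions, clustered by
average-linkage hierarchical clustering on distance 1 − r cut at k = 2 —
the simplest scheme that exposes a two-block high- versus mid/low-amplitude
structure. Axis alignment is Spearman by default (invariant to monotone
transforms of either map).

The spin test is parcel-level: Haar-uniform 3-D rotations (QR of Gaussian
matrices, deterministic under a seeded generator) are applied to
left-hemisphere unit-sphere centroids and the x-mirrored rotations to the
right hemisphere; each parcel then inherits the value of the nearest
rotated parcel within its hemisphere. Duplicate nearest assignments are
permitted (standard parcel-spin behavior) and logged. The two-tailed
p-value is `(1 + #{|null| ≥ |observed|}) / (1 + n_rotations)`, bounded
below by `1/(n_rotations + 1)`; the default rotation count is 10,000
(resolution 1e-4) while tests use ≤ 1,000. Observed and null statistics
share one vectorized code path so an identity rotation reproduces the
observed value bit-for-bit. Rotation ensembles can be precomputed and
shared across many maps; the type-I error at α = 0.05 on spatially
uncorrelated maps calibrates to 0.03–0.07.

## Condition contrasts

Rest-versus-movie contrasts average each subject's scores over a stated
bin range (high = the [90%, 100%] amplitude fraction, intermediate =
[40%, 60%]) and test the paired within-subject differences per region with
a two-sided paired t-test (Wilcoxon signed-rank behind a flag; the t-test
is the default for a paired per-subject design). The FDR family is all
regions within one bin-range analysis, adjusted by Benjamini–Hochberg
step-up (statsmodels). Zero-variance difference regions are flagged and
assigned p = 1 rather than dropped.

## Synthetic cohort generator

The generator emulates z-scored parcellated BOLD whose co-fluctuation is
gated by a latent per-frame global-amplitude state `a ~ Uniform(0,1)`
(i.i.d. by default — the pipeline treats frames exchangeably after binning
— with an optional AR(1) latent state that is off by default). Regions
belong to three classes sharing one factor each:

    x_i(t) = sqrt(g_k(a(t))) f_k(t) + noise_sd ε_i(t)

with defaults `g_S = 0.1 + 1.8a²` (increasing), `g_A = 0.1 + 3.6a(1−a)`
(inverted-U), `g_L = 0.1 + 0.45(1−a)²` (decreasing), noise_sd 0.25,
2000 frames, 20 subjects, 20 regions per class. The gain amplitudes are
deliberately asymmetric so that the *summed* coupling increases with `a`:
realized global RSS is then a monotone (noisy) readout of the latent state.
A mirror-symmetric choice (equal S and L amplitudes) makes realized
amplitude carry no information about `a` — the quantile bins would all mix
low- and high-state frames and the decreasing class could not appear
decreasing — so asymmetry is a structural requirement of the design, not a
tuning choice. With these defaults the group-level alignment profile
reproduces the qualitative empirical pattern: strong negative correlation
with the low end of the synthetic SA axis at top-amplitude bins, positive
at intermediate bins.

Parcel geometry samples centroids uniformly per unit hemisphere; the SA
rank is the rank of latitude plus a small longitude ripple, giving a
spatially autocorrelated axis, and classes are SA-rank tertiles (S lowest).
Covariates exist to exercise the model's nuisance terms: age uniform over
a configurable range, sex Bernoulli(0.5), mean FD |N(0.1, 0.03)| mm, and a
per-frame FD trace |N(mean_fd, 0.04)| censored at 0.2 mm. Development is a
gain-contrast exponent `γ = 1 + dev_sharpening (age − 6)` applied to the
normalized modulation, which sharpens class contrast monotonically with age
while fixing each gain's floor and peak. The "movie" condition multiplies
the coupling amplitude of the visual half of the S class by 1.5, which
sharpens those regions' amplitude dependence (high-bin scores rise relative
to other regions, low-bin scores fall) — the planted signature used by the
contrast tests.

What the generator does *not* emulate: hemodynamic response, temporal
autocorrelation of noise, physiological confounds, spatial noise
correlations beyond class structure, or realistic motion artifacts.
Passing tests therefore demonstrate correctness of the pipeline's
estimators and calibration of its inference under a known ground truth,
not robustness to real-data artifacts.

## Problem sizes and numerical choices

Test and acceptance runs use 20-subject, 60-region, 2000-frame cohorts
(10 seeds) for regime recovery; 1000 simulated map pairs over ten
500-rotation ensembles for spin calibration; and 200 simulated cohorts for
FDR control — sizes chosen so the full suite completes in well under a
minute while keeping every rate estimate's Monte-Carlo error far from its
acceptance margin. TSV writers use a `%.17g` float format so doubles
round-trip exactly and repeated runs are byte-identical. All randomness
derives from explicit integer seeds via `numpy.random.SeedSequence`
spawning, so cohorts, rotations and pipelines are pure functions of
(config, seed).

## Known limitations

* The smoothing-parameter search is a fixed log grid, not a continuous
  optimizer; resolution is ~0.25 decades, ample for effect summaries but
  not for exact λ comparisons with other software.
* The F-type smooth test treats effective degrees of freedom as fixed,
  ignoring smoothing-parameter uncertainty; its type-I error is validated
  empirically (~5% under shuffled scores) but is approximate, as in
  standard GAM practice.
* Spin nulls require roughly hemispherically symmetric parcellations; with
  few parcels, nearest-neighbour collisions make some rotations
  non-bijective (logged, and standard for parcel-level spins).
* CIFTI/GIFTI surface inputs are not parsed; users supply parcellated TSVs.
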