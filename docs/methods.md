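# Methods

`otoshape` implements an analysis chain for discriminating mixing herring
populations — Norwegian spring spawners (NSS), coastal Skagerrak spring
spawners (CSS) and the Landvik lake population (LV) — from otolith shape,
meristics, growth and gillnet survey structure. Because the underlying
field data are not publicly deposited, the package pairs every stage with
a synthetic-data generator whose ground truth is analytic, so the whole
chain is testable end to end.

## Otolith outlines and radii profiles

An otolith image is binarised (Otsu by default), the largest connected
component is selected, and its boundary is traced as a subpixel
marching-squares contour, returned counterclockwise in mathematical
(y-up) coordinates. Objects under 100 px or touching the image border are
rejected rather than silently clipped. Outlines are standardised to unit
area by centring on the polygon centroid and dividing coordinates by the
square root of the shoelace area; this removes overall size before any
shape comparison and is exactly idempotent.

The standardised outline is resampled as `n` equally spaced radii from
the centroid (angles 2πi/n from the positive x-axis, counterclockwise).
`n` defaults to 512 — a power of two is required by the dyadic wavelet
transform; the choice of 512 balances angular resolution against noise
and is configurable. If the outline is not star-shaped about its
centroid, a ray can cross the boundary more than once; the farthest
crossing is kept and a warning is raised, never a silent drop. Rays that
pass exactly through a polygon vertex are admitted by tolerance so the
crossing registers on the adjacent edges. Images are assumed pre-oriented
(rostrum to a fixed side), as in standard otolith protocols; no automatic
rotation is applied.

## Wavelet shape descriptors

Radii profiles are decomposed to full dyadic depth with an orthonormal
discrete wavelet transform: least-asymmetric (symlet) order-10 family,
periodic boundary. Under this combination the transform of a length-2^k
profile yields exactly 2^k coefficients, preserves energy (Parseval holds
to ~1e-11) and inverts exactly; both properties are enforced by tests.
Coefficients are stored coarse-to-fine (one scaling coefficient, then
detail bands at levels 1..k), so truncating the flattened vector after
2^j entries keeps exactly the j coarsest bands.

The number of detail bands retained for analysis is chosen by
reconstructing at every depth and taking the smallest depth whose mean
absolute relative deviation from the original profile falls below a
tolerance (default 1%). A relative-RMS metric is available by flag. For
the default synthetic shapes this selects 4 levels (16 coefficients).
Group mean shapes are coefficient-wise means reconstructed back to (x, y);
by linearity of the transform this equals the transform of the mean
profile, which is also tested.

## Length correction

Two stages remove fish-length effects from the retained coefficients:

1. **ANCOVA screen.** Per coefficient, the parallel-slopes model
   `coeff ~ group + length` is compared with the full interaction model by
   F-test. A significant group×length interaction (α = 0.05, the study's
   global significance level) means the coefficient cannot be adjusted by
   a common linear relationship and it is excluded. When a group's
   lengths are (near-)constant the interaction is not estimable: the tests
   are reported NA and the coefficient retained with a warning. Note the
   direct statistical consequence of per-coefficient screening at
   α = 0.05: a coefficient whose slopes are truly equal across groups is
   still excluded 5% of the time; the screen trades that false-exclusion
   rate for protection against non-adjustable coefficients.
2. **Allometric rescaling.** Each retained coefficient is rescaled to a
   common reference length L0 (default: grand mean length, recorded in
   the run manifest) as `value · (L0/length)^b`, with the allometric
   exponent b estimated as the slope of log|value| on log(length). The
   classical formulation assumes positive traits; wavelet coefficients
   can be negative, so magnitudes are regressed and signs reattached.
   Coefficients whose values span zero fall back to the linear residual
   adjustment `value − slope·(length − L0)` and are flagged. Scaling at
   L0 equal to each fish's own length is the identity.

## Constrained ordination

With Euclidean distances on the scaled coefficients, canonical analysis
of principal coordinates reduces to redundancy analysis, which is what is
implemented: the column-centred response is projected onto the span of
the group design (reference-coded dummies, centred), optionally augmented
with covariates; the fitted matrix is SVD-decomposed into canonical axes.
Covariates can enter either as additional constraints (default) or be
partialled out of both response and design (`condition=True`).

Inertia is reported as raw sums of squares, so constrained + residual =
total holds exactly and the pseudo-F

    F = (constrained/df_constraints) / (residual/df_residual)

coincides with the classical one-way ANOVA F in the one-variable,
two-group case (verified to 1e-10, and against vegan's `rda`/`anova` to
1e-9 on a fixture). Significance is assessed by permuting rows of the
(centred, possibly residualised) response; p = (1 + #{F* ≥ F}) / (1 +
n_perm), which cannot reach zero. Degenerate fits with zero residual
inertia report F = ∞ and the minimum attainable p. Axis signs follow a
fixed convention — the alphabetically first group has non-negative mean
score on every axis — so runs are reproducible. Pairwise group contrasts
refit each pair on its own subset and Bonferroni-correct across pairs;
pairs with fewer than three fish per group are skipped with a warning.

A factorial helper builds population×month×age designs, tests each
interaction marginally by permutation (extra constrained inertia over the
model without the term) and removes interactions with p > 0.05 from the
highest order down before the final fit.

## Growth

Length-at-age is fitted to the von Bertalanffy model
L(t) = L∞(1 − e^{−K(t − t0)}) by bounded nonlinear least squares with
multi-start initialisation (L∞ at 1.1× the group maximum; K ∈ {0.1, 0.3,
0.6}; t0 ∈ {−2, 0}), keeping the best of the converged starts and raising
if none converges. Several populations can be fitted jointly with any
subset of {L∞, K, t0} shared across groups — a shared t0 mirrors the
published parameter table, where all three populations carry the same age
intercept; the default leaves all parameters free. Standard errors come
from the Jacobian at the optimum. Recovery is unbiased to well under 2%
at n = 500 and 0.5 cm length noise (simulation suite), and the fit is
scale-consistent: rescaling lengths rescales L̂∞ and leaves K̂, t̂0
unchanged.

## Population statistics

CPUE is catch per gillnet. Mixing proportions weight each sample's
analysed composition by its CPUE and aggregate to month (and habitat);
per-month proportions sum to one and are invariant to rescaling all net
counts. The spawning variant restricts the numerator to maturity stage
≥ 6 (spawning/running or spent) while keeping the full denominator, so it
reads as the spawning fraction. Samples present in the records but absent
from the catch table are a hard error listing the orphan keys.

Vertebral counts are compared by one-way ANOVA with pairwise Welch
t-tests (the populations are unpaired samples of different fish, so
Welch's test replaces a paired design; a pooled-variance flag exists);
length and age, being skewed, use Kruskal-Wallis with pairwise
Mann-Whitney. All pairwise p-values are Bonferroni-corrected, and samples
(date×location×group) under five fish are excluded first. A sex ANCOVA
(character ~ sex + length) gates pooling of sexes. Maturity seasonality
uses Spearman's rank correlation of stage on month with midrank ties; for
n ≤ 9 the two-sided p is computed by exact enumeration of rank pairings
instead of the t-approximation. The vertebral-count trend is a linear
regression on month per group, reported alongside temperature and
salinity trends at each habitat's assumed spawning depth (3 m in the
lake, constrained by oxygen depletion; 5 m in the fjord), using the
nearest measured depth.

## Synthetic data

The generator encodes the study conditions so downstream stages see
realistic structure with known truth:

* **Outlines.** The radius function is a fixed low-order Fourier base
  (mildly elliptic with a rostrum-like bulge) times
  `1 + Σ windowed effects + noise`, scaled by `0.12 · length^a` with
  allometric exponent a = 1 by default (isometric, so the length
  correction is exercised against a known truth). Population effects are
  raised-cosine bumps in two angular sectors emulating the excisura-major
  and antirostrum regions where the populations differ; amplitudes are
  ordered NSS (+0.10) > CSS (+0.03) > LV (−0.06) in the main sector so
  the leading canonical axis orders the populations monotonically.
  Individual variation is band-limited (16 random harmonics, pointwise sd
  2% by default) to keep boundaries smooth like real otoliths; white
  noise would make the polygon locally non-star-shaped. A perturbation
  driving the radius non-positive raises a degenerate-shape error.
* **Records.** Ages are drawn from a fixed distribution on 2–12 with mode
  3 (the dominant age in the study season) and a long right tail; lengths
  follow each population's von Bertalanffy row — NSS (34.51, 0.33,
  −1.98), CSS (31.31, 0.41, −1.98), LV (30.33, 0.43, −1.98) — with
  Gaussian noise (sd 0.5 cm), optionally floored to the 0.5 cm below as
  in survey measurement; weight follows a standard length-weight power
  law. Vertebral counts are rounded Gaussians with means 57.5/56.7/55.7
  (NSS/CSS/LV) and sd 0.6 — the real populations' VS spread is not
  published, so 0.6 is a placeholder flagged in the config docs. Maturity
  stage is `clip(6 + month − spawn_peak ± noise, 3, 8)`, putting stage 6
  (spawning) at each population's peak: March for NSS, April for CSS,
  June for LV. Habitat occupancy follows monthly preference weights; the
  default study has LV shifting into the lake in May–June while NSS/CSS
  occupy the fjord earlier, and monthly abundances echo the survey season
  (no LV in February, no NSS in June).
* **Catches.** One catch row per date×location aggregates the records
  exactly (default one net per sample), so conservation is testable.

All draws flow from a single integer seed; identical seeds give
bit-identical tables and outlines.

What the generator does **not** emulate: real otolith texture and ring
structure, reading error in ages, gillnet size selectivity, spatial
autocorrelation within schools, and environmental fields (the
environment table is ingested, not simulated). Passing tests therefore
demonstrate that the statistical machinery recovers known structure of
this kind, not that the field conclusions themselves are reproduced.

## Numerical choices and degenerate inputs

* Ray-polygon intersection uses a 1e-9 parameter tolerance so rays through
  vertices register; multiple crossings keep the farthest hit with a
  warning.
* Rank-deficient ordination designs drop aliased directions (SVD basis)
  with a warning rather than failing.
* Zero-area polygons, centroids outside the outline, non-power-of-two
  radii counts, t ≤ t0 predictions and zero-permutation configurations
  are all explicit errors.
* Permutation p-values use the add-one estimator; permutation streams are
  sub-seeded per pairwise test via `SeedSequence` so stage order does not
  couple results.

## Problem sizes

The default test-suite problem sizes are chosen as the smallest that
exercise each property cleanly: 512-point profiles for transform
identities, n = 500 fish per group and 10–50 replicates for estimator
recovery, 199–999 permutations for inference checks, 1000 simulated
datasets for type-I calibration, and twenty pipeline replicates at 40%
of the default abundances (128 radii, 99 permutations) for the
end-to-end seasonal-mixing pattern.

## Known limitations

* Individual assignment of fish to CSS vs LV is out of scope by design —
  the constrained ordination separates group centroids; it is not a
  classifier.
* The allometric exponent of real otoliths is not identifiable from the
  synthetic default (isometric); the machinery supports a ≠ 1 but the
  defaults do not exercise strong allometry end-to-end.
* `factorial_cap` tests interactions by unrestricted row permutation; a
  residual-permutation scheme under the reduced model would be more exact
  for nested terms.
* The wavelet family, boundary rule and 1% deviation tolerance are
  documented assumptions; alternatives are configurable but untested
  beyond invertibility.
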