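# Methods

This note records the models implemented in `habtrack`, their assumptions,
the defaults that matter, and the design choices made where the methodology
was genuinely open.

## Spatial reference

All spatial computation uses a South-Pole-centred Lambert azimuthal
equal-area projection on a sphere of radius 6371 km (`grid.py`), implemented
in closed form. Because the projection preserves area, every cell of a
regular projected grid covers the same area on the sphere, so UD mass sums,
isopleth areas and the UDOI overlap-area term are exact cell counts times
cell area rather than latitude-weighted approximations. The analysis grid
uses 50-km cells; synthetic environments use 100-km cells (the covariate
fields are smooth at scales well above 100 km, so a finer environmental grid
costs memory without adding information). Great-circle distances are
haversine on the same sphere.

## Kernel utilization distributions

A UD is estimated by placing a Gaussian kernel of standard deviation
`smoothing_km` (default 200 km) at each projected fix, hard-truncating at
3σ, summing over fixes and normalizing so that Σ density × cell area = 1.
Choices worth stating:

- *Smoothing parameter = kernel standard deviation.* "Smoothing parameter"
  is ambiguous across software; the standard deviation reading is the
  dominant convention in the tracking literature and is fixed here
  bit-exactly. 200 km is deliberately wide: it absorbs light-level
  geolocation error (~186 km mean).
- *Hard truncation at 3σ.* An untruncated Gaussian is positive everywhere,
  which would make the UDOI joint-support area equal to the whole grid.
  Truncation makes ">0 density" meaningful. The discarded mass (~1.1%) is
  restored by renormalization.
- *Kernels sit at exact projected fix coordinates*, not binned cell centres;
  the estimator is verified cellwise against a direct Gaussian-sum oracle to
  1e-10 relative.
- *Merging across individuals* is the unweighted mean of normalized
  individual UDs — the only reading of "equal representation" that makes a
  bird's contribution independent of its tracking duration. Merging
  preserves normalization exactly.
- *Isopleths* accumulate cells in decreasing density order until the target
  mass is reached; ties at the cut are all included, which guarantees
  nesting across levels. Region mass therefore lies in
  [level, level + max single-cell mass].
- *No ocean clipping*: UDs are not masked to ocean cells. With a 200-km
  smoother, mass smeared over land is small and clipping conventions vary;
  the choice is recorded here rather than hidden.
- *Bandwidth selection is out of scope*: the smoother is a configuration
  constant, not estimated from the data.

Bootstrap sufficiency draws, for each n = 1..N, `replicates` subsets of n
individuals without replacement, merges each subset and records the isopleth
area. The sample is called saturated when the final step (N−1 → N) raises the
mean pooled area by less than 5% of the final mean. The 5% threshold is a
package constant chosen to make the verdict testable; it is reported
alongside the curve, never instead of it.

## Overlap and the segregation randomization test

UDOI is computed on the shared grid as A₁₂ · Σ u₁u₂Δ with A₁₂ the area of
joint (truncated) support; PHR is the mass of one UD inside another's
isopleth region, computed in both directions and symmetrized as their mean
(the directed values are always reported too, since the direction convention
in published tables is rarely stated).

The randomization test treats *individuals* as the exchangeable units:
locations within an individual are strongly serially dependent, so permuting
locations would be anticonservative. Group labels are reshuffled preserving
group sizes, group UDs are rebuilt by equal-weight merging of cached
individual UDs (each permutation is a matrix average, so N = 1000
permutations is cheap), and P is the proportion of randomized overlaps
smaller than the observed. When no null draw falls below the observed
overlap, P is reported as "< 1/N". Calibration is verified by simulation:
with two groups drawn from one spatial process the rejection rate at
α = 0.05 stays within [0.02, 0.08] over 200 replicate datasets.

## Availability: CRW pseudo-absences

For each observed track the empirical step lengths and turning angles are
extracted on projected coordinates (tracks with irregular cadence are first
interpolated to the nominal 12-h fix interval). Pseudo-tracks start at the
parent's first fix with a uniform random heading and draw (step, turn)
*pairs* jointly with replacement — joint resampling preserves the
speed–tortuosity correlation of the parent, which independent marginals
would destroy. Steps landing on land are redrawn up to a cap, then placed at
the nearest ocean cell (counted and reported, never silent). Timestamps are
copied from the parent, giving an exact 1:n_sim observed:simulated record
ratio per individual before missing-covariate drops. The default n_sim is 5;
`sensitivity_n_sim` sweeps {1, 2, 5, 10, 20} and reports linear-predictor
stability. Pseudo-tracks are constrained by the land mask and movement
kernel only — no habitat constraint, since the point of the null is to
represent where the animal *could* have gone.

Covariate sampling takes the weekly composite nearest the fix within ±1
week; chlorophyll is log₁₀-transformed (right-skewed); SST and depth
gradients are 3×3 focal standard deviations; the two distance covariates are
great-circle distances to the own colony and to the nearest other colony.
Records with any missing covariate (e.g. a noisy fix displaced onto land)
are flagged and, by default, dropped with a reported count.

## The habitat model

The use-availability response is modelled as a logistic additive model. Each
covariate enters through a fixed-dimension cubic B-spline basis (default 5
basis functions; knots at covariate quantiles; evaluation outside the
training range is clamped to the boundary). Group-specific smooths replicate
each basis per factor level; a year effect enters as categorical dummies.
Fitting is IRLS (statsmodels GLM, binomial family, tolerance 1e-8, 100
iterations); an independent direct likelihood optimization is used in the
tests as a cross-check, never as the implementation.

Design choices:

- *Fixed-dimension bases instead of penalized smooths.* Penalized thin-plate
  smooths have an effective degrees of freedom that depends on the estimated
  smoothing parameter, which makes AIC comparison and exact reproducibility
  awkward. With fixed bases the parameter count in AIC
  (−2 logL + 2k) is exact. The cost is slightly wigglier curves; response
  direction should therefore be read at covariate quantiles rather than at
  arbitrarily dense grid points (the tests evaluate monotonicity at the
  deciles of the central 90% of the covariate range).
- *Aliased columns dropped by QR column pivoting.* The B-spline partition of
  unity makes each full basis collinear with the intercept; rank-revealing
  QR removes a deterministic set of columns, and the dropped names are
  recorded on the fitted model.
- *Response curves are centred* to mean zero over the training covariate
  values, so contributions are comparable across models; standard errors
  come from the coefficient covariance of the kept block.
- *Complete separation* is flagged (|coefficient| > 30 on standardized-scale
  bases) rather than raised; flagged fits are excluded from rankings.
- *Population and season are handled by fitting separate models*, not by
  high-order interactions.
- *Importance = drop-one deviance.* importance(v) = (deviance without v −
  full deviance) / null deviance, with > 1% flagged important. Drop-one is
  transparent but shares deviance among collinear covariates (two copies of
  one covariate both score ≈ 0); this is a property of the definition, not a
  bug, and is covered by a test.

All-subsets selection fits every covariate subset (2^p models, capped at
p = 12), ranks by AIC and normalizes Akaike weights; spline knots are
computed once from the full data so every candidate sees identical bases.

## Evaluation

AUC is the Mann–Whitney statistic (ties half-counted; verified against a
brute-force concordant-pair count). Weekly AUC evaluates a fitted model one
ISO-style week at a time; leave-one-individual-out makes each individual a
fold (its own observed fixes are the presences and its own pseudo-absences
the absences, so the fold measures transfer to an unseen individual).
Cross-site transfer scores a model on the other population's records, whose
distance covariates are computed relative to *their* colony.

The driver comparison refits the model with all, habitat-only and
distance-only covariates and compares weekly AUCs with a paired Wilcoxon
signed-rank test (a distribution-free paired default; fewer than 6 common
weeks yields a descriptive comparison only). It accepts an optional held-out
record set: on strongly autocorrelated tracking data an in-sample weekly AUC
rewards any flexible model that memorizes the spatial fingerprint of the
training tracks, so the decisive comparison is made on individuals not used
for fitting.

Suitability maps threshold predicted probabilities at the ROC point
maximizing Youden's J = sensitivity − false-positive rate ("highest
sensitivity and lowest proportion of false positives" is not otherwise a
unique criterion); ties break toward the higher threshold. Map covariates
are per-cell medians of the season's weekly composites — medians resist
single-composite outliers; whether week-specific or climatological layers
are more faithful to any given published map is usually unstated, so the
choice is recorded here.

The group-smoother test compares leave-one-individual-out AUC under shared
and group-specific smooths with a paired Wilcoxon across individuals;
"group-specific preferred" requires P < 0.05 *and* a positive median AUC
difference.

## Synthetic data: what it emulates and what it does not

The generator produces weekly covariate composites on the polar grid: SST
with a linear poleward-cooling trend (16 °C at 30° S, −0.35 °C per degree
southward), a seasonal cycle (±1.5 °C) and AR(1)-evolving smooth mesoscale
noise (500-km correlation, 0.9 weekly persistence); log-normal chlorophyll
with a mid-latitude productivity band; zero-mean SLA; positive EKE; wind;
and static ridge-structured bathymetry. Land is the Antarctic continent, the
domain edge north of 30° S, and one cell per colony. Seven sub-Antarctic
colony groups at approximately real positions provide the distance
covariates.

Tracks are habitat-biased correlated random walks: gamma step lengths (mean
190 km per 12-h fix, matching a ~380 km/day travel rate at two fixes per
day), wrapped-normal turning angles, K = 10 candidate endpoints per step
scored by the preference specification (standardized-covariate log-weights,
colony attraction per 1000 km, colony avoidance decaying with a 1000-km
scale so walkers keep roughly 800–1200 km clear of foreign colonies), and
softmax selection. Positional error is isotropic Gaussian in the projected
plane (default sd 186 km), injected directly on true positions.

What passing tests on these data do **not** show: the generator has
independent noise fields per covariate, so it cannot produce the strong
covariate collinearity of a real ocean (e.g. SLA–EKE coupling); its
land-mask is minimal; positional error is Gaussian and stationary, whereas
geolocation error is latitude- and season-dependent; and preference
coefficients are constant in time. Recovery results therefore demonstrate
the machinery is correct and well calibrated, not that any particular field
dataset would yield equally clean inference. Ground-truth recovery tests run
with zero positional noise — noise robustness is checked separately (the
noise model itself is verified against its nominal sd), because recovery
*through* 186-km noise at desk-scale sample sizes would confound estimator
correctness with signal attenuation.

## Problem sizes and numerical conventions

Simulation-based tests use 10–20 individuals, 50–80-day tracks, 5–10
pseudo-tracks per bird, 500-permutation randomization tests, and 20–200
replicate datasets depending on the property under test — sizes chosen so
each calibration claim has adequate Monte-Carlo resolution while the whole
suite stays desk-scale. Seeds are fixed everywhere; identical seeds
reproduce identical environments, tracks and permutations bit-for-bit.
Degenerate inputs fail loudly (non-polar grids, single-class AUC, one-group
randomization tests) or warn and continue where the field convention is to
proceed (grid auto-expansion around out-of-extent fixes, empty equinox
filters, sub-30 bootstrap replicates).
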