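# habtrack

Utilization distributions, spatial-segregation randomization tests, and
use-availability habitat-preference models for animal tracking data on a
South-Pole-centred equal-area grid.

`habtrack` is aimed at movement ecologists analysing long non-breeding
migrations of wide-ranging marine animals (albatrosses and other pelagic
seabirds tracked with light-level geolocators are the motivating case). It
implements a complete pipeline:

1. **Track processing** — equinox filtering of geolocation fixes, a
   summer/winter seasonal split (winter = May 16 to Sep 15), and per-individual
   migration metrics (departure/return dates, cumulative distance, maximum
   range, circumpolar status, circular mean longitude).
2. **Space use** — kernel utilization distributions (UDs) on a 50-km
   Lambert-azimuthal equal-area grid with a 200-km Gaussian smoother truncated
   at 3σ, 50%/90% isopleths (core and general-use areas), equal-representation
   merging across individuals, and a bootstrap test that home-range area has
   saturated with sample size.
3. **Segregation** — the utilization distribution overlap index

   UDOI = A₁₂ · Σᵢ u₁ᵢ u₂ᵢ Δ,  A₁₂ = Δ · #{i : u₁ᵢ > 0 ∧ u₂ᵢ > 0}

   (Δ the cell area; 1 for identical uniform UDs, 0 for disjoint ones), the
   PHR home-range overlap, and a permutation test that reshuffles individuals
   between groups: P is the proportion of randomized overlaps *smaller* than
   the observed one, so small P means segregation.
4. **Availability** — correlated-random-walk (CRW) pseudo-absence tracks that
   jointly resample each bird's empirical step-length/turning-angle pairs,
   and sampling of ten covariates (SST, SST gradient, log₁₀ chlorophyll,
   depth, depth gradient, SLA, EKE, wind, distance to the own colony,
   distance to the closest other colony) from weekly composites.
5. **Habitat model** — a binomial additive model with cubic B-spline smooths
   (`SplineBinomialGAM`, a scikit-learn-style estimator), all-subsets AIC
   ranking with Akaike weights, drop-one deviance importance (covariates
   explaining > 1 % of null deviance are "important"), and centred response
   curves with standard errors.
6. **Evaluation** — weekly AUC, leave-one-individual-out cross-validation,
   cross-site transferability, full vs habitat-only vs distance-only driver
   comparison (paired Wilcoxon over weeks), Youden-threshold suitability maps,
   and a test for sex- or outcome-specific smooths.

A first-class synthetic-data module generates seasonal Southern-Ocean
covariate fields, a sub-Antarctic colony registry, and habitat-biased CRW
tracks with known preference coefficients and geolocation-style positional
error (sd 186 km, two fixes per day), so the entire pipeline is testable with
known ground truth and no downloads.

## Worked example

```python
import habtrack as ht

env = ht.generate_environment(seed=11, weeks=16)
colonies = ht.default_colonies()
sg = ht.simulate_tracks(env, colonies,
                        ht.PreferenceSpec(weights={"sst": 1.5}, colony_attraction=2.0),
                        8, 60, seed=11, own_colony="south_georgia", population="SG")
pei = ht.simulate_tracks(env, colonies,
                         ht.PreferenceSpec(weights={"sst": -1.0}, colony_attraction=2.0),
                         8, 60, seed=12, own_colony="marion", population="PEI")

grid = ht.SpatialGrid(cell_km=50.0, half_extent_km=7600.0)
uds = [ht.kernel_ud(t.lonlat, grid=grid, smoothing_km=200.0) for t in sg + pei]
res = ht.randomization_test(uds, [t.population for t in sg + pei],
                            statistic="udoi", n_permutations=500, seed=1)
print(f"observed UDOI  {res.observed:.2f}")
print(f"randomized     {res.null_mean:.2f} +/- {res.null_sd:.2f}")
print(f"P              {res.pvalue_label}")

rec = ht.build_use_availability(sg, env, colonies, n_sim=5, seed=2)
m = ht.SplineBinomialGAM(covariates=["sst", "dist_own"], df=4).fit(
    rec, rec["response"].to_numpy())
weekly = ht.weekly_auc(m, rec)
print(f"AIC            {m.aic_:.1f}")
print(f"weekly AUC     median {weekly['auc'].median():.2f}")
```

prints

```
observed UDOI  0.00
randomized     1.53 +/- 0.25
P              <0.002
AIC            4858.3
weekly AUC     median 0.69
```

The two simulated populations use opposite SST preferences, so their merged
UDs overlap far less than any of the 500 label permutations (observed 0.00
vs randomized 1.53 ± 0.25) — strong spatial segregation. The habitat model
fitted to the warm-water population discriminates observed from simulated
locations with a median weekly AUC of 0.69 using SST and colony distance
alone.

A thin CLI mirrors the main stages: `habtrack synth-env`, `synth-tracks`,
`summarize`, `ud`, `segregate` (see `habtrack --help`).

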