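# Methods

This note documents the model, the data-processing rules, the synthetic-data
generator, and the numerical and design choices behind `cjspersist`, in the
spirit of a package methods appendix. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## 1. The persistence model

### State process

Each population *i* = 1…N has a latent annual state `z[i,t] ∈ {0,1}` over
modeled years *t* = 1…T (default 1950–2024, T = 75). Assumptions:

- **Presence at the start.** Every population was extant in the first modeled
  year, regardless of when it was first recorded: `z[i,1] = 1`. Populations
  whose records all predate the start enter with an all-zero detection history
  (and a year-one non-detection term); populations first recorded later are
  treated as present-but-undetected before that record.
- **Absorbing extirpation, no colonization.** A population persists from one
  year to the next with a constant, population-specific probability φ_i, and
  once extirpated never returns. Equivalently the extirpation year
  τ_i ∈ {2, …, T+1} follows a truncated geometric law,
  P(τ = k) = φ^(k−2)(1−φ) for k ≤ T and P(τ = T+1) = φ^(T−1).
- **Time-constant covariates.** logit(φ_i) = α_r(i) + β_HS·h_i + β_rain·w_i +
  β_imp·v_i, with an intercept per level-III ecoregion and three covariates on
  [0,1] (mean habitat suitability, min–max-scaled mean winter precipitation,
  mean imperviousness fraction). The covariates come from recent rasters and
  are assumed representative of the whole span — a recognized approximation.

### Observation process

Detection of an *extant* population in year *t* is Bernoulli with
logit(p_it) = γ0 + β_trend·(t − t_ref) + β_effort·e[i,t]; an extirpated
population is never detected. `e[i,t]` is the scaled observer-day count
(one observer reporting any effort-indexing species — or the target — inside
the population polygon on one date).

Two choices the data-generating description leaves open are fixed here:

- **t_ref = 1987** (the span midpoint) rather than the first year; centering
  the trend reduces the posterior correlation between γ0 and β_trend that a
  1950 reference induces.
- **Effort scaling = z-score** over all population-year cells (mean/SD stored
  with the matrix); min–max and identity scalings are available. β_effort is
  therefore "per SD of observer-days".
- **Detection terms before the first detection count.** Since presence at
  1950 is assumed, the years between 1950 and a population's first record are
  genuine non-detections and contribute (1 − p) factors. This is the
  consistent reading of the presence-at-start assumption; it is flagged for
  sensitivity because the alternative (conditioning on first detection, as in
  a classic CJS) cannot be distinguished from the source description.

### Marginalized likelihood

Instead of sampling the latent states, the extirpation year is summed out
analytically. With L_i the (1-based) index of the last detection year
(L_i = 1 for never-detected populations):

    L_i(θ) = Σ_{τ = L_i+1}^{T+1}  φ^(τ−2) (1−φ)^[τ≤T]
             · Π_{t<τ} p_it^y_it (1 − p_it)^(1−y_it)

Terms with τ ≤ L_i vanish (a detection after extirpation has probability
zero), so the sum starts after the last detection. The per-population
persistence posterior given parameters is the τ = T+1 term divided by the
sum; the overall persistence probability `P_i` is its average over retained
posterior draws. `P_i = 1` exactly when the population was detected in the
final year. The marginalized likelihood is validated against brute-force
enumeration over all monotone latent histories (|Δ log L| < 1e-12 on random
instances with T ≤ 8).

### Priors, sampler, protocol

- Priors: independent Normal(0, sd 10) on every logit/linear-scale parameter
  (effectively flat on the probability scale); sd configurable.
- Sampler: adaptive random-walk Metropolis-within-Gibbs over the nine scalar
  parameters. Proposal scales adapt by Robbins–Monro toward 0.37 acceptance
  during burn-in only (diminishing adaptation, step exponent 0.6), then
  freeze, so the post-burn-in chain is a valid fixed-kernel MCMC. Detection
  cells that share a (year, scaled-effort) value are collapsed into a code
  table so each proposal touches every distinct logistic value once; ecoregion
  intercepts update only their own populations.
- Protocol: 3 chains × 100,000 iterations, first 50,000 discarded, every
  third retained (≈ 50k samples). Chains start from independent N(0,1) draws;
  a non-finite likelihood at initialization triggers a bounded number of
  re-draws. All randomness flows from one seed (per-chain streams via
  `SeedSequence`); identical config + seed reproduces every retained draw and
  output table byte-for-byte.
- A latent-state-augmented sampler (Gibbs on τ_i from its categorical full
  conditional, Metropolis on parameters given imputed states) targets the
  identical posterior and is compared against the marginalized sampler in the
  test suite (posterior means within Monte Carlo error, two-sample KS on
  thinned draws). It exists purely as a correctness cross-check; the
  marginalized sampler is the production path.

### Diagnostics

- **Split-chain Brooks–Gelman–Rubin**: each chain halved, R̂ = sqrt(((n−1)/n·W
  + B/n)/W); < 1.1 taken as converged. Zero within-chain variance is flagged
  degenerate rather than reported as a number. Cross-checked against
  `arviz.rhat`.
- **Posterior predictive checks**: for each retained draw, a full replicate
  state/detection history is simulated with the observed effort; the
  statistic is, per year window (defaults 1970–74, 2000–04, 2020–24), the
  mean over window years of the count of populations with a detection. The
  Bayesian p-value is the fraction of draws with simulated statistic ≥
  observed. With very sparse windows (observed statistic 0) ties push the
  p-value to 1 by construction; the diagnostic is informative only where the
  window statistic has spread.

## 2. Cleaning rules and their fixed points

Target records: (a) drop points > 10 km outside the range polygon (distances
in the equal-area plane); (b) drop location uncertainty > 5 km, *retain*
missing uncertainty; (c) same-day records within 10 m (geodesic/haversine)
are single-linkage clustered and collapsed to one representative. Effort
records: Nov 1 – Apr 30 window (inclusive, wrapping the year boundary); drop
uncertainty > 2.5 km or missing; region-restricted effort species kept only
in their allowed states (record's state field, else point-in-state-polygon,
else dropped with a report entry); one event per (date, coordinates rounded
to 5 decimals ≈ 1 m, observer). Every rule logs its drop count to a cleaning
report whose entries must reconcile exactly with row counts, and every rule
is idempotent.

Open points fixed by this package (the source protocol is silent):

- **Duplicate tie-break**: representative = highest-priority source
  (configurable ranking), then lexicographically smallest record id — making
  deduplication invariant to input row order.
- **"Exact same coordinates"** for effort dedup = rounded to 5 decimal
  places; a missing observer falls back to the record's source in the event
  key.
- **Year assignment** = calendar year of the event date; an optional switch
  maps Nov–Dec events to the following breeding-season year.

## 3. Geometry and zonal statistics

All metric geometry lives in one projected plane: a spherical Albers
equal-area conic on the authalic sphere (standard parallels 29.5°/45.5°,
central meridian −96°). Equal-area is the property that matters (buffer
dissolve, km² areas, zonal grids); the spherical form keeps forward/inverse
closed-form, and its area fidelity is verified against the analytic spherical
area of a graticule quad. Short-range duplicate distances use haversine
directly rather than the projection (an equal-area projection does not
preserve small distances).

Delineation buffers points at 32 quadrant segments (polygonal area deficit
< 0.05%, well inside the 1% tolerance on the isolated-disc check), dissolves
with a geometric union, and assigns records by polygon containment — the
union-find connected-components structure is used only as an independent test
oracle, never in the implementation. Population ids are stable
(west-to-east), so outputs are order-invariant.

Zonal statistics use **cell-center containment** (a cell belongs to a polygon
iff its center does), which is exactly reproducible by per-cell enumeration;
fractional-area weighting is noted as a refinement, not implemented. A
polygon containing no cell center falls back to the nearest finite cell,
flagged. Winter precipitation is the per-cell mean over December (of the
prior calendar year), January and February across the configured span
(default 1993–2023), min–max-scaled to [0,1] **before** zonal averaging —
scaling first, then averaging, is the stated processing order and the two do
not commute.

Vector I/O is GeoJSON; rasters are plain-text ESRI ASCII grids handled by a
small in-package container. These formats keep every fixture
human-readable; the package's projection utilities are self-contained.

## 4. The synthetic-data generator

The generator stands in for a multi-source compiled occurrence dataset that
has no runnable accession. Two levels:

**Matrix level** (`simulate_matrices`) draws covariates (h, w ~ Beta(2,2);
v ~ Beta(1.2, 8), mostly-rural with a few built-up polygons), uniform
ecoregions, Poisson observer-days with log-mean linear in calendar year, and
then states and detections *exactly from the model equations*. Every
simulated population is anchored present in the first modeled year, so the
fitted marginal likelihood is precisely the generating law — this is the
path used for simulation-based parameter recovery (5 replicates × 400
populations × 75 years in the acceptance suite; 95% interval coverage and
sign agreement of the strong coefficients are the acceptance properties).

**Record level** (`simulate_records`, `fixture_bundle`) fabricates a full
landscape (smooth suitability field, patchy imperviousness, precipitation
gradient with winter-to-winter noise, three ecoregion bands, seven state
bands, rectangular protected areas covering ≈ 40% of the range — matching
the study's share of protected population centroids — and a range polygon),
places population centers ≥ 7.5 km apart inside the range, and emits a
record stream: anchor records dated before the modeled span (every
population is known historically), observer-day events whose Poisson
intensity rises log-linearly (defaults put ≈ 87% of effort on/after 2000 and
≈ 10 events per population over the span, mirroring the compiled data's
shape), per-event target detections at the model's detection probability
while extant, non-target records of eight effort-indexing species (two
restricted to "SC", two to "MS") in the Nov–Apr window sharing each event's
reported coordinates, heterogeneous lognormal location uncertainty with a
stated missing fraction (36% for target records) and a small large-error
fraction, injected same-day < 10 m duplicates, and out-of-range decoys
> 10 km beyond the range polygon.

Geometry of the jitter is chosen so cleaning + delineation at the 2.5-km
baseline recovers the generated population count exactly: records sit ≤ 1 km
from their center, so within-population record gaps stay < 5 km (connected)
and between-population gaps stay > 5 km (separate). Centers ≥ 7.5 km apart
still allow 5-km buffers to merge close pairs, so the buffer-sensitivity
rerun exercises genuine regrouping.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: real spatial clustering of records along
roads and near cities; taxonomic misidentification; observer-level
heterogeneity in reporting; any causal effect of protection (protected
rectangles are placed independently of the covariates, so the
protected-vs-unprotected comparison on synthetic data measures incidental
spatial association only); colonization or metapopulation turnover (absent
by model assumption); and temporal change in the covariates. Note also that
the record-level generator detects *per event* while the model's detection
is *per year*, and the pipeline measures covariates as zonal polygon means
while the generator's truth uses center-point values — so parameters
re-estimated from the record-level pipeline are expected to differ
systematically from the generating values (effort slopes absorb the
events-per-year aggregation; covariate slopes rescale under aggregation).
Exact recovery is asserted only on the matrix-level path, where the model
and generator coincide.

## 5. Reporting conventions

- Threshold proportions are strict on both sides: "< 0.5" excludes 0.5,
  "> 0.9" excludes 0.9. Category bins are left-closed, with the last bin
  closed on both ends, so counts always sum to n.
- The protected/unprotected comparison uses Welch's unequal-variance t-test
  (statistic, Welch–Satterthwaite df, two-sided p, via scipy), chosen because
  group variances differ and the source report's fractional-free df is
  consistent with a rounded Welch df.
- A population's state/ecoregion/protected category is decided by the state
  polygon containing its *centroid* (nearest, flagged, if outside all).
- Persistence-vs-last-observation correlation is Pearson's r between the
  posterior persistence mean and the last detection year; never-detected
  populations use the year before the span (their anchored presence year).
- Buffer sensitivity reruns delineation → histories → fit per radius and
  reports coefficient signs/intervals plus the Spearman rank correlation of
  *record-level* persistence (each record inherits its population's
  posterior mean), which gives a common index across buffers whose
  populations do not correspond one-to-one.

## 6. Problem sizes and caches

The test suite runs the recovery study at 5 replicates with 3 × 30,000
iteration chains (thin 10) — enough for split-R̂ near 1 at this model size —
and the full protocol (3 × 100,000, thin 3) is used by the acceptance script
and the analysis drivers. Numba JIT-compiles the likelihood and sampler
kernels on first use (cached on disk afterwards). Per-population persistence
quantiles are computed from an evenly-spaced subsample of retained draws
(cap 4,000 per chain); posterior means use every retained draw.

## 7. Known limitations

- Constant φ_i over time: a population's hazard cannot trend or respond to
  droughts, disease, or land-use change within the span.
- No colonization: a location recolonized after local extinction is scored
  as continuous persistence (or its new records simply extend L_i).
- Search effort enters only through indexing species; places never visited
  by anyone reporting those species look like zero effort even if surveyed
  by other means.
- Detection-scale parameters are only as interpretable as the effort
  scaling; comparisons across datasets require the stored scaling constants.
- The spherical (rather than ellipsoidal) equal-area projection misstates
  areas by the sphere/ellipsoid authalic difference (well below the 1%
  tolerances used anywhere in the package), and distances used for the 10-m
  duplicate rule are great-circle, not geodesic-on-ellipsoid (sub-0.5%
  difference at these scales).
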