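# cjspersist

Range-wide **population persistence from presence-only occurrence records**,
via a modified Cormack–Jolly–Seber (CJS) state-space model.

Many declining amphibians — the Ornate Chorus Frog (*Pseudacris ornata*) of
the southeastern US coastal plain is the motivating case — are known mostly
from scattered museum and community-science records. Such data say where the
species *was*; they rarely say where anyone looked and failed to find it.
This package implements the full inference chain that turns raw occurrence
tables into per-population posterior probabilities of persistence:

1. **Cleaning** — range-polygon tolerance (drop points > 10 km outside the
   range map), location-uncertainty thresholds (> 5 km dropped for the target,
   missing retained; > 2.5 km *or missing* dropped for effort records),
   same-day 10-m duplicate collapse, a Nov 1–Apr 30 activity window for
   effort records, and one-event-per-(date, coordinates, observer)
   deduplication.
2. **Population delineation** — a 2.5-km buffer around every target record,
   overlapping buffers dissolved, so records < 5 km apart share a population;
   centroids assigned to level-III ecoregions, states and protected-area
   categories; zonal means of three covariate rasters.
3. **Effort reconstruction** — detections of co-occurring non-target species
   (plus the target's own records) inside each population polygon index
   search effort as observer-days per population-year.
4. **Model fitting** — Bayesian MCMC for the modified CJS model below, with
   split-chain Brooks–Gelman–Rubin diagnostics and posterior predictive
   checks.
5. **Reporting** — per-state/ecoregion/protected-area summaries, persistence
   categories, Welch *t* comparisons, and buffer-size sensitivity reruns.

## The model

Population *i* carries a latent state `z[i,t] ∈ {0,1}` (extant/extirpated)
over years *t* = 1…T (1950–2024). Every population is assumed present in the
first year; extirpation is absorbing:

    z[i,1] = 1,   z[i,t+1] | z[i,t] ~ Bernoulli(z[i,t] · φ_i)

    logit(φ_i) = α_r(i) + β_HS·h_i + β_rain·w_i + β_imp·v_i

with ecoregion intercepts `α_r` and three time-constant covariates on [0,1]:
mean habitat suitability `h`, scaled mean winter (Dec–Feb) precipitation `w`,
and mean surface imperviousness `v`. Detection of an extant population in
year *t* is

    y[i,t] | z[i,t] ~ Bernoulli(z[i,t] · p_it),
    logit(p_it) = γ0 + β_trend·(t − t_ref) + β_effort·e[i,t]

where `e[i,t]` is the scaled observer-day count. Rather than sampling the
latent states, the likelihood marginalizes the extirpation year `τ_i`
analytically (a sum of at most T+1 terms per population), which makes the
posterior target exact and cheap; an equivalent latent-state-augmented Gibbs
sampler is included as a cross-check. The quantity of interest is the
posterior `P(z[i,T] = 1 | data)` — the probability the population persists in
the final year. Priors are Normal(0, 10) on all logit/linear-scale
parameters; the default protocol is 3 chains × 100,000 iterations, the first
half discarded, every third retained.

Because the study's compiled multi-source dataset is not deposited as a
runnable accession, the package ships a first-class synthetic-data module
(`cjspersist.simulate`) that fabricates landscapes, populations and record
streams with known generating parameters, so every stage — and full-model
parameter recovery — is testable offline.

## Worked example

The `tiny` fixture (12 synthetic populations, 1950–2024) runs end to end in
seconds:

```python
import cjspersist as cp

res = cp.run_pipeline({
    "seed": 11, "outdir": "runs/tiny", "fixture": "tiny",
    "mcmc": {"chains": 3, "iterations": 20000, "burn_in": 10000,
             "thin": 5, "prior_sd": 10.0},
})
print(res.persistence[["pop_id", "persistence_mean", "state"]].round(3))
```

which prints (abridged):

```
 pop_id  persistence_mean  persistence_q2.5  state  ecoregion                protected_category
pop0000             0.134             0.000     LA  Southeastern Plains                    none
pop0002             0.888             0.234     MS  Southern Coastal Plain             military
pop0003             0.998             0.984     MS  Southern Coastal Plain         state forest
pop0007             0.143             0.000     FL  Southeastern Plains             ngo/private
...
```

and a run summary:

```
n_populations        12
mean_persistence     0.471   (SD 0.361)
pearson_r_last_obs   0.627
max_rhat             1.007
```

`pop0003` was detected recently under real search effort, so its persistence
posterior is ~1; `pop0000`'s last record is decades old despite ongoing
effort nearby, so it is probably extirpated (0.13). The positive correlation
between persistence and the year of last observation (r = 0.63 here) is the
expected signature of the model. All artifacts (cleaning report, population
polygons, detection/effort matrices, posterior draws, summary tables) land in
`runs/tiny/`.

The same pipeline is exposed as a CLI
(`cjspersist all --config cfg.yaml --seed 11 --outdir runs/tiny`, plus
staged subcommands `simulate`, `clean`, `delineate`, `histories`, `fit`,
`report`, `sensitivity`), and the `analysis/` directory holds numbered
scripts that walk the full-scale analysis (simulate → clean →
delineate → histories → fit → summarize → sensitivity), writing their tables
under `results/`.

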