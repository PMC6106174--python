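# betadrift

Tools for asking whether communities on a gridded species atlas are becoming
more alike over time — **biotic homogenization** — and whether the loss of
compositional distinctness is accompanied by a loss of *functional*
distinctness, or masked by trait redundancy.  The package targets analyses of
national atlas data (e.g., breeding-bird atlases on a 10 km national grid
surveyed decades apart) but every input is a plain CSV, and a synthetic-data
generator with known, controllable structure stands in for real atlases so
each stage can be validated end to end.

It is written for spatial community ecologists and macroecologists who want a
tested, reproducible version of the "difference in turnover" workflow:
neighborhood turnover in two periods, the change between them, a trait-shuffle
null model, and spatial regressions of the change on biotic and climatic
covariates.

## The measures

For a focal grid cell and one of its (up to 8) Moore neighbors, with `a`
species shared, `b` only in the neighbor and `c` only in the focal cell,
taxonomic turnover is the Simpson-family index

    beta_sim = min(b, c) / (min(b, c) + a)

which ignores richness gradients and nestedness.  Functional turnover uses
Rao's quadratic entropy Q = sum_ij p_i p_j d_ij over Gower distances d_ij on
mixed traits (continuous, ordinal, categorical and multi-label):

    beta_rao = Q_gamma(pooled pair) - mean(Q_alpha within each community)

on the Jost equivalent-numbers scale by default.  Each cell's turnover is the
mean of the pairwise measure over its surviving neighbors (a moving window,
so coastal cells just average fewer pairs), and homogenization is a *negative*
change: turnover(period 2) − turnover(period 1) < 0.

Whether a cell's change in `beta_rao` is surprising *given* its change in
`beta_sim` is judged against a trait-shuffle null: species labels are
permuted against intact trait rows 999 times (occurrences, richness and
taxonomic turnover are untouched by construction), and a two-tailed rank
p-value locates the observed change in the null distribution.

Drivers are assessed with intrinsic-CAR Gaussian regressions (spatial random
field on the Moore graph plus iid noise, fitted by a collapsed Gibbs
sampler), comparing three covariate sets by DIC: biotic (earlier-period
richness, Rao Q, mean binomial variance of local occupancy), climate (3
attributes x 5 time-series measures = 15 covariates), and their union, with
latitude and longitude always included.

## Worked example

```python
import numpy as np
import betadrift as bd

cfg = bd.SimConfig(grid_size=27, n_species=60, seed=1,
                   homog_region=(4, 4, 14, 14), homog_strength=1.0,
                   trait_coupling=0.8)
a1, a2 = bd.simulate_atlas_pair(cfg)          # two survey periods
traits = bd.simulate_traits(cfg)
dmat = bd.gower(traits)

t1 = bd.neighborhood_turnover(a1, dmat, "sim")
t2 = bd.neighborhood_turnover(a2, dmat, "sim")
dsim = bd.delta(t1, t2)
region = cfg.region_mask().ravel()
print(f"mean delta beta_sim inside forced region: "
      f"{np.nanmean(dsim.delta[region]):+.3f}")
print(f"mean delta beta_sim outside:              "
      f"{np.nanmean(dsim.delta[~region]):+.3f}")

null = bd.null_delta_distribution(a1, a2, traits, n_reps=199, seed=2)
drao = bd.delta(bd.neighborhood_turnover(a1, dmat, "rao"),
                bd.neighborhood_turnover(a2, dmat, "rao"))
counts = bd.classification_counts(bd.classify(dsim, drao, null.p_two_tailed))
print(counts)

fit = bd.regress_rao_on_sim(drao, dsim, n_iter=2000, n_burn=500, seed=3)
s = fit.summary.loc["delta_sim"]
print(f"slope: median {s['median']:.4f}, "
      f"95% CI ({s['q2.5']:.4f}, {s['q97.5']:.4f})")
```

prints

```
mean delta beta_sim inside forced region: -0.210
mean delta beta_sim outside:              -0.003
                           Functional homogenization  Functional differentiation
Taxonomic homogenization                          18                           7
Taxonomic differentiation                          0                           0
slope: median 0.0279, 95% CI (0.0147, 0.0411)
```

The generator forced full-strength homogenization inside an 11x11-cell
region, and the analysis finds it: neighborhood taxonomic turnover drops by
0.21 there and is flat elsewhere; the 25 cells where the trait-shuffle null
is rejected are dominated by joint taxonomic + functional homogenization
(the traits were coupled to species' environmental niches, so compositional
convergence drags trait composition along); and the change in functional
turnover tracks the change in taxonomic turnover with a credibly positive
slope.

## Command line

The same stages are exposed as subcommands (`betadrift simulate | climate |
biotic | turnover | nulltest | fit | compare | run-all`); `run-all` drives a
whole study from a YAML config:

```yaml
seed: 1
scales: [10, 30, 90]
simulation:
  grid_size: 27
  n_species: 60
  homog_region: [4, 4, 14, 14]
  homog_strength: 1.0
  trait_coupling: 0.8
nulltest: {reps: 999, alpha: 0.05}
fit: {n_iter: 6000, n_burn: 1000}
```

and writes per-scale turnover fields, delta maps, null-test classifications
with 2x2 count tables, covariate tables, fit summaries, a DIC ranking, and a
manifest that reproduces every output byte for byte.

## Layout

- `src/betadrift/atlas.py` — grid data model, CSV IO, land/neighbor
  exclusions, 3x/9x block aggregation
- `src/betadrift/traits.py` — Gower distances on mixed traits, Rao Q
- `src/betadrift/turnover.py` — pairwise measures, moving-window fields,
  period deltas
- `src/betadrift/nullmodel.py` — trait-shuffle null, two-tailed tests,
  quadrant classification
- `src/betadrift/climate.py` — annualization (min temp, Thornthwaite-PET
  drought, growing degree days) and the 15 derived covariates
- `src/betadrift/biotic.py` — richness, Rao Q, mean binomial variance
- `src/betadrift/icar.py` — ICAR regressions, collapsed Gibbs sampler, DIC
- `src/betadrift/simulate.py` — the synthetic-data generator
- `src/betadrift/pipeline.py`, `cli.py` — orchestration and the CLI

See `docs/methods.md` for the model details, defaults and design choices.
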