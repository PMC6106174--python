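# Methods

This note documents the models and procedures implemented in `betadrift`,
the defaults and the reasoning behind the genuinely open design choices.

## Grid model and exclusions

Cells are squares of a regular national-style grid, identified by the
integer lower-left corner (easting, northing) in km.  Two filters are
applied before any analysis: cells with land fraction strictly below 0.5 are
dropped, then cells left without any Moore (8-way) neighbor are dropped,
*iterated to a fixed point* — removing an isolated cell can orphan a former
neighbor, and a fixed point makes the rule order-independent.  Aggregation
to 30 km and 90 km squares unions presences over 3x3 / 9x9 blocks anchored
at the minimum easting/northing; a block's land fraction is the mean over
the full block (missing members count as water), and partial edge blocks are
kept whenever that mean passes the land rule, mirroring the 50%-land filter
rather than inventing a separate member-count rule.

## Turnover measures

All measures are pairwise focal-vs-neighbor, averaged over the focal cell's
surviving neighbors; pairs with an empty community are dropped from the
mean, and a cell with no valid pair is NA.  The pairwise treatment is used
for *both* the taxonomic and the functional measure so the two are
comparable (the alternative — focal versus pooled neighborhood — would mix
scales between measures).

* `beta_sim = min(b,c) / (min(b,c) + a)`.  When one community is empty
  (`a = 0` and `min(b,c) = 0`) the index is undefined and returns NA.
* `beta_rao`: Rao quadratic entropy decomposition.  With presence-only data
  every present species has weight `1/S`; pooling weights are 1/2 per
  community (two randomly chosen individuals, one from the pooled pair).
  By default both alpha (the mean within-community Q) and gamma (pooled Q)
  are mapped to equivalent numbers `1/(1-Q)` before differencing
  (`jost=True`); the raw additive and the proportional
  `(gamma-alpha)/gamma` variants are available by flag because the
  literature uses all three.  For Gower distances the decomposition is
  non-negative in any variant: Gower dissimilarity is conditionally
  negative definite (each per-trait part is an L1 / mismatch / Jaccard
  distance), so pooled Q can never fall below mean within Q.
* Nearest functional neighbor (NFN) averages, over both directions, each
  species' distance to its nearest counterpart in the opposite community;
  mean functional dissimilarity (MFD) averages all cross-community pairs.
  Note MFD is positive even for identical communities (it includes the
  within-community mixture), so only beta_sim, beta_rao and NFN vanish on a
  spatially constant atlas.

Change is always `turnover(period 2) - turnover(period 1)`; negative values
mean homogenization.

## Gower distances

Per-trait contributions are averaged with equal weight: continuous traits
use range-normalized absolute differences (body-mass-like traits flagged in
config are log-transformed first); ordinal traits are rank-scaled and then
treated as continuous; categorical traits contribute a 0/1 mismatch;
multi-label traits ("and/or" nest types, diet) are coded as label sets and
contribute one minus Jaccard similarity.  A zero-range trait contributes 0
with a warning (it still counts in the denominator).  No Podani ordinal
extension and no trait weighting are applied.

## Trait-shuffle null model

The null randomizes the species-to-trait-row assignment: a permutation of
species labels over intact rows.  For a complete one-row-per-species table
this is exactly what the independent-swap-style randomization of trait-matrix
row names reduces to.  It preserves richness, occupancy, spatial structure
and taxonomic turnover verbatim (occurrences are never touched) as well as
trait ranges and covariances (rows travel whole).  One shuffle serves both
periods within a replicate, so the null distribution of `delta beta_rao`
isolates the trait assignment rather than period-specific traits.  With 999
replicates the two-tailed p-value is `min(1, 2*min(r_low+1, r_high+1)/(n+1))`
with ties counted inclusively on both tails — conservative, and never 0.
Rejected cells are classified by the sign pair of (`delta beta_sim`,
`delta beta_rao`) into the four homogenization/differentiation quadrants; a
rejected cell with `delta beta_rao` exactly 0 cannot be signed and is NA
with a warning.  No across-cell multiplicity correction is applied.

## Climate covariates

From monthly series (tmin, tmean, precipitation) per cell, three annual
attributes are derived: coldest-month mean daily minimum temperature (degC);
drought = annual potential evapotranspiration minus total precipitation
(mm); growing degree days = sum over months of max(0, tmean - 5.5 degC)
weighted by month length (daily data are not assumed).  PET is a pluggable
interface defaulting to Thornthwaite's monthly formula (tmean + latitude,
daylength from solar declination); it is a documented stand-in — any
callable with the same signature can replace it, and the hot-climate
(>26.5 degC) correction is not implemented since the intended domain is
temperate.

Each attribute is summarized by five measures over ~30 annual values: mean;
long-term trend (OLS slope per year); detrended variance (residual sum of
squares about the OLS line divided by n-2, the regression residual
variance); lag-1 autocorrelation (Pearson r of consecutive values, NA for a
constant series); and the fat-tail statistic
`(Q0.975 - Q0.025) / (Q0.875 - Q0.125)`, the ratio of the central 95% to the
central 75% quantile range — about 1.267 for uniform data, 1.704 for
Gaussian, larger under heavier tails.  Quantiles use linear interpolation by
default; the convention is configurable and recorded in the output metadata
because the statistic is sensitive to it at n = 30.  The 3 x 5 layout gives
the 15 covariates `Min.temp, Drought, GDD, var{T,D,G}, auto{T,D,G},
LTT{T,D,G}, Ftail{T,D,G}`.

## Biotic covariates

Computed on the *earlier* atlas: species richness; Rao Q of the focal cell;
and the mean binomial variance (MBV) of local occupancy — for every species
found in the focal cell or its surviving Moore neighbors, `n p q` with `p`
the occupied fraction of the window and `n` the realized window size, then
averaged over species.  By default `p` and `n` refer to the *surrounding*
cells only (the focal cell defines membership but not occupancy), matching
the "surrounding squares" reading; `include_focal=True` switches to the
whole-window convention.  MBV ranges over [0, n/4], maximal when species
occupy half the window — the configuration with the most room for local
range expansion or contraction.

## ICAR regressions

Per cell, `y_i = x_i' beta + phi_i + eps_i` with Gaussian noise and an
intrinsic CAR field on the Moore graph: prior density proportional to
`exp(-tau_phi/2 * phi' R phi)`, `R = D - W`, with a sum-to-zero constraint
per connected graph component.  `R` is rescaled once per component so the
geometric mean of the constrained field's marginal variances (diagonal of
the generalized inverse) is 1, putting `tau_phi` on an interpretable scale.
Covariates are standardized to mean 0, sd 1 (latitude/longitude — cell
center coordinates — included in every model and standardized like the
rest); the response stays on its own scale.  Coefficients get N(0, 1/0.001)
priors; both precisions get Gamma(shape 1, rate 0.005) priors by default
(configurable, recorded in the fit).

Inference is a collapsed Gibbs sampler.  In the spectral basis of `R` the
marginal model (field integrated out) has diagonal covariance
`1/tau_eps + 1/(tau_phi * lambda_k)`, so `beta` has an exact Gaussian
update and each precision an exact univariate update by slice sampling;
the field is then drawn conjugately (null-space coordinates pinned to zero,
which *is* the per-component sum-to-zero constraint).  A fully conjugate
sweep (`phi | rest`, `tau | phi`) was implemented first and abandoned: it
mixes pathologically between the correct mode and a ridge where the field
absorbs the noise, a known weak identifiability of ICAR-plus-noise models.
Defaults are 6000 iterations with 1000 burn-in; a split-chain R-hat above
1.1 on any coefficient logs a convergence warning.

DIC is `Dbar + pD`, `pD = Dbar - D(plug-in)`, computed from the *marginal*
deviance `-2 log N(y | X beta, I/tau_eps + R^+/tau_phi)`.  The conditional
(field-given) deviance was rejected after it systematically favored
whichever model let the field soak up missed signal plus noise — the
underpenalization DIC is known for under rich random-effect structures.
Plug-ins use posterior means for `beta` and log-scale (geometric) means for
the precisions, since the precision posteriors are strongly right-skewed on
the identifiability ridge.  Model comparison ranks fits by DIC with a
delta-DIC column; `regress_rao_on_sim` fits the single-covariate model of
functional on taxonomic turnover change with the covariate centered but
unscaled (the slope is then change-per-unit-change) and flags the effect
substantial when the 95% credible interval excludes 0.

## Synthetic data generator

The generator emulates the shape of a two-period national atlas study, not
any real geography.  Occupancy: a smooth latent environmental surface
(linear gradient plus low-frequency sinusoids), species optima spread along
it, occupancy probability logistic in the squared environment-optimum
mismatch, presences drawn independently per cell.  Period 2 copies period 1
outside a configurable rectangle; inside, occupancy is redrawn from
`(1-h) * p + h * majority`, where `majority` is the period-1 3x3-window
occupied fraction thresholded at 1/2 (ties keep `p`).  At `h = 0` the
region is an independent redraw from the same law (a no-signal control); at
`h = 1` neighborhoods converge deterministically, forcing negative
`delta beta_sim` of known location.  Traits: mixed types mirroring typical
avian trait tables (log-normal body mass, ordinal age at first breeding,
categorical development mode, multi-label nest/diet categories); a coupling
parameter in [0, 1] correlates every trait's latent score with the species'
niche optimum, creating real trait-environment structure at high coupling
and exact independence at 0.  Climate: per attribute, seasonal cycle +
linear year trend + AR(1) monthly noise with Student-t innovations
(df configurable; infinite = Gaussian), parameters varying smoothly in
space; defaults are temperate-maritime-like (tmean ~9 degC, amplitude
6 degC, trend 0.02 degC/yr, AR 0.3, precipitation ~80 mm/month).

What the generator does *not* emulate: real coastlines (land fraction is 1
everywhere, so exclusion logic is exercised by dedicated fixtures instead),
recorder effort variation, dispersal limitation, species interactions, and
spatially correlated detection error.  Passing tests therefore demonstrate
that the estimators recover known structure of this generative family, not
that real atlas data satisfy its assumptions.

## Numerical conventions and degenerate inputs

NA propagates through turnover deltas and covariates; cells with missing
values are dropped (and logged) before model fitting, and a constant design
column is a hard error.  Empty communities yield NA for all pairwise
measures; an empty-window MBV is NA; Rao Q of an empty community is an
error.  Quantile interpolation, the Rao decomposition variant, and the MBV
focal convention are all explicit flags recorded in outputs.  All
randomness flows from explicit integer seeds; re-running any pipeline
config reproduces outputs byte for byte.

## Problem sizes used by the test suite

The suite validates pairwise measures against independent brute-force
oracles (500 random pairs for beta_sim, 100 instances at 1e-12 for the
functional measures), calibrates the null model on a 27x27-cell, 60-species,
199-replicate no-signal study, checks ICAR coefficient recovery and interval
coverage over 50 replicates on a 15x15 lattice, and runs DIC covariate-set
selection over 20 replicates per direction on a 12x12 lattice with chains of
3000 sweeps.  These sizes give stable Monte-Carlo behavior (DIC noise ~1
unit, coverage binomial error ~2%) while keeping the full suite at a few
minutes on one core; the same machinery scales unchanged to atlas-sized
grids (thousands of cells), where the dense spectral decomposition —
computed once per graph — is the dominant cost.

## Known limitations

* The Thornthwaite PET stand-in ignores radiation, wind and humidity; the
  drought attribute is therefore a temperature-driven index, not a water
  balance.
* DIC on the marginal deviance ranks covariate sets reliably in simulation
  but remains an in-sample criterion with AIC-like flip probability for
  small parameter-count differences.
* The trait-shuffle null conditions on observed occupancy change; it cannot
  detect functional structure that is orthogonal to species identity.
* The ICAR field and iid noise are only weakly separable at moderate
  smoothness; variance-partition parameters (tau_phi, tau_eps) should not
  be interpreted individually, though coefficient inference is unaffected.
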