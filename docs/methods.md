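# Methods

## 1. Metrics

For a predator of body mass `M` (g) whose stomach holds prey of individual
masses `m_1 … m_n` (g):

- number-weighted PPMR: `r_num = (1/n) Σ_j M/m_j` — the mean per-link mass
  ratio; every ingested individual counts equally.
- biomass-weighted PPMR: `r_bio = M / mean(m_j)`.  Algebraically identical
  to the per-link form `Σ_j (M/m_j)(m_j/w)` with `w = Σ m_j`; the package
  carries both implementations (`r_bio`, `r_bio_linkwise`) and tests their
  equality at 1e-12 as an internal oracle.

By the arithmetic–harmonic mean inequality `r_num ≥ r_bio`, with equality
iff all prey in a stomach share one mass.

Group-level metrics pool predators within cells of species × 0.1-wide log10
mass bin × subregion.  `R_num` averages individual `r_num` with weights
`n_i/N` (each predator's share of prey counts); `R_bio` averages `r_bio`
with weights proportional to specific total prey mass `w_i/M_i` (g prey per
g predator), so stomachs holding more food relative to their owner's size
count more.  The weighted mean predator mass reported for a cell follows the
same weighting as the corresponding metric.  Cells with fewer than 10
predators (default) are dropped and logged.

Mass bins are half-open `[k/10, k/10 + 1/10)` in log10 g with an inclusive
lower edge; a 1e-9 epsilon inside `assign_mass_bin` keeps masses sitting
exactly on an edge (e.g. `10^2.3`) in the bin they open.

## 2. Preprocessing

Steps, in order, each gated by provenance flags so the chain is idempotent:

1. **Length–weight models** per prey (taxon, life stage), OLS on
   log10 mass vs log10 length over largely intact (≥ 75%) fish and crab prey
   carrying both measurements; pooled-stage fallback per taxon; minimum 10
   pairs.  No back-transform bias correction is applied — the models
   reconstruct individual masses, not population means.
2. **Digested-mass reconstruction**: fish and crab prey < 75% intact with at
   least one measurable length get their masses replaced by length–weight
   predictions.
3. **Digestion filter**: remaining prey strictly below the threshold are
   excluded; the 75.0 boundary itself is retained.  Predators emptied by the
   filter leave the data set (logged).
4. **Imputation of aggregated records**: if count and total mass were both
   recorded, each individual gets `total/count`.  If only a total was
   recorded, the count is back-imputed as `round(total / mean)` (floor 1)
   from a pooled mean-mass table keyed by (taxon, stage, region) with
   coarser fallbacks, and the recorded total is divided evenly — measured
   biomass is preserved; only the count is inferred.  Unresolvable records
   are dropped and logged.
5. **Predator mass from length** via species-specific length–weight models
   fitted to predators carrying both measurements.

Parameters (`IngestConfig`): digestion threshold 75% — below this, soft
tissue loss makes recorded masses unusable while hard parts still allow a
length measurement; minimum length–weight sample size 10 — below this the
allometric slope is too noisy to back-calculate masses spanning decades.

## 3. Hierarchical model

Response: `log10 R` per group (either metric, fitted separately).
Predictor: `u = log10` of the group's weighted mean predator mass, matched
to the response weighting.  Two standardized regressors are built
*independently*: `x = (u − ū)/sd(u)` and `x2 = (u² − mean(u²))/sd(u²)` — the
quadratic regressor is the standardized *square of raw mass*, not the square
of the standardized mass.

```
log10 R_g = β0 + β1 x_g + β2 x2_g
          + Σ_l (u_{l,0} + u_{l,1} x_g + u_{l,2} x2_g) + ε_g
```

with nested levels l ∈ {order ⊃ family ⊃ species ⊃ region ⊃ subregion},
uncorrelated deviations per term, and `ε ~ N(0, σ²)`.

Priors: fixed effects `N(0, 3)` (variance 3 — weakly informative on the
log10 scale, where plausible intercepts span roughly 0–5); random-effect
sds half-Cauchy(0, 10); residual sd half-Student-t(df 3, scale 10) by
default.  `prior_residual="literal"` instead places InverseGamma(0.001,
0.001) on σ², matching a common legacy specification; it is near-flat on
log σ and gives indistinguishable results at this data size.

### Sampler

No probabilistic-programming backend is available in the target
environment, so the model is fitted by a purpose-built blocked Gibbs
sampler:

- half-Cauchy and half-t sd priors are expressed as inverse-gamma scale
  mixtures (parameter expansion), making every conditional conjugate;
- coefficient blocks are drawn jointly per grouping unit via batched 3×3
  Cholesky solves;
- **translation ("sweep") moves**: the sum of a level's intercepts is nearly
  unidentified against its parent's intercept; after each scan, a
  generalized-Gibbs move shifts per-parent child means into the parent (the
  likelihood is invariant, the shift's conditional is Gaussian in the priors
  alone), which removes a severe random-walk pathology;
- **interweaved sd updates (ASIS)**: holding the standardized deviations
  fixed, the signed sd enters the likelihood linearly; a univariate slice
  step samples it under its Cauchy prior, then deviations are rescaled.
  This breaks the funnel that traps near-zero variance components in the
  centered parameterization.

Presets: `default` — 3 chains × 1000 iterations, 300 burn-in, no thinning
(2100 draws); `paper-mcmc` — 3 × 1550, 50 burn-in, thin 3 (1500 draws),
mirroring the original study's published chain settings.  The longer default
burn-in is a robustness choice: at ~1000 groups the sweep/ASIS-corrected
sampler reaches split-R̂ ≈ 1.05–1.15 within 300 iterations, while 50 is
occasionally marginal.  Fits with max split-R̂ ≥ 1.2 (arviz, over fixed
effects, level sds and σ) raise `NoConvergenceError`; settings yielding
fewer than 500 total draws are rejected up front.

### Explained variance

`bayesian_r2_sequence` computes, per posterior draw,
`R² = Var(ŷ)/(Var(ŷ) + σ²)` with predictions built from the fixed effects
alone and then cumulatively adding each level (order, family, species,
region, subregion); it reports the median and 95% HPD per level set.  The
increment attributable to a level is the difference between consecutive
rows.

## 4. Community aggregation

Given posterior draws and a biomass-density table per (species, region,
subregion, mass bin), the community mean PPMR for a region × bin is a
two-stage biomass-weighted average computed per posterior draw on the ratio
scale: subregion predictions are first averaged within species (weights:
subregion share of the species' biomass), then species averaged (weights:
species share of community biomass).  Because the weights are proportional
within the nesting, this equals a single-pass weighted sum over (species,
subregion) cells — the package carries that brute-force oracle separately
and tests equality at 1e-12.

Cells whose labels the model never saw fall back up the ladder subregion →
region → species → family → order → fixed effects; the level used is
recorded per cell, and each region × bin reports *coverage*: the biomass
fraction predicted at species level or deeper.  Summaries are the median and
5th/95th percentiles over ≥ 100 draws.

Predictions are made at bin midpoints (`bin_lo + 0.05` log10 g) on the
posterior median curve without retransformation bias correction by default;
`bias_correct=True` applies the log-normal factor `10^(σ² ln10 / 2)`.

## 5. Spectrum comparative statics

With a community PPMR `R`, the relative trophic level of mass `M_t` against
baseline `M_r` is `log10(M_t/M_r)/log10(R)` — each factor of `R` in body
mass is one trophic step.  The preferred PPMR (feeding-kernel mode under
equal prey availability) is approximated as 60% of the realized
(stomach-measured) ratio.

## 6. Synthetic generator

`simulate_dataset` emulates trawl-survey diet data: a five-level taxonomy
(defaults: 3 orders × 2 families × 4 species, 2 regions × 2 subregions, 6
mass bins spanning log10 mass 0.5–4.5, 20 predators per cell) with
level-specific random deviations of a quadratic log10 PPMR–mass curve
(fixed coefficients (2.7, 0.05, −0.2) on the generator's own standardized
scale; species-dominant sds, e.g. species intercept 0.45 vs ≤ 0.15
elsewhere, so variance decomposition has a known ordering).  Prey masses
are log-normal around `log10 M − log10 β` with kernel width σ = 0.5 log10
units, chosen so `R_num/R_bio = 10^(σ² ln10) ≈ 3.8` — a realistic separation
between the two metrics.  Reporting imperfections mirror field data: 64% of
intact invertebrate records carry only count + total, a further 19% only a
total; 10% of records are digested (< 75% intact, lengths retained for fish
and crab so reconstruction is exercised); 46% of predators carry length
only.  Prey taxa are decade-wide size bands so mean-mass imputation is
coherent by construction.  Length–weight truths: fish `10⁻⁵ L³` (g, mm),
crab `10⁻⁴ L³`, predators `0.01 L³` (g, cm).

Because the kernel is log-normal, group truths are closed-form:
`R_bio* = β·10^(−σ² ln10/2)`, `R_num* = β·10^(+σ² ln10/2)`; these drive all
recovery tests.  `simulate_group_table` draws the group table directly from
the mixed model (residual sd 0.08) for fast sampler-recovery studies.

These defaults are study conditions: tests are written against them, never
the reverse.

## 7. Numerical choices

- Canonical row sort in `build_design` (stable mergesort on the full label
  hierarchy plus bin) makes fits bit-identical under input row permutation.
- Chain seeds derive from one `SeedSequence.spawn`, so results are
  reproducible given (data, seed) and independent across chains.
- Percentile summaries use linear interpolation; HPD intervals use arviz.
- CSV serialization uses 6 significant digits; the record-level consistency
  check (`Σ individual masses ≤ total`) allows 1e-3 relative slack to absorb
  that rounding.

## 8. Limitations

- Equal-mass imputation of aggregated records flattens within-record prey
  mass variation.  `R_bio` is unaffected (it depends only on totals), but
  the mean-of-reciprocals `R_num` is biased downward by Jensen's
  inequality; under the generator's full study conditions the bias reaches
  ~10–15% in some groups.  This is inherent to count + total reporting, not
  to the implementation.
- Random-effect terms are mutually uncorrelated within a level (no
  intercept–slope correlation), matching the model the sampler was built
  for; correlated deviations would need a different conjugate structure.
- Length–weight fits use OLS on logs without retransformation bias
  correction; reconstructed masses are medians, not means, of the
  conditional mass-at-length distribution.
- The community fallback ladder assumes taxonomy supplied for unseen
  species is correct; a wrong family assignment silently borrows the wrong
  deviations.
- The generator draws predator masses uniformly within bins and biomass
  densities log-normally; it makes no attempt to mimic gear selectivity,
  seasonal effects or empty stomachs.
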