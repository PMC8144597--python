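# Methods

`pedsurv` analyses offspring survival to reproductive maturity in managed
captive-breeding programs, from studbook (pedigree registry) data. This
note records the model, the conventions, the numerical choices, and what
the synthetic data do and do not establish.

## Pedigree conventions

All genetic quantities are pedigree-based and follow standard captive-
management practice:

- **Founders.** Wild-born individuals are assumed mutually unrelated and
  non-inbred (f = 0). By default (`wild_ancestry="truncate"`) a wild-born
  animal is treated as a founder even when parents happen to be recorded,
  so its recorded ancestry contributes no pedigree paths; the
  `wild_ancestry="keep"` switch follows recorded parents instead.
- **Unknown parents.** Each UNKNOWN parent slot is a distinct phantom wild
  founder: f = 0, generation 0, unrelated to everything ("set unknown
  parents to wild"). Any identity-by-descent path through an unknown
  parent therefore contributes zero.
- **Kinship** phi(i, j) is the probability that one random allele from
  each of i and j is identical by descent. It is computed by the memoized
  recursion phi(i, j) = (phi(sire_i, j) + phi(dam_i, j)) / 2, recursing
  through the deeper individual's parents, with phi(i, i) =
  (1 + f(i)) / 2. The recursion is exact: all values are dyadic rationals
  represented exactly in double precision at realistic pedigree depths.
- **Inbreeding** f(i) equals the kinship of i's parents.
- **Generations in captivity** G: wild-born animals are G0; captive-born
  animals get the parental mean plus one, so G can be non-integer
  (a G0 x G1 pairing yields G1.5).
- **Effective population size** uses Wright's sex-ratio estimator
  Ne = 4 Nm Nf / (Nm + Nf) over distinct breeding males and females (an
  individual counts as a breeder if it appears as a sire/dam). Studbook
  software computes related but not always identical quantities; equality
  with any particular program's output is not asserted.
- **Gene dropping** is the independent Monte Carlo oracle for the kinship
  machinery: two globally distinct alleles per founder, Mendelian
  transmission in topological order, and the estimator "one random allele
  from each individual per replicate" with a binomial standard error. The
  recursion and the oracle are required to agree within 3 Monte Carlo
  standard errors in the test suite.

Dates are ISO-8601 calendar dates; all ages and durations are integer
days.

## Dataset construction

1. **Truncation.** The final 364 days of the studbook are dropped
   (recent deaths may not yet be registered); the reference date becomes
   the latest record date minus 364 days.
2. **Survival label.** Survival to the sex-specific age at reproductive
   maturity (days; unknown-sex individuals use the shorter of the two
   ages): 1 if the individual reached that age before death, 0 if it died
   younger. Any individual born within its maturity window of the
   reference date is excluded outright - including those that already
   died - because its cohort has not had full opportunity to reach
   maturity; keeping the early deaths but not their surviving cohort-mates
   would bias survival downward.
3. **Exclusions**, in order, each counted: too-young (above), flagged
   hybrids, wild-born offspring and animals released to the wild before
   maturity (optional `release_date` column; absent column leaves the
   filter inert), offspring with an unknown sire or dam. Excluded animals
   remain in the pedigree as ancestors - exclusion removes analysis rows,
   not pedigree nodes - otherwise f and G of retained offspring would be
   corrupted.
4. **Predictors.** Seven per offspring: dam/sire generations in
   captivity, dam/sire age at the offspring's birth (days), dam/sire f,
   offspring f. Parental ages are birth-date arithmetic (age at birth,
   not conception).
5. **Litters.** Same dam + same day for mammal-style species, same dam +
   same calendar year for clutch-laying species. Litter-mates are not
   independent; one offspring per litter is sampled uniformly at random,
   and the whole analysis is repeated over five such samples (seeds
   base_seed + 1 ... + 5) and pooled.
6. **Standardization.** The seven predictors are centred and scaled
   (sample SD, n-1) within species, so coefficients are comparable across
   species with very different scales. A predictor constant within a
   species (a real situation: species whose recorded parents are all
   non-inbred) is centred only, with a warning - dropping the species
   would silently change the model.
7. **G2+ subset.** The multi-generational analysis retains only offspring
   both of whose parents are captive-born (raw parental generation >= 1).
   Subsetting happens after standardization of the replicate, using the
   retained raw columns.

## The survival model

Bernoulli survival with logit link:

    survival ~ dam_G + sire_G + dam_age + sire_age + dam_f + sire_f +
               offspring_f + (1|species) + (1|species:program) +
               (1|species:year)

The nested design "(1|Species/BirthProgram)" is expanded into independent
intercepts for species and species:program; species:year is the third
independent term. Estimation is maximum likelihood under the Laplace
approximation: for a given vector of random-effect SDs, fixed effects and
spherical conditional modes are maximized jointly by penalized IRLS with
step halving; the profiled deviance

    dev(sigma) = -2 l_y + ||s||^2 + log det(Lambda' Z' W Z Lambda + I)

is minimized over sigma >= 0 by bounded L-BFGS-B (finite differences,
step 1e-5) with a Powell fallback. Starting values are deterministic
(beta and modes at zero, SDs at 0.5), so fits carry no randomness. With
all SDs pinned at zero the objective is exactly the logistic-regression
likelihood, which is the engine's primary oracle; a second, external
cross-check against lme4's Laplace `glmer` on a common dataset agrees to
|d beta| < 0.01 and |d logLik| < 0.01 at n = 1500. Wald standard errors
are conditional on the estimated variance parameters (as in lme4).
Standardized coefficients beyond |15| trigger a separation warning.

**Random slopes.** Species-level effects of a predictor come from adding
an uncorrelated species-level random slope to the full global model; the
species effect is the fixed slope plus the species BLUP. The slope term
is uncorrelated with the species intercept - with ~15 species a
correlated pair is poorly identified. Slope models may legitimately fail
to converge when between-species variation is negligible; the failure is
reported, never forced.

## Diagnostics

DHARMa-style simulation-based checks: randomized quantile residuals (the
exact randomized-rank form (B + U(E + 1)) / (m + 1), uniform at any
finite simulation count), a Kolmogorov-Smirnov uniformity test, a
dispersion test on the variance of residuals about the simulation mean
(each simulation scored leave-one-out against the others so observed and
simulated statistics are comparable), a zero-inflation envelope test, and
an outlier count with a Bernoulli-appropriate expected rate. Diagnostics
simulate *conditionally* on the estimated random effects: re-drawing the
effects would make residuals of observations sharing a group strongly
dependent and the KS test anti-conservative (measured: 24/40 rejections
at nominal 5% marginally vs 1/30 conditionally). `Results.simulate`
defaults to marginal simulation for general use; the diagnostics pass
`conditional=True`. Collinearity is checked by VIF = 1/(1 - R^2) per
predictor (threshold < 2).

## Model selection, averaging, pooling

All 2^7 = 128 subsets of the fixed predictors (intercept always
included) are fitted with the identical random structure and ranked by
AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1), where k counts fixed effects
plus variance parameters. Sub-models are warm-started at the global
model's variance estimates with a capped number of refinement iterations;
the residual AICc error of the cap was measured below 0.01, far inside
the 2-unit retention granularity. Models within 2 AICc of the best
(boundary inclusive) are retained; weights are renormalized over the
retained set (MuMIn's behaviour for a subset table). The *conditional*
average of a predictor runs over retained models containing it, with the
revised Burnham-Anderson standard error sum_m w_m sqrt(se_m^2 + (b_m -
b_avg)^2); relative importance is the summed renormalized weight of
models containing the predictor. A predictor absent from every retained
model keeps an aligned NaN row with importance 0. Replicates are pooled
as mean estimate, mean SE, CI = mean +/- 1.96 x mean SE; a CI excluding
zero is flagged significant. Random-slope models are refitted from the
global model - averaging cannot produce slope estimates - on the
"representative" replicate, defined operationally as the replicate whose
averaged estimates have minimal summed absolute deviation from the pooled
means (the choice is a documented stand-in, not a claim about any other
operationalization).

## Phylogenetic signal

Pagel's lambda multiplies the off-diagonal of the Brownian-motion
covariance (shared root-to-MRCA path lengths; unit branch lengths
substituted, with a warning, for topology-only trees). The Gaussian
likelihood profiles the mean and rate analytically, leaving a bounded
1-D ML search in lambda on [0, 1] (tolerance 1e-8, with an 11-point grid
pre-scan and endpoint snapping). The LRT against lambda = 0 uses the
boundary-corrected null, an equal mixture of a point mass at zero and
chi-square(1), so p = 0.5 P(chi2_1 >= LRT). Star phylogenies make the
likelihood flat in lambda; the fit then reports an unidentifiable flag
rather than an arbitrary interior value. The implementation is
cross-checked against phytools' `phylosig` in the test suite. Signal is
assessed both for species mean survival and for each predictor's
species-level random-slope effects.

## Synthetic studbooks

The generator forward-simulates a breeding program per species and year:
wild founder intakes (Poisson), eligibility by survival and sex-specific
maturity, a capped number of breeding females per year (managed programs
pair a limited number), mate choice (random, kin-avoiding or
kin-preferring over sampled candidates), litters/clutches under both
litter rules, region inheritance with occasional transfer, and Bernoulli
survival with logit linear in the seven within-species-standardized
predictors plus species intercepts, species-level slope deviations, and
program- and year-within-species effects. Internal f/G bookkeeping uses
the same recursion as the analysis side and must agree exactly (tested).

Default parameters emulate the multi-species captive-breeding setting
the package targets: 15 species of which 3 are clutch layers, pooled-
analysis-scale coefficients (strong negative offspring-f effect, small
generation effects, opposite-signed parental-age effects of ~0.06 per
SD), random-effect SDs of 0.5 (species) and 0.3 (program, year), slope-
deviation SDs of 0.15, maturity ages of 300-750 days (mammal-style) and
900-1600 days (clutch-layers), litters of mean 2.5 capped at 8, and a
0.5/year wild-intake rate.

Because the predictors emerge from pedigree dynamics, their moments are
unknown a priori; to make true coefficients interpretable per 1 realized
SD the simulator runs twice - a calibration pass measures realized
per-species moments, then the definitive pass re-runs the forward process
standardizing against those frozen moments. Death dates are assigned so
survival labels are exactly recoverable (non-survivors die uniformly
before maturity; survivors at maturity plus an exponential tail); the
realism of age distributions is cosmetic and not asserted.

What the generator does **not** emulate: age-specific fecundity and
seasonality, parity effects, maternal/epigenetic mechanisms, non-random
missingness of parentage, or transfers during early life. Passing tests
therefore demonstrate that the pipeline recovers effects under its own
model class, not that real studbooks satisfy that class.

## Problem sizes used by the test suite

Test problem sizes are chosen so the full suite runs in tens of minutes
on one CPU: oracle agreement uses 10 random pedigrees (<= ~250
individuals) x 20 pairs x 100,000 gene-dropping replicates; the GLM
reduction uses n = 4,000; CI coverage uses 50 replicates at n = 2,500;
the pooled-pipeline recovery study simulates 10 studbooks of ~3,500
analysis rows (5 species, 24 years; ~1,400 rows per litter-sampled
replicate) with a -0.5 offspring-f effect and requires a correctly
signed, significant pooled estimate in >= 90%; lambda calibration uses
200 i.i.d. replicates on 15 tips and 20 Brownian replicates on 50 tips;
byte-level reproducibility reruns the full pipeline twice on a 4-species
studbook.

## Known limitations

- The Laplace approximation can bias variance estimates for binary data
  with few observations per group; the coverage test budgets for this
  (>= 80% observed at nominal 95%).
- Sub-model AICc values carry the (measured, < 0.01) error of the capped
  variance refinement.
- The kinship recursion assumes founder unrelatedness; molecular kinship
  would differ where that assumption fails.
- The zero-inflation diagnostic has essentially no power against
  misspecification that a refitted Bernoulli model can absorb; it is
  informative only against a fixed fitted model.
- `effective_size` is the Wright sex-ratio form only; census-size and
  drift-based estimators are out of scope.
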