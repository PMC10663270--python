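# Methods

## Simulation model

Phenotypes are generated plot by plot from the additive decomposition

    Y_ijkl = mu + G_i + L_j + Y_k + GL_ij + GY_ik + LY_jk + GLY_ijk + eps_ijkl

with the trait mean mu = 46 bu/ac.  All genotype-related terms are built
from an infinitesimal-model approximation: 1000 biallelic QTL assigned to
loci on a 20-chromosome map of 2145.5 cM, and per-term QTL effect vectors
phi so that, e.g., `G_i = theta_i . phi_G` with `theta_i` the QTL dosage
vector of line i.  Effects are sampled i.i.d. normal and deterministically
rescaled so the realized variance of `theta . phi` among founders equals
the target component exactly (the construction of the published study is
supplementary-only; exact rescaling is this package's choice and removes
one source of Monte-Carlo noise from every variance target).

Variance components, (bu/ac)^2:

| term | A scenarios | B scenarios |
|------|------------:|------------|
| G    | 6.3  | log-logistic, median 6.3 |
| GL   | 4.8  | log-logistic, median 4.8 |
| GY   | 3.2  | log-logistic, median 3.2 |
| GLY  | 10.1 | gamma, median 10.1 |
| Y    | 15.3 | 15.3 |
| LY   | 81.4 | 81.4 |
| plot error | log-logistic, median 23 | same |

The B-family draws use single log-logistic (Fisk) and gamma distributions
with shape 5, rescaled so the median equals the A-scenario point value;
the published mixtures are supplementary-only, and a single heavy-tailed
density preserves the property that matters (per-run heterogeneity of
variance components).  The plot-error median of 23 (bu/ac)^2 is not
printed with the other components; it corresponds to a ~10% trial CV at
the 46 bu/ac trait mean, a typical figure for soybean yield trials.

B scenarios draw the per-QTL rows of the GL (GY) effect matrices from a
compound-symmetry covariance with correlation rho ~ Uniform(0.2, 0.8),
inducing correlated line-level GEI across locations (years).  One emergent
consequence worth knowing: the common component of GL/GY is heritable and
co-selected with yield, so part of the realized phenotypic trend in B
scenarios is GEI gain rather than main-effect gain — estimators that do
not separate GEI from G overestimate RGG there, and underestimate
slightly in the A scenarios.

The cumulative non-genetic trend (scenarios A2, B2, B2-M, B2-R) splits the
location-year effect into `LY_jk = u_jk + z_jk * eta_j`, where `z_jk`
counts the previous years location j was used and eta_j is drawn once per
location from {1/2, 1/3, 1/4, 1/5, 1/6}.  B2-M divides the GL/GY/GLY
draws by 10; B2-R replaces every selection step with uniform random
sampling (its true gain is ~0 by construction).

Location main effects are fixed, drawn once per program from N(0, 6^2);
per-trial residual variances are heterogeneous; zero to 12% of plots per
trial are set missing; each trial carries 3-6 replicated check cultivars
drawn from the founders and kept fixed throughout.

## Breeding program

Each year 50-80 biparental crosses among the current parents produce
families of F2 seed; each F2 is advanced by two selfing generations
(2-3 F3 sampled, one F4 representative frozen as the F4:5 line genotype).
Meiosis uses Poisson crossovers (no interference, Haldane map function).
The staged funnel BT1 (1 location, 1 rep) -> BT2 (2, 2) -> BT3 (3, 3) ->
PYT (8, 3) -> URT (12, 3) selects 10% after BT1 and 20% thereafter by
within-year eBLUP ranking; 20-30 parents per year are selected at BT3 on
combined BT1+BT2+BT3 data and enter both the crossing block and the PYT
(so parents are a subset of PYT entries).  Crosses made in year t reach
BT1 in year t+2 and PYT in year t+5 (a five-year cycle); the first five
years cross random founders and are excluded from estimation, as are the
years before the first selected-parent PYT cohort.

Within-year selection ranks lines by inverse-variance-weighted means of
trial-centered plot values — the eBLUP ranking of the within-year model
(genotype random, location fixed, known heterogeneous trial residuals):
with equal replication BLUP shrinkage is common to all lines, so the
weighted mean is the ranking statistic and a full REML fit per stage-year
is unnecessary.  The full REML engine remains available for this model.

## REML engine

The estimation models are fitted by restricted maximum likelihood on the
dense marginal covariance `V = sum_r Z_r K_r Z_r' + R`, maximized by
average-information Newton steps with step-halving (the restricted
likelihood never decreases across accepted iterations) and an L-BFGS
fallback when the AI step cannot improve from the starting point (e.g.
degenerate exact-fit data).  Variances are log-parameterized with a floor
of 1e-4; boundary estimates are reported, not dropped.  Covariance kinds:
identity, diagonal-by-group (one variance per location or year), FA1
(`lambda lambda' + Psi` across an environment index within independent
line blocks), and a known genomic relationship matrix (VanRaden centering,
with a 1e-4 diagonal ridge so clone pairs stay invertible).  Two-stage
entry-mean analyses weight records by their stage-one variances
(`resvar / n_plots`); with one record per genotype-location-year the
three-way interaction is confounded with, and absorbed by, the residual.

Convergence: relative change of the restricted log-likelihood below 1e-12
(1e-9 in production estimator fits) or gradient below tolerance, with at
most 200 (150) iterations.  Estimator fits warm-start from the previous
run's parameters when the experiment driver loops over runs.

## Estimator registry

Table-style registry of 28 models.  Notable resolved choices (the
published model table is an unrendered figure; the footnotes define the
terms):

* One-stage models (EB, E0*, E1*, E2*, E3*, E4*, E5*, E6*) include the
  fixed location-usage covariate `delta * z`, with z reconstructed from
  the records themselves (number of earlier years the location appears).
* "V" variants default to diagonal heterogeneous GL (per location) and GY
  (per year); FA1 is selectable per fit.  "G" variants put the genomic
  relationship matrix on the genotype (or parent) term, built from the
  full marker panel of lines that reached PYT.
* E2/E2V carry the direct fixed slope `beta_g r_i` on experimental lines
  only (checks get a separate population intercept); E3 adds a random
  first-test-year cohort deviation (random regression on the trend
  covariate).
* E6 contrasts checks and lines through a calendar-year covariate on the
  line population.
* E7/E8 first predict environment eBLUPs from checks only, then use them
  as a fixed covariate in a lines-only second stage (indirect/direct).
  E7's genotypic variance absorbs GEI — the variance-inflation property
  the registry tests — and its indirect slope attenuates with BLUP
  shrinkage, which falls as records per line grow.
* E9 fits within-year models and chains year corrections through the mean
  difference of genotypes shared by consecutive years, forward from the
  first year by default (reference year configurable).
* E10-E14 add general (P_i, both parents load one effect) and specific
  (F_ii', unordered pair) combining abilities on BT3+PYT+URT records;
  gains are computed from breeding lines only, on crossing year, with
  parent predictions doubled (2 * P_hat) for scale.  E12/E14 regress
  directly on the line's F1 crossing year.
* "Pheno" is ordinary least squares of raw entry means on first-test year.

Check records never contribute to a gain slope; perturbing all check
phenotypes by a constant leaves the estimates unchanged (the perturbation
lies in the fixed-effect span).

## Evaluation

True RGG is the OLS slope of parents' breeding values on crossing year;
the expected MET trend replaces predictions with true values for the lines
in the records, so expected bias isolates the sampling mismatch between
PYT/URT entries and actual parents.  Bias metrics are the mean error, the
mean of per-run error/truth (x100, runs with |truth| < 1e-3 excluded — the
no-selection scenario is excluded from summaries for this reason), and
RMSE.  Linearity uses an AR(p)-sieve bootstrap of the trend t-statistic
(order by AIC over p <= 4, centered-innovation resampling, 500-1000
replicates, Bonferroni across the models tested) on the yearly-mean series
of the indirect estimates, and the normal z-ratio for direct estimates.
Model contrasts use a two-way (run + model) fixed-effects ANOVA with
studentized-range (Tukey) adjustment.  Units convert at 67.25 kg/ha per
bu/ac.

## Desk-scale study conditions

Full-scale programs (46 years, BT1 cohorts of 5000-18723) are the library
defaults but take hours per run; all tests and the acceptance script use
two scaled-down configurations that shrink *different* dimensions:

* `desk_scale_config` — truth-focused: keeps the paper's 20-30 parents
  per year and the 10%/20% funnel, shrinks BT1 to ~1500 lines, the genome
  to 1000 loci / 500 QTL, the trial network to PYT 3 / URT 4 locations,
  26 years.  Used for the average true gain under selection (~0.44
  bu/ac/yr emerges untuned) and the no-selection scenario.
* `desk_estimation_config` — estimator-focused: keeps per-line trial
  replication near full scale (PYT 6 locations; the acceptance ensembles
  use PYT 5 / URT 4 and a 28-year horizon giving an 18-year estimation
  record) and scales the line numbers down (10-14 parents/yr) instead.
  BLUP shrinkage — hence the attenuation of indirect estimators such as
  E7 — depends on records per line, and the expected-bias magnitude
  depends on the non-parent fraction of PYT, so these are the dimensions
  to hold fixed when benchmarking estimators.

Both configurations size their location pools so the yearly reuse rate of
locations (~0.6 of the pool active per year) matches the full-scale
network: the drift rate of the cumulative non-genetic trend per calendar
year is the mean location increment times that reuse rate, so a saturated
pool would overstate the non-genetic trend (and with it the no-selection
raw-phenotype slope).

Ensemble sizes in `scripts/acceptance.py`: 20 truth-only runs (selection),
30 no-selection runs (36-year programs: the no-selection raw-phenotype
slope is Monte-Carlo noisy, and record length plus replicates control its
standard error), and 10 estimator-benchmark runs for each of the five
selection scenarios — all 50 fit the three headline models for bias and
containment (a containment fraction needs ~50 runs before its binomial
error fits inside a 15-point band), and the first 2 per scenario also fit
the V/G-covariance variants and run the linearity bootstrap.  What passing at
this scale shows: the generator hits its variance targets exactly, the
truth behaves as designed, and the estimators' bias ordering, containment
and linearity behavior reproduce the full-scale findings in direction and
magnitude.  What it does not show: full-scale Monte-Carlo precision (225
runs per scenario), behavior of FA structures of order > 1, or anything
about real (non-simulated) records beyond the structural match of the
entry-mean format.

## Known limitations

* The within-year selection model is the rank-equivalent weighted-mean
  shortcut, not an iterated REML fit per stage-year.
* Two-step estimators propagate stage-one uncertainty only through
  inverse-variance weights; no errors-in-variables correction is applied
  to the environment covariate of E7/E8/E13/E14.
* The sieve-bootstrap test conditions on the AIC-selected AR order; order
  uncertainty is not propagated.
* Founder genomes are simulated in linkage equilibrium (frequencies
  uniform on [0.05, 0.95]); a real genotype matrix can be supplied as
  delimited text where LD structure matters.
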