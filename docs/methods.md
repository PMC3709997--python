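# Methods

This note documents the statistical procedures implemented in `mudswim`,
the assumptions behind them, the defaults of the synthetic survey
generator, and the numerical choices made where the procedures' published
descriptions leave details open.

## The survey design and its random model

The design crosses Site (a mudflats, random) with Round (b lunar sampling
windows, random) and nests Night (c consecutive nights, random) in Round;
each site × round × night cell holds replicate plankton nets.  Responses
are densities transformed with log₁₀(x + 1) before analysis (zero catches
occur; the offset stabilises variance).  The transform is applied by the
pipeline, not inside the ANOVA module, so the module stays reusable for
any response.

`mean_squares` computes the classical unweighted-means analysis: sums of
squares among cells are formed from unweighted cell means and scaled by
the harmonic mean *n* of cell sizes; the error SS pools within-cell
deviations with df = N − (number of cells).  On balanced data this reduces
exactly to the textbook decomposition (verified against a type-I general
linear model fit to 10⁻¹⁰ relative).  Unbalanced replication (lost nets)
is thus handled by the same device the expected-mean-square formulas
assume, rather than switching to REML; the trade-off is that the
decomposition is only approximate under imbalance, which is mild here
(2–3 nets per cell).

Under the fully random model the expected mean squares leave Round
without a single valid error term; the quasi-F
(MS_R + MS_SN(R)) / (MS_N(R) + MS_RS) equates expectations under H₀.
Its p-value uses Satterthwaite-synthesised df on both composites,
ν = (ΣMS)² / Σ(MS²/df); the synthesised df are exposed in the results
object because this is an approximation, and sources differ on how the
original analyses obtained quasi-F p-values.  Plain ratios use the F
distribution with the df of the two mean squares involved.

Variance components follow the expected-mean-square algebra in the table
in the README.  Negative estimates are truncated to zero before
percentages are formed (the classical convention).  Simulation studies of
the estimators themselves should pass `truncate=False`: the untruncated
estimators are unbiased, whereas truncation biases small components
upward, which would contaminate a recovery test.  The package's recovery
test simulates 200 surveys from the random-effects model directly
(9 × 3 × 3 × 3, site component 4, all others 1) and checks each mean
estimate against truth within Monte-Carlo error.

A note on degrees of freedom: a fully balanced 9 × 3 × 3 × 3 survey has
243 observations and error df 162.  Field campaigns of this design lose
occasional nets; with 241 samples the error df is 160, and the harmonic
mean n ≈ 2.96 rather than 3.  The generator's default net-dropout
probability (2/243) reproduces this behaviour.

## Size-distribution bootstrap

The null hypothesis is that swimmers are a random subsample of the mud
residents.  For each site × round with at least 100 measured swimmers and
100 residents (below threshold the analysis is reported as
"not analysed", never silently skipped), resident lengths are resampled
**with replacement** B = 1000 times, m lengths per iteration where m is
the number of swimmers actually measured.  Lengths are binned into 0.5-mm
classes from 1 to 11 mm (bins closed on the left; the top edge belongs to
the last bin; lengths below 1 mm would fall into the first class).  Per
class the B bootstrap proportions are sorted and 25 values removed from
each tail, the remaining extremes being the 95% limits — i.e. the 26th and
975th order statistics.  Observed proportions are computed per net and
averaged unweighted across nets (the mean-of-nets estimator; this differs
from pooling counts when net totals are unequal, and the package
implements the mean-of-nets reading).  Classes outside the band are
flagged over/under.

Whether the original procedure resampled with or without replacement is
not documented; with-replacement is the standard bootstrap reading and is
what is implemented.  Calibration: under the null generator the per-class
flag rate is ≈ 5% for classes with adequate expected counts.  The test
suite restricts the calibration count to classes with expected count ≥ 5
(the usual large-sample rule): percentile bands on nearly-empty classes
are degenerate ([0, 0] or [1, 1]) and cannot attain nominal non-coverage,
so including them would measure discreteness, not calibration.

## Adult stage G-test

Five adult stages: small (4–6 mm) and large (> 6 mm) males, small and
large non-ovigerous females, and ovigerous females (intersex individuals
are functional males and are pooled with males throughout).  Applicability
requires strictly more than 100 resident adults and 100 swimmers.
Expected counts (residents) are scaled to the observed total and
G = 2 Σ O ln(O/E) is referred to χ² with df = (categories − 1).  Zero
observed cells contribute 0 (the O ln O limit).  A stage with zero
expected count is pooled into its designated partner — large males into
small males, large non-ovigerous females into ovigerous females —
reducing df below 4; the within-group reverse poolings are also defined
for degenerate tables the published rules never faced.  A stage empty on
both margins is dropped.  Swimmer counts are subsample-expanded and
rounded to whole animals before testing (the treatment of expanded counts
is not documented in the source material; this choice is recorded here).

## Model II regression and the shape of density dependence

Swimmer density (site × round mean over 7–9 nets) is regressed on
resident density or biomass (mean over 12 cores) on log₁₀ scale.  Because
the predictor is itself an estimate, the reduced major axis slope
b = sign(r)·SD_y/SD_x is used; SE(b) = |b|·√((1−r²)/(n−2)).  Cells with a
zero swimmer mean are excluded (log undefined) and the exclusion logged.

Two tests are applied in sequence:

* H₀: β = 0 — Student's t = r√(n−2)/√(1−r²), df = n−2 (equivalent to the
  correlation test).  If this does not reject, no further test is run and
  the relationship shape is "none".
* H₀: β = 1 — Clark's T on the log slope ratio,
  T = |log₁₀(b/1)|·√((n−3)/(1−r²)), referred to a t distribution with
  ν = (n−3)/(1 + r⁴/2) degrees of freedom (non-integer in general), after
  Clarke (1980) as presented by McArdle (1988).  Base-10 logarithms are
  used consistently with the log₁₀-transformed analysis scale.  The test
  operates on the slope magnitude; the labels below presume the intended
  use on positive associations.

Shape labels at α = 0.05: slope ≠ 0 and slope < 1 → *ascending-
decelerating* (a decreasing proportion swims as density rises); slope ≠ 0
and not distinguishable from 1 → *proportional*; slope ≠ 0 and > 1 →
*ascending-accelerating*; otherwise *none*.  No multiplicity correction
is applied anywhere in the package: each regression and each correlation
addresses a distinct hypothesis.

## Standardized swimming activity and patchiness

Standardized swimming activity of a stage is its swimmer density (m⁻³)
divided by the same stage's resident density (m⁻²), per site × round
cell; cells with a zero denominator are undefined and excluded.  The
default correlation battery pairs juvenile size-class activity with
resident adult density, male-stage activity with female-stage densities,
and female-stage activity with male-stage densities — Pearson r on
untransformed values, df = n − 2, two-sided p.  The battery is data
(configuration), not code, so users can extend the pair list.  Patchiness
is the variance-to-mean ratio with the unbiased (n − 1) sample variance
(the denominator convention is not documented in the source material).

A practical caveat established while validating the battery: when cell
densities span several orders of magnitude, Pearson correlations on
untransformed near-power-law quantities are strongly diluted (the
correlation of two lognormals shrinks toward zero as their log-scale
spread grows).  The propensity recovery test therefore runs the generator
with moderated among-cell variance (total log₁₀ variance 0.15) so that
the built-in negative coupling is detectable on the raw scale; at the
full default variance the same coupling is present but the untransformed
correlation has little power.

## The synthetic survey generator

`SurveyConfig` defaults encode the survey conditions the analyses assume:

* design 9 sites × 3 rounds × 3 nights × 3 nets (net dropout 2/243,
  giving the realistic 7–9 nets per site × round) and 12 cores of a 7-cm
  corer per site × round;
* a latent log₁₀ resident density per net position: grand mean 3.7
  (≈ 5 000 ind·m⁻², mid-range for dense mudflat populations and enough
  that 12 cores usually clear the 100-resident thresholds) plus
  independent normal effects whose variances are the fractions
  9.7 / 56.3 / 13.8 / 3.8 / 9.7 / 6.7 % (Round / Site / Round × Site /
  Night(Round) / Site × Night(Round) / Error) of a total of 0.703 — the
  site-dominated hierarchy characteristic of these surveys;
* resident composition: 30 / 20 / 15 % small / medium / large juveniles;
  adults split 2:1 female:male, 30% of females ovigerous, 70% of each sex
  small; per-cell logistic-normal jitter (σ = 0.15 log₁₀) perturbs the
  mix so stage structure varies among cells;
* swimmers: expected density of stage s is
  A_s · 10^(β_s·(z − μ)) · 10^(coupling), with per-stage log-log slopes
  β (0.30 / 0.22 / 0.18 for juvenile classes, 0.15 / 0.06 for small/large
  adults, 0.03 for ovigerous females — sub-linear throughout), propensity
  multipliers that overrepresent small juveniles (×2.5) and small adults
  (×1.2–1.5) and underrepresent large adults and ovigerous females
  (×0.4–0.5), and a base total of 30 ind·m⁻³ at the mean resident
  density.  The coupling term ties a stage's swimming to the
  *compositional anomaly* of a covariate group (large-juvenile swimming
  suppressed by resident adult share, small-female swimming by small-male
  share, both −0.6): acting on composition rather than absolute density
  leaves the density-dependence slopes and the variance hierarchy intact;
* counts: negative binomial with dispersion k = 5 (variance
  mean + mean²/k — field counts are aggregated); filtered volumes
  lognormal around ≈ 40 m³; catches over 200 are Folsom-split to the
  power-of-two fraction (down to 1/512) leaving ≤ 200 individuals, and
  processed counts are binomial thinnings of the raw counts, which makes
  subsample expansion unbiased by construction;
* body lengths: truncated normals within stage bounds (e.g. ovigerous
  females 4.7–10.8 mm); intersex 2% among swimming males, 0 among
  residents (only the swimming rate is documented; the mud rate is a
  separate knob);
* everything is bit-for-bit reproducible under (config, seed).

What the generator does **not** emulate: tidal hydrodynamics, movement
trajectories, spatial autocorrelation along transects, seasonal cohort
progression, or any dependence of resident length distributions beyond
the class proportions (the true length distributions are unknown; tests
therefore avoid relying on distributional shape within classes).  Passing
recovery tests demonstrate that the estimators are correctly implemented
and calibrated for data of this structure — not that real surveys satisfy
the structure.

`simulate_counts` produces the vectorised count tables (fast; used by the
200-replicate recovery harnesses), and `generate_survey` materialises
individual animals on top of it.  Recovery tests use 200 replicates and
the bootstrap calibration 500 null surveys with ≈ 400 residents and 300
swimmers each — sizes at which Monte-Carlo error is small relative to the
tolerances tested.

## Known limitations

* The unweighted-means ANOVA is exact only for balanced data; severe
  imbalance would warrant REML, which is out of scope.
* Quasi-F p-values rest on the Satterthwaite approximation; with b = 3
  rounds the synthesised df are small and the p-value rough.
* Clark's T formulation follows the reconstruction documented above;
  other software may use a different variance or df convention for RMA
  slope tests.
* The generator's sub-linear slopes make activity of *every* stage decline
  with resident density; the explicit couplings add stage-specific
  structure on top, so battery results on synthetic data should be read
  against both mechanisms.
* `SYNTHETIC_ALLOMETRY` (0.02 · L³) is a placeholder for demonstrations;
  biomass analyses of real data require a literature length-weight
  relationship supplied via configuration.
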