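# mudswim

Inference tools for **stage-biased dispersal in intertidal amphipods**,
built around paired surveys of the mudflat amphipod *Corophium volutator*:
stationary plankton nets catch the **swimmers** (a proxy for dispersing
individuals, ind·m⁻³ of filtered water) while sediment cores sample the
**mud residents** (ind·m⁻²).  Given the two sample streams the package
answers the three questions such surveys are designed for:

1. **Where does the variation live?**  A fully random ANOVA of
   log₁₀(density + 1) with Site (a mudflats) crossed with Round (b
   sampling rounds) and Night (c per round) nested in Round.  Under the
   random model no single mean square tests Round, so a quasi-F is used:

   ```
   Source            F or quasi-F                       Variance component
   Round (R)         (MS_R + MS_SN(R))/(MS_N(R)+MS_RS)  (MS_R+MS_SN(R)−MS_RS−MS_N(R))/acn
   Site (S)          MS_S / MS_RS                       (MS_S − MS_RS)/bcn
   R × S             MS_RS / MS_SN(R)                   (MS_RS − MS_SN(R))/cn
   Night(R)          MS_N(R) / MS_SN(R)                 (MS_N(R) − MS_SN(R))/an
   S × N(R)          MS_SN(R) / MS_e                    (MS_SN(R) − MS_e)/n
   Error             —                                  MS_e
   ```

   with *n* the harmonic mean of replicate nets per cell.  Components are
   converted to percent of total variation.

2. **Which stages disperse?**  The swimmer size distribution (0.5-mm
   classes, 1–11 mm) is compared to the resident distribution by
   bootstrap: resident lengths are resampled (B = 1000, with replacement,
   to the number of swimmers actually measured), 25 values are trimmed
   from each tail per class to give 95% limits, and observed
   mean-over-nets proportions outside the band are flagged over/under.
   Adult stage structure (small/large males, small/large non-ovigerous
   females, ovigerous females) is compared by likelihood-ratio G-test with
   category pooling when a stage is absent from the residents.

3. **What drives dispersal?**  Reduced major axis (Model II) regression of
   log₁₀ swimmer density on log₁₀ resident density or biomass
   (slope = sign(r)·SD_y/SD_x), with a Student's t test of slope = 0 and —
   when that rejects — Clark's T test of slope = 1 with non-integer
   degrees of freedom; a slope significantly below 1 labels the
   relationship *ascending-decelerating* (proportionally less swimming at
   higher resident density).  Standardized swimming activity
   (swimmer density ÷ same-stage resident density) is correlated (Pearson,
   untransformed) against resident covariate stages, and patchiness
   (variance/mean) summarises aggregation.

Because raw field data of this kind are rarely deposited, the package
ships a **synthetic survey generator** (`mudswim.simulate`) that emulates
the design — 9 sites × 3 rounds × 3 nights × 2–3 nets plus 12 cores per
site × round — with a site-dominated variance hierarchy, female-biased sex
ratio, stage-specific swimming overrepresentation and sub-linear log-log
density dependence, so every analysis can be validated against known
truth.

## Worked example

```python
from mudswim import SurveyConfig, RandomEffectsAnova, generate_survey, rma_fit
from mudswim.summaries import anova_input, cell_stage_table
from mudswim.transforms import log10_strict

nets, cores, truth = generate_survey(SurveyConfig(), seed=7)
res = RandomEffectsAnova(anova_input(nets, "total"), "y").fit()
print(res.summary())
```

```
Random-model ANOVA — response: y
Design: a=9 sites, b=3 rounds, c=3 nights/round, harmonic n=2.982
Round quasi-F df (Satterthwaite): 3.92, 12.98

             source  df         MS          F          p  variance_component  pct_variation
              Round   2     0.0515     0.5981     0.6674              0.0000         0.0000
               Site   8     0.3376     7.8382     0.0003              0.0110        34.9365
       Round x Site  16     0.0431     2.0694     0.0268              0.0025         7.9206
       Night(Round)   6     0.0779     3.7408     0.0039              0.0021         6.7666
Night(Round) x Site  48     0.0208     1.5637     0.0210              0.0025         8.0098
              Error 161     0.0133        NaN        NaN              0.0133        42.3665
```

Site is the dominant non-error source of variation in swimmer density —
mudflats differ far more than nights or rounds within a mudflat (the error
row absorbs net-to-net count noise).  Density dependence of swimming on
the same survey:

```python
cells = cell_stage_table(nets, cores)
sub = cells[["mud_total", "swim_total"]].dropna()
sub = sub[(sub > 0).all(axis=1)]
fit = rma_fit(log10_strict(sub["mud_total"].to_numpy()),
              log10_strict(sub["swim_total"].to_numpy()))
print(fit.summary())
```

```
RMA regression (n=27)
  slope = 0.2288 +/- 0.0167, intercept = 0.6350, r = 0.9310
  H0 slope=0: t(25) = 12.751, p = 1.935e-12
  H0 slope=1: T(17.4) = 8.595, p = 1.11e-07
  shape: ascending-decelerating
```

Swimmer density rises with resident density (slope ≠ 0) but with a log-log
slope well below 1: a decreasing *proportion* of the population swims as
resident density increases, exactly the sub-linear density dependence the
generator was configured with (its per-stage slopes average ≈ 0.23 for
total density).

## Command line

```bash
mudswim simulate --seed 1 --out survey/          # write a synthetic survey
mudswim anova --data survey/ --response total
mudswim compare-distributions --data survey/ --seed 1
mudswim density-dependence --data survey/
mudswim propensity --data survey/
mudswim run-all --data survey/ --seed 1 --out reports/
```

All inputs and reports are delimited text; `run-all` also writes a
manifest (config hash, seed, input digests, per-analysis statuses) so a
run can be reproduced exactly.

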