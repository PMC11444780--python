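# splitcost

**What does categorizing a continuous predictor cost you?**

Ecologists, ethologists and evolutionary biologists routinely measure
predictors continuously — body mass in kilograms, breeding date as day of
year, elevation in metres — and then analyse them as categories (early vs
late, high vs low, 5-day bins). `splitcost` is a simulation laboratory for
quantifying what that practice costs in model fit, precision and
interpretation, built around a worked single-predictor example: the day of
year a penguin initiates breeding and its body mass (kg) at the start of the
next season.

The laboratory provides:

- **A calibrated generator** (`simgen`): breeding dates from a shifted Gamma
  distribution (10th/50th/90th percentiles near days 55/60/65, a right tail
  of late breeders), and mass from a Gamma response around the log-linear
  mean `E[mass | day] = exp(β₀ + β₁·day)` with `exp(β₁) = 0.985` — a 1.5%
  mass cost per day of delay, so a 10-day delay (day 55 → 65) moves expected
  mass from 43 kg to ~37 kg (−14%). A smooth unimodal alternative generates
  nonlinear data.
- **Every common breakpoint scheme** (`breakpoints`): median split, uneven
  thirds (<25%, 25–75%, >75%), quartiles, fixed-width intervals ("60–65"),
  "natural break" splits for bimodal data, and custom edges.
- **Gamma GLMs with log link** (`gammaglm`): IRLS to convergence, profile-ML
  shape, full-likelihood AIC (`−2ℓ + 2(p+1)`, shape counted).
- **The inference layer** (`marginal`): back-transformed marginal means with
  `exp(η ± 1.96·se)` intervals, Wald pairwise contrasts with Bonferroni
  adjustment, minimal compact letter displays, McFadden's pseudo-R².
- **A penalized-spline smooth** (`smooth`): cubic P-splines in the Gamma
  likelihood with a second-difference penalty, optional cyclic (day-of-year)
  basis, GCV smoothness selection, edf-based AIC.
- **Experiments** (`experiment`): continuous-vs-categorized comparisons,
  range-preserving sample-size studies, seeded replicate Monte Carlo, and
  the median-split efficiency experiment whose analytic answer is
  `1 − 2/π ≈ 0.363` — dichotomizing at the median throws away about a third
  of your data.
- **A literature tally** (`review`): counts of publications whose final
  model categorized a predictor that could have stayed continuous
  (packaged synthetic fixture: 22 of 72, i.e. 31%).

## Worked example

```bash
splitcost simulate --seed 0 --out demo
splitcost compare --data demo/dataset.csv --out demo
```

prints the model-comparison table for one n = 120 dataset:

```
     model        aic  pseudo_r2  exp_slope   n  delta_aic  replicate
continuous 658.844723   0.049021   0.986517 120   0.451892          0
    median 672.129531   0.029669        NaN 120  13.736699          0
    uneven 658.392832   0.052593        NaN 120   0.000000          0
  interval 659.827388   0.056330        NaN 120   1.434557          0
```

The continuous model estimates `exp(slope) = 0.987` — each day of delay
costs ~1.3% of next year's mass in this realization (truth: 0.985). The
median split pays a ~14-point AIC penalty for discarding within-group
variation. On any single realization a many-parameter categorical model can
edge out the continuous one (here `uneven` wins by 0.45 AIC); across 200
replicates the continuous model has the lowest AIC in ~91% and its
first-category CI is always the narrowest (median < uneven < interval
spans, mirroring the growing information loss per extra category).
`demo/marginals.csv` holds the per-category means, 95% CIs and grouping
letters; `provenance.json` records config, seed and version.

```bash
splitcost efficiency --seed 0 --out demo     # -> fraction of data effectively lost: 0.371
splitcost review --out demo                  # -> 22 of 72 records categorized (31%)
splitcost power --seed 0 --sizes 120,80,20 --out demo   # sample-size study
```

The same operations are available as library calls
(`splitcost.generate_dataset`, `splitcost.run_comparison`,
`splitcost.replicate_study`, ...); see `docs/methods.md` for the model and
its assumptions.

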