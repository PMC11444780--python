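# Methods

## The data-generating model

The laboratory simulates a single-predictor life-history study: for each of
`n` individuals, a breeding initiation date `t` (day of year) and next-year
body mass `y` (kg).

**Timing.** `t = shift + Gamma(shape, scale)` with defaults
`shape = 6`, `scale = 1.633`, `shift = 50.30`. These were calibrated once, by
minimax fit, so that the distribution's 10th/25th/50th/75th/90th percentiles
sit at 55.4/57.2/59.6/62.4/65.4 days — the canonical "most birds start around
day 55–65" pattern with a right-skewed tail of late breeders (99.9th
percentile ≈ 77; the expected maximum of an n = 120 sample ≈ 74). A gamma
family was chosen over a normal because breeding-date distributions are
bounded below by the earliest feasible date and trail off to the right.

**Mass.** Given `t`, the response is mean-parameterized Gamma:
`y ~ Gamma(k, μ(t)/k)` so `E[y|t] = μ(t)` and `CV = 1/√k` independent of `t`.
The linear log-mean is `μ(t) = exp(β₀ + t·ln m)` with defaults

- `m = 0.985` (daily multiplier): a 1.5% multiplicative mass cost per day of
  delay, hence 14% over the 10-day gap between the 10th and 90th timing
  percentiles;
- `β₀ = ln 43 − 55·ln 0.985 ≈ 4.5925`, fixed by anchoring a day-55 breeder
  at 43 kg (so day 65 ≈ 37 kg). This anchor and the multiplier jointly
  determine the intercept; it is not a free parameter.
- `k = 120` (mass shape): CV ≈ 9%, i.e. a few kg of biological scatter
  around the mean for a ~40 kg animal. This value reproduces the reference
  precision of the continuous fit at n = 120 — a 95% CI span of ≈ 1.3 kg for
  the predicted mass at the mean breeding date — and yields unbiased slope
  recovery (mean fitted multiplier 0.985 across replicates).

The nonlinear generator replaces the log-mean with an arbitrary smooth
function of day; the packaged default is the quadratic
`ln μ(t) = ln 43 − 0.0015·(t − 62)²`, a unimodal curve peaking inside the
observed day range with ~14% mass loss 10 days either side of the peak.

**Determinism.** All randomness flows through NumPy's PCG64 generator; a
config (including its seed) maps to a bit-identical dataset on any platform.
Replicate studies spawn independent substreams via
`SeedSequence(master_seed).spawn(reps)`.

## Breakpoint schemes

Quantile-based schemes (median; uneven <25%/25–75%/>75%; quartiles) use
linear interpolation of order statistics (the "type 7" convention) — stated
because quantile dialects differ. Interval bins are aligned to multiples of
the bin width (floor alignment), so labels read "55–60", "60–65" rather than
starting at the observed minimum. The bimodal rule cuts at the midpoint of
the widest internal gap, refusing when no gap reaches `bimodal_min_gap`.
Categories are half-open `[low, high)` with the last interval closed; a value
exactly on an interior edge goes to the *higher* category (so day 60 is
"late" under a median split at 60). Outer bins are open-ended when assigning
new values.

## Gamma GLM and AIC

Fitting is IRLS; for the log link the Gamma working weights are identically
one, so each step is an OLS solve of `z = η + (y−μ)/μ` on the design.
Convergence: relative deviance change `< 1e−10`, cap 100 iterations
(non-convergence raises, with the deviance trace). The shape is then the
profile MLE given fitted means, solving
`ln k + 1 − ψ(k) = mean(y/μ − ln(y/μ))` by bracketed root finding (tolerance
1e−8); an exactly-fitted response makes the optimum diverge, in which case
the search is capped at 1e8 with a warning. The coefficient covariance is
the inverse expected information scaled by dispersion, `(X'X)⁻¹/k̂`.

`AIC = −2ℓ + 2(p+1)` uses the full Gamma likelihood with the shape counted
as a parameter. Software differs in its Gamma-AIC dispersion conventions
(deviance-based vs profile-ML shape, whether dispersion is counted), so
*differences* in AIC between models fit to the same data are the meaningful
output; absolute levels are not comparable across toolchains. For smooth
fits the coefficient count is replaced by the effective degrees of freedom.

Categorical designs use treatment coding by default (sum coding available);
marginal means are coding-invariant, which the tests assert.

## Marginal means, letters, pseudo-R²

Predicted means use the delta method on the linear predictor and
back-transform: `exp(η ± 1.96·se)` (normal rather than t multiplier, to
match the conventional 1.96). Pairwise contrasts are Wald z tests;
multiplicity adjustment is Bonferroni — exactly implementable, slightly more
conservative than Tukey's studentized range, affecting only borderline
letters.

The compact letter display is computed as an exact minimum edge-clique cover
of the non-significance graph: each letter is a set of pairwise
non-different levels (a clique), every non-different pair must share a
letter, and no different pair may. Enumerating maximal cliques and searching
the smallest covering subset is exact and fast at the handful of levels a
breakpoint scheme produces, and guarantees the minimal letter count
(heuristic insert-and-absorb can overshoot). Note that a triangle-free
non-significance pattern can require *more* letters than levels.

McFadden's pseudo-R² is `1 − ℓ(model)/ℓ(null)` with the intercept-only null
fit to the same data; each model profiles its own shape (affects the third
decimal only). Two caveats, documented deliberately: (i) for a continuous
response the log-likelihood depends on the absolute density scale, so the
statistic's magnitude is driven by the response CV and is *not* comparable
to variance-explained intuition — under the default calibration (CV ≈ 9%)
the continuous fit's median pseudo-R² is ≈ 0.06, even though the same fits
show large AIC advantages; (ii) McFadden carries no complexity penalty, so
a many-bin categorical model can out-score the continuous truth by
overfitting. Both behaviours are visible in the replicate experiments and
are part of the pedagogical point: prefer likelihood-based comparisons that
penalize parameters (ΔAIC) over R²-style summaries.

## Penalized spline smooth

The nonlinear fit is an Eilers–Marx P-spline inside the Gamma likelihood:
cubic B-splines on a uniform knot grid (`n_knots` interior knots, default 6 —
a deliberately small basis for field-study sample sizes), second-difference
coefficient penalty, penalized IRLS `(B'B + λD'D)β = B'z`. Because the knots
are uniform, the penalty null space is exactly the linear functions of the
predictor, so `λ → ∞` recovers the straight-line Gamma GLM (constants only,
for the cyclic wrap). `λ` is chosen by GCV, `n·deviance/(n − edf)²`, over 30
log-spaced values in `[1e−3, 1e7]`; `edf = tr[(B'B + λD'D)⁻¹B'B]`. The
cyclic basis wraps coefficients modulo the period (365 d), giving identical
basis rows and continuous derivatives at the year boundary. CI bands use the
Bayesian covariance `(B'B + λD'D)⁻¹/k̂`.

## Efficiency experiment

The median-split cost is estimated in the claim's native setting: Gaussian
simple regression with a small standardized slope (default 0.1), n = 1000,
5000 replicates. Per replicate the squared slope t statistic is computed
with the predictor continuous and median-dichotomized;
`fraction_lost = 1 − mean(t²_dich − 1)/mean(t²_cont − 1)`, the ratio of
noncentrality estimates, which equals the effective-sample-size ratio in the
small-effect limit. The analytic value is `1 − 2/π ≈ 0.363` (the squared
correlation between a standard normal and its median split is 2/π). The
noncentrality-ratio estimator was chosen over power-at-fixed-α because it is
variance-stable at desk-scale replicate counts; rejection rates at α = 0.05
are reported alongside. A Gamma-GLM variant of the same design is exposed
for curiosity; no reference value is attached to it. Fewer than 100
replicates triggers an instability warning.

## What the synthetic data do and do not emulate

The generator reproduces the marginal timing distribution, the
multiplicative mass cost, and constant-CV Gamma noise. It does not emulate
measurement error in timing, year effects, individual repeatability,
missingness, or correlated covariates — so passing tests demonstrate the
statistical cost of categorization under clean conditions, not robustness of
any pipeline to real field data. The packaged review fixture is synthetic:
it reproduces published *marginal* totals (22 of 72 publications
categorizing, more in behaviour journals) but its per-journal and
per-rationale splits are invented.

## Problem sizes and numerical choices

Replicate experiments default to 200 replicates at n = 120 — enough for the
Monte-Carlo error on the mean fitted multiplier (~0.0002) to sit well inside
the ±0.002 acceptance band, and for rate estimates (AIC win fraction) to be
stable to ±2 percentage points. The efficiency experiment uses 5000
replicates of n = 1000 (Monte-Carlo SE ≈ 0.005 on the fraction lost).
Degenerate inputs are refused loudly rather than patched: tied quantile
edges, rank-deficient designs (the aliased column is named), non-positive
masses, NaN predictors, bimodal schemes without a qualifying gap.

## Known limitations

- AIC levels (not differences) follow this package's profile-ML convention
  and will not match toolchains using deviance-based dispersion.
- Bonferroni letters can differ from Tukey-based letters for borderline
  pairs.
- The smooth module is a fixed-knot P-spline with GCV, not a REML-based
  thin-plate GAM; smoothness selection at very small n is noisier under GCV.
- The continuous-lowest-AIC property sits near its threshold by nature: at
  n = 120 the three-group "uneven" model captures most of the linear signal,
  so the continuous model's AIC win rate is ≈ 0.90, not ≈ 1.
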