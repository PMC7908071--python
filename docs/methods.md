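# Methods

## What the package models

The unit of processing is a *station panel*: one monitoring station's
daily table of five pollutants (PM10, CO, NO2, O3, SO2, reported in
mg/m3) and four meteorological covariates (air temperature degC, relative
humidity %, wind speed m/s, wind direction degrees, treated as a plain
numeric variable). The study design is a five-station network observed
for 2192 days. All imputation work happens on the *working scale*:
pollutants natural-log transformed (their raw distributions are strongly
right-skewed), meteorology untouched, and any pollutant whose pooled
missing fraction strictly exceeds 50% (PM10 in the emulated network)
excluded from imputation entirely, as neither target nor predictor.

## The synthetic-data generator

Real data from the emulated network are not distributable, so the
generator reproduces their published statistical structure:

* **Marginals.** Pollutants are moment-matched log-normals: for a target
  original-scale mean m and SD s, sigma^2 = log(1 + s^2/m^2) and
  mu = log m − sigma^2/2. Defaults are the published network-wide values
  (PM10 0.23±1.07, CO 0.91±0.90, NO2 0.04±0.02, O3 0.02±0.01,
  SO2 0.01±0.01 mg/m3). Meteorology defaults are field-realistic for
  Kuwait: temperature 27±8 degC plus an additive annual sinusoid of
  amplitude 6 degC; humidity 35±18% clipped to [0,100]; wind speed
  log-normal 3.5±1.8 m/s; wind direction uniform on [0,360) via the
  probability-integral transform.
* **Dependence.** A Gaussian copula: correlated standard normals pushed
  through the marginal transforms. The target correlation matrix is the
  published pairwise table (strongest entries NO2–SO2 +0.40, NO2–O3
  −0.35, temperature–humidity −0.61), applied on the Gaussian (log)
  scale because that is the scale the pipeline analyses; entries reported
  as non-significant are zeroed. Slightly indefinite matrices are
  repaired by eigenvalue clipping (tolerance 1e−4, then renormalized to
  unit diagonal). The temperature noise SD (8) deliberately dominates the
  annual cycle (variance 6^2/2 = 18) so the cycle dilutes observed
  cross-correlations by only ~12%.
* **Time structure.** Days are i.i.d. by default; an optional AR(1)
  coefficient on the copula innovations adds within-series memory without
  changing the marginals. No spatial correlation between stations and no
  dust-event extremes are modelled.

What passing tests on these panels shows — and does not. The generator
is *exactly* multivariate normal on the working scale (up to humidity
clipping, the temperature cycle and the wrapped wind direction). Real
pollutant series have nonlinear dependencies, heavier tails, and long
block-shaped gaps; method rankings measured here transfer to the linear-
Gaussian regime they encode, not automatically to every network. One
consequence is quantified below (MNAR/MAE).

## Amputation

Missingness is imposed per target variable with *exact* counts,
`round(rate * n)` cells, so realized rates are identical across
mechanisms, methods and replicates (Bernoulli cell-wise draws would add
between-replicate noise). Mechanisms:

* **MCAR** — uniform sampling without replacement.
* **MAR** — deletion probability proportional to a logistic function of
  the standardized rank of a fully observed conditioning covariate
  (default temperature, slope 1.5); rank-based so the mechanism is
  invariant to the covariate's scale, and by construction depends on
  observed data only.
* **MNAR** — the `round(rate*n)` largest values of the target itself
  (side "high"; "low" and "both" are symmetric options), ties broken by
  row order. High extremes are the default because pollution peaks are
  the plausible loss mode.

The removed truths are kept in a vault; un-masking reproduces the
original panel bit-exactly, and all scoring reads vault cells only.

## The iterative forest imputer

Mean initial fill; variables visited in ascending missing count (the
conventional order; descending is a parameter); per variable a
100-tree regression forest with sqrt(p−1) features per split, fit on the
currently completed predictors; stopping when the continuous matrix
difference delta_N first increases, returning the *previous* iterate
(the last matrix before the increase — the criterion's intent, since the
increase signals the iteration has begun to drift); hard cap 10 sweeps.
With no categorical variables in this pipeline the categorical
difference delta_F plays no role in stopping, and one warm-up sweep
always runs before the rule can fire. Observed cells are never modified;
with a fixed seed the procedure is fully deterministic (forest seeds are
derived per sweep and column). A constant column is completed with its
constant and skipped by the forests, with a warning.

The per-variable OOB error is reported on the NRMSE scale with
population (1/n) variance, using each forest's out-of-bag predictions
for the observed part as stand-ins for imputations. On the bivariate
recovery benchmark (y = x + N(0, 0.1^2), n = 500, 10% MCAR) the median
absolute gap between OOB NRMSE and vault-truth NRMSE over 50 seeds is
well under 0.15.

## Baseline imputers

Each baseline is a simplified but faithful form of the published
algorithm it stands for; numeric parity with the R packages that
popularized them is a non-goal.

* **kNN** — distances are Euclidean over mutually observed z-scored
  coordinates, rescaled by sqrt(p/#shared) to compare rows with
  different overlap; the missing cell takes the mean of its k = 5
  nearest donors observed in that variable. Gower distance is
  unnecessary here (all variables continuous).
* **PMM** (type 1) — per variable, ordinary least squares on the other
  (mean-filled) columns; coefficients for the missing rows are a
  Bayesian draw (sigma^2 from the scaled inverse chi-square, beta from
  its normal posterior); each missing cell takes the observed value of a
  donor sampled among the 5 closest predicted means.
* **EM with bootstrapping** — multivariate-normal EM (pattern-wise
  E-step with conditional-covariance corrections; monotone
  log-likelihood; relative tolerance 1e−6, max 200 iterations) fit to a
  bootstrap resample of the rows; each missing block is then *drawn*
  from its conditional normal given the observed block. Drawing rather
  than plugging in the conditional mean follows the algorithm this
  baseline represents (a proper multiple-imputation engine propagates
  residual uncertainty); a `draw=False` switch exposes the pure
  conditional mean, which the test suite checks against the closed-form
  bivariate formula.
* **BPCA-style** — iterative truncated-SVD reconstruction on
  standardized columns (EM-PCA): re-estimate column location/scale from
  the current completion, reconstruct at rank k (default p−1), replace
  missing cells, repeat to a 1e−8 fixed-point tolerance. Non-convergence
  returns the last iterate with a warning; with k near p the scheme is
  weakly constrained and behaves erratically, which is visible in the
  benchmark.
* **Chained RF** — like the iterative forest but each missing cell takes
  the prediction of *one* tree sampled at random (a chained-equations
  style stochastic draw) from a 10-tree forest, for a fixed 10 cycles.
* **Mean** — the no-skill null; by the population-variance convention
  its NRMSE is exactly 1.0 when the masked-cell mean is imputed, which
  anchors the scale.

## Multiple imputation and pooling

m = 20 completions per station (10 inner iterations for the iterative
methods), distinct sub-seeds for stochastic imputers; deterministic
imputers (mean, kNN, BPCA) must run in bootstrap mode — retrain on a row
resample, impute the original matrix — so completions differ, and
requesting them without it is an error. Pooling follows Rubin's rules:
pooled estimate = mean of the m estimates, total variance
T = W + (1 + 1/m)B with W the mean within-imputation variance and B the
between-imputation sample variance. The variance decomposition is
reported for transparency; the benchmark scores single completions.

## Evaluation

RMSE, MAE, Pearson R and NRMSE are computed on vault cells only, on the
working (log) scale, per amputed variable and then macro-averaged so no
variable's scale dominates. NRMSE uses population variance to keep the
mean-imputation identity exact. The benchmark grid is fully factorial
(method x mechanism x rate), replicates rotate through the station
panels, and the amputation sub-seed depends only on (mechanism, rate,
replicate) so all methods score identical amputations. A failed imputer
marks its cell failed and the grid continues.

Default problem sizes: the canonical benchmark runs five 500-day
stations with 10 replicates per cell (the full factorial takes roughly a
quarter hour on one CPU); unit tests use 80–1000-day panels.

## Known limitation: MNAR mean-absolute-error

On this generator the working-scale data are genuinely Gaussian, so
under MNAR tail-truncation the linear conditional-normal methods (EM,
PMM) extrapolate beyond the observed range, while regression forests
predict within the convex hull of observed responses. The result, at
every MNAR rate: the iterative forest has the lowest RMSE, but EM or PMM
achieve 1–5% lower MAE (their residual draws are penalized more by the
quadratic loss than by the absolute one). On real monitoring data —
nonlinear, non-Gaussian — forests also win MAE; on an exactly Gaussian
emulation they cannot, and the corresponding benchmark test documents
this honestly rather than hiding it.

## Kuwait AQI

Piecewise-linear sub-index per pollutant over the national breakpoint
grid (gases in ppm, PM10 in ug/m3):

    I_p = (I_high − I_low)/(C_high − C_low) * (C_p − C_low) + I_low

Printed grids carry reporting-resolution gaps between adjacent segments
(e.g. NO2 0.03 → 0.04); concentrations inside a gap are interpolated
linearly between the adjacent knots, keeping the scale continuous and
monotone with every printed knot exact (the alternative — extending a
segment to the midpoint — was rejected because it produces non-monotone
indices). Both raw and integer-rounded indices are returned (the
rounding convention is not fixed by the source grid). The grid lists CO
under a 24-h averaging header although the pipeline's concentration time
for CO is 8 h; the breakpoint table stores both windows as metadata and
defaults to the printed header. Concentrations above the Hazardous
ceiling raise an error ("beyond Hazardous scale"); the daily overall AQI
is the maximum sub-index over the pollutants available that day, with
missing pollutants skipped, never zero-filled.

## Numerical conventions and degenerate inputs

* Quantiles: linear interpolation; SD: n−1 denominator in descriptive
  tables, population variance inside NRMSE.
* log(0): offset by half the smallest positive observed value of the
  column (scale-aware, order-preserving); negative pollutant values are
  an error naming the cell.
* 75% completeness rule for temporal aggregation is inclusive; 8-h
  concentration times use the daily maximum of rolling 8-h means.
* The >50% exclusion threshold is strict.
* Chi-square homogeneity tests use no continuity correction; identical
  station columns short-circuit to p = 1.
* One master seed spawns every sub-seed (station, amputation, imputer)
  through a counter/CRC scheme, so any single grid cell is recomputable
  in isolation; all derived seeds stay below 2^31.
* Descriptive tables report both the full-frame missing denominator and
  the observed count, since network reports are ambiguous about which
  they use.
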