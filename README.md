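# airimpute

Benchmarking missing-data imputation for multi-station air-quality panels,
with an iterative random-forest imputer at its core and the Kuwait Air
Quality Index as the reporting layer.

Environmental monitoring networks lose observations to maintenance,
sensor faults and tagging errors, and most downstream analyses (receptor
modeling, health-effect regressions, AQI reporting) need complete
matrices. This package is for researchers who want to *choose* an
imputation method defensibly: it simulates daily multi-station panels
with realistic statistical structure, deletes values under controlled
missingness mechanisms while keeping the removed truth, repairs the gaps
with six imputers, and scores every combination.

## The core algorithm

Let `X` be an `n x p` matrix with missing entries. The iterative forest
imputer (missForest-style) proceeds:

1. initial guess: fill each missing cell with its column mean;
2. visit variables in order of missing count; for variable `s`, fit a
   random forest of `y_obs(s)` on `x_obs(s)` (the other columns at their
   current imputed values) and replace `y_mis(s)` with forest predictions;
3. after each sweep compute the matrix difference

       delta_N = sum((X_new - X_old)^2) / sum(X_new^2)

   (continuous variables; categorical columns use the disagreement
   fraction per missing cell), and stop the first time `delta_N`
   increases, returning the previous sweep's matrix.

Each forest also yields an out-of-bag (OOB) NRMSE per variable — an
estimate of imputation error that needs no ground truth, where

    NRMSE = sqrt( mean[(X_true - X_imp)^2] / var[X_true] )

with mean and variance taken over the missing cells only (1.0 = no skill
beyond mean imputation).

Deliberate missingness ("amputation") is exact — every target variable
loses `round(rate * n)` cells — under three mechanisms: MCAR (uniform),
MAR (deletion probability logistic in the rank of a fully observed
covariate, default temperature) and MNAR (the largest values of the
variable itself are removed). Comparison methods: k-nearest-neighbour
donors, predictive mean matching, multivariate-normal EM with
bootstrapping, iterative low-rank reconstruction (BPCA-style), chained
random-forest draws, and column-mean imputation as the null. Multiple
imputation (default m = 20) is pooled with Rubin's rules
(`T = W + (1 + 1/m) B`).

## A worked example

```python
import airimpute as ai
from airimpute.missforest import ImputerParams

panel = ai.prepare_study(                      # log-scale, PM10 dropped
    ai.StudyConfig(panel=ai.default_config(n_days=500, seed=7))
)[0]
amputed = ai.ampute(panel, ai.MissingnessSpec("MCAR", rate=0.20, seed=7))
result = ai.missforest_impute(amputed.panel.data, ImputerParams(seed=7))
print(result.stopped_by, result.iterations)
print(ai.score_imputation(amputed, result.X_imp))
print(ai.oob_error_gap(result, amputed.vault, amputed.mask))
```

prints

```
criterion 6
{'rmse': 0.611, 'mae': 0.482, 'r': 0.425, 'nrmse': 0.912}
{'CO': 0.107, 'NO2': 0.036, 'O3': 0.106, 'SO2': 0.023}
```

— the stopping rule fired after six sweeps; the true NRMSE on the
amputed cells is 0.91 (real skill: mean imputation would score 1.0); and
the truth-free OOB estimate lands within 0.02–0.11 of the true error per
pollutant. The `examples/` directory holds one short script per
capability (simulation, imputation, benchmarking, multiple imputation,
AQI), and the `airimpute` CLI exposes the same steps
(`airimpute simulate | ampute | impute | mi | benchmark | aqi | reproduce`).

On the default synthetic study (five stations, 500 days, three mechanisms
x five rates x ten replicates) the iterative forest attains the lowest
replicate-averaged RMSE in every mechanism-rate block, kNN ranks second
overall, and MNAR amputation is consistently harder than MAR — the
qualitative pattern reported for real Gulf-region monitoring data.

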