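# nirselect

Chemometric calibration of lipid-oxidation markers in edible oils from
near-infrared (NIR) spectra, for analytical chemists and quality-control
labs monitoring oils under thermal stress (deep frying, storage).

Wet-chemical oxidation assays — free acidity, peroxide value (PV),
p-anisidine value (AnV), the UV extinctions K₂₃₂/K₂₇₀ and their baseline
deviation ΔK, and the composite index TOTOX = 2·PV + AnV — are slow,
destructive and reagent-hungry. A single NIR scan (here: 1100–2498 nm,
2 nm resolution, 700 channels) contains enough chemical information to
predict all seven markers, but its channels are massively collinear.
`nirselect` implements the SELECT–OLS approach to that problem:

1. **SELECT** (stepwise decorrelation of variables): iteratively pick the
   wavelength most correlated with the response, then orthogonalize all
   remaining wavelengths *and* the response against it (Gram–Schmidt
   deflation), so each subsequent pick carries only new, non-redundant
   information. Formally, at step *t* the selected channel is
   `argmax_k |corr(x̃_k, ỹ)|` over the deflated quantities, and the recorded
   weight is that absolute partial correlation.
2. **OLS** on the selected wavelengths (refit on the original autoscaled
   channels), with leave-one-out (LOO) cross-validation: PRESS,
   residual/explained variance, and a model size chosen to minimize the
   LOO mean prediction error.

A synthetic deep-frying study generator (142 oil samples: 12 olive
categories × 11 treatments + 2 sunflower categories × 5; triplicate
spectra; marker-linked absorption bands with the empirically observed
signs) provides a full ground truth so every stage of the pipeline is
testable without any external data. See `docs/methods.md` for the models
and the design decisions.

## Worked example

```python
from nirselect import SimConfig, generate_study, SelectOLS

study = generate_study(SimConfig(seed=1))         # 142 samples, 426 spectra
model = SelectOLS.from_study(study.markers, study.spectra, "k232")
res = model.fit(k_max=30)                         # SELECT + size choice + OLS
print(res.summary(decimals=2))
```

prints the classic two-panel calibration report (abridged):

```
(A) SELECT-OLS Chemometric Modeling
Order of Selection  Predictor Index  Wavelength (nm)  Weight  Coefficient
1                   508              2114             0.62    0.14
2                   144              1386             0.62    -0.10
3                   146              1390             0.37    -0.06
...
Intercept           1.61
(B) Statistical Characteristics
Standard Deviation of the Error           0.13
Mean Absolute Error (MAE)                 0.09
Multiple Correlation Coefficient (R)      0.98
Leave-One-Out Residual Variance (%)       7.58
Leave-One-Out Residual Standard Deviation 0.16
Leave-One-Out Explained Variance (%)      92.42
Leave-One-Out Mean Prediction Error       0.12
```

Panel A lists the wavelengths in selection order with their 1-based
predictor index (`nm = 1100 + 2·(index−1)`), the absolute partial
correlation at selection ("weight"), and the OLS coefficient in
autoscaled-predictor units. Here the first pick for the conjugated-diene
index K₂₃₂ lands at 2114 nm with the next picks at 1386–1392 nm — the
generator plants the K₂₃₂ band at 1392 nm, which the selection recovers
within one channel. Panel B says the 30-wavelength model correlates at
R = 0.98 with the reference values and keeps 92.4% explained variance
under leave-one-out validation; explained and residual variance complement
to 100 by construction.

`res.predict(raw_spectra)` applies the calibration to new spectra;
`res.plot_loo_curve()` and `res.plot_fit()` visualize the size choice and
the calibration. Beware that the panel-B LOO conditions on the selected
wavelengths; `nirselect.selection_loo` re-runs the selection inside every
fold for an unbiased estimate (see `docs/methods.md`).

The same pipeline is scriptable from the shell:

```sh
nirselect simulate --seed 1 --out data/
nirselect train --spectra data/spectra.csv --markers data/markers.csv --out run/
nirselect evaluate --run run/        # for simulated runs: band recovery vs truth
nirselect predict --model run/pv_model.json --spectra data/spectra.csv --out pred.csv
```

## Layout

- `src/nirselect/spectra.py` — wavelength grid, spectra/marker/metadata
  containers and CSV formats
- `src/nirselect/preprocess.py` — column autoscaling with stored parameters
- `src/nirselect/select.py` — the SELECT algorithm
- `src/nirselect/model.py` — OLS refit, reports, and the
  `SelectOLS`/`SelectOLSResults` model–results API
- `src/nirselect/validation.py` — calibration/LOO statistics, model-size
  choice, nested selection-inside-LOO
- `src/nirselect/indices.py` — oxidation-index arithmetic
- `src/nirselect/simulate.py` — the synthetic deep-frying study
- `src/nirselect/pipeline.py`, `src/nirselect/cli.py` — orchestration and
  the `nirselect` command
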