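# Methods

`nirselect` implements a complete chemometric calibration pipeline for
lipid-oxidation markers in edible oils: stepwise-decorrelation variable
selection (SELECT) on near-infrared absorbance spectra, ordinary least
squares on the selected wavelengths, leave-one-out validation, and a
synthetic deep-frying study generator that gives every stage a testable
ground truth. This note records the models, the defaults and why they were
chosen, and the limits of what the synthetic tests demonstrate.

## Data model

Spectra live on a fixed acquisition grid, 1100–2498 nm in 2 nm steps (700
channels). Channels are reported with 1-based predictor indices, so channel
*i* sits at `1100 + 2·(i−1)` nm; the mapping is bijective and exact, and
every serialized artifact uses it. Spectra are exchanged as wide CSV (one
row per recorded spectrum, header named by wavelength); the alternative of
a JCAMP-DX reader was rejected because plain CSV keeps fixtures
human-diffable and no instrument-native files are involved.

Each oil sample carries seven responses: free acidity (% oleic acid), the
specific UV extinctions K232 and K270 (Beer–Lambert, `K = A/(c·l)`), the
baseline deviation ΔK = K270 − (K266 + K274)/2 (the standard trade
definition, adopted here as a convention), the peroxide value PV
(meq O₂/kg), the p-anisidine value AnV, and the composite total-oxidation
index TOTOX = 2·PV + AnV. TOTOX is always derived from PV and AnV by that
identity, never measured or sampled independently.

Replicate spectra (three per sample) are averaged with an unweighted
arithmetic mean before modeling by default, mirroring the use of triplicate
means in conventional assays; an `individual` mode keeps every replicate
row, repeating the sample's marker value.

## Preprocessing

Predictors are column-autoscaled: per-channel mean-centering and division
by the sample standard deviation (denominator n−1, the chemometric
convention; the choice does not affect selection order, which is built from
scale-free correlations, but it fixes coefficient magnitudes). The fitted
means and SDs are stored with every model so it can be applied to raw
spectra. Channels whose SD falls below `1e−12·(|mean|+1)` are flagged as
effectively constant and skipped by selection rather than raising. The
response is not autoscaled by default (intercepts then live on the marker's
natural scale); a sensitivity flag can scale it.

## SELECT

At each step, the channel with the largest absolute Pearson correlation to
the current response residual is selected (ties broken toward the smaller
index for determinism); then every remaining channel and the response are
deflated by Gram–Schmidt projection against the selected channel. Because
the deflated quantities are exactly the residuals of a regression on all
previously selected channels (plus intercept), each step's correlation is a
partial correlation, and redundant, collinear channels drop out of
contention once their first representative is picked — the property that
keeps the selected subset compact on heavily overlapping NIR bands. The
recorded *weight* of a step is the absolute partial correlation at
selection; it lies in [0, 1] and is legitimately non-monotone across steps
(a suppressor channel can become highly informative only after earlier
channels are projected out — the test suite constructs such a case).

Stopping: at `k_max` steps (default 30, bracketing the 16–30-wavelength
models typical of published NIR oxidation calibrations), when the best
remaining |partial correlation| falls below `r_min` (default 0.05), or when
the residual response variance falls below `tol_var` (default 1e−6) of the
original. Deflated channels whose remaining variance is numerically zero
relative to their original variance are retired. Inputs with n ≤ 2 rows are
refused.

The implementation is verified step-for-step against a brute-force oracle
that re-residualizes every candidate and the response on the selected set
from scratch at every step.

## OLS refit and reporting

The final model is refit by least squares (QR/SVD factorization, with a
pivoted-QR rank check that names offending wavelengths; the explicit
normal-equations solve exists only as a test oracle) on the *original*
autoscaled selected channels — not the orthogonalized working copies.
Neighboring selected wavelengths are highly collinear, so coefficients of
adjacent channels can be large with opposing signs while predictions remain
stable; a test perturbs such a design by 1e−8 and confirms prediction
stability. Models serialize to JSON with coefficients in both
autoscaled-predictor and raw-absorbance space (`b_raw = b/sd`,
`a_raw = a − Σ b·mean/sd`), and render as a two-panel TSV report: panel A
(order of selection, predictor index, wavelength, weight, coefficient,
intercept) and panel B (seven statistics, below).

## Validation statistics

Calibration side: residual SD `sqrt(SS_res/(n−p−1))`, mean absolute error,
and the multiple correlation coefficient R between observed and fitted
values (reported as 0 with a degeneracy flag if the fit is constant).
Leave-one-out side, from the PRESS statistic `Σ (y_i − ŷ_(−i),i)²`:
residual variance % = `100·PRESS/SS_tot`, explained variance % as its exact
complement (reported unclipped — negative values are informative), LOO
residual SD with denominator n−p−1 (mirroring the calibration SD; a flag
switches to n), and the LOO mean absolute prediction error.

Two LOO preprocessing modes exist: `refit` (default) re-fits the
autoscaling inside every fold and computes explicit refits; `fixed` keeps
the full-data scaling and uses the exact hat-matrix shortcut
`d_i = e_i/(1−h_ii)`. Because OLS with an intercept is equivariant under
per-column affine maps, the two modes give identical held-out predictions
up to round-off; both are implemented so the equivalence is a verified test
rather than an assumption.

Model size is chosen by evaluating the nested prefixes k = 1..len(trace) of
the selection trace and taking the smallest k minimizing the LOO mean
prediction error. On planted-truth simulations the chosen size never
underfits; because the LOO curve is near-flat beyond the true size, the
exact true size is the modal but not the invariable choice.

### Selection bias and the honest nested LOO

The per-model LOO above conditions on a selection made from *all* samples.
With 700 candidate channels and ~142 samples that conditioning is
optimistic: on a permuted (pure-noise) response the fixed-trace LOO can
report ≈75% spurious explained variance. The panel-B statistics therefore
measure coefficient stability given the selection — the quantity the
classic chemometric reports print — not the unbiased generalization error
of the full procedure. For that, `selection_loo` re-runs SELECT inside
every fold; the shuffled-response negative control uses it with the model
size pinned to the size chosen on the real response (re-choosing the size
on the permuted data would re-introduce a winner's-curse bias of ≈+10%).
Under this control the explained variance is strongly negative, as a null
should be.

## Synthetic study generator

The generator reproduces the design of a deep-frying oxidation study: 12
olive-oil categories × 11 treatments (controls C1, C2, S; frying
experiments E1–E8 on a {170, 210} °C × {3, 6} h grid, E5–E8
polyphenol-supplemented) plus 2 sunflower categories × 5 treatments
(control C, E1–E4), i.e. 142 samples, each with triplicate spectra (426
rows).

Markers follow `m = base(category) · g(T, t) · s · exp(ε)`:

- `base` is drawn once per category from a class-level control range
  (e.g. PV 7–10 meq O₂/kg for olive, 5–7 for sunflower; acidity 0.08–0.30 %
  oleic — an invented range, as no reference values exist for it), mildly
  coupled to the category's stability so stabler oils start cleaner;
- `g(T, t) = 1 + stability · a_m · ((T−160)/50)^qT · (t/6)^qt` is a
  monotone power-law growth (exponents default to 1), an invented form
  chosen only to satisfy the known orderings — more oxidation at higher
  temperature and longer frying, worst at 210 °C/6 h; `a_m` is the relative
  growth at 210 °C/6 h for a stability-1 category (e.g. 1.3 for PV, 10 for
  AnV), calibrated so stressed values reach the observed envelopes (PV up
  to ~27, AnV up to ~60, K232 ≤ ~4.7, K270 ≤ ~2.7, ΔK ≤ ~0.32);
- `s` is a supplementation attenuation (default 0.6) applied to E5–E8,
  encoding the protective polyphenol effect; `ε` is lognormal measurement
  noise (SD 0.08).

Category stability scalars encode the observed ranking (high-oleic
sunflower and the stabler cultivars lowest, regular sunflower and
Hojiblanca highest). TOTOX is computed exactly from the realized PV and
AnV.

Spectra are `A(λ) = baseline_category(λ) + Σ_bands slope·(marker −
median)·Gaussian(λ; center, 12 nm) + N(0, σ_rep)` per replicate. The
baseline is a monotone-smooth (PCHIP) curve anchored so absorbance near
1392 nm sits at ~0.40 and near 2114 nm at ~1.08, with a small per-category
offset and tilt. The default band table places one principal band per
marker with the observed signs — acidity 1792 nm (−), K232 1392 nm (−),
K270 2114 nm (+), ΔK 2118 nm (+), AnV 1970 nm (+) with a minor band at
2362 nm — plus an invented PV band at 1376 nm (−, consistent with the
published PV model's first pick) and carbonyl-region TOTOX bands at 2254
and 2404 nm; TOTOX additionally inherits the PV and AnV bands as candidate
generators since it is their composite. The 12 nm Gaussian SD spreads each
band over several 2 nm channels, creating the collinearity SELECT exists to
handle.

All randomness derives from one root seed through named sub-streams
(`markers`, `baseline`, `replicates`; CRC32 of the stream name mixed into a
`SeedSequence`), so any stage can be re-run reproducibly in isolation.

### Calibration of the defaults, and what the tests do and do not show

Band slopes and the replicate noise SD jointly set the spectral
signal-to-noise. Two published-scale properties pull in opposite
directions: LOO explained variance in the 72–94% span of the reference
models, and recovery of each marker's generating band to ±6 nm. White
channel noise strong enough to push explained variance to the middle of
that span also jitters the selected channel 8–24 nm off-band in 20–40% of
seeds, because a 30-channel model averages white noise away while the
argmax of a noisy correlation profile does not. The frozen defaults
(σ_rep = 0.015 absorbance) prioritize recovery: over 20 seeds every
marker's strongest band is recovered within ±6 nm in 20/20 runs with
calibration R ≥ 0.96, and LOO explained variance spans ≈88–98%, overlapping
the upper part of the published range rather than all of it.

The generator emulates the statistical structure the analysis assumes —
marker-linked bands at known positions, realistic collinearity, positive
inter-marker correlations, monotone treatment effects — but not real NIR
physics: no scattering, no temperature-dependent band shifts, no structured
instrument noise, and spectra are built from the same realized marker
values the models are trained on (only replicate noise is irreducible).
Passing tests therefore demonstrate that the pipeline recovers the
structure it was designed to recover, not that the published accuracies
transfer to real spectra, which are not available.

## Problem sizes

Default test and acceptance runs use the full 142-sample/426-spectrum
design; oracle-equivalence checks use 50 random 30×8 instances; recovery
statistics aggregate 20 seeds in the test suite and 10 in the acceptance
script.

## Known limitations

- The printed "weight" column of classic SELECT reports is not formally
  defined anywhere; its identification with the absolute partial
  correlation at selection matches its range and non-monotonicity but is a
  convention of this package.
- Whether published coefficients live in autoscaled or raw predictor space
  cannot be determined without the original data; both are serialized.
- Fixed-trace LOO statistics are optimistic for a data-driven selection
  (see above); compare with `selection_loo` before interpreting them as
  generalization error.
- The model-size search, like any LOO-argmin rule, is noisy beyond the true
  size; sizes chosen are upper bounds more often than underestimates.
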