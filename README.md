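# wheatspec

Monitoring wheat growth from three-band canopy reflectance.

Portable multispectral crop sensors read canopy reflectance at a red
(660 nm), red-edge (730 nm) and near-infrared (815 nm) band and turn it
into estimates of four growth indices: leaf area index (LAI,
dimensionless), leaf dry weight (LDW, g·m⁻²), leaf nitrogen content
(LNC, % of dry mass) and leaf nitrogen accumulation
(LNA = LNC/100 × LDW, g·m⁻²). `wheatspec` implements the full analysis
chain for such instruments:

* **Vegetation indices.** The classical two-band forms over all three band
  pairs, plus two three-band indices that splice the red band into the
  NDVI/DVI construction:

  ```
  NDVI  = (ρ1 − ρ2)/(ρ1 + ρ2)        RVI = ρ1/ρ2        DVI = ρ1 − ρ2
  TVI-1 = (2·ρNIR − ρred − ρred-edge)/(2·ρNIR + ρred + ρred-edge)
  TVI-2 =  2·ρNIR − ρred − ρred-edge
  ```

* **Exponential calibration.** Monitoring models y = a·e^{b·x} (growth
  index y on vegetation index x), fitted by nonlinear least squares from a
  log-linear start, trained and validated on plot-disjoint 70/30 splits and
  scored by R² and RRMSE = RMSE/mean(observed).

* **Stage-segmented models.** Vegetation indices saturate once the canopy
  closes (around LAI ≈ 3), so a single whole-season model under-predicts
  large values. Each growth index gets a two-period split of the
  jointing→flowering season, independent per-period fits, and an automatic
  fallback to the whole-season model where the early period is too narrow
  to support its own fit.

* **Cross-instrument consistency.** Index-by-index agreement between the
  portable sensor and a reference spectroradiometer: min–max
  normalization, then OLS with R²/RRMSE per index.

* **Synthetic split-plot experiments.** A generator emulating a
  3 nitrogen × 3 density × 3 replicate wheat trial (27 plots × 4 stages)
  with realistic stage-wise growth dynamics, a Beer–Lambert-style canopy
  reflectance model that reproduces index saturation, and band-dependent
  sensor noise — so the entire pipeline is testable without field data.

## Worked example

```python
from wheatspec import (fit_model, evaluate_model, fit_staged,
                       evaluate_staged, split_by_plot, saturation_diagnostic)
from wheatspec.synthetic import SyntheticConfig, generate_experiment

data, paired = generate_experiment(SyntheticConfig(seed=7))   # 108 records
split = split_by_plot(data, 0.7, seed=108)                    # 72 / 36

fit = fit_model(split.train, "lai", "TVI2")
rep = evaluate_model(fit, split.validation)
print(f"LAI = {fit.coef_a:.3f} * exp({fit.coef_b:.3f} * TVI2)")
print(f"validation R2={rep.r2:.2f} RRMSE={rep.rrmse:.2f} (n={rep.n})")

low, high = saturation_diagnostic(data, "NDVI(660,815)", "lai", 3.0)
print(f"NDVI(660,815) sensitivity to LAI: {low:.3f} below LAI=3, {high:.3f} above")
```

prints

```
LAI = 0.099 * exp(5.297 * TVI2)
validation R2=0.90 RRMSE=0.13 (n=36)
NDVI(660,815) sensitivity to LAI: 0.122 below LAI=3, 0.017 above
```

The fitted model explains 90 % of validation-set LAI variance with a
relative error of 13 %, and the saturation diagnostic shows NDVI losing
~85 % of its sensitivity to LAI above the canopy-closure threshold — the
behavior the stage-segmented models are built to counter.

The same workflow runs from the shell:

```sh
wheatspec run --seed 7 --out-dir out
cat out/summary.txt
```

```
wheatspec pipeline report (seed=7)
records: 108  train/validation: 72/36

staged vs whole-period validation (delta = staged - whole):
  LAI  vi=TVI2           staged R2=0.902 RRMSE=0.128 dR2=+0.005 dRRMSE=-0.005
  LDW  vi=TVI1           staged R2=0.502 RRMSE=0.362 dR2=-0.010 dRRMSE=+0.000
  LNC  vi=NDVI(730,815)  staged R2=0.347 RRMSE=0.138 dR2=+0.023 dRRMSE=-0.002
  LNA  vi=NDVI(730,815)  staged R2=0.540 RRMSE=0.407 dR2=+0.002 dRRMSE=-0.002
```

Further CLI verbs (`generate`, `indices`, `fit`, `stage`, `evaluate`,
`consistency`) expose the individual pipeline stages; see
`wheatspec --help`.

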