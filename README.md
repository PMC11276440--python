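# alfaspec

Calibration pipeline for estimating **crude protein (CP)** in forage
(alfalfa) from **mid-infrared transmission spectra** (FTIR, 4000→400 cm⁻¹,
KBr pellets). Wet-chemistry CP determination (Kjeldahl, total N × 6.25) is
slow, hazardous and reagent-hungry; an FTIR spectrum takes minutes. The
package implements the full chemometric chain that turns spectra plus a
modest set of reference values into a quantitative CP model, and a
synthetic-data generator that emulates the study population so every stage
is testable without instrument access.

Intended users: chemometricians and feed/food-quality researchers building
small-sample (n ≈ 100) spectroscopic calibrations, and anyone needing a
tested, scriptable reference implementation of the airPLS/CARS/PLSR stack.

## Methods

- **Baseline correction — airPLS** (adaptive iteratively reweighted
  penalized least squares). A Whittaker smoother solves
  `(W + λ DᵀD) z = W x` with a sparse order-*d* difference penalty
  (defaults λ = 1e10, d = 2, ≤ 20 iterations); weights are re-estimated each
  iteration so points above the running baseline are excluded
  (`wᵢ = 0` where `xᵢ ≥ zᵢ`, `wᵢ = exp(t·|dᵢ|/|d⁻|₁)` below), leaving the
  smooth under-envelope as the baseline estimate.
- **Smoothing / differentiation — Savitzky–Golay**, and per-spectrum
  **min–max scaling**, composable as ordered preprocessing recipes.
- **Wavelength selection — CARS** (competitive adaptive reweighted
  sampling): over N = 50 Monte-Carlo runs the retained set shrinks along an
  exponentially decreasing schedule (`r₁ = 1` … `r_N = 2/p₀`) via an
  enforced top-weight reduction followed by weighted sampling with
  replacement; each run's subset is scored by repeated K-fold RMSECV and
  the smallest subset statistically tied with the best (and no worse than
  the full spectrum) wins. Alternatively **FG&M**: a fixed list of 20
  protein-chemistry wavenumbers (N–H, amide, C–N, COOH bands and their
  documented neighbours).
- **Calibration models** — single-response **PLSR** (NIPALS, mean-centred,
  component count chosen by K-fold cross-validation) and **random-forest
  regression** (bootstrap CART ensemble, `√p` features per split, exhaustive
  K-fold grid search).
- **Evaluation** — seeded 7:1.5:1.5 calibration/validation/prediction split
  (90 samples → 63/13/14) and the standard statistics

  `R² = 1 − Σ(Cᵢ−Ĉᵢ)²/Σ(Cᵢ−C̄)²`,  `RMSE = √(Σ(Cᵢ−Ĉᵢ)²/count)`

  reported as Rc²/RMSEC on the calibration subset and Rp²/RMSEP on the
  held-out prediction subset.

See `docs/methods.md` for the model assumptions, the synthetic-data
generator's design, and every numerical choice.

## Worked example

```python
from alfaspec import SimulationConfig, generate_dataset, run_combination

sset, truth = generate_dataset(SimulationConfig(seed=1))   # 90 x 10,329 %T
report = run_combination(
    sset,
    recipe=("to_absorbance", "airpls"),   # convert, then baseline-correct
    selector="cars",
    model_kind="plsr",
    cv=True,                              # K-fold component selection
    seed=1,
)
print(f"combination      : {report.label}")
print(f"wavelengths kept : {report.n_features} of {sset.n_points}")
print(f"PLS components   : {report.details['n_components']}")
print(f"calibration      : Rc2 = {report.rc2:.3f}, RMSEC = {report.rmsec:.3f} %CP")
print(f"prediction       : Rp2 = {report.rp2:.3f}, RMSEP = {report.rmsep:.3f} %CP")
```

```
combination      : airpls-CARS-PLSR-CV
wavelengths kept : 96 of 10329
PLS components   : 8
calibration      : Rc2 = 1.000, RMSEC = 0.044 %CP
prediction       : Rp2 = 0.975, RMSEP = 0.616 %CP
```

CARS kept 96 of 10,329 wavelengths (clustered on the N–H/amide/C–N protein
bands), cross-validation chose 8 latent components, and the model predicts
the 14 held-out samples to about 0.6 %CP — against a population whose CP
spans 9.00–22.04 %. Modelling the raw transmittance spectra with no
pretreatment instead gives Rp² ≈ 0.60 on the same split: baseline removal
and the absorbance transform carry most of that gap.

The same pipeline is scriptable from the shell:

```bash
alfaspec simulate --n 90 --seed 1 --out spectra.csv --refs refs.csv
alfaspec run-all --seed 1 --outdir results/
```

`run-all` executes the full pretreatment × selector × model comparison
matrix (11 combinations) and writes `reports.json`, `comparison.csv` and an
aligned-text ranking by prediction accuracy (Rp² descending, RMSEP
ascending).

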