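# Methods

This note records the models behind `alfaspec`, the assumptions they make,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions a maintainer would
otherwise have to reverse-engineer. Nothing here states a result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The calibration problem

Crude protein (CP, % of dry matter) is to be predicted from a mid-IR
transmission spectrum: 10,329 points spanning 4000→400 cm⁻¹, stored in the
instrument's descending order. Beer–Lambert absorption makes *absorbance*
(`A = −log10(T/100)`) approximately linear in constituent concentrations,
so modelling converts to absorbance first (transmittance itself is a
nonlinear, saturating transform of concentration). Protein chemistry is
visible through N–H stretching/bending, amide, C–N and COOH bands; the
measured spectrum adds carbohydrate and mineral bands, a broad ~3400 cm⁻¹
moisture band (hygroscopic KBr), a smooth scattering baseline, and noise.

With ~90 samples against ~10⁴ wavelengths the calibration is severely
underdetermined; the pipeline therefore combines baseline removal,
wavelength selection and latent-variable (or ensemble) regression, each
stage fit strictly on the calibration subset.

## airPLS baseline correction

The Whittaker smoother solves `(W + λ DᵀD) z = W x` with `D` the order-*d*
finite-difference operator. We solve for the correction `δ = z − x`
instead: `(W + λDᵀD) δ = −λ Dᵀ(Δᵈ x)`. The right-hand side vanishes when
`x` lies in the penalty null space (polynomials of degree < d), so such
signals are reproduced to rounding error even at λ ~ 1e12, where the direct
form loses ~12 digits to conditioning (cond ≈ λ‖DᵀD‖). The sparse LU solve
costs O(p) per iteration at p = 10,329.

airPLS re-weights iteratively: after each smooth, points at or above the
baseline get weight 0 and points below get `exp(t·|dᵢ|/|d⁻|₁)`; iteration
stops when the negative-residual mass falls below `0.001·|x|₁` or after 20
iterations. Defaults λ = 1e10, d = 2, and an endpoint anchor: the first and
last 5% of points keep a weight floor of 0.5. The anchor is our reading of
"start/end weight exception proportion 0.05, asymmetry 0.5" — parameters
that are not part of canonical airPLS; anchoring prevents endpoint
divergence and is flagged as an interpretation, not a standard.

Numerical caveats:

- `BaselineResult.corrected` is defined as the exact float subtraction
  `x − baseline`; recomputing that subtraction reproduces it
  bit-identically. The literal sum `corrected + baseline` equals `x` to
  within ~1 ulp but not always bit-exactly — where the signal crosses zero
  under an O(1) baseline no float pair can sum to the signal's ulp.
- Recovery accuracy (measured against the generator's truth table on
  noise-free populations) is ~0.3–2% RMS of the baseline's dynamic range in
  peak-free regions, occasionally ~3% for unlucky draws; the residual error
  is smoother bleed of band tails across the support boundary, decaying on
  the smoother's length scale λ^¼ ≈ 100 points. "Peak-free" is
  operationalized as beyond 4σ of every band centre: at 3σ a Gaussian still
  carries ~1% of its height, which is band tail rather than baseline.

## Savitzky–Golay and min–max

SG filtering delegates to `scipy.signal.savgol_filter` (window 11, order 2,
no derivative by default — the derivative variant is exposed but not part
of the default comparison, since smoothing alone already performed worst in
the pretreatment comparison this package mirrors). Derivatives are scaled
by the absolute axis spacing. Min–max scales each spectrum to [0, 1];
it is row-wise by design (scatter effects act per spectrum) and is *not*
part of the quantitative default recipes: scaling each spectrum
individually destroys the absolute band heights that carry the CP signal.

## CARS wavelength selection

Competitive adaptive reweighted sampling with N = 50 Monte-Carlo runs:

1. Run *i* draws `⌈0.8·n⌉` calibration rows, fits PLS on the currently
   retained wavelengths and weights each one by its **standardized
   coefficient magnitude** `|bⱼ|·sd(xⱼ)` — the size of that wavelength's
   term in the prediction sum. The original method operates on autoscaled
   data, where the raw coefficient *is* the standardized one; on unscaled
   absorbance, raw `|bⱼ|` would spuriously inflate near-constant noise
   channels.
2. The current set's RMSECV is recorded from repeated K-fold CV
   (5 folds × 3 repeats, folds fixed across runs) at the CV-chosen
   component count, together with its standard error across folds. A fixed
   large component count would overfit noise wavelengths and corrupt both
   the score and the weights.
3. The next set is formed by enforced reduction to the exponentially
   decreasing quota `⌈rᵢ₊₁·p₀⌉` (schedule `r₁ = 1`, `r_N = 2/p₀`, floor 2)
   followed by weighted sampling **with replacement** with `⌈rᵢ₊₁·p₀⌉`
   draws; the unique survivors form the new set. Draw counts may exceed the
   candidate count — capping them at the set size makes survivorship halve
   the set every run regardless of the schedule.
4. The winner is the **smallest retained set whose RMSECV is within one
   standard error of the trace minimum and no worse than the full-spectrum
   run** (run 1 evaluates the full spectrum, so the winner never scores
   worse than it). Near the minimum the trace is flat at fold-noise scale;
   a strict argmin there is decided by noise, and the package's global
   tie-break — smallest model — is the appropriate rule. The full trace
   (sizes, RMSECV, SE, component counts) is retained in `CARSResult` so a
   strict argmin remains recoverable.

On the three-band benchmark (below) the selected wavelengths concentrate on
the protein band supports (≥80% within ±3σ of a band centre across seeds),
and on the full study population CARS avoids the broad water band,
selecting N–H shoulders beside it — emergent behaviour, not a rule.

### FG&M fixed peaks

The chemistry-motivated alternative: 20 wavenumber centres — the eleven
strong absorption peaks of an alfalfa mid-IR spectrum (593, 600, 665, 1053,
1102, 1246, 1381, 1417, 1630, 2915, 3394 cm⁻¹), the selection-overlap peaks
1633/1512/1420/1242, the water-avoiding shoulders 3368/3445/3477, and two
forest-importance neighbours 1426.07/1051.69 — mapped to nearest grid
points and deduplicated. With a mean calibration spectrum supplied,
`fgm_select` optionally adds local extrema within a tolerance of each
centre (peak maxima drift between populations); the evaluation pipeline
uses the plain 20-point list.

## Regression models

**PLSR** is single-response NIPALS: mean-centre, then per component
`w ∝ Eᵀf`, `t = Ew`, deflate; no inner iteration is needed for one
response, so fits are exactly deterministic. Coefficients in original
variable space are `B = W(PᵀW)⁻¹q` (`PᵀW` unit upper-triangular);
predictions from `B` agree with sequential score projection to 1e−10.
X-autoscaling is off by default — spectra are preprocessed upstream.
Component count: K-fold CV (K = 5, seeded shuffle then contiguous blocks),
pooled RMSE, smallest count on ties, cap 15. Note that PLS at fixed
A < rank is *not* invariant to duplicating a column (the duplicate doubles
its coordinate in `Xᵀy`); invariance holds at A = rank.

**RFR** delegates tree construction to scikit-learn's
`RandomForestRegressor` (bootstrap rows, fresh `⌊√p⌋` feature subset per
split, variance-reduction splits, impurity importances normalised to 1)
under this package's hyperparameter surface: defaults 15 trees, depth 10,
min-split 2, min-leaf 1; the exhaustive grid search (trees {15, 50, 100} ×
depth {5, 10, ∞} × leaf {1, 2} × split {2, 4}) scores by K-fold RMSE with
ties broken toward fewer trees, then shallower depth.

## Splitting and statistics

Samples are shuffled with a seeded generator and cut 7:1.5:1.5 into
calibration/validation/prediction using floor/floor/remainder, so 90
samples give 63/13/14. K-fold searches run inside the 63 calibration
samples; the 13 validation samples are scored as a monitoring metric; the
14 prediction samples are untouched until final scoring. `R²` uses the
scored subset's measured mean by default; the variant that centres on the
predicted-value mean is available via `reference_mean` (and is logged in
every report as `rp2_literal`) but is nonstandard and not used for ranking.
Rankings sort by Rp² descending, then RMSEP ascending.

One master seed derives named sub-seeds (split, CARS, CV folds, forests)
through `numpy.random.SeedSequence`, making a whole evaluation
bit-reproducible.

## The synthetic-data generator

`generate_dataset` emulates the study population the pipeline assumes:

- **n = 90** samples, true CP ~ Uniform(9.00, 22.04) %DM (only the range is
  known; uniform is the maximum-entropy choice), recorded reference
  `y = CP + N(0, 0.15)` as a Kjeldahl-error proxy, clipped to the range.
- **Axis**: 10,329 points, 4000→400 cm⁻¹ descending.
- **Bands**: Gaussian by default (Lorentzian available); protein heights
  scale as `base_amplitude · cp/15` (mid-range normalised) with 5%
  per-sample multiplicative jitter — real band ratios are not perfectly
  locked to total CP; carbohydrate/mineral heights vary as independent
  N(1, 0.2) nuisance levels, the broad water band (3400 cm⁻¹, σ = 200) as
  N(1, 0.3).
- **Baseline**: per-sample degree-2 polynomial plus one broad Gaussian
  drift, amplitudes in the scattering-dominated KBr-pellet regime
  (coefficients up to ~0.3, drift up to 0.4 absorbance). Slope and drift
  magnitudes are bounded away from zero: a flat baseline draw is a
  degenerate condition, not a realistic one.
- **Noise**: white absorbance noise (sd 0.02, band-height SNR ≈ 20) plus a
  smaller smoothly correlated component (sd 0.01, 25 cm⁻¹ correlation
  length) standing in for detector drift and imperfect background
  subtraction. The correlated part matters: it cannot be averaged away
  across channels, so uninformative wavelengths carry a real
  cross-validation cost — without it, wavelength selection has no genuine
  benefit on Beer–Lambert data and selection benchmarks degenerate into
  coin flips. An optional heteroscedastic mode scales noise by (1+|A|);
  optional replicate averaging divides noise variance by r (default off,
  equivalent to reducing the sd).
- **Output**: percent transmittance (instrument-native); pipelines convert
  to absorbance as their first step. A sidecar truth table records true CP,
  per-band heights and per-sample baselines for recovery tests.

`three_band_config` is the reduced benchmark for selection behaviour:
63 samples, 400 points, exactly three protein bands (3394/1630/1246 cm⁻¹,
all σ = 30 cm⁻¹), no nuisance/baseline/jitter/reference noise, white noise
0.005 with the default correlated component. The equal 30 cm⁻¹ widths keep
the ripple-reference shoulders — channels useful for correcting correlated
noise, which sit within about two correlation lengths of a band core —
inside the ±3σ band support that enrichment is scored against.

**What passing tests do and do not show.** The generator is linear
Beer–Lambert mixing with Gaussian bands and stationary noise. It does not
model instrument line-shape convolution, wavelength-dependent scattering
(beyond a smooth baseline), atmospheric CO₂/H₂O vapour lines, band-shape
changes with matrix chemistry, or between-sample covariance from variety
and region effects (nuisance levels are independent draws). Pipeline
performance on this population (Rp² ≈ 0.96–0.99, RMSEP ≈ 0.4–0.7 %CP)
demonstrates correct mechanics and the direction of pretreatment/selection
effects — not field performance on real forage, which depends on exactly
the unmodelled effects.

## Degenerate inputs and tie rules

- Constant spectra: min–max raises; zero-variance columns get zero PLS
  weight; constant `y` makes R² undefined (raises) and CARS refuses it.
- All-zero Whittaker weights raise; λ = 0 with mixed zero weights would be
  singular and surfaces as a solver error.
- Ties everywhere break toward the smaller model: fewest components,
  fewest trees, shallowest depth, smallest wavelength subset, earliest run.
- Seeds derived from the master seed are reduced mod 2³¹.

## Known limitations

- airPLS endpoint anchoring is an interpretation of printed parameters that
  canonical airPLS lacks (see above); disable it by setting
  `edge_protect_fraction = 0`.
- The CARS winner rule is the 1-SE parsimony variant; strict argmin can be
  recovered from the stored trace but is noise-decided on flat traces.
- The JCAMP-DX reader accepts uncompressed AFFN `(X++(Y..Y))` tables only;
  SQZ/DIF/DUP compression raises.
- RMSECV inside CARS is computed on the same calibration samples that drive
  the selection, so it carries the usual optimistic selection bias; honest
  generalization numbers come only from the untouched prediction subset.
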