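# Methods

This note documents the models implemented in `oleanir`, their
assumptions, the default parameters (with units), and the numerical
choices that affect results. Nothing here is an empirical claim beyond
what the test suite and the `analysis/` scripts actually compute.

## 1. Synthetic data generator (`oleanir.simulate`)

No public NIR dataset exists for olive-leaf antioxidant calibration, so
the package generates one. The generator is designed to be *linear by
construction* so that the downstream chain can be validated against a
known ground truth.

### 1.1 Phenolic profiles

Each sample draws five compound concentrations (mg/g dry leaf) from
independent lognormal distributions:

| compound | mean (mg/g) | CV |
|---|---:|---:|
| oleuropein | 30.0 | 0.35 |
| hydroxytyrosol | 3.5 | 0.40 |
| hydroxytyrosol hexoside | 2.0 | 0.40 |
| verbascoside | 2.5 | 0.45 |
| apigenin-7-glucoside | 0.8 | 0.40 |

Oleuropein dominating the phenolic fraction of dried olive leaf is the
one compositional fact the generator takes from the domain literature;
the CVs are plausible batch-to-batch spreads, not measurements.
Lognormality encodes positivity and right skew of natural
concentrations. Independence between compounds is a simplification
(Section 5).

### 1.2 Reference values

Assay values are affine in the concentrations plus Gaussian noise:
`y = intercept + Σ_k w_k c_k + ε`, `ε ~ N(0, noise_sd_reference²)`
(default 0.02 mM Trolox; ORAC in mmol TE/g). The weights are derived
analytically from per-assay "share" vectors (the signed fraction of the
assay SD each compound contributes) so that the noise-free values have
a prescribed mean and SD under the lognormal profile distribution.
Defaults:

| assay | mean | pre-clip SD | reporting range |
|---|---:|---:|---|
| DPPH | 0.69 mM TE | 0.15 | 0.42–0.96 |
| ABTS | 0.74 mM TE | 0.11 | 0.60–0.99 |
| ORAC | 2.72 mmol TE/g | 0.55 | 0.94–4.10 |

Values are clipped to the reporting range by default
(`clip_range="default"`); pass `clip_range=None` for the unclipped,
exactly affine ground truth. Clipping is a reporting convention — it
makes the concentration→value map nonlinear at the range edges, which
is why the parameter-recovery tests disable it while keeping the noise.
The DPPH/ABTS pre-clip SDs are set to range/3.6 so the clipped
distribution remains unimodal within its range; a larger SD would be
statistically inconsistent with the stated ranges.

### 1.3 Spectra

Absorbance follows Beer–Lambert linear mixing on a descending grid from
13,333 to 4000 cm⁻¹ in 4 cm⁻¹ steps (2334 points):

```
A(ν) = m · [ matrix(ν) + Σ_k c_k s_k(ν) ] + a + (b0 + b1·ν̃) + noise
```

- `s_k(ν)`: each compound contributes Gaussian combination/overtone
  bands of width σ = 40 cm⁻¹ centred at 5785, 5677, 5222, 4861, 4404,
  4337 and 4262 cm⁻¹ with compound-specific signed amplitudes.
- `matrix(ν)`: a constant dried-leaf background (cellulose/water O–H
  and C–H bands: broad Gaussians at 10300, 8400, 6900, 5600, 5180,
  4740, 4330 and 4020 cm⁻¹) scaled by `matrix_amplitude` (default 1.0).
  Physically this is the absorbing bulk of the powder; numerically it
  matters because per-sample normalisations (SNV, MSC) are only
  approximately linear in the concentrations when a dominant common
  background exists. Without it, SNV's row norm varies strongly with
  total phenolic load and destroys the linear signal.
- `m ~ N(1, 0.05²)` multiplicative and `a ~ N(0, 0.01²)` additive
  scatter per sample; baseline offset U(0, 0.05) and slope
  U(−0.02, 0.02) across the grid; i.i.d. spectral noise
  N(0, (2·10⁻⁴)²) per point.

All randomness derives from `numpy.random.default_rng([seed, stream])`
with a distinct stream constant per stage, so profiles, references and
spectra are independently reproducible from one seed.

### 1.4 Kinetic curves

For the ORAC-style decay, fluorescence follows
`F(t) = F₀ · exp(−r·t)` with `r = decay_rate / (1 + c/half_protect)`
(defaults: F₀ = 1000, decay_rate = 0.002 s⁻¹, half-protection
concentration 0.2 mM, 3600 s read every 300 s). Antioxidant
concentration `c` slows the decay monotonically. Optional Gaussian
noise is applied to every reading except the first, so the F₁
normalisation of the AUC statistics stays exact. Curves with a single
reading are allowed (AUC_full = 1), since the simplified statistic's
worked cases include them.

### What the generator does *not* emulate

Instrument line-shape and detector nonlinearity, wavelength-dependent
scatter (it is affine per sample), water-activity band shifts,
compound–compound covariance, batch/seasonal structure, and any matrix
interference in the assays (assay values are exactly affine pre-clip).

## 2. Pretreatments (`oleanir.preprocess`)

`SCATTER-a.b.c` means: SG derivative of order `a` (window `b` points,
polynomial order 2) → SG smoothing (window `c`, derivative 0) → scatter
correction (`MSC` or `SNV`). Derivatives are with respect to wavenumber
(units of absorbance per cm⁻¹ᵃ); the descending axis is handled by
sign-flipping odd-order derivatives of the index-space filter. Edges
use scipy's `mode="interp"` (the edge polynomial is evaluated, output
length preserved). SNV uses the n−1 denominator. MSC regresses each
spectrum on the mean spectrum (or a supplied reference) and corrects to
`(x − a)/b`. The default grid is the six codes `MSC-1.19.5`,
`SNV-2.13.9`, `MSC-2.19.5`, `SNV-2.19.5`, `SNV-2.5.19`, `MSC-2.5.19`.

## 3. Splitting, regression, evaluation

**Kennard–Stone** (`oleanir.split`): greedy max–min Euclidean selection
starting from the farthest pair, on mean-centred pretreated spectra;
ties break to the lowest index. `split_sets` keeps the first
`round(0.7·n)` selected samples as Set 1 (calibration/CV) and the rest
as Set 2 (prediction); 120 → 84/36.

**PLS1** (`oleanir.pls`): NIPALS with the non-iterative single-y update
(w ∝ Xᵀy), X-deflation, and the rotation matrix R = W(PᵀW)⁻¹ computed
by recursion, which yields regression coefficients at *every* latent
variable count from one fit. Deflation stops early when the residual
X-norm falls below 1e-14 (recorded as `n_effective`); this keeps the
n−1-component interpolating fit numerically clean. Leave-one-out CV
therefore costs exactly n refits regardless of `max_lv`. The selected
LV count is the smallest whose RMSECV is within 1e-12 of the minimum.

**Evaluation** (`oleanir.evaluate`): RMSE = √(Σ(ŷ−y)²/n);
RPD = SD/RMSE with SD over the evaluated set (n−1 denominator); bands
≥ 3 "quality control", 2–3 "screening", < 2 "not recommended". R² is
the squared Pearson correlation between predicted and observed (the
1−SSE/SST variant is also reported as `r_squared_sse`). Calibration
metrics always come from a model fitted on all samples (Set 1+2). By
default the prediction set is scored by a model re-fitted on Set 1 only
(no leakage); `paper_mode=True` instead scores Set 2 with the
all-sample model, reproducing the common but leaky reporting protocol —
it changes only the prediction-set entries.

## 4. Assay math (`oleanir.assay`)

AUC_full = Σᵢ Fᵢ/F₁ (a constant n-reading curve gives exactly n);
AUC_simplified = F₁/Fₙ by default, with the reciprocal available via
`direction="end_over_start"` since the statistic is defined only up to
orientation. Trolox standard curves are OLS lines (fit in mM or µM;
µM-curve results are converted to mM), inverted as
`((response − blank − intercept)/slope) · dilution_factor`. Slopes
within 1e-12 (relative) of zero are rejected.

## 5. Limitations

- All empirical numbers in this repository are computed on synthetic
  data; they validate the *software chain*, not any instrument or
  laboratory claim.
- The generator's linearity is favourable to PLS; real leaf spectra
  contain nonlinear scatter and moisture effects that would lower RPD.
- Scatter normalisations (SNV/MSC) are mildly nonlinear in the
  concentrations even on noise-free synthetic spectra, which caps
  prediction R² slightly below 1 (observed ≈ 0.98–0.99 at n = 40).
- Independent lognormal compound profiles understate the collinearity
  of real phenolic co-regulation, making the correlation grid cleaner
  than field data would be.
- The RPD bands are conventions, not inferential statements; no
  uncertainty is attached to a single RPD value.
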