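# Methods

This document records the models, algorithms and numerical choices behind
`nmrsigex`. Notation: spectra live on a ppm axis `x` (stored descending,
processed ascending), intensities `y`, spectrometer frequency `F` in MHz.

## 1. Multiplet templates

A multiplet is parameterized by metabolite name, center shift (ppm),
coupling pattern (`singlet`, `doublet`, `triplet`, `quartet`,
`double_doublet`, or a sampled `raster` curve), J-couplings (Hz), proton
count `p`, optional relative peak intensities, and a chemical-shift
tolerance (default 0.005 ppm).

**Intensity conservation.** Raw peak intensities `y_i` are rescaled to

    h_i = p * y_i / sum_j y_j

so the multiplet's total intensity equals its proton count. For symmetric
patterns the `y_i` default to the binomial ratios; asymmetric ("leaning")
multiplets such as the citrate doublet supply measured ratios (e.g.
`y = (0.6, 0.4)`, `p = 2`, giving `h = (1.2, 0.8)`).

**Line shape.** Each peak is a unit-area Lorentzian of full width `w` Hz
(`w/F` ppm) centered at `center + offset/F`, where the offsets follow the
coupling pattern (doublet at ±J/2; double-doublet at (±J1 ± J2)/2, etc.).
Peak spacings therefore shrink in ppm as the field grows; template curves
evaluated on matched Hz grids at different fields coincide after the 1/F
area scaling. Raster multiplets store a measured segment, clipped at zero
and renormalized to area `p`.

Template libraries round-trip through CSV; the packaged catalogues hold 33
quantified metabolites at 400 MHz (44 multiplets) and two extra singlets
(betaine, choline) at 900 MHz that are excluded from classification so both
fields expose the same 33 features.

## 2. Synthetic cohort generator

The generator is the study's ground truth, not a physical simulator; its
scope is "plasma-like CPMG spectra with the artifacts the pipeline claims
to handle":

- **FIDs** are sums of damped complex exponentials: each multiplet peak at
  frequency `(ppm − 4.7) · F` Hz with amplitude `concentration × h_i` and
  decay `T2 = 0.35 s`; broad lipid resonances (nine classes, widths
  14–45 Hz), a TSP singlet at 0.015 ppm, residual water at 4.78 ppm, and
  2–3 very broad baseline humps. Complex white noise (SD 0.02/point) is
  added in the time domain.
- **Cohorts** draw per-sample concentrations log-normally around class
  means (CV 0.2); the case mean is the control mean times `exp(effect)`.
  Default effects perturb six metabolites and two lipid classes by
  |log 1.25|–|log 1.8|. Per-multiplet shift jitter is N(0, 0.002 ppm);
  per-sample calibration error N(0, 0.010 ppm); phase errors
  N(0, 20°)/N(0, 10°) (zero/first order).
- Determinism: one seed drives the design; per-sample substreams come from
  `SeedSequence([seed, i])`.

## 3. Pre-processing

Ordered stages (`preprocess_fid`): exponential apodization (1 Hz manual /
0.3 Hz automated), zero-filling to 2N and orthonormal FFT with first-point
halving, phasing, asymmetric-least-squares baseline correction, TSP
referencing, water/TSP exclusion, optional piecewise-linear warping
(automated protocol), and total-area normalization over unmasked points
(the constant is stored in `meta["norm_constant"]`).

- **Autophase** minimizes `sum(min(I,0)^2)` over (φ0, φ1) — a 15° grid on
  φ0 seeds Nelder-Mead. For clean sparse spectra this objective is exactly
  zero over a plateau of phase pairs (absorption tails and the FFT DC
  offset mask small dispersion lobes), so the individual angles are not
  identifiable there; the method guarantees objective optimality and
  intensity recovery, not exact angle recovery.
- **Baseline**: AsLS with asymmetry `p = 0.01` and smoothness `λ = 1e7`
  (manual) / `1e8` (automated), solved with a banded Cholesky.
- **TSP referencing** finds the apex in ±0.20 ppm (median/MAD SNR gate at
  5), refines it by parabolic interpolation, and translates the axis so the
  apex sits at 0.015 ppm.
- **Warping** estimates one integer shift per segment (64 segments) by
  windowed normalized cross-correlation against the full signal array,
  averages adjacent segment shifts into node shifts weighted by segment
  energy (signal-free segments carry no vote), enforces monotonicity and
  interpolates. The "after" policy picks the reference spectrum minimizing
  total post-warp SSD over a candidate subset.

## 4. Spectral binning

Features are trapezoid integrals over named half-open regions `[lo, hi)`;
masked (excluded) points contribute zero. Packaged tables: 110 regions at
400 MHz, 105 (manual-style) and 103 (automated-style) at 900 MHz, built
deterministically from the catalogue and lipid positions with water/TSP
gaps (`scripts/build_default_tables.py`).

## 5. Two-component deconvolution

Model: `y = X(δ) β + r + ε` with `β ≥ 0` the per-metabolite coefficients,
`X(δ)` the template curves shifted by per-multiplet offsets `|δ| ≤`
tolerance, and `r` a wavelet-sparse residual for everything the catalogue
does not describe (lipids, water remnants, baseline).

The MAP estimate minimizes

    0.5 ||y − Xβ − r||² + t ||W r||₁ ,  t = σ √(2 ln N)

by block-coordinate descent: (a) NNLS for `β`; (b) per-multiplet discrete
shift search (dot-product matching on the multiplet's window, ties toward
zero lag); (c) soft-thresholding of the db4 wavelet detail coefficients of
`y − Xβ` at level `log2(N) − 4` with the approximation left untouched
(universal threshold; `σ` from the signal-free 8.55–9.45 ppm window via the
MAD of first differences, falling back to the high-ppm axis edge). The
line width is refined over a small factor grid during the first two
iterations. Iteration stops when the relative objective change drops below
1e-6 or after 50 iterations; non-convergence is flagged in
`convergence["converged"]` and warned about. On realistic spectra the
objective decreases monotonically but geometrically slowly (the wavelet
and NNLS blocks exchange small corrections), so the 50-iteration cap is
usually reached; estimates at the cap are stable.

**Credible intervals.** Componentwise random-walk Metropolis on `β` with
the Gaussian likelihood (`σ` as above), a diffuse half-normal prior
truncating at zero, and optional grid moves of the shifts. Gram-matrix
updates make a sweep O(m²). Proposal scales follow the diagonal curvature
and adapt once after burn-in (first 20%); 95% intervals are the 2.5/97.5
percentiles. Empirical coverage on simulated fixtures is 90–98%.

**Diagnostics** report, per multiplet, the spectrum integral over the
multiplet window, the metabolite's own fitted integral, and a crowding
score (fraction of window signal from other templates plus residual).

## 6. Feature assembly

Deconvolution feature sets: `metabolites` (the 33 classification
coefficients), `lipids` (trapezoid integrals of the residual component over
9/10 broad lipid regions), or `both`. A warning flags lipid regions where
the metabolite fit's area exceeds 20% of the residual area
(contamination). Normalization can be undone via the stored constant.

## 7. Moderated t and repeated CV

The per-feature two-sample t uses empirical-Bayes variance shrinkage:
pooled variances `s_g²` (d degrees of freedom) are shrunk to
`(d0 s0² + d s_g²)/(d0 + d)` with `(d0, s0²)` fitted by method of moments
on `log s_g²` (the scaled-F prior; Newton inversion of the trigamma
function). `d0 = 0` recovers the ordinary t; `d0 = ∞` equalizes all
variances. The implementation agrees with the R/limma `eBayes` reference
(t, d0, s0², posterior variances) to ≤1e-4 relative.

Evaluation: stratified 3-fold CV repeated 333 times (999 fits). Selection
(for binning features: top-15 by |moderated t|) and classifier training see
training folds only; standardization happens inside the pipeline.
Reference classifier: elastic-net logistic regression (saga, l1_ratio 0.5,
inner CV over C ∈ {0.01, 0.1, 1, 10} with fold count adapting to the
smallest class); `lasso`, `logistic`, `random_forest`, `svm` and `plsda`
satisfy the same fit/predict_proba contract. Metrics per held-out fold:
error, sensitivity, specificity (case iff p > 0.5); summaries report mean
and SD/√n over fold records.

## 8. The study pipeline

`run_study` reproduces the five predictor-set comparison: binning at
400 MHz (manual protocol), deconvolution at 400 MHz (three sub-modes),
binning at 900 MHz (automated), deconvolution at 900 MHz (three
sub-modes), binning at 900 MHz (manual-style; no warping, 105 regions).
Seeds derive from one master seed via `SeedSequence`; the report carries
one row per feature set with fit counts and metric summaries, and
`provenance.json` records the config and its hash.

## 9. Known limitations

- The generator and the deconvolver share the Lorentzian line-shape family;
  real spectra contain shoulders and lineshape distortions the templates
  cannot absorb (they land in the residual and hence in lipid features).
- Autophase angles are unidentifiable on its objective's zero plateau
  (§3); phase quality should be judged by the spectrum, not the angles.
- The per-multiplet shift search is greedy and discrete (one axis step);
  strongly overlapping multiplets can lock into a joint local optimum.
- Credible intervals condition on the fitted residual component and the
  final shifts; they do not propagate wavelet-model uncertainty.
- The moderated-t selector assumes approximately independent features;
  heavily correlated bins inflate the effective selection pressure.
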