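# nmrsigex

Metabolic signal extraction from 1D ¹H-NMR blood-plasma spectra: classical
spectral binning versus two-component Bayesian template deconvolution, with
repeated cross-validated classification to compare the resulting feature
sets.

## The problem

A 1D ¹H-NMR spectrum of blood plasma is a superposition of two very
different signal classes: sharp multiplets from small-molecule metabolites
and broad, rolling resonances from lipoprotein lipids, plus residual water,
baseline drift, phase errors and chemical-shift jitter. The standard way to
turn such spectra into statistical features is *spectral binning* —
integrating the intensity over fixed ppm regions. Binning is robust but
confounds every signal that shares a region: a metabolite that goes up and a
co-resident metabolite that goes down can cancel inside one bin.

This package implements the alternative: a *two-component deconvolution*
that models each spectrum as a non-negative combination of parametric
metabolite multiplet templates (sharp Lorentzian lines with known positions,
J-couplings and intensity ratios) plus a free wavelet-regularized residual
that absorbs the broad lipid background. The fit alternates non-negative
least squares for the template coefficients, a per-multiplet chemical-shift
search within a small tolerance, and wavelet soft-thresholding of the
residual. Metabolite features are the fitted coefficients; lipid features
are integrals of the residual component over broad lipid regions. A
Metropolis sampler provides 95% credible intervals for the coefficients.

Multiplet templates respect the intensity-conservation rule: given raw peak
intensities `y` and a proton count `p`, the template peaks are scaled to
`h_i = p * y_i / sum(y_j)`, so every template integrates to its proton
count (e.g. the citrate doublet with `y = (0.6, 0.4)` and `p = 2` gives
`h = (1.2, 0.8)`).

Both feature sets are evaluated the same way: stratified 3-fold
cross-validation repeated 333 times (999 classifier fits) with an
elastic-net logistic regression, in-fold moderated-*t* feature selection
for binning features, and error / sensitivity / specificity summaries.

Everything runs against a synthetic plasma-spectrum generator with stored
ground truth (33-metabolite catalogue, nine lipid resonance classes, TSP
reference, residual water, baseline, phase errors, shift jitter, noise), so
every processing stage is testable against known answers.

## Worked example

```python
import numpy as np, pandas as pd
from nmrsigex import simulate, preprocess, deconvolve, binning

catalogue = simulate.build_catalogue(400.0)
acq = simulate.default_acquisition(400.0)
design = simulate.CohortDesign(n_cases=4, n_controls=4, seed=11)
truth = simulate.simulate_cohort(design, catalogue)
fids = simulate.cohort_fids(truth, catalogue, acq)
spectra = preprocess.preprocess_cohort(fids, labels=list(truth.labels),
                                       protocol="manual", warp=False)

fit = deconvolve.fit(spectra[0], catalogue.library)
sid = truth.sample_ids[0]
scale = np.median(fit.beta / truth.concentrations.loc[sid])  # spectra are
print(pd.DataFrame({"estimate": fit.beta / scale,            # area-normalized
                    "truth": truth.concentrations.loc[sid]}).head(6).round(3))

table = binning.default_region_table(400.0, "manual")
fm = binning.bin_cohort(spectra, table, sample_ids=truth.sample_ids,
                        labels=truth.labels)
print("binning features:", fm.values.shape)
```

Output:

```
            estimate  truth
alanine        0.589  0.578
arginine       0.141  0.136
asparagine     0.112  0.115
aspartate      0.067  0.067
cysteine       0.083  0.102
glutamine      0.437  0.444
binning features: (8, 110)
```

(Pre-processing normalizes each spectrum to unit area, so fitted
coefficients are relative; the `scale` line puts them back on the
generator's concentration scale for the comparison.)

On realistic spectra the alternating solver typically exhausts its 50
iterations before the relative objective change drops below 1e-6 and warns
that it returns the last iterate; the objective decreases monotonically and
the coefficient estimates are stable, so the warning is informational
(see `fit.convergence`).

## Command line

```
nmrsigex simulate   --field 400 --n-cases 69 --n-controls 74 --seed 0 --out cohort/
nmrsigex preprocess --manifest cohort/manifest.csv --protocol automated --out spectra/
nmrsigex bin        --manifest spectra/manifest.csv --out features.csv
nmrsigex decon      --manifest spectra/manifest.csv --out fits/
nmrsigex classify   --features features.csv --selector moderated_t_top_k --out cv/
nmrsigex study      --out study_out/          # the full five-predictor-set study
```

`nmrsigex study` reproduces the complete synthetic comparison: 400 and
900 MHz cohorts (69 cases / 74 controls), manual- and automated-style
pre-processing, binning (110 / 105 / 103 regions) and deconvolution
(metabolites, lipids, both) feature sets, each evaluated with the repeated
CV protocol; it writes `report.csv` with one row per feature set.

## Reproduction and tests

```
python -m pytest -q tests/                 # unit, property and acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the package's headline numeric targets
(the worked-example intensities 1.2 / 0.8 and the TSP referencing target
0.015 ppm) at runtime and writes them as JSON.

## Layout

- `src/nmrsigex/simulate.py` — synthetic plasma cohort generator with ground truth
- `src/nmrsigex/preprocess.py` — apodization, FFT, phasing, baseline, TSP referencing, exclusion, warping, normalization
- `src/nmrsigex/templates.py` — multiplet template library (Eq. above), CSV I/O
- `src/nmrsigex/deconvolve.py` — two-component fit, credible intervals, diagnostics
- `src/nmrsigex/binning.py` — integrated-spectral-region features
- `src/nmrsigex/features.py` — deconvolution feature assembly (metabolites + lipid residual integrals)
- `src/nmrsigex/classify.py` — moderated *t*, repeated stratified CV, classifiers
- `src/nmrsigex/pipeline.py` — the end-to-end five-predictor-set study
- `docs/methods.md` — model equations, algorithms and numerical choices
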