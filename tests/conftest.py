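"""Shared fixtures and spectrum-building helpers for the test suite."""
from __future__ import annotations

import numpy as np
import pytest

from nmrsigex.preprocess import Spectrum
from nmrsigex.templates import MultipletSpec, TemplateLibrary, build_template


def lorentzian(x: np.ndarray, center: float, fwhm: float,
               area: float = 1.0) -> np.ndarray:
    """Unit-area Lorentzian scaled by ``area`` on the given axis."""
    g = fwhm / 2.0
    return area * (g / np.pi) / ((x - center) ** 2 + g ** 2)


def make_spectrum(intensity_fn=None, lo: float = -0.5, hi: float = 10.0,
                  n: int = 8192, field_mhz: float = 400.0,
                  intensity: np.ndarray | None = None) -> Spectrum:
    """Spectrum on a uniform descending axis from a function of ascending ppm."""
    x_asc = np.linspace(lo, hi, n)
    if intensity is None:
        intensity = intensity_fn(x_asc) if intensity_fn is not None \
            else np.zeros(n)
    return Spectrum(ppm=x_asc[::-1].copy(), intensity=np.asarray(intensity)[::-1],
                    field_mhz=field_mhz)


def trapezoid_weights(x: np.ndarray) -> np.ndarray:
    w = np.empty_like(x)
    dx = np.diff(x)
    w[0] = dx[0] / 2
    w[-1] = dx[-1] / 2
    w[1:-1] = (dx[:-1] + dx[1:]) / 2
    return w


def singlet_library(centers, tolerance_ppm=0.005, protons=None) -> TemplateLibrary:
    """A library of singlet metabolites named m0, m1, ... at given centers."""
    protons = protons or [1] * len(centers)
    mult = [MultipletSpec(metabolite=f"m{i}", center_ppm=c, pattern="singlet",
                          protons=p, shift_tolerance_ppm=tolerance_ppm)
            for i, (c, p) in enumerate(zip(centers, protons))]
    return TemplateLibrary(multiplets=mult)


def template_design(library: TemplateLibrary, x_asc: np.ndarray,
                    field_mhz: float, fwhm_hz: float) -> np.ndarray:
    """Design matrix of per-metabolite template curves (ascending axis)."""
    cols = {}
    for m in library.multiplets:
        t = build_template(m, field_mhz, fwhm_hz, x_asc).intensity
        cols[m.metabolite] = cols.get(m.metabolite, 0) + t
    return np.column_stack([cols[n] for n in library.metabolites])


@pytest.fixture(scope="session")
def catalogue_400():
    from nmrsigex.simulate import build_catalogue
    return build_catalogue(400.0)


@pytest.fixture(scope="session")
def catalogue_900():
    from nmrsigex.simulate import build_catalogue
    return build_catalogue(900.0)


@pytest.fixture(scope="session")
def small_cohort():
    """A 3-case/3-control 400 MHz cohort with FIDs (reduced FID length)."""
    from nmrsigex import simulate
    catalogue = simulate.build_catalogue(400.0)
    acq = simulate.default_acquisition(400.0, n_points=4096)
    design = simulate.CohortDesign(n_cases=3, n_controls=3, seed=7)
    truth = simulate.simulate_cohort(design, catalogue)
    fids = simulate.cohort_fids(truth, catalogue, acq)
    return catalogue, acq, truth, fids


@pytest.fixture(scope="session")
def small_cohort_spectra(small_cohort):
    from nmrsigex import preprocess
    catalogue, acq, truth, fids = small_cohort
    spectra = preprocess.preprocess_cohort(
        fids, labels=list(truth.labels), protocol="manual", warp=False)
    return catalogue, acq, truth, spectra
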