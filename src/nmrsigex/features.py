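"""Classifier-ready features from deconvolution fits.

Relative metabolite concentrations come straight from the fitted template
coefficients; lipid features are integrals of the residual (wavelet)
component over broad regions covering the standard plasma lipid resonance
classes.  Those regions are deliberately wider than binning regions: they
target broad humps the template library does not catalogue.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binning import FeatureMatrix
from .deconvolve import DeconFit
from .templates import TemplateLibrary

__all__ = ["LipidRegionTable", "load_lipid_table", "default_lipid_table",
           "integrate_residual", "assemble_features"]

_PACKAGED_LIPIDS = {400.0: "lipid_regions_400.csv", 900.0: "lipid_regions_900.csv"}


@dataclass
class LipidRegionTable:
    """Broad, non-overlapping integration regions for lipid resonances."""

    table: pd.DataFrame  # lipid_id, resonance_label, ppm_lo, ppm_hi

    def __post_init__(self) -> None:
        df = self.table
        for c in ("lipid_id", "ppm_lo", "ppm_hi"):
            if c not in df.columns:
                raise ValueError(f"lipid table missing column {c!r}")
        if (df.ppm_lo >= df.ppm_hi).any():
            raise ValueError("lipid region with inverted bounds")
        df = df.sort_values("ppm_lo").reset_index(drop=True)
        if (df.ppm_lo.values[1:] < df.ppm_hi.values[:-1] - 1e-12).any():
            raise ValueError("overlapping lipid regions")
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    @property
    def lipid_ids(self) -> list[str]:
        return list(self.table.lipid_id)


def load_lipid_table(path: str | Path) -> LipidRegionTable:
    return LipidRegionTable(pd.read_csv(path))


def default_lipid_table(field_mhz: float) -> LipidRegionTable:
    """Packaged lipid regions: 9 at 400 MHz, 10 at 900 MHz."""
    if float(field_mhz) not in _PACKAGED_LIPIDS:
        raise ValueError(f"no packaged lipid table for {field_mhz} MHz")
    ref = resources.files("nmrsigex").joinpath("data",
                                               _PACKAGED_LIPIDS[float(field_mhz)])
    with resources.as_file(ref) as p:
        return load_lipid_table(p)


def integrate_residual(decon_fit: DeconFit, lipid_table: LipidRegionTable,
                       contamination_warn: float = 0.20) -> pd.Series:
    """Trapezoid integral of the residual component over each lipid region.

    Warns when the metabolite fit's area inside a region exceeds the given
    fraction of the residual area there — imperfectly extracted metabolite
    peaks contaminate the lipid estimate in that case.
    """
    x = decon_fit.ppm[::-1]
    resid = decon_fit.residual_fit[::-1]
    metab = decon_fit.metabolite_fit[::-1]
    out = {}
    for _, row in lipid_table.table.iterrows():
        lo, hi = row.ppm_lo, row.ppm_hi
        if hi <= x[0] or lo >= x[-1]:
            raise ValueError(f"lipid region {row.lipid_id!r} outside the axis")
        sel = (x >= lo) & (x < hi)
        r_area = float(np.trapezoid(resid[sel], x[sel]))
        m_area = float(np.trapezoid(metab[sel], x[sel]))
        if m_area > contamination_warn * max(abs(r_area), 1e-30):
            warnings.warn(
                f"lipid region {row.lipid_id!r}: metabolite fit area "
                f"({m_area:.3g}) exceeds {contamination_warn:.0%} of the "
                f"residual area ({r_area:.3g}); possible contamination")
        out[str(row.lipid_id)] = r_area
    return pd.Series(out)


def assemble_features(fits: Mapping[str, DeconFit], mode: str,
                      library: TemplateLibrary,
                      lipid_table: LipidRegionTable | None = None,
                      labels: Mapping[str, str] | pd.Series | None = None,
                      undo_normalization: bool = False) -> FeatureMatrix:
    """Assemble the deconvolution feature matrix for a fitted cohort.

    ``mode`` is "metabolites", "lipids" or "both".  Metabolites flagged as
    excluded from classification (e.g. betaine/choline in the 900 MHz
    catalogue) are dropped.  With ``undo_normalization`` the stored
    spectrum-level normalization constant is multiplied back in.
    """
    if mode not in ("metabolites", "lipids", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    keep = library.classification_metabolites
    rows = {}
    for sid, f in fits.items():
        if f is None:
            raise ValueError(f"missing fit for sample {sid!r}")
        parts = []
        if mode in ("metabolites", "both"):
            parts.append(f.beta.reindex(keep))
        if mode in ("lipids", "both"):
            if lipid_table is None:
                raise ValueError("lipid mode requires a lipid region table")
            parts.append(integrate_residual(f, lipid_table))
        vec = pd.concat(parts)
        if undo_normalization:
            vec = vec * f.norm_constant
        rows[sid] = vec
    values = pd.DataFrame(rows).T
    lab = None
    if labels is not None:
        lab = pd.Series(labels).reindex(values.index)
    return FeatureMatrix(values=values, labels=lab, provenance="deconvolution")
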