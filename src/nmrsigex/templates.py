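"""Prior template library for metabolite spectral signatures.

Each metabolite is described by one or more multiplets.  A multiplet is either
parametric — a first-order J-coupling pattern (singlet, doublet, triplet,
quartet, double doublet) whose peak offsets in Hz follow from the coupling
constants — or a *raster* multiplet, a non-parametric curve taken from a pure
(or spiked) compound spectrum.  Second-order roofing/leaning is captured
empirically by per-peak relative intensities normalized to sum to the number
of resonating protons.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MultipletSpec",
    "TemplateCurve",
    "TemplateLibrary",
    "relative_intensities",
    "pattern_offsets",
    "build_template",
    "load_raster",
    "read_template_csv",
    "write_template_csv",
]

PATTERNS = ("singlet", "doublet", "triplet", "quartet", "double_doublet", "raster")

#: number of J constants each first-order pattern requires
_N_J = {"singlet": 0, "doublet": 1, "triplet": 1, "quartet": 1, "double_doublet": 2}

#: default local-displacement tolerance for fitted multiplet positions, by field
DEFAULT_SHIFT_TOLERANCE_PPM = {400.0: 0.005, 900.0: 0.003}

#: default Lorentzian full width at half maximum of the template peaks, by field
DEFAULT_FWHM_HZ = {400.0: 1.5, 900.0: 1.0}


def relative_intensities(y: Sequence[float], p: int) -> np.ndarray:
    """Normalize observed peak intensities to sum to the proton count.

    ``h_i = p * y_i / sum_j y_j`` — the empirical relative intensities used to
    encode roofing/leaning within a multiplet.  The observed intensities ``y``
    come from pure-compound (or baseline-corrected spiked) spectra; ``p`` is
    the number of protons resonating in the multiplet.

    >>> relative_intensities([0.6, 0.4], p=2)
    array([1.2, 0.8])
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("y must be a non-empty 1-D sequence of intensities")
    if np.any(y <= 0):
        raise ValueError("all observed peak intensities must be positive")
    if not (isinstance(p, (int, np.integer)) and p >= 1):
        raise ValueError(f"proton count must be a positive integer, got {p!r}")
    return p * y / y.sum()


def pattern_offsets(pattern: str, J_hz: Sequence[float] | float | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Peak offsets (Hz, ascending) and default intensity ratios for a pattern.

    Offsets are measured from the multiplet center.  Ratios are fractions of
    the multiplet's total intensity (they sum to 1); multiply by the proton
    count to obtain default relative intensities.  For a double doublet with
    constants (J1, J2) the outer peaks sit at ±(J1+J2)/2 and the inner peaks
    at ±|J1−J2|/2.
    """
    if pattern == "raster":
        raise ValueError("raster multiplets carry an explicit curve, not offsets")
    if pattern not in _N_J:
        raise ValueError(f"unknown pattern {pattern!r}")
    J = np.atleast_1d(np.asarray(J_hz if J_hz is not None else [], dtype=float))
    if J.size != _N_J[pattern]:
        raise ValueError(
            f"pattern {pattern!r} needs {_N_J[pattern]} J constant(s), got {J.size}")
    if pattern == "singlet":
        return np.array([0.0]), np.array([1.0])
    if pattern == "doublet":
        j = J[0]
        return np.array([-j / 2, j / 2]), np.array([0.5, 0.5])
    if pattern == "triplet":
        j = J[0]
        return np.array([-j, 0.0, j]), np.array([0.25, 0.5, 0.25])
    if pattern == "quartet":
        j = J[0]
        return (np.array([-1.5 * j, -0.5 * j, 0.5 * j, 1.5 * j]),
                np.array([0.125, 0.375, 0.375, 0.125]))
    # double_doublet
    j1, j2 = float(J[0]), float(J[1])
    outer, inner = (j1 + j2) / 2, abs(j1 - j2) / 2
    return (np.array([-outer, -inner, inner, outer]),
            np.array([0.25, 0.25, 0.25, 0.25]))


@dataclass
class MultipletSpec:
    """Prior description of one multiplet of one metabolite."""

    metabolite: str
    center_ppm: float
    pattern: str
    J_hz: tuple[float, ...] = ()
    protons: int = 1
    rel_intensities: tuple[float, ...] | None = None  # sum = protons
    raster: tuple[np.ndarray, np.ndarray] | None = None  # (ppm asc, intensity)
    shift_tolerance_ppm: float = 0.005
    multiplet_id: str = ""

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.protons < 1:
            raise ValueError("proton count must be >= 1")
        if self.pattern == "raster":
            if self.raster is None:
                raise ValueError("raster pattern requires a raster curve")
        else:
            if self.raster is not None:
                raise ValueError("raster curve only allowed for pattern='raster'")
            offs, ratios = pattern_offsets(self.pattern, self.J_hz)
            if self.rel_intensities is None:
                self.rel_intensities = tuple(ratios * self.protons)
            h = np.asarray(self.rel_intensities, float)
            if h.size != offs.size:
                raise ValueError(
                    f"{self.metabolite}: {h.size} relative intensities for a "
                    f"{self.pattern} with {offs.size} peaks")
            if abs(h.sum() - self.protons) > 1e-6:
                raise ValueError(
                    f"{self.metabolite}: relative intensities sum to {h.sum():g}, "
                    f"expected proton count {self.protons}")
        if not self.multiplet_id:
            self.multiplet_id = f"{self.metabolite}_{self.center_ppm:.3f}"

    @property
    def offsets_hz(self) -> np.ndarray:
        """Peak offsets from the multiplet center, in Hz (ascending)."""
        if self.pattern == "raster":
            raise ValueError("raster multiplets have no parametric offsets")
        return pattern_offsets(self.pattern, self.J_hz)[0]

    def peak_ppm(self, field_mhz: float) -> np.ndarray:
        """Peak positions in ppm at the given field strength."""
        if self.pattern == "raster":
            ppm, inten = self.raster
            return np.array([ppm[np.argmax(inten)]])
        return self.center_ppm + self.offsets_hz / field_mhz

    def span_ppm(self, field_mhz: float, fwhm_hz: float = 1.5) -> tuple[float, float]:
        """(lo, hi) ppm extent of the multiplet including a linewidth margin."""
        if self.pattern == "raster":
            ppm, _ = self.raster
            return float(ppm[0]), float(ppm[-1])
        pk = self.peak_ppm(field_mhz)
        margin = 2.0 * fwhm_hz / field_mhz
        return float(pk.min() - margin), float(pk.max() + margin)


@dataclass
class TemplateCurve:
    """A multiplet signature discretized on a ppm grid, total area = protons."""

    ppm: np.ndarray  # ascending
    intensity: np.ndarray
    source: str = "parametric"  # or "raster"

    def area(self) -> float:
        return float(np.trapezoid(self.intensity, self.ppm))


def build_template(spec: MultipletSpec, field_mhz: float, fwhm_hz: float,
                   ppm_grid: np.ndarray) -> TemplateCurve:
    """Discretize a parametric multiplet as a sum of Lorentzians.

    Peaks sit at ``center_ppm + offset/field_mhz``; heights are proportional
    to the relative intensities; every peak has the same FWHM (in Hz).  The
    curve is rescaled so its trapezoid area on the grid equals the proton
    count exactly (analytic Lorentzian tails extend beyond any finite grid).
    """
    grid = np.asarray(ppm_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("ppm_grid must be a 1-D array with >= 2 points")
    asc = grid[0] < grid[-1]
    x = grid if asc else grid[::-1]
    if spec.pattern == "raster":
        return _raster_on_grid(spec, x, asc)
    peaks = spec.center_ppm + spec.offsets_hz / field_mhz
    if peaks.min() < x[0] or peaks.max() > x[-1]:
        raise ValueError(
            f"{spec.multiplet_id}: peaks at {peaks} ppm fall outside the grid "
            f"[{x[0]:.3f}, {x[-1]:.3f}]")
    gamma = (fwhm_hz / 2.0) / field_mhz  # half width at half max, ppm
    h = np.asarray(spec.rel_intensities, float)
    y = np.zeros_like(x)
    for c, hi in zip(peaks, h):
        y += hi * (gamma / np.pi) / ((x - c) ** 2 + gamma ** 2)
    area = np.trapezoid(y, x)
    if area <= 0:
        raise ValueError(f"{spec.multiplet_id}: degenerate template (zero area)")
    y *= spec.protons / area
    y_out = y if asc else y[::-1]
    return TemplateCurve(ppm=grid.copy(), intensity=y_out, source="parametric")


def _raster_on_grid(spec: MultipletSpec, x_asc: np.ndarray, asc: bool) -> TemplateCurve:
    ppm, inten = spec.raster
    y = np.interp(x_asc, ppm, np.clip(inten, 0.0, None), left=0.0, right=0.0)
    area = np.trapezoid(y, x_asc)
    if area <= 0:
        raise ValueError(f"{spec.multiplet_id}: raster segment has zero area on grid")
    y *= spec.protons / area
    grid = x_asc if asc else x_asc[::-1]
    return TemplateCurve(ppm=grid.copy(), intensity=y if asc else y[::-1],
                         source="raster")


def load_raster(segment_ppm: np.ndarray, segment_intensity: np.ndarray,
                ppm_window: tuple[float, float], p: int, *,
                metabolite: str = "raster", shift_tolerance_ppm: float = 0.005
                ) -> MultipletSpec:
    """Build a raster multiplet from a baseline-corrected spectrum segment.

    The segment is restricted to ``ppm_window``, clipped at zero, and rescaled
    so its area equals the proton count ``p``.  Pure-compound spectra are the
    ideal source; baseline-corrected spiked spectra are an accepted substitute
    for multiplets in regions free of overlap.
    """
    ppm = np.asarray(segment_ppm, float)
    inten = np.asarray(segment_intensity, float)
    if ppm.size != inten.size:
        raise ValueError("segment ppm and intensity lengths differ")
    if ppm[0] > ppm[-1]:
        ppm, inten = ppm[::-1], inten[::-1]
    lo, hi = min(ppm_window), max(ppm_window)
    sel = (ppm >= lo) & (ppm <= hi)
    if sel.sum() < 3:
        raise ValueError("ppm_window selects fewer than 3 segment points")
    xs, ys = ppm[sel], np.clip(inten[sel], 0.0, None)
    area = np.trapezoid(ys, xs)
    if area <= 0:
        raise ValueError("segment is all-zero (or negative) inside the window")
    ys = ys * (p / area)
    center = float(xs[np.argmax(ys)])
    return MultipletSpec(metabolite=metabolite, center_ppm=center, pattern="raster",
                         protons=p, raster=(xs.copy(), ys),
                         shift_tolerance_ppm=shift_tolerance_ppm)


@dataclass
class TemplateLibrary:
    """All multiplets for a set of target metabolites."""

    multiplets: list[MultipletSpec] = field(default_factory=list)
    excluded_from_classification: frozenset[str] = frozenset()

    @property
    def metabolites(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.multiplets:
            seen.setdefault(m.metabolite, None)
        return list(seen)

    @property
    def classification_metabolites(self) -> list[str]:
        return [m for m in self.metabolites
                if m not in self.excluded_from_classification]

    def for_metabolite(self, name: str) -> list[MultipletSpec]:
        out = [m for m in self.multiplets if m.metabolite == name]
        if not out:
            raise KeyError(f"metabolite {name!r} not in library")
        return out

    def protons_total(self, name: str) -> int:
        return sum(m.protons for m in self.for_metabolite(name))

    def subset(self, names: Iterable[str]) -> "TemplateLibrary":
        names = set(names)
        return TemplateLibrary(
            multiplets=[replace(m) for m in self.multiplets if m.metabolite in names],
            excluded_from_classification=self.excluded_from_classification & names,
        )


_CSV_COLUMNS = ["metabolite", "multiplet_id", "center_ppm", "pattern", "J_hz",
                "protons", "rel_intensities", "raster_file",
                "shift_tolerance_ppm", "exclude_from_classification"]


def _semi_join(values: Iterable[float] | None) -> str:
    if values is None:
        return ""
    return ";".join(f"{v:.10g}" for v in values)


def _semi_split(text) -> tuple[float, ...]:
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return ()
    return tuple(float(v) for v in str(text).split(";"))


def write_template_csv(lib: TemplateLibrary, path: str | Path) -> None:
    """Write a template library in the package's CSV dialect."""
    path = Path(path)
    rows = []
    for m in lib.multiplets:
        raster_file = ""
        if m.pattern == "raster":
            raster_file = f"{m.multiplet_id}.raster.csv"
            rp, ri = m.raster
            pd.DataFrame({"ppm": rp, "intensity": ri}).to_csv(
                path.parent / raster_file, index=False)
        rows.append({
            "metabolite": m.metabolite,
            "multiplet_id": m.multiplet_id,
            "center_ppm": m.center_ppm,
            "pattern": m.pattern,
            "J_hz": _semi_join(m.J_hz),
            "protons": m.protons,
            "rel_intensities": _semi_join(m.rel_intensities),
            "raster_file": raster_file,
            "shift_tolerance_ppm": m.shift_tolerance_ppm,
            "exclude_from_classification":
                m.metabolite in lib.excluded_from_classification,
        })
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_template_csv(path_or_buffer) -> TemplateLibrary:
    """Read a template library; validation errors name the offending row."""
    if isinstance(path_or_buffer, (str, Path)):
        base = Path(path_or_buffer).parent
        df = pd.read_csv(path_or_buffer)
    else:
        base = Path(".")
        df = pd.read_csv(path_or_buffer)
    missing = [c for c in _CSV_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"template CSV missing columns: {missing}")
    multiplets: list[MultipletSpec] = []
    excluded: set[str] = set()
    for idx, row in df.iterrows():
        try:
            pattern = str(row["pattern"])
            raster = None
            if pattern == "raster":
                rf = row.get("raster_file", "")
                if not isinstance(rf, str) or not rf:
                    raise ValueError("raster row lacks raster_file")
                rdf = pd.read_csv(base / rf)
                raster = (rdf["ppm"].to_numpy(float),
                          rdf["intensity"].to_numpy(float))
            rel = _semi_split(row.get("rel_intensities"))
            tol = row.get("shift_tolerance_ppm", 0.005)
            if tol is None or (isinstance(tol, float) and np.isnan(tol)):
                tol = 0.005
            spec = MultipletSpec(
                metabolite=str(row["metabolite"]),
                multiplet_id=str(row.get("multiplet_id") or ""),
                center_ppm=float(row["center_ppm"]),
                pattern=pattern,
                J_hz=_semi_split(row.get("J_hz")),
                protons=int(row["protons"]),
                rel_intensities=rel or None,
                raster=raster,
                shift_tolerance_ppm=float(tol),
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"template CSV row {idx + 2}: {exc}") from exc
        multiplets.append(spec)
        flag = row.get("exclude_from_classification", False)
        if isinstance(flag, str):
            flag = flag.strip().lower() in ("true", "1", "yes")
        if bool(flag) and not (isinstance(flag, float) and np.isnan(flag)):
            excluded.add(spec.metabolite)
    return TemplateLibrary(multiplets=multiplets,
                           excluded_from_classification=frozenset(excluded))
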