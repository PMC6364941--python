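"""Pre-processing of 1D 1H-NMR free induction decays into analysis-ready spectra.

Two protocol flavours are supported, mirroring common practice for plasma
spectra:

* a *manual-style* protocol — apodization, zero-filling, Fourier transform,
  phasing, baseline correction, TSP referencing, total-area normalization
  (water and TSP regions excluded from the area);
* an *automated-style* protocol — the same front end with automatic phasing,
  asymmetric-least-squares baseline correction (asymmetry 0.01), piecewise
  warping alignment of the cohort, and median normalization.

The ppm axis is stored in the conventional descending order: chemical shift
is the resonance frequency offset from the reference compound divided by the
reference frequency.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solveh_banded
from scipy.optimize import minimize

__all__ = [
    "Fid", "Spectrum", "PreprocessConfig",
    "apodize", "zero_fill_transform", "phase_correct", "autophase",
    "baseline_correct", "reference_to_tsp", "exclude_regions",
    "warp_align", "normalize", "preprocess_fid", "preprocess_cohort",
    "read_fid", "write_fid", "read_spectrum", "write_spectrum",
]


@dataclass
class Fid:
    """Time-domain complex NMR signal with acquisition metadata."""

    samples: np.ndarray          # complex
    dwell_s: float               # sampling interval (s)
    field_mhz: float             # spectrometer proton frequency
    ref_offset_hz: float = 0.0   # carrier offset from the 0-ppm reference (Hz)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("FID needs at least two complex samples")
        if self.dwell_s <= 0:
            raise ValueError("dwell time must be positive")
        if self.field_mhz <= 0:
            raise ValueError("field strength must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dwell_s

    @property
    def spectral_width_hz(self) -> float:
        return 1.0 / self.dwell_s


@dataclass
class Spectrum:
    """Frequency-domain spectrum on a strictly descending ppm axis."""

    ppm: np.ndarray
    intensity: np.ndarray
    field_mhz: float
    complex_data: np.ndarray | None = None   # retained until phasing is final
    mask: np.ndarray | None = None           # True = excluded point
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.size != self.intensity.size:
            raise ValueError("ppm and intensity lengths differ")
        if self.ppm.size < 2 or not np.all(np.diff(self.ppm) < 0):
            raise ValueError("ppm axis must be strictly decreasing")
        if self.mask is None:
            self.mask = np.zeros(self.ppm.size, dtype=bool)
        self.meta.setdefault("history", [])

    def _log(self, step: str) -> None:
        self.meta["history"].append(step)

    @property
    def step_ppm(self) -> float:
        """Median axis spacing (positive)."""
        return float(np.median(-np.diff(self.ppm)))

    def ascending(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(ppm, intensity, mask) views in ascending ppm order."""
        return self.ppm[::-1], self.intensity[::-1], self.mask[::-1]

    def copy(self) -> "Spectrum":
        return Spectrum(
            ppm=self.ppm.copy(), intensity=self.intensity.copy(),
            field_mhz=self.field_mhz,
            complex_data=None if self.complex_data is None else self.complex_data.copy(),
            mask=self.mask.copy(),
            meta={**self.meta, "history": list(self.meta["history"])})


@dataclass
class PreprocessConfig:
    """Tunable parameters of the pre-processing protocols."""

    lb_hz: float = 0.7
    zero_fill_to: int | None = None          # default: next pow2 >= 2x length
    baseline_asymmetry: float = 0.01
    baseline_smoothness: float = 1e7
    water_window_ppm: tuple[float, float] = (4.50, 5.10)
    tsp_window_ppm: tuple[float, float] = (-0.20, 0.20)
    tsp_target_ppm: float = 0.015
    normalization: Literal["total_area_excluding", "median"] = "total_area_excluding"
    warp_reference_policy: Literal["after", "fixed"] = "after"
    warp_segments: int = 64
    warp_max_shift_ppm: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.baseline_asymmetry < 1:
            raise ValueError("baseline asymmetry must lie in (0, 1)")


# ---------------------------------------------------------------- operations

def apodize(fid: Fid, lb_hz: float) -> Fid:
    """Exponential line broadening: sample k scaled by exp(-pi*lb*t_k)."""
    if lb_hz < 0:
        raise ValueError("line broadening must be >= 0")
    out = replace(fid, samples=fid.samples * np.exp(-np.pi * lb_hz * fid.times),
                  meta={**fid.meta, "lb_hz": lb_hz})
    return out


def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def zero_fill_transform(fid: Fid, zero_fill_to: int | None = None) -> Spectrum:
    """Zero-fill, Fourier transform and map the frequency axis to ppm.

    Uses the unitary (norm="ortho") FFT so energy is preserved.  The first
    FID point is halved, the standard correction for the half-sample offset
    of the discrete transform.  ppm = (f + carrier offset)/field.
    """
    n = fid.samples.size
    target = zero_fill_to if zero_fill_to is not None else _next_pow2(2 * n)
    if target < n:
        raise ValueError(f"zero_fill_to={target} < FID length {n}")
    if target & (target - 1):
        raise ValueError("zero_fill_to must be a power of two")
    padded = np.zeros(target, dtype=complex)
    padded[:n] = fid.samples
    padded[0] *= 0.5
    spec = np.fft.fftshift(np.fft.fft(padded, norm="ortho"))
    freqs = np.fft.fftshift(np.fft.fftfreq(target, d=fid.dwell_s))
    ppm = (freqs + fid.ref_offset_hz) / fid.field_mhz
    # descending ppm order
    out = Spectrum(ppm=ppm[::-1], intensity=spec.real[::-1],
                   field_mhz=fid.field_mhz, complex_data=spec[::-1],
                   meta={"history": [], "dwell_s": fid.dwell_s,
                         "ref_offset_hz": fid.ref_offset_hz})
    out._log(f"zero_fill_transform(n={n}->{target})")
    return out


def phase_correct(spectrum: Spectrum, phi0_deg: float, phi1_deg: float,
                  pivot_ppm: float | None = None) -> Spectrum:
    """Apply zero/first-order phase: S * exp(-i(phi0 + phi1*(x-pivot)/span))."""
    if spectrum.complex_data is None:
        raise ValueError("spectrum no longer holds a complex representation")
    out = spectrum.copy()
    x = out.ppm
    pivot = float(np.mean(x)) if pivot_ppm is None else pivot_ppm
    span = x[0] - x[-1]
    phi = np.deg2rad(phi0_deg) + np.deg2rad(phi1_deg) * (x - pivot) / span
    out.complex_data = out.complex_data * np.exp(-1j * phi)
    out.intensity = out.complex_data.real
    out._log(f"phase_correct(phi0={phi0_deg:.2f}, phi1={phi1_deg:.2f})")
    return out


def _negativity(spectrum: Spectrum, phi0: float, phi1: float) -> float:
    x = spectrum.ppm
    span = x[0] - x[-1]
    pivot = float(np.mean(x))
    phi = np.deg2rad(phi0) + np.deg2rad(phi1) * (x - pivot) / span
    re = (spectrum.complex_data * np.exp(-1j * phi)).real
    neg = np.minimum(re, 0.0)
    return float(np.dot(neg, neg))


def autophase(spectrum: Spectrum) -> tuple[Spectrum, float, float]:
    """Automatic phasing by minimizing the squared negative-intensity penalty.

    A coarse grid over the zero-order angle seeds a Nelder-Mead refinement of
    (phi0, phi1).  Returns the phased spectrum and the angles found.
    """
    if spectrum.complex_data is None:
        raise ValueError("spectrum no longer holds a complex representation")
    best = None
    for p0 in range(0, 360, 15):
        v = _negativity(spectrum, p0, 0.0)
        if best is None or v < best[0]:
            best = (v, float(p0))
    res = minimize(lambda q: _negativity(spectrum, q[0], q[1]),
                   x0=[best[1], 0.0], method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-12, "maxiter": 2000})
    if not res.success:
        warnings.warn("autophase did not fully converge; using best iterate")
    phi0, phi1 = float(res.x[0]), float(res.x[1])
    phi0 %= 360.0
    return phase_correct(spectrum, phi0, phi1), phi0, phi1


def _asls_baseline(y: np.ndarray, lam: float, p: float,
                   max_iter: int = 30, tol: float = 1e-6) -> np.ndarray:
    """Asymmetric least squares baseline (banded Cholesky solver).

    Minimizes sum w_i (y_i - b_i)^2 + lam * sum (d2 b)^2 with w_i = p where
    y > b and 1-p where y <= b, iterating the weights to convergence.
    """
    n = y.size
    w = np.ones(n)
    # banded representation of lam * D2'D2 (pentadiagonal, symmetric)
    ab0 = np.full(n, 6.0 * lam)
    ab0[[0, -1]] = lam
    ab0[[1, -2]] = 5.0 * lam
    ab1 = np.full(n - 1, -4.0 * lam)
    ab1[[0, -1]] = -2.0 * lam
    ab2 = np.full(n - 2, lam)
    b = y.copy()
    for _ in range(max_iter):
        ab = np.zeros((3, n))
        ab[0, 2:] = ab2
        ab[1, 1:] = ab1
        ab[2, :] = ab0 + w
        b = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > b, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        if np.mean(w_new != w) < tol:
            w = w_new
            break
        w = w_new
    else:
        warnings.warn("AsLS baseline did not converge; returning last iterate")
    return b


def baseline_correct(spectrum: Spectrum, asymmetry: float = 0.01,
                     smoothness: float = 1e7) -> Spectrum:
    """Asymmetric-least-squares baseline removal.

    A small asymmetry (default 0.01) treats points above the baseline as
    signal, keeping the number of negative points after subtraction small.
    The fraction of negative points is recorded in the processing history.
    """
    if not 0 < asymmetry < 1:
        raise ValueError("asymmetry must lie in (0, 1)")
    out = spectrum.copy()
    b = _asls_baseline(out.intensity, smoothness, asymmetry)
    out.intensity = out.intensity - b
    if out.complex_data is not None:
        out.complex_data = out.complex_data - b  # real baseline model
    neg_frac = float(np.mean(out.intensity < 0))
    out.meta["baseline_negative_fraction"] = neg_frac
    out.meta["baseline"] = b
    out._log(f"baseline_correct(asym={asymmetry}, lam={smoothness:g}, "
             f"neg_frac={neg_frac:.4f})")
    return out


def reference_to_tsp(spectrum: Spectrum, tsp_target_ppm: float = 0.015,
                     search_window_ppm: tuple[float, float] = (-0.20, 0.20),
                     snr_threshold: float = 5.0) -> Spectrum:
    """Translate the ppm axis so the TSP apex sits at the target shift.

    The apex is located as the maximum in the search window, refined by
    parabolic interpolation of the three points around it.
    """
    lo, hi = min(search_window_ppm), max(search_window_ppm)
    sel = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    if sel.sum() < 3:
        raise ValueError("TSP search window contains fewer than 3 points")
    idx = np.flatnonzero(sel)
    seg = spectrum.intensity[idx]
    med = np.median(seg)
    mad = np.median(np.abs(seg - med)) * 1.4826 + 1e-30
    k = int(np.argmax(seg))
    if (seg[k] - med) / mad < snr_threshold:
        raise ValueError("no peak apex above the noise threshold in the TSP window")
    j = idx[k]
    apex = spectrum.ppm[j]
    if 0 < j < spectrum.ppm.size - 1:
        y0, y1, y2 = spectrum.intensity[j - 1], spectrum.intensity[j], spectrum.intensity[j + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            delta = 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            apex = apex + delta * (spectrum.ppm[j + 1] - spectrum.ppm[j])
    shift = tsp_target_ppm - apex
    out = spectrum.copy()
    out.ppm = out.ppm + shift
    out.meta["tsp_shift_ppm"] = float(shift)
    out._log(f"reference_to_tsp(apex={apex:.5f}, shift={shift:+.5f})")
    return out


def exclude_regions(spectrum: Spectrum,
                    windows: Sequence[tuple[float, float]]) -> Spectrum:
    """Mask points inside the given ppm windows (e.g. water and TSP).

    Masked points are excluded from normalization and from binning.
    """
    out = spectrum.copy()
    for win in windows:
        lo, hi = min(win), max(win)
        out.mask |= (out.ppm >= lo) & (out.ppm <= hi)
    if out.mask.all():
        raise ValueError("exclusion windows cover the whole axis")
    if windows:
        out._log(f"exclude_regions({list(windows)!r})")
    return out


# ------------------------------------------------------------------- warping

def _segment_shift(ref: np.ndarray, sig: np.ndarray, i0: int, i1: int,
                   max_lag: int) -> int:
    """Integer lag (|lag| <= max_lag) maximizing windowed correlation.

    The window [i0, i1) is taken on the reference while the signal is
    sampled from the full array, so features sitting on a window boundary
    are not truncated away at nonzero lags.
    """
    best_lag, best_val = 0, -np.inf
    n = ref.size
    for lag in range(-max_lag, max_lag + 1):
        j0 = max(i0, lag)
        j1 = min(i1, n + lag)
        if j1 - j0 < 8:
            continue
        b = sig[j0 - lag:j1 - lag]
        bb = float(np.dot(b, b))
        if bb == 0.0:
            continue
        # normalized correlation: an unnormalized dot would reward pulling
        # a tall feature from just outside the window into it
        val = float(np.dot(ref[j0:j1], b)) / np.sqrt(bb)
        if val > best_val or (val == best_val and abs(lag) < abs(best_lag)):
            best_val, best_lag = val, lag
    return best_lag


def _warp_to_reference(ref: Spectrum, spec: Spectrum, n_segments: int,
                       max_shift_ppm: float) -> Spectrum:
    """Warp `spec` onto `ref` with a piecewise-linear monotone ppm map."""
    x_asc = ref.ppm[::-1]
    y_ref = ref.intensity[::-1]
    y_sig = spec.intensity[::-1]
    n = x_asc.size
    step = float(np.median(np.diff(x_asc)))
    max_lag = max(1, int(round(max_shift_ppm / step)))
    bounds = np.linspace(0, n, n_segments + 1).astype(int)
    seg_shift = np.zeros(n_segments)
    seg_weight = np.zeros(n_segments)
    for s in range(n_segments):
        i0, i1 = bounds[s], bounds[s + 1]
        if i1 - i0 < 16:
            continue
        a, b = y_ref[i0:i1], y_sig[i0:i1]
        e = float(np.dot(a, a)) * float(np.dot(b, b))
        if e == 0.0:
            continue  # signal-free segment: no shift information
        seg_shift[s] = _segment_shift(y_ref, y_sig, i0, i1, max_lag) * step
        seg_weight[s] = np.sqrt(e)
    node_x = x_asc[np.minimum(bounds, n - 1)]
    if not seg_weight.any():
        return spec.copy()
    # node shifts: energy-weighted mean of the two adjacent segment shifts,
    # so near-empty segments do not dilute the correction at nearby peaks
    w = np.concatenate([[0.0], seg_weight, [0.0]])
    sh = np.concatenate([[0.0], seg_shift, [0.0]])
    denom = w[:-1] + w[1:]
    node_shift = np.divide(w[:-1] * sh[:-1] + w[1:] * sh[1:], denom,
                           out=np.zeros(n_segments + 1),
                           where=denom > 0)
    # a positive segment lag means sig's features sit at higher ppm than the
    # reference's, so the map samples sig at x + shift to pull them back
    mapped = node_x - node_shift
    # enforce strict monotonicity of the map (reject non-monotone proposals)
    eps = 0.25 * step
    for i in range(1, mapped.size):
        if mapped[i] <= mapped[i - 1] + eps:
            mapped[i] = mapped[i - 1] + eps
    coords = np.interp(x_asc, node_x, mapped)
    y_warp = np.interp(coords, x_asc, y_sig, left=0.0, right=0.0)
    out = spec.copy()
    out.intensity = y_warp[::-1]
    out.complex_data = None  # warping is defined on the real spectrum
    out._log(f"warp(segments={n_segments}, max_shift={max_shift_ppm})")
    return out


def warp_align(spectra: Sequence[Spectrum], policy: str = "after",
               n_segments: int = 64, max_shift_ppm: float = 0.01,
               reference_index: int | None = None,
               candidate_indices: Sequence[int] | None = None
               ) -> tuple[list[Spectrum], int]:
    """Align a group of spectra by piecewise-linear warping.

    With the "after" policy every candidate reference is tried: all other
    spectra are warped onto it and the reference minimizing the total
    post-warp sum of squared differences is kept.  ``candidate_indices``
    restricts the candidate set (the search is quadratic in cohort size).
    With "fixed", ``reference_index`` is used directly.
    """
    if len(spectra) < 2:
        raise ValueError("warping needs at least two spectra")
    n0 = spectra[0].ppm.size
    if any(s.ppm.size != n0 for s in spectra):
        raise ValueError("spectra must share a common axis")
    if policy == "fixed":
        if reference_index is None:
            raise ValueError("policy='fixed' requires reference_index")
        ref = spectra[reference_index]
        warped = [s if i == reference_index else
                  _warp_to_reference(ref, s, n_segments, max_shift_ppm)
                  for i, s in enumerate(spectra)]
        return warped, reference_index
    if policy != "after":
        raise ValueError(f"unknown warp reference policy {policy!r}")
    candidates = (list(range(len(spectra))) if candidate_indices is None
                  else list(candidate_indices))
    best_ssd, best_ref, best_warped = np.inf, -1, None
    for r in candidates:
        ref = spectra[r]
        warped = []
        ssd = 0.0
        for i, s in enumerate(spectra):
            if i == r:
                warped.append(s)
                continue
            w = _warp_to_reference(ref, s, n_segments, max_shift_ppm)
            ssd += float(np.sum((w.intensity - ref.intensity) ** 2))
            warped.append(w)
        if ssd < best_ssd:
            best_ssd, best_ref, best_warped = ssd, r, warped
    return best_warped, best_ref


def _unmasked_area(spectrum: Spectrum) -> float:
    x, y, m = spectrum.ascending()
    yy = np.where(m, 0.0, y)
    # trapezoid with masked points contributing zero
    wts = np.empty_like(x)
    dx = np.diff(x)
    wts[0] = dx[0] / 2
    wts[-1] = dx[-1] / 2
    wts[1:-1] = (dx[:-1] + dx[1:]) / 2
    return float(np.dot(yy, wts))


def normalize(spectrum: Spectrum, method: str = "total_area_excluding") -> Spectrum:
    """Scale the spectrum by total unmasked area or by the positive median."""
    if method == "total_area_excluding":
        const = _unmasked_area(spectrum)
    elif method == "median":
        vals = spectrum.intensity[~spectrum.mask]
        vals = vals[vals > 0]
        const = float(np.median(vals)) if vals.size else 0.0
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if not np.isfinite(const) or const <= 0:
        raise ValueError(f"normalization constant is not positive ({const!r})")
    out = spectrum.copy()
    out.intensity = out.intensity / const
    if out.complex_data is not None:
        out.complex_data = out.complex_data / const
    out.meta["norm_constant"] = const
    out.meta["norm_method"] = method
    out._log(f"normalize({method}, const={const:.6g})")
    return out


# ----------------------------------------------------------------- protocols

def preprocess_fid(fid: Fid, config: PreprocessConfig | None = None,
                   protocol: str = "automated",
                   phases: tuple[float, float] | None = None) -> Spectrum:
    """Run the single-spectrum part of a pre-processing protocol.

    ``protocol="manual"`` emulates vendor-style processing (given or automatic
    phases, baseline, TSP referencing, total-area normalization excluding the
    water and TSP windows); ``"automated"`` uses automatic phasing, the AsLS
    baseline with asymmetry 0.01, and median normalization.  Cohort-level
    warping is a separate step (see :func:`warp_align`).
    """
    cfg = config or PreprocessConfig()
    f = apodize(fid, cfg.lb_hz)
    spec = zero_fill_transform(f, cfg.zero_fill_to)
    if phases is not None:
        spec = phase_correct(spec, *phases)
    else:
        spec, _, _ = autophase(spec)
    spec = baseline_correct(spec, cfg.baseline_asymmetry, cfg.baseline_smoothness)
    spec = reference_to_tsp(spec, cfg.tsp_target_ppm, cfg.tsp_window_ppm)
    spec = exclude_regions(spec, [cfg.water_window_ppm, cfg.tsp_window_ppm])
    if protocol == "manual":
        spec = normalize(spec, "total_area_excluding")
    elif protocol == "automated":
        spec = normalize(spec, "median")
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    spec.meta["protocol"] = protocol
    return spec


def preprocess_cohort(fids: Sequence[Fid], labels: Sequence[str] | None = None,
                      config: PreprocessConfig | None = None,
                      protocol: str = "automated",
                      warp: bool | None = None,
                      warp_candidates: int | None = 8) -> list[Spectrum]:
    """Pre-process a cohort; the automated protocol warps per label group.

    Normalization runs after warping so aligned intensities are compared.
    ``warp_candidates`` caps the number of candidate references tried under
    the "after" policy (evenly spaced through the group).
    """
    cfg = config or PreprocessConfig()
    do_warp = (protocol == "automated") if warp is None else warp
    # per-spectrum stages, normalization deferred
    specs = []
    for fid in fids:
        f = apodize(fid, cfg.lb_hz)
        s = zero_fill_transform(f, cfg.zero_fill_to)
        s, _, _ = autophase(s)
        s = baseline_correct(s, cfg.baseline_asymmetry, cfg.baseline_smoothness)
        s = reference_to_tsp(s, cfg.tsp_target_ppm, cfg.tsp_window_ppm)
        specs.append(s)
    specs = _common_axis(specs)
    if do_warp and len(specs) >= 2:
        groups: dict[str, list[int]] = {}
        if labels is None:
            groups["all"] = list(range(len(specs)))
        else:
            for i, lab in enumerate(labels):
                groups.setdefault(str(lab), []).append(i)
        for idxs in groups.values():
            if len(idxs) < 2:
                continue
            sub = [specs[i] for i in idxs]
            cands = None
            if (warp_candidates is not None and cfg.warp_reference_policy == "after"
                    and len(sub) > warp_candidates):
                cands = list(np.linspace(0, len(sub) - 1, warp_candidates).astype(int))
            warped, _ = warp_align(sub, cfg.warp_reference_policy,
                                   cfg.warp_segments, cfg.warp_max_shift_ppm,
                                   reference_index=0, candidate_indices=cands)
            for i, w in zip(idxs, warped):
                specs[i] = w
    out = []
    for s in specs:
        s = exclude_regions(s, [cfg.water_window_ppm, cfg.tsp_window_ppm])
        method = "total_area_excluding" if protocol == "manual" else "median"
        s = normalize(s, method)
        s.meta["protocol"] = protocol
        out.append(s)
    return out


def _common_axis(specs: list[Spectrum]) -> list[Spectrum]:
    """Interpolate all spectra onto the first spectrum's ppm axis."""
    ref = specs[0]
    out = [ref]
    x_ref = ref.ppm[::-1]
    for s in specs[1:]:
        if s.ppm.size == ref.ppm.size and np.allclose(s.ppm, ref.ppm):
            out.append(s)
            continue
        y = np.interp(x_ref, s.ppm[::-1], s.intensity[::-1], left=0.0, right=0.0)
        ns = s.copy()
        ns.ppm = ref.ppm.copy()
        ns.intensity = y[::-1]
        ns.complex_data = None
        ns.mask = np.zeros(ref.ppm.size, dtype=bool)
        ns._log("resample_to_common_axis")
        out.append(ns)
    return out


# ----------------------------------------------------------------- file I/O

def write_fid(fid: Fid, path: str | Path) -> None:
    """Three-column text file: t, re, im."""
    arr = np.column_stack([fid.times, fid.samples.real, fid.samples.imag])
    header = (f"# dwell_s={fid.dwell_s!r} field_mhz={fid.field_mhz!r} "
              f"ref_offset_hz={fid.ref_offset_hz!r}\nt,re,im")
    np.savetxt(path, arr, delimiter=",", header=header, comments="")


def read_fid(path: str | Path) -> Fid:
    meta = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = float(v)
    arr = np.loadtxt(path, delimiter=",", skiprows=2 if first.startswith("#") else 1)
    dwell = meta.get("dwell_s", float(arr[1, 0] - arr[0, 0]))
    return Fid(samples=arr[:, 1] + 1j * arr[:, 2], dwell_s=dwell,
               field_mhz=meta.get("field_mhz", 400.0),
               ref_offset_hz=meta.get("ref_offset_hz", 0.0))


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Two-column text file: ppm (descending), intensity."""
    arr = np.column_stack([spectrum.ppm, spectrum.intensity])
    np.savetxt(path, arr, delimiter=",",
               header=f"# field_mhz={spectrum.field_mhz!r}\nppm,intensity",
               comments="")


def read_spectrum(path: str | Path) -> Spectrum:
    with open(path) as fh:
        first = fh.readline()
    field = 400.0
    if first.startswith("#"):
        for tok in first[1:].split():
            if tok.startswith("field_mhz="):
                field = float(tok.split("=", 1)[1])
    arr = np.loadtxt(path, delimiter=",", skiprows=2 if first.startswith("#") else 1)
    return Spectrum(ppm=arr[:, 0], intensity=arr[:, 1], field_mhz=field)
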