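"""Synthetic plasma-like NMR cohorts with known ground truth.

The generator emulates CPMG-style 1D 1H plasma spectra at 400 and 900 MHz:
~30-40 catalogued metabolites as Lorentzian multiplets (damped-exponential
FIDs), broad lipid resonances, a residual water hump, a TSP reference
singlet, smooth baseline components, per-spectrum chemical-shift jitter and
phase errors, additive complex white noise, and a two-class cohort with
class-dependent mean concentrations.  Every downstream stage (pre-processing,
binning, deconvolution, classification) is testable against the stored truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import Fid, write_fid, write_spectrum
from .templates import MultipletSpec, TemplateLibrary, read_template_csv

__all__ = [
    "MetaboliteCatalogue", "AcquisitionParams", "CohortDesign", "CohortTruth",
    "ArtifactConfig", "LIPID_RESONANCES", "LIPID_BASE_LEVELS",
    "build_catalogue", "spiking_metabolites", "default_effects",
    "simulate_cohort", "synthesize_fid", "write_cohort", "default_acquisition",
]

#: carrier position (ppm) used to map multiplet positions to FID frequencies
CARRIER_PPM = 4.7

#: broad lipid resonance classes: id -> (annotation, center ppm, FWHM Hz)
LIPID_RESONANCES: dict[str, tuple[str, float, float]] = {
    "lip_CH3":       ("CH3-(CH2)n fatty acid chain",        0.88, 25.0),
    "lip_CH2n":      ("-(CH2)n- fatty acid chain",          1.29, 40.0),
    "lip_CH2CH2CO":  ("-CH2-CH2-C=O fatty acid chain",      1.57, 30.0),
    "lip_lysyl":     ("lysyl",                              1.71, 30.0),
    "lip_allylic":   ("-CH2-CH=CH- fatty acid chain",       1.99, 30.0),
    "lip_NAG":       ("CH3 in N-acetylated glycoproteins",  2.05, 14.0),
    "lip_CH2CO":     ("-CH2-C=O fatty acid chain",          2.24, 30.0),
    "lip_diallylic": ("=CH-CH2-CH= fatty acid chain",       2.76, 30.0),
    "lip_olefinic":  ("-CH=CH- fatty acid chain",           5.31, 45.0),
}

#: mean lipid levels of the control class (relative units)
LIPID_BASE_LEVELS: dict[str, float] = {
    "lip_CH3": 2.0, "lip_CH2n": 4.0, "lip_CH2CH2CO": 0.8, "lip_lysyl": 0.5,
    "lip_allylic": 1.0, "lip_NAG": 0.6, "lip_CH2CO": 0.8,
    "lip_diallylic": 0.5, "lip_olefinic": 1.2,
}


@dataclass
class MetaboliteCatalogue:
    """Target-metabolite library plus mean control-class concentrations."""

    library: TemplateLibrary
    base_conc: dict[str, float]
    field_mhz: float

    def __post_init__(self) -> None:
        names = self.library.metabolites
        if len(set(names)) != len(names):
            raise ValueError("metabolite names must be unique")
        for m in self.library.multiplets:
            if not -0.5 < m.center_ppm < 10.0:
                raise ValueError(
                    f"{m.multiplet_id}: center {m.center_ppm} ppm outside (-0.5, 10)")

    @property
    def entries(self) -> list[tuple[str, list[MultipletSpec], int]]:
        return [(name, self.library.for_metabolite(name),
                 self.library.protons_total(name))
                for name in self.library.metabolites]

    @property
    def metabolites(self) -> list[str]:
        return self.library.metabolites

    def __len__(self) -> int:
        return len(self.library.metabolites)


@dataclass
class AcquisitionParams:
    """Synthetic acquisition settings (one pulse-acquire analogue)."""

    field_mhz: float = 400.0
    spectral_width_hz: float = 6000.0
    n_points: int = 8192
    t2_s: float = 0.35          # apparent transverse decay of metabolite lines
    noise_sd: float = 0.02      # complex white noise SD per FID point

    def __post_init__(self) -> None:
        if self.field_mhz <= 0 or self.spectral_width_hz <= 0:
            raise ValueError("field and spectral width must be positive")
        if self.n_points < 4:
            raise ValueError("n_points too small")

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.spectral_width_hz

    @property
    def ref_offset_hz(self) -> float:
        return CARRIER_PPM * self.field_mhz

    def ppm_range(self) -> tuple[float, float]:
        half = self.spectral_width_hz / 2 / self.field_mhz
        return CARRIER_PPM - half, CARRIER_PPM + half


def default_acquisition(field_mhz: float, n_points: int | None = None,
                        noise_sd: float | None = None) -> AcquisitionParams:
    """Packaged acquisition defaults for the 400 and 900 MHz variants."""
    if field_mhz == 400.0:
        return AcquisitionParams(400.0, 6000.0, n_points or 8192,
                                 noise_sd=0.02 if noise_sd is None else noise_sd)
    if field_mhz == 900.0:
        return AcquisitionParams(900.0, 14423.0, n_points or 16384,
                                 noise_sd=0.02 if noise_sd is None else noise_sd)
    raise ValueError(f"no packaged acquisition defaults for {field_mhz} MHz")


@dataclass
class ArtifactConfig:
    """Instrumental artifacts added to synthesized FIDs."""

    tsp_amplitude: float = 0.6
    tsp_true_ppm: float = 0.015
    water_amplitude: float = 60.0
    water_residual_fraction: float = 0.01   # after (emulated) suppression
    water_center_ppm: float = 4.78
    water_fwhm_hz: float = 80.0
    baseline_n_humps: int = 3
    baseline_fwhm_hz: float = 250.0
    phase0_sd_deg: float = 20.0
    phase1_sd_deg: float = 10.0
    global_shift_sd_ppm: float = 0.010       # pre-referencing calibration error

    def water_effective_amplitude(self) -> float:
        return self.water_amplitude * self.water_residual_fraction


def default_effects() -> dict[str, float]:
    """Default class effects: six metabolites and two lipid classes perturbed.

    Log-fold changes (case vs control) span |log 1.25| to |log 1.8| — large
    enough to be detectable, small enough that classification is imperfect.
    """
    return {
        "lactate": np.log(1.5), "pyruvate": np.log(1.8),
        "alanine": np.log(1.3), "citrate": -np.log(1.5),
        "glutamine": -np.log(1.3), "histidine": -np.log(1.25),
        "lip_CH2n": np.log(1.5), "lip_CH3": np.log(1.4),
    }


@dataclass
class CohortDesign:
    """Two-class cohort design; defaults mirror a 69-case/74-control study."""

    n_cases: int = 69
    n_controls: int = 74
    effects: dict[str, float] = field(default_factory=default_effects)
    biological_cv: float = 0.2
    shift_jitter_ppm: float = 0.002
    baseline_amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("class counts must be positive")
        if self.biological_cv < 0 or self.shift_jitter_ppm < 0:
            raise ValueError("biological_cv and shift_jitter_ppm must be >= 0")


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort."""

    labels: np.ndarray                    # "case" / "control"
    concentrations: pd.DataFrame          # samples x metabolites
    lipid_levels: pd.DataFrame            # samples x lipid resonances
    per_sample_shifts: pd.DataFrame       # samples x multiplets (ppm)
    global_shifts_ppm: np.ndarray         # per-sample calibration error
    phase_errors_deg: np.ndarray          # samples x 2 (phi0, phi1)
    design: CohortDesign | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.concentrations.index)


# --------------------------------------------------------------- catalogue

_PACKAGED_CATALOGUE = {400.0: "catalogue_400.csv", 900.0: "catalogue_900.csv"}


def _data_path(name: str):
    return resources.files("nmrsigex").joinpath("data", name)


def build_catalogue(field_mhz: float,
                    user_catalogue: MetaboliteCatalogue | None = None
                    ) -> MetaboliteCatalogue:
    """Return the packaged target catalogue for 400 or 900 MHz.

    The 900 MHz catalogue adds betaine and choline, flagged as excluded from
    classification so both fields share the same 33 classification features.
    A user catalogue bypasses the packaged defaults entirely.
    """
    if user_catalogue is not None:
        return user_catalogue
    if field_mhz not in _PACKAGED_CATALOGUE:
        raise ValueError(
            f"no packaged catalogue for field {field_mhz} MHz; supply a user "
            f"catalogue (packaged fields: {sorted(_PACKAGED_CATALOGUE)})")
    path = _data_path(_PACKAGED_CATALOGUE[field_mhz])
    with resources.as_file(path) as p:
        lib = read_template_csv(p)
        df = pd.read_csv(p)
    base = (df.drop_duplicates("metabolite").set_index("metabolite")["base_conc"]
            .astype(float).to_dict())
    return MetaboliteCatalogue(library=lib, base_conc=base, field_mhz=field_mhz)


def spiking_metabolites() -> list[str]:
    """The 37 metabolites of the spiking experiments (shift calibration)."""
    return [
        "alanine", "arginine", "asparagine", "aspartate", "cysteine",
        "glutamine", "glutamate", "glycine", "histidine", "isoleucine",
        "leucine", "lysine", "methionine", "phenylalanine", "proline",
        "serine", "threonine", "tryptophan", "tyrosine", "valine",
        "glucose", "myo-inositol", "acetate", "acetoacetate",
        "alpha-ketoglutarate", "beta-hydroxybutyrate", "citrate", "lactate",
        "pyruvate", "succinate", "creatine", "creatinine", "acetone",
        "betaine", "choline", "glycerol", "methanol",
    ]


# --------------------------------------------------------------- simulation

def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def simulate_cohort(design: CohortDesign,
                    catalogue: MetaboliteCatalogue) -> CohortTruth:
    """Draw per-sample concentrations, lipid levels, shifts and artifacts.

    Concentrations are log-normal around class means with the configured
    coefficient of variation; the case mean is the control mean times
    exp(effect).  Per-spectrum multiplet jitter is Normal(0, shift_jitter).
    """
    known = set(catalogue.metabolites) | set(LIPID_RESONANCES)
    unknown = sorted(set(design.effects) - known)
    if unknown:
        raise ValueError(f"effects refer to unknown metabolites/lipids: {unknown}")
    rng = np.random.default_rng(design.seed)
    n = design.n_cases + design.n_controls
    labels = np.array(["case"] * design.n_cases + ["control"] * design.n_controls)
    is_case = (labels == "case").astype(float)
    sample_ids = [f"s{i:04d}" for i in range(n)]
    sigma = _lognormal_sigma(design.biological_cv)

    def draw(names: Sequence[str], base: Mapping[str, float]) -> pd.DataFrame:
        data = {}
        for name in names:
            eff = design.effects.get(name, 0.0)
            mean = base[name] * np.exp(eff * is_case)
            # log-normal with the requested mean and CV
            data[name] = mean * np.exp(rng.normal(-sigma**2 / 2, sigma, n))
        return pd.DataFrame(data, index=sample_ids)

    conc = draw(catalogue.metabolites, catalogue.base_conc)
    lipids = draw(list(LIPID_RESONANCES), LIPID_BASE_LEVELS)
    mult_ids = [m.multiplet_id for m in catalogue.library.multiplets]
    shifts = pd.DataFrame(
        rng.normal(0.0, design.shift_jitter_ppm, (n, len(mult_ids))),
        index=sample_ids, columns=mult_ids)
    global_shifts = rng.normal(0.0, 1.0, n)  # scaled by artifact config later
    phases = rng.normal(0.0, 1.0, (n, 2))
    return CohortTruth(labels=labels, concentrations=conc, lipid_levels=lipids,
                       per_sample_shifts=shifts, global_shifts_ppm=global_shifts,
                       phase_errors_deg=phases, design=design)


def _peak_list(concentrations: Mapping[str, float],
               lipid_levels: Mapping[str, float],
               shifts: Mapping[str, float],
               catalogue: MetaboliteCatalogue,
               acq: AcquisitionParams,
               artifacts: ArtifactConfig | None,
               baseline_amplitude: float,
               rng: np.random.Generator | None
               ) -> list[tuple[float, float, float, float]]:
    """(ppm, amplitude, T2_s, extra_phase_rad) for every Lorentzian line."""
    peaks: list[tuple[float, float, float, float]] = []
    for m in catalogue.library.multiplets:
        c = float(concentrations.get(m.metabolite, 0.0))
        if c == 0.0:
            continue
        d = float(shifts.get(m.multiplet_id, 0.0))
        if m.pattern == "raster":
            # approximate the raster curve by its dominant peak
            pk = m.peak_ppm(acq.field_mhz)
            hs = [m.protons]
            offs_ppm = pk - m.center_ppm
        else:
            offs_ppm = m.offsets_hz / acq.field_mhz
            hs = list(m.rel_intensities)
        for off, h in zip(np.atleast_1d(offs_ppm), hs):
            peaks.append((m.center_ppm + d + off, c * h, acq.t2_s, 0.0))
    for lip, level in lipid_levels.items():
        ann, center, fwhm = LIPID_RESONANCES[lip]
        t2 = 1.0 / (np.pi * fwhm)
        peaks.append((center, float(level), t2, 0.0))
    if artifacts is not None:
        peaks.append((artifacts.tsp_true_ppm, artifacts.tsp_amplitude,
                      acq.t2_s * 1.5, 0.0))
        if artifacts.water_effective_amplitude() > 0:
            peaks.append((artifacts.water_center_ppm,
                          artifacts.water_effective_amplitude(),
                          1.0 / (np.pi * artifacts.water_fwhm_hz), 0.0))
        if baseline_amplitude > 0 and artifacts.baseline_n_humps > 0:
            r = rng or np.random.default_rng(0)
            lo, hi = acq.ppm_range()
            for _ in range(artifacts.baseline_n_humps):
                peaks.append((float(r.uniform(lo + 1, hi - 1)),
                              baseline_amplitude * float(r.uniform(0.5, 1.5)),
                              1.0 / (np.pi * artifacts.baseline_fwhm_hz), 0.0))
    return peaks


def synthesize_fid(concentrations: Mapping[str, float],
                   catalogue: MetaboliteCatalogue,
                   acq: AcquisitionParams,
                   artifacts: ArtifactConfig | None = None,
                   *,
                   lipid_levels: Mapping[str, float] | None = None,
                   shifts: Mapping[str, float] | None = None,
                   baseline_amplitude: float = 0.0,
                   global_shift_ppm: float = 0.0,
                   phase_deg: tuple[float, float] = (0.0, 0.0),
                   rng: np.random.Generator | None = None) -> Fid:
    """Synthesize one FID as a sum of damped complex exponentials plus noise.

    Each multiplet contributes peaks at (center + jitter + offset/field) ppm
    with amplitudes proportional to concentration x relative intensity; broad
    lipid lines, TSP, residual water and smooth baseline humps are optional.
    A zero/first-order phase error is applied per peak (first-order linear in
    frequency across the spectral width).
    """
    lipid_levels = lipid_levels or {}
    shifts = shifts or {}
    peaks = _peak_list(concentrations, lipid_levels, shifts, catalogue, acq,
                       artifacts, baseline_amplitude, rng)
    lo, hi = acq.ppm_range()
    bad = [p for p in peaks if not (lo < p[0] + global_shift_ppm < hi)]
    if bad:
        raise ValueError(
            f"peak frequencies outside the spectral width ({lo:.2f}..{hi:.2f} "
            f"ppm): {[round(p[0], 3) for p in bad]}")
    t = np.arange(acq.n_points) * acq.dwell_s
    fid = np.zeros(acq.n_points, dtype=complex)
    phi0 = np.deg2rad(phase_deg[0])
    phi1 = np.deg2rad(phase_deg[1])
    for ppm, amp, t2, _ in peaks:
        f_hz = (ppm + global_shift_ppm - CARRIER_PPM) * acq.field_mhz
        frac = (ppm + global_shift_ppm - lo) / (hi - lo)  # 0..1 across width
        phase = phi0 + phi1 * (frac - 0.5)
        fid += amp * np.exp((2j * np.pi * f_hz - 1.0 / t2) * t + 1j * phase)
    if acq.noise_sd > 0:
        r = rng or np.random.default_rng(0)
        fid += (r.normal(0, acq.noise_sd, acq.n_points)
                + 1j * r.normal(0, acq.noise_sd, acq.n_points))
    return Fid(samples=fid, dwell_s=acq.dwell_s, field_mhz=acq.field_mhz,
               ref_offset_hz=acq.ref_offset_hz)


def cohort_fids(truth: CohortTruth, catalogue: MetaboliteCatalogue,
                acq: AcquisitionParams,
                artifacts: ArtifactConfig | None = None) -> list[Fid]:
    """Synthesize every sample of a cohort (deterministic given the design seed)."""
    art = artifacts if artifacts is not None else ArtifactConfig()
    design = truth.design or CohortDesign()
    fids = []
    for i, sid in enumerate(truth.sample_ids):
        rng = np.random.default_rng(np.random.SeedSequence([design.seed, i]))
        fid = synthesize_fid(
            truth.concentrations.loc[sid].to_dict(), catalogue, acq, art,
            lipid_levels=truth.lipid_levels.loc[sid].to_dict(),
            shifts=truth.per_sample_shifts.loc[sid].to_dict(),
            baseline_amplitude=design.baseline_amplitude,
            global_shift_ppm=float(truth.global_shifts_ppm[i]
                                   * art.global_shift_sd_ppm),
            phase_deg=(float(truth.phase_errors_deg[i, 0] * art.phase0_sd_deg),
                       float(truth.phase_errors_deg[i, 1] * art.phase1_sd_deg)),
            rng=rng)
        fid.meta["sample_id"] = sid
        fids.append(fid)
    return fids


def write_cohort(truth: CohortTruth, catalogue: MetaboliteCatalogue,
                 acq: AcquisitionParams, spectra_dir: str | Path,
                 artifacts: ArtifactConfig | None = None,
                 file_format: str = "fid") -> pd.DataFrame:
    """Write one FID (or spectrum) file per sample plus a manifest CSV.

    Ground-truth tables are stored alongside for tests.  Returns the manifest
    (columns sample_id, label, path, field_mhz).
    """
    out = Path(spectra_dir)
    out.mkdir(parents=True, exist_ok=True)
    fids = cohort_fids(truth, catalogue, acq, artifacts)
    rows = []
    for fid, sid, label in zip(fids, truth.sample_ids, truth.labels):
        if file_format == "fid":
            path = out / f"{sid}.fid.csv"
            write_fid(fid, path)
        elif file_format == "spectrum":
            from .preprocess import zero_fill_transform
            path = out / f"{sid}.spec.csv"
            write_spectrum(zero_fill_transform(fid), path)
        else:
            raise ValueError(f"unknown file format {file_format!r}")
        rows.append({"sample_id": sid, "label": label, "path": str(path),
                     "field_mhz": acq.field_mhz})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    truth.concentrations.to_csv(out / "truth_concentrations.csv")
    truth.lipid_levels.to_csv(out / "truth_lipids.csv")
    truth.per_sample_shifts.to_csv(out / "truth_shifts.csv")
    pd.DataFrame({"sample_id": truth.sample_ids,
                  "label": truth.labels}).to_csv(out / "truth_labels.csv",
                                                 index=False)
    return manifest
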