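"""Regenerate the packaged default tables under src/nmrsigex/data/.

The catalogue uses standard plasma chemical-shift assignments (HMDB-style).
Binning region boundaries are derived deterministically from the catalogue's
multiplet positions plus linewidth margins; uniform filler regions bring each
table to its fixed row count (110 at 400 MHz; 105 manual / 103 automated at
900 MHz).  Lipid integration regions are broad windows around the standard
plasma lipid resonance classes (9 rows at 400 MHz, 10 at 900 MHz, where the
-(CH2)n- class uses two regions).
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

DATA = Path(__file__).resolve().parents[1] / "src" / "nmrsigex" / "data"

# name, multiplet rows: (center_ppm, pattern, J list, protons, h list or None)
CATALOGUE_400 = {
    "alanine":      [(1.509, "doublet", [7.2], 3, None),
                     (3.810, "quartet", [7.2], 1, None)],
    "arginine":     [(3.230, "triplet", [6.8], 2, None),
                     (1.680, "triplet", [7.2], 2, None)],
    "asparagine":   [(2.950, "double_doublet", [16.9, 7.6], 1, None)],
    "aspartate":    [(2.702, "double_doublet", [17.4, 3.7], 1, None),
                     (2.810, "double_doublet", [17.4, 3.7], 1, None)],
    "cysteine":     [(3.075, "double_doublet", [14.4, 4.3], 1, None)],
    "glutamine":    [(2.450, "triplet", [7.6], 2, None)],
    "glutamate":    [(2.350, "triplet", [7.5], 2, None)],
    "glycine":      [(3.561, "singlet", [], 2, None)],
    "histidine":    [(7.060, "singlet", [], 1, None)],
    "isoleucine":   [(1.010, "doublet", [7.0], 3, None)],
    "leucine":      [(0.961, "doublet", [6.3], 6, None)],
    "lysine":       [(3.012, "triplet", [7.6], 2, None)],
    "methionine":   [(2.138, "singlet", [], 3, None)],
    "phenylalanine": [(7.420, "doublet", [7.7], 2, None)],
    "proline":      [(4.130, "double_doublet", [8.6, 6.4], 1, None),
                     (3.340, "triplet", [6.8], 2, None)],
    "serine":       [(3.945, "double_doublet", [12.3, 3.9], 1, None)],
    "threonine":    [(1.318, "doublet", [6.6], 3, None),
                     (4.250, "double_doublet", [6.6, 4.9], 1, None)],
    "tryptophan":   [(7.720, "doublet", [8.0], 1, None)],
    "tyrosine":     [(3.055, "double_doublet", [14.7, 5.1], 1, None),
                     (6.900, "doublet", [8.5], 2, None)],
    "valine":       [(0.984, "doublet", [7.0], 3, None),
                     (1.031, "doublet", [7.0], 3, None)],
    "alpha-D-glucopyranose": [(5.230, "doublet", [3.8], 1, None)],
    "beta-D-glucopyranose":  [(3.240, "double_doublet", [9.4, 8.0], 1, None)],
    "myo-inositol": [(4.054, "triplet", [2.8], 1, None)],
    "acetate":      [(1.918, "singlet", [], 3, None)],
    "acetoacetate": [(2.270, "singlet", [], 3, None)],
    "alpha-ketoglutarate":   [(3.001, "triplet", [6.9], 2, None)],
    "beta-hydroxybutyrate":  [(1.200, "doublet", [6.3], 3, None)],
    # citrate AB system: two leaning doublets, inner peaks taller (h per Eq 1)
    "citrate":      [(2.566, "doublet", [15.6], 2, [0.8, 1.2]),
                     (2.717, "doublet", [15.6], 2, [1.2, 0.8])],
    "lactate":      [(1.330, "doublet", [7.0], 3, None),
                     (4.110, "quartet", [7.0], 1, None)],
    "pyruvate":     [(2.370, "singlet", [], 3, None)],
    "succinate":    [(2.410, "singlet", [], 4, None)],
    "creatine":     [(3.029, "singlet", [], 3, None),
                     (3.913, "singlet", [], 2, None)],
    "creatinine":   [(3.045, "singlet", [], 3, None),
                     (4.060, "singlet", [], 2, None)],
}

EXTRA_900 = {
    "betaine": [(3.260, "singlet", [], 9, None)],
    "choline": [(3.205, "singlet", [], 9, None)],
}
EXCLUDED_900 = {"betaine", "choline"}

BASE_CONC = {
    "alanine": 0.45, "arginine": 0.12, "asparagine": 0.10, "aspartate": 0.10,
    "cysteine": 0.12, "glutamine": 0.55, "glutamate": 0.25, "glycine": 0.30,
    "histidine": 0.10, "isoleucine": 0.12, "leucine": 0.18, "lysine": 0.20,
    "methionine": 0.10, "phenylalanine": 0.10, "proline": 0.20, "serine": 0.15,
    "threonine": 0.15, "tryptophan": 0.10, "tyrosine": 0.10, "valine": 0.25,
    "alpha-D-glucopyranose": 1.6, "beta-D-glucopyranose": 2.4,
    "myo-inositol": 0.10, "acetate": 0.15, "acetoacetate": 0.10,
    "alpha-ketoglutarate": 0.10, "beta-hydroxybutyrate": 0.15, "citrate": 0.15,
    "lactate": 1.5, "pyruvate": 0.12, "succinate": 0.10, "creatine": 0.10,
    "creatinine": 0.08, "betaine": 0.10, "choline": 0.10,
}

SHIFT_TOL = {400.0: 0.005, 900.0: 0.003}
FWHM_HZ = {400.0: 1.5, 900.0: 1.0}

LIPID_REGIONS_400 = [
    ("lip_CH3", "CH3-(CH2)n fatty acid chain", 0.78, 1.00),
    ("lip_CH2n", "-(CH2)n- fatty acid chain", 1.18, 1.45),
    ("lip_CH2CH2CO", "-CH2-CH2-C=O fatty acid chain", 1.48, 1.64),
    ("lip_lysyl", "lysyl", 1.66, 1.78),
    ("lip_allylic", "-CH2-CH=CH- fatty acid chain", 1.90, 2.02),
    ("lip_NAG", "CH3 in N-acetylated glycoproteins", 2.02, 2.10),
    ("lip_CH2CO", "-CH2-C=O fatty acid chain", 2.18, 2.32),
    ("lip_diallylic", "=CH-CH2-CH= fatty acid chain", 2.68, 2.86),
    ("lip_olefinic", "-CH=CH- fatty acid chain", 5.20, 5.45),
]
LIPID_REGIONS_900 = [
    ("lip_CH3", "CH3-(CH2)n fatty acid chain", 0.78, 1.00),
    ("lip_CH2n_a", "-(CH2)n- fatty acid chain (upfield)", 1.18, 1.30),
    ("lip_CH2n_b", "-(CH2)n- fatty acid chain (downfield)", 1.30, 1.45),
    ("lip_CH2CH2CO", "-CH2-CH2-C=O fatty acid chain", 1.48, 1.64),
    ("lip_lysyl", "lysyl", 1.66, 1.78),
    ("lip_allylic", "-CH2-CH=CH- fatty acid chain", 1.90, 2.02),
    ("lip_NAG", "CH3 in N-acetylated glycoproteins", 2.02, 2.10),
    ("lip_CH2CO", "-CH2-C=O fatty acid chain", 2.18, 2.32),
    ("lip_diallylic", "=CH-CH2-CH= fatty acid chain", 2.68, 2.86),
    ("lip_olefinic", "-CH=CH- fatty acid chain", 5.20, 5.45),
]

WATER = (4.50, 5.10)
AXIS = (0.30, 9.50)   # binning span; TSP (<0.2 ppm) excluded by construction


def catalogue_rows(entries, field):
    rows = []
    for name, mults in entries.items():
        for center, pattern, J, p, h in mults:
            rows.append({
                "metabolite": name,
                "multiplet_id": f"{name}_{center:.3f}",
                "center_ppm": center,
                "pattern": pattern,
                "J_hz": ";".join(f"{j:g}" for j in J),
                "protons": p,
                "rel_intensities": ";".join(f"{v:g}" for v in h) if h else "",
                "raster_file": "",
                "shift_tolerance_ppm": SHIFT_TOL[field],
                "exclude_from_classification": name in EXCLUDED_900,
                "base_conc": BASE_CONC[name],
            })
    return pd.DataFrame(rows)


def peak_extents(entries, field, margin_factor):
    """Merged [lo, hi) intervals around multiplet peak groups."""
    from nmrsigex.templates import pattern_offsets
    margin = margin_factor * FWHM_HZ[field] / field + SHIFT_TOL[field] + 0.004
    spans = []
    for name, mults in entries.items():
        for center, pattern, J, p, h in mults:
            offs = pattern_offsets(pattern, J)[0] / field
            spans.append((center + offs.min() - margin,
                          center + offs.max() + margin, name))
    spans.sort()
    merged = []
    for lo, hi, name in spans:
        if merged and lo <= merged[-1][1]:
            mlo, mhi, names = merged.pop()
            merged.append((mlo, max(hi, mhi), names + [name]))
        else:
            merged.append((lo, hi, [name]))
    return merged


def build_region_table(entries, field, target_count, margin_factor):
    merged = [m for m in merged_clip(peak_extents(entries, field, margin_factor))]
    n_fill = target_count - len(merged)
    assert n_fill >= 0, (field, target_count, len(merged))
    # gaps between metabolite regions inside the axis, excluding water
    edges = [AXIS[0]]
    for lo, hi, _ in merged:
        edges += [lo, hi]
    edges.append(AXIS[1])
    gaps = []
    for i in range(0, len(edges), 2):
        lo, hi = edges[i], edges[i + 1]
        for glo, ghi in subtract_water(lo, hi):
            if ghi - glo > 0.02:
                gaps.append((glo, ghi))
    # allocate filler bins to gaps proportionally to width (largest remainder)
    widths = np.array([hi - lo for lo, hi in gaps])
    raw = widths / widths.sum() * n_fill
    alloc = np.floor(raw).astype(int)
    rem = n_fill - alloc.sum()
    for i in np.argsort(raw - alloc)[::-1][:rem]:
        alloc[i] += 1
    rows = []
    for (lo, hi, names) in merged:
        cat = "metabolite" if len(set(names)) == 1 else "mixed"
        rows.append((lo, hi, "+".join(sorted(set(names))), cat))
    for (lo, hi), k in zip(gaps, alloc):
        if k == 0:
            continue
        cuts = np.linspace(lo, hi, k + 1)
        for a, b in zip(cuts[:-1], cuts[1:]):
            rows.append((a, b, "", "unknown"))
    rows.sort()
    table = pd.DataFrame(
        [{"region_id": f"r{i+1:03d}", "ppm_lo": round(lo, 4),
          "ppm_hi": round(hi, 4), "annotation": ann, "category": cat}
         for i, (lo, hi, ann, cat) in enumerate(rows)])
    assert len(table) == target_count, (field, target_count, len(table))
    return table


def subtract_water(lo, hi):
    wlo, whi = WATER
    if hi <= wlo or lo >= whi:
        return [(lo, hi)]
    out = []
    if lo < wlo:
        out.append((lo, wlo))
    if hi > whi:
        out.append((whi, hi))
    return out


def merged_clip(merged):
    """Clip merged metabolite regions to the axis, drop those inside water."""
    out = []
    for lo, hi, names in merged:
        lo, hi = max(lo, AXIS[0]), min(hi, AXIS[1])
        if hi <= lo:
            continue
        pieces = subtract_water(lo, hi)
        for plo, phi in pieces:
            out.append((plo, phi, names))
    return out


def main():
    DATA.mkdir(parents=True, exist_ok=True)
    cat400 = catalogue_rows(CATALOGUE_400, 400.0)
    cat400.to_csv(DATA / "catalogue_400.csv", index=False)
    entries_900 = {**CATALOGUE_400, **EXTRA_900}
    cat900 = catalogue_rows(entries_900, 900.0)
    cat900.to_csv(DATA / "catalogue_900.csv", index=False)

    build_region_table(CATALOGUE_400, 400.0, 110, 4.0).to_csv(
        DATA / "regions_400.csv", index=False)
    build_region_table(entries_900, 900.0, 105, 6.0).to_csv(
        DATA / "regions_900_manual.csv", index=False)
    build_region_table(entries_900, 900.0, 103, 4.0).to_csv(
        DATA / "regions_900_automated.csv", index=False)

    for name, regs in (("lipid_regions_400.csv", LIPID_REGIONS_400),
                       ("lipid_regions_900.csv", LIPID_REGIONS_900)):
        pd.DataFrame(regs, columns=["lipid_id", "resonance_label",
                                    "ppm_lo", "ppm_hi"]).to_csv(
            DATA / name, index=False)
    print("tables written to", DATA)


if __name__ == "__main__":
    main()
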