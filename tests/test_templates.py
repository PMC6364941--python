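"""Unit and property tests for the template library."""
import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrsigex.templates import (MultipletSpec, TemplateLibrary, build_template,
                                load_raster, pattern_offsets,
                                read_template_csv, relative_intensities,
                                write_template_csv)

from conftest import lorentzian


# ------------------------------------------------------ relative_intensities

def test_eq1_citrate_worked_example():
    h = relative_intensities([0.6, 0.4], p=2)
    assert h[0] == 1.2 and h[1] == 0.8


def test_eq1_symmetric_doublet():
    assert np.array_equal(relative_intensities([1.0, 1.0], p=2), [1.0, 1.0])


def test_eq1_single_peak():
    assert np.array_equal(relative_intensities([5.0], p=3), [3.0])


def test_eq1_rejects_nonpositive_intensity():
    with pytest.raises(ValueError):
        relative_intensities([0.5, 0.0], p=2)
    with pytest.raises(ValueError):
        relative_intensities([0.5, -0.1], p=2)


def test_eq1_rejects_bad_proton_count():
    with pytest.raises(ValueError):
        relative_intensities([1.0], p=0)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(min_value=1e-3, max_value=1e3), min_size=1, max_size=8),
       st.integers(min_value=1, max_value=12))
def test_eq1_conservation_property(y, p):
    h = relative_intensities(y, p)
    assert np.isclose(h.sum(), p, rtol=0, atol=1e-9)
    assert np.all(h > 0)


# ---------------------------------------------------------- pattern_offsets

def test_double_doublet_offsets_fig5_rule():
    offs, ratios = pattern_offsets("double_doublet", [8.0, 4.0])
    assert np.allclose(offs, [-6.0, -2.0, 2.0, 6.0])
    assert np.allclose(ratios, 0.25)


def test_doublet_offsets_half_j():
    offs, ratios = pattern_offsets("doublet", [7.0])
    assert np.allclose(offs, [-3.5, 3.5])
    assert np.allclose(ratios, [0.5, 0.5])


def test_triplet_binomial_ratios_respected_by_eq1():
    offs, ratios = pattern_offsets("triplet", [7.0])
    assert np.allclose(ratios, [0.25, 0.5, 0.25])
    # Eq 1 applied to the binomial pattern preserves it
    h = relative_intensities(ratios, p=1)
    assert np.allclose(h, ratios)


def test_quartet_offsets_and_ratios():
    offs, ratios = pattern_offsets("quartet", [7.0])
    assert np.allclose(offs, [-10.5, -3.5, 3.5, 10.5])
    assert np.allclose(ratios, [0.125, 0.375, 0.375, 0.125])


def test_mismatched_j_count_errors():
    with pytest.raises(ValueError):
        pattern_offsets("double_doublet", [8.0])
    with pytest.raises(ValueError):
        pattern_offsets("singlet", [1.0])
    with pytest.raises(ValueError):
        pattern_offsets("nonsense", [1.0])


# ------------------------------------------------------------ MultipletSpec

def test_spec_defaults_rel_intensities_from_pattern():
    m = MultipletSpec("ala", 1.5, "doublet", (7.2,), protons=3)
    assert np.allclose(m.rel_intensities, [1.5, 1.5])


def test_spec_rejects_wrong_h_sum():
    with pytest.raises(ValueError):
        MultipletSpec("x", 1.0, "doublet", (7.0,), protons=2,
                      rel_intensities=(1.5, 1.0))


# ----------------------------------------------------------- build_template

def test_singlet_unit_area():
    x = np.linspace(0.0, 2.0, 4096)
    m = MultipletSpec("s", 1.0, "singlet", protons=1)
    t = build_template(m, 400.0, 1.5, x)
    assert abs(t.area() - 1.0) <= 1e-6


def test_doublet_spacing_shrinks_with_field():
    x = np.linspace(0.0, 2.0, 16384)
    m = MultipletSpec("d", 1.0, "doublet", (7.2,), protons=2)
    def spacing(field):
        t = build_template(m, field, 0.8, x)
        y = t.intensity
        mid = np.searchsorted(x, 1.0)
        i1 = np.argmax(y[:mid])
        i2 = mid + np.argmax(y[mid:])
        return x[i2] - x[i1]
    assert spacing(900.0) / spacing(400.0) == pytest.approx(400.0 / 900.0,
                                                            rel=0.02)


def test_citrate_leaning_height_ratio():
    x = np.linspace(2.3, 2.9, 32768)
    m = MultipletSpec("citrate", 2.566, "doublet", (15.6,), protons=2,
                      rel_intensities=(0.8, 1.2))
    y = build_template(m, 400.0, 1.5, x).intensity
    mid = np.searchsorted(x, 2.566)
    h_lo = y[:mid].max()
    h_hi = y[mid:].max()
    assert h_hi / h_lo == pytest.approx(1.5, rel=0.01)


def test_field_strength_consistency_in_hz_domain():
    # same Hz-domain template at both fields: value/field on matched Hz grids
    m400 = MultipletSpec("d", 3.0, "doublet", (7.2,), protons=2)
    f_hz = np.linspace(-200.0, 200.0, 8192)
    t400 = build_template(m400, 400.0, 1.0, 3.0 + f_hz / 400.0).intensity / 400.0
    t900 = build_template(m400, 900.0, 1.0, 3.0 + f_hz / 900.0).intensity / 900.0
    assert np.max(np.abs(t400 - t900)) <= 1e-6


def test_peaks_outside_grid_error():
    x = np.linspace(0.0, 1.0, 512)
    m = MultipletSpec("s", 2.0, "singlet", protons=1)
    with pytest.raises(ValueError):
        build_template(m, 400.0, 1.5, x)


def test_template_on_descending_grid_matches_ascending():
    x = np.linspace(0.0, 2.0, 2048)
    m = MultipletSpec("s", 1.0, "singlet", protons=2)
    up = build_template(m, 400.0, 1.5, x).intensity
    down = build_template(m, 400.0, 1.5, x[::-1]).intensity
    assert np.array_equal(up, down[::-1])


# -------------------------------------------------------------- load_raster

def test_raster_from_unit_lorentzian_matches_parametric():
    x = np.linspace(0.5, 1.5, 8192)
    seg = lorentzian(x, 1.0, 1.5 / 400.0)
    spec = load_raster(x, seg, (0.8, 1.2), p=1)
    t_raster = build_template(spec, 400.0, 1.5, x).intensity
    t_param = build_template(MultipletSpec("s", 1.0, "singlet", protons=1),
                             400.0, 1.5, x).intensity
    # identical up to the window truncation / renormalization of the raster
    sel = (x > 0.9) & (x < 1.1)
    assert np.allclose(t_raster[sel], t_param[sel], rtol=0.02)


def test_raster_scale_invariance():
    x = np.linspace(0.5, 1.5, 2048)
    seg = lorentzian(x, 1.0, 0.01)
    a = load_raster(x, seg, (0.8, 1.2), p=2)
    b = load_raster(x, 7.0 * seg, (0.8, 1.2), p=2)
    assert np.allclose(a.raster[1], b.raster[1])


def test_raster_negative_dips_clipped_area_p():
    x = np.linspace(0.5, 1.5, 2048)
    seg = lorentzian(x, 1.0, 0.01) - 0.2
    spec = load_raster(x, seg, (0.8, 1.2), p=3)
    xs, ys = spec.raster
    assert np.all(ys >= 0)
    assert np.trapezoid(ys, xs) == pytest.approx(3.0, rel=1e-9)


def test_raster_all_zero_segment_errors():
    x = np.linspace(0.5, 1.5, 256)
    with pytest.raises(ValueError):
        load_raster(x, np.zeros_like(x), (0.8, 1.2), p=1)


# ----------------------------------------------------------------- CSV I/O

def _demo_library():
    return TemplateLibrary(multiplets=[
        MultipletSpec("alanine", 1.509, "doublet", (7.2,), protons=3,
                      shift_tolerance_ppm=0.005),
        MultipletSpec("citrate", 2.566, "doublet", (15.6,), protons=2,
                      rel_intensities=(0.8, 1.2)),
        MultipletSpec("creatine", 3.029, "singlet", protons=3),
    ], excluded_from_classification=frozenset({"creatine"}))


def test_csv_round_trip(tmp_path):
    lib = _demo_library()
    path = tmp_path / "lib.csv"
    write_template_csv(lib, path)
    back = read_template_csv(path)
    assert back.metabolites == lib.metabolites
    assert back.excluded_from_classification == lib.excluded_from_classification
    for a, b in zip(lib.multiplets, back.multiplets):
        assert a.metabolite == b.metabolite
        assert a.center_ppm == pytest.approx(b.center_ppm)
        assert np.allclose(a.rel_intensities, b.rel_intensities)
        assert a.J_hz == pytest.approx(b.J_hz)


def test_csv_error_names_row():
    csv = ("metabolite,multiplet_id,center_ppm,pattern,J_hz,protons\n"
           "good,g_1,1.0,singlet,,1\n"
           "bad,b_1,2.0,double_doublet,8.0,1\n")
    with pytest.raises(ValueError, match="row 3"):
        read_template_csv(io.StringIO(csv))


def test_csv_omitted_rel_intensities_defaulted():
    csv = ("metabolite,multiplet_id,center_ppm,pattern,J_hz,protons\n"
           "ala,a_1,1.509,doublet,7.2,3\n")
    lib = read_template_csv(io.StringIO(csv))
    assert np.allclose(lib.multiplets[0].rel_intensities, [1.5, 1.5])


def test_csv_bad_h_sum_errors():
    csv = ("metabolite,multiplet_id,center_ppm,pattern,J_hz,protons,"
           "rel_intensities\n"
           "x,x_1,1.0,doublet,7.0,2,1.5;1.0\n")
    with pytest.raises(ValueError, match="row 2"):
        read_template_csv(io.StringIO(csv))


# ------------------------------------------- packaged catalogue invariants

def test_packaged_catalogues_conserve_eq1(catalogue_400, catalogue_900):
    for cat in (catalogue_400, catalogue_900):
        for m in cat.library.multiplets:
            assert abs(sum(m.rel_intensities) - m.protons) <= 1e-6
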