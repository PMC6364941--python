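"""Unit and property tests for FID/spectrum pre-processing."""
import numpy as np
import pytest

from nmrsigex.preprocess import (Fid, PreprocessConfig, Spectrum, apodize,
                                 autophase, baseline_correct, exclude_regions,
                                 normalize, phase_correct, preprocess_cohort,
                                 read_fid, read_spectrum, reference_to_tsp,
                                 warp_align, write_fid, write_spectrum,
                                 zero_fill_transform)

from conftest import lorentzian, make_spectrum, trapezoid_weights


def damped_fid(freqs_hz, amps=None, t2=0.3, n=2048, sw=1000.0,
               field=400.0, ref_offset_hz=0.0, noise_sd=0.0, seed=0):
    """A sum of damped complex exponentials, frequencies relative to carrier."""
    amps = amps or [1.0] * len(freqs_hz)
    t = np.arange(n) / sw
    s = np.zeros(n, dtype=complex)
    for f, a in zip(freqs_hz, amps):
        s += a * np.exp((2j * np.pi * f - 1.0 / t2) * t)
    if noise_sd:
        rng = np.random.default_rng(seed)
        s += rng.normal(0, noise_sd, n) + 1j * rng.normal(0, noise_sd, n)
    return Fid(samples=s, dwell_s=1.0 / sw, field_mhz=field,
               ref_offset_hz=ref_offset_hz)


def measure_fwhm(x_asc, y):
    """FWHM by linear interpolation of the half-maximum crossings."""
    k = int(np.argmax(y))
    half = y[k] / 2.0
    i = k
    while y[i] > half:
        i -= 1
    left = np.interp(half, [y[i], y[i + 1]], [x_asc[i], x_asc[i + 1]])
    j = k
    while y[j] > half:
        j += 1
    right = np.interp(half, [y[j], y[j - 1]], [x_asc[j], x_asc[j - 1]])
    return right - left


# ----------------------------------------------------------------- apodize

def test_apodize_lb_zero_identity():
    fid = damped_fid([50.0])
    out = apodize(fid, 0.0)
    assert np.array_equal(out.samples, fid.samples)


def test_apodize_envelope():
    n, sw = 512, 1000.0
    fid = Fid(samples=np.ones(n, dtype=complex), dwell_s=1.0 / sw,
              field_mhz=400.0)
    out = apodize(fid, 0.7)
    t = np.arange(n) / sw
    assert np.allclose(np.abs(out.samples), np.exp(-0.7 * np.pi * t))


def test_apodize_widens_fwhm_by_lb():
    fid = damped_fid([0.0], t2=0.3, n=4096, sw=500.0)
    lb = 2.0
    def fwhm_of(f):
        spec = zero_fill_transform(f, 65536)
        x, y, _ = spec.ascending()
        return measure_fwhm(x, y) * f.field_mhz  # ppm -> Hz
    w0 = fwhm_of(fid)
    w1 = fwhm_of(apodize(fid, lb))
    assert w0 == pytest.approx(1.0 / (np.pi * 0.3), abs=0.05)
    assert w1 - w0 == pytest.approx(lb, abs=0.05)


def test_apodize_rejects_negative_lb():
    with pytest.raises(ValueError):
        apodize(damped_fid([10.0]), -1.0)


# ----------------------------------------------------- zero_fill_transform

def test_zero_fid_gives_zero_spectrum():
    fid = Fid(samples=np.zeros(64, dtype=complex), dwell_s=1e-3,
              field_mhz=400.0)
    spec = zero_fill_transform(fid)
    assert np.all(spec.intensity == 0)


def test_peak_position_f_over_field():
    fid = damped_fid([200.0], t2=0.5, n=2048, sw=2000.0, field=400.0,
                     ref_offset_hz=0.0)
    spec = zero_fill_transform(fid)
    apex = spec.ppm[np.argmax(spec.intensity)]
    assert apex == pytest.approx(200.0 / 400.0, abs=2 * spec.step_ppm)


def test_parseval_energy_preserved():
    fid = damped_fid([120.0], t2=0.2, n=1024, sw=2000.0)
    target = 4096
    spec = zero_fill_transform(fid, target)
    padded = np.zeros(target, dtype=complex)
    padded[:fid.samples.size] = fid.samples
    padded[0] *= 0.5  # the first-point correction applied by the transform
    e_time = np.sum(np.abs(padded) ** 2)
    e_freq = np.sum(np.abs(spec.complex_data) ** 2)
    assert e_freq == pytest.approx(e_time, rel=1e-9)


def test_zero_fill_validation():
    fid = damped_fid([10.0], n=1000)
    with pytest.raises(ValueError):
        zero_fill_transform(fid, 512)       # shorter than the FID
    with pytest.raises(ValueError):
        zero_fill_transform(fid, 3000)      # not a power of two


def test_point_spacing_halves_when_length_doubles():
    fid = damped_fid([10.0], n=1024)
    s1 = zero_fill_transform(fid, 2048)
    s2 = zero_fill_transform(fid, 4096)
    assert s2.step_ppm == pytest.approx(s1.step_ppm / 2, rel=1e-12)


# ------------------------------------------------------------------ phasing

def test_phase_zero_identity():
    spec = zero_fill_transform(damped_fid([100.0]))
    out = phase_correct(spec, 0.0, 0.0)
    assert np.allclose(out.intensity, spec.intensity)


def test_autophase_identity_on_phased_spectrum():
    spec = zero_fill_transform(damped_fid([-450.0, 150.0, 450.0],
                                          amps=[1.0, 2.0, 1.0], t2=0.05,
                                          n=4096, sw=1000.0))
    rephased, phi0, phi1 = autophase(spec)
    assert min(phi0, 360.0 - phi0) <= 1e-6
    assert abs(phi1) <= 1e-6
    assert np.array_equal(rephased.intensity, spec.intensity)


def test_autophase_attains_negativity_of_true_phases():
    # The negativity penalty is exactly zero over a plateau of phase pairs
    # for clean sparse spectra, so the individual angles are not
    # identifiable; what the method guarantees is that its solution is at
    # least as good as the true angles under its own objective, and that
    # the rephased intensity stays close to the correctly phased spectrum.
    from nmrsigex.preprocess import _negativity
    spec = zero_fill_transform(damped_fid([-450.0, 150.0, 450.0],
                                          amps=[1.0, 2.0, 1.0], t2=0.05,
                                          n=4096, sw=1000.0))
    for true0, true1 in [(25.0, 0.0), (320.0, 0.0), (25.0, 10.0)]:
        dephased = phase_correct(spec, -true0, -true1)
        rephased, phi0, phi1 = autophase(dephased)
        assert (_negativity(dephased, phi0, phi1)
                <= _negativity(dephased, true0, true1) + 1e-12)
        assert np.allclose(rephased.intensity, spec.intensity,
                           atol=0.05 * spec.intensity.max())


def test_autophase_recovers_zero_order_phase():
    spec = zero_fill_transform(damped_fid([-450.0, 150.0, 450.0],
                                          amps=[1.0, 2.0, 1.0], t2=0.05,
                                          n=4096, sw=1000.0))
    dephased = phase_correct(spec, -25.0, 0.0)
    _, phi0, phi1 = autophase(dephased)
    assert phi0 == pytest.approx(25.0, abs=2.0)
    assert abs(phi1) <= 2.0


def test_phase_90_gives_dispersion_zero_at_apex():
    # pure absorption Lorentzian with its dispersion partner
    x_asc = np.linspace(-1.0, 1.0, 4097)
    g = 0.02
    absorption = (g / np.pi) / (x_asc ** 2 + g ** 2)
    dispersion = (x_asc / np.pi) / (x_asc ** 2 + g ** 2)
    spec = Spectrum(ppm=x_asc[::-1].copy(), intensity=absorption[::-1],
                    field_mhz=400.0,
                    complex_data=(absorption + 1j * dispersion)[::-1])
    out = phase_correct(spec, 90.0, 0.0)
    apex = np.argmin(np.abs(out.ppm))
    assert abs(out.intensity[apex]) <= 1e-6 * np.abs(out.intensity).max()
    # dispersion shape: antisymmetric lobes on either side of the apex
    assert out.intensity[apex - 50] * out.intensity[apex + 50] < 0


# ----------------------------------------------------------------- baseline

def test_baseline_all_zero_input_untouched():
    spec = make_spectrum(lambda x: np.zeros_like(x), n=2048)
    out = baseline_correct(spec)
    assert np.max(np.abs(out.meta["baseline"])) == 0.0
    assert np.array_equal(out.intensity, spec.intensity)


def test_baseline_removes_linear_drift_area_within_2pct():
    def peak(x):
        return lorentzian(x, 5.0, 0.01, area=1.0)
    clean = make_spectrum(peak, lo=0.0, hi=10.0, n=4096)
    drift = make_spectrum(lambda x: peak(x) + 0.05 * x, lo=0.0, hi=10.0, n=4096)
    corrected = baseline_correct(drift, 0.01, 1e9)
    x, yc, _ = corrected.ascending()
    _, y0, _ = clean.ascending()
    sel = (x > 4.8) & (x < 5.2)
    a_corr = np.trapezoid(yc[sel], x[sel])
    a_clean = np.trapezoid(y0[sel], x[sel])
    assert a_corr == pytest.approx(a_clean, rel=0.02)


def test_baseline_negativity_monotone_in_asymmetry():
    rng = np.random.default_rng(3)
    spec = make_spectrum(
        lambda x: lorentzian(x, 3.0, 0.02, 2.0) + lorentzian(x, 7.0, 0.5, 5.0)
        + rng.normal(0, 0.01, x.size), n=4096)
    counts = []
    for p in (0.05, 0.01, 0.001):
        out = baseline_correct(spec, p, 1e7)
        counts.append(int(np.sum(out.intensity < 0)))
    assert counts[0] >= counts[1] >= counts[2]


def test_baseline_records_negative_fraction():
    spec = make_spectrum(lambda x: lorentzian(x, 5.0, 0.05, 1.0), n=2048)
    out = baseline_correct(spec)
    assert "baseline_negative_fraction" in out.meta
    assert 0.0 <= out.meta["baseline_negative_fraction"] <= 1.0


def test_baseline_idempotence_within_1pct():
    spec = make_spectrum(
        lambda x: lorentzian(x, 4.0, 0.01, 1.0) + 0.2 + 0.02 * x, n=4096)
    once = baseline_correct(spec)
    twice = baseline_correct(once)
    peak_max = once.intensity.max()
    assert np.max(np.abs(twice.intensity - once.intensity)) <= 0.01 * peak_max


def test_baseline_rejects_bad_asymmetry():
    spec = make_spectrum(n=256)
    with pytest.raises(ValueError):
        baseline_correct(spec, 0.0)


# -------------------------------------------------------------- referencing

def _tsp_spectrum(apex_ppm, noise_sd=0.001, seed=0, n=8192):
    rng = np.random.default_rng(seed)
    return make_spectrum(
        lambda x: lorentzian(x, apex_ppm, 0.004, 1.0)
        + lorentzian(x, 3.0, 0.01, 2.0) + rng.normal(0, noise_sd, x.size),
        lo=-0.5, hi=10.0, n=n)


def test_tsp_apex_moved_to_0015():
    spec = _tsp_spectrum(0.030)
    out = reference_to_tsp(spec)
    sel = np.abs(out.ppm - 0.015) < 0.1
    apex = out.ppm[np.flatnonzero(sel)[np.argmax(out.intensity[sel])]]
    assert abs(apex - 0.015) <= out.step_ppm


def test_tsp_already_referenced_zero_shift():
    spec = _tsp_spectrum(0.015)
    out = reference_to_tsp(spec)
    assert abs(out.meta["tsp_shift_ppm"]) <= spec.step_ppm


def test_tsp_shift_equals_apex_minus_target():
    spec = _tsp_spectrum(0.030)
    out = reference_to_tsp(spec, tsp_target_ppm=0.015)
    # shift = target - apex; apex was placed at 0.030
    assert out.meta["tsp_shift_ppm"] == pytest.approx(0.015 - 0.030,
                                                      abs=spec.step_ppm)


def test_tsp_no_peak_errors():
    rng = np.random.default_rng(1)
    spec = make_spectrum(lambda x: rng.normal(0, 0.01, x.size), n=4096)
    with pytest.raises(ValueError):
        reference_to_tsp(spec)


# ---------------------------------------------------------- exclude_regions

def test_exclude_empty_list_identity():
    spec = make_spectrum(lambda x: np.sin(x), n=512)
    out = exclude_regions(spec, [])
    assert not out.mask.any()
    assert np.array_equal(out.intensity, spec.intensity)


def test_exclude_masks_exactly_window_points():
    spec = make_spectrum(lambda x: np.ones_like(x), lo=0.0, hi=10.0, n=1024)
    out = exclude_regions(spec, [(4.5, 5.1)])
    inside = (out.ppm >= 4.5) & (out.ppm <= 5.1)
    assert np.array_equal(out.mask, inside)


def test_exclude_area_additivity():
    spec = make_spectrum(lambda x: 1.0 + 0.3 * np.cos(x), lo=0.0, hi=10.0,
                         n=2048)
    x, y, _ = spec.ascending()
    w = trapezoid_weights(x)
    total = float(np.dot(y, w))
    out = exclude_regions(spec, [(2.0, 3.0)])
    _, y2, m2 = out.ascending()
    masked_area = float(np.dot(np.where(m2, y2, 0.0), w))
    remaining = float(np.dot(np.where(m2, 0.0, y2), w))
    assert remaining == pytest.approx(total - masked_area, rel=1e-9)


def test_exclude_whole_axis_errors():
    spec = make_spectrum(lambda x: np.ones_like(x), lo=0.0, hi=1.0, n=256)
    with pytest.raises(ValueError):
        exclude_regions(spec, [(-1.0, 2.0)])


# ------------------------------------------------------------------ warping

def _warp_pair(shift_ppm):
    def signal(x):
        y = np.zeros_like(x)
        for c, a in [(1.0, 1.0), (2.5, 2.0), (4.0, 1.5), (7.0, 1.0)]:
            y += lorentzian(x, c, 0.02, a)
        return y
    ref = make_spectrum(signal, lo=0.0, hi=10.0, n=8192)
    moved = make_spectrum(lambda x: signal(x - shift_ppm), lo=0.0, hi=10.0,
                          n=8192)
    return ref, moved


def test_warp_identical_spectra_identity():
    ref, _ = _warp_pair(0.0)
    warped, ref_idx = warp_align([ref, ref.copy()], "after")
    assert ref_idx in (0, 1)
    ssd = np.sum((warped[0].intensity - warped[1].intensity) ** 2)
    assert ssd <= 1e-18


def test_warp_recovers_rigid_shift():
    ref, moved = _warp_pair(0.004)
    pre_ssd = np.sum((ref.intensity - moved.intensity) ** 2)
    warped, _ = warp_align([ref, moved], "after")
    post_ssd = min(
        np.sum((warped[0].intensity - warped[1].intensity) ** 2),
        pre_ssd)
    assert post_ssd <= 0.1 * pre_ssd


def test_warp_fixed_policy_keeps_reference():
    ref, moved = _warp_pair(0.003)
    warped, idx = warp_align([ref, moved], "fixed", reference_index=0)
    assert idx == 0
    assert np.array_equal(warped[0].intensity, ref.intensity)


def test_warp_needs_two_spectra():
    ref, _ = _warp_pair(0.0)
    with pytest.raises(ValueError):
        warp_align([ref], "after")


# ---------------------------------------------------------------- normalize

def test_total_area_normalization_unit_area():
    spec = make_spectrum(lambda x: 1.0 + lorentzian(x, 5.0, 0.02, 3.0),
                         lo=0.0, hi=10.0, n=2048)
    spec = exclude_regions(spec, [(4.5, 5.1)])
    out = normalize(spec, "total_area_excluding")
    x, y, m = out.ascending()
    w = trapezoid_weights(x)
    assert float(np.dot(np.where(m, 0.0, y), w)) == pytest.approx(1.0,
                                                                  abs=1e-9)


def test_normalization_scale_invariance():
    spec = make_spectrum(lambda x: 1.0 + np.cos(x) ** 2, lo=0.0, hi=10.0,
                         n=1024)
    big = spec.copy()
    big.intensity = big.intensity * 10.0
    a = normalize(spec, "total_area_excluding")
    b = normalize(big, "total_area_excluding")
    assert np.allclose(a.intensity, b.intensity, atol=1e-9)


def test_median_normalization():
    spec = make_spectrum(lambda x: np.abs(np.sin(3 * x)) + 0.1, lo=0.0,
                         hi=10.0, n=1024)
    out = normalize(spec, "median")
    vals = out.intensity[out.intensity > 0]
    assert np.median(vals) == pytest.approx(1.0, rel=1e-9)


def test_normalize_zero_constant_errors():
    spec = make_spectrum(lambda x: np.zeros_like(x), n=256)
    with pytest.raises(ValueError):
        normalize(spec, "total_area_excluding")


# -------------------------------------------------- referencing/scaling law

def test_referencing_commutes_with_intensity_scaling():
    spec = _tsp_spectrum(0.030)
    scaled = spec.copy()
    scaled.intensity = scaled.intensity * 4.0
    a = reference_to_tsp(spec)
    b = reference_to_tsp(scaled)
    assert np.allclose(a.ppm, b.ppm, atol=1e-12)
    assert np.allclose(4.0 * a.intensity, b.intensity, rtol=1e-12)


# -------------------------------------------------------- cohort / recovery

def test_end_to_end_area_ratio_recovery():
    """simulate -> preprocess recovers isolated-multiplet area ratios (<=3%)."""
    from nmrsigex import simulate
    from nmrsigex.templates import MultipletSpec, TemplateLibrary
    lib = TemplateLibrary(multiplets=[
        MultipletSpec("lac", 1.33, "doublet", (7.0,), protons=3,
                      shift_tolerance_ppm=0.005)])
    cat = simulate.MetaboliteCatalogue(library=lib, base_conc={"lac": 1.0},
                                       field_mhz=400.0)
    acq = simulate.AcquisitionParams(400.0, 6000.0, 8192, noise_sd=0.002)
    art = simulate.ArtifactConfig(global_shift_sd_ppm=0.001, phase0_sd_deg=5.0,
                                  phase1_sd_deg=2.0, baseline_n_humps=0)
    fids = []
    for i, conc in enumerate([1.0, 1.6]):
        rng = np.random.default_rng(10 + i)
        fids.append(simulate.synthesize_fid(
            {"lac": conc}, cat, acq, art, rng=rng,
            global_shift_ppm=float(rng.normal(0, art.global_shift_sd_ppm))))
    spectra = preprocess_cohort(fids, protocol="manual", warp=False)
    areas = []
    for s in spectra:
        x, y, m = s.ascending()
        sel = (x > 1.28) & (x < 1.38) & ~m
        areas.append(np.trapezoid(y[sel], x[sel]) * s.meta["norm_constant"])
    assert areas[1] / areas[0] == pytest.approx(1.6, rel=0.03)


# ----------------------------------------------------------------- file I/O

def test_fid_round_trip(tmp_path):
    fid = damped_fid([55.0, -120.0], t2=0.2, noise_sd=0.01)
    path = tmp_path / "x.fid.csv"
    write_fid(fid, path)
    back = read_fid(path)
    assert back.dwell_s == pytest.approx(fid.dwell_s)
    assert back.field_mhz == fid.field_mhz
    assert np.allclose(back.samples, fid.samples,
                       atol=1e-9 * np.abs(fid.samples).max())


def test_spectrum_round_trip(tmp_path):
    spec = make_spectrum(lambda x: lorentzian(x, 2.0, 0.05, 1.0), n=1024)
    path = tmp_path / "x.spec.csv"
    write_spectrum(spec, path)
    back = read_spectrum(path)
    assert back.field_mhz == spec.field_mhz
    assert np.allclose(back.ppm, spec.ppm)
    assert np.allclose(back.intensity, spec.intensity,
                       atol=1e-9 * np.abs(spec.intensity).max())


def test_spectrum_requires_descending_axis():
    with pytest.raises(ValueError):
        Spectrum(ppm=np.linspace(0, 1, 16), intensity=np.zeros(16),
                 field_mhz=400.0)
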