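"""Diffraction peak fitting, Bragg spacings, Scherrer sizes, gap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibrilwater.lineshapes import pseudo_voigt
from fibrilwater.synthetic import CELLULOSE_XRD_PEAKS, generate_xrd_pattern
from fibrilwater.xrd import (
    CU_KALPHA,
    DiffractionPeak,
    bragg_spacing,
    fit_diffraction_peaks,
    interfibril_gap,
    peak_report,
    scherrer_size,
)


# --- peak fitting ---------------------------------------------------------------


def test_four_peak_pattern_recovery():
    """Centers within 0.05 degrees and FWHMs within 5% at 1% noise."""
    pattern = generate_xrd_pattern(noise=0.01, seed=4)
    init = [{"hkl": p["hkl"], "center": p["center"]} for p in CELLULOSE_XRD_PEAKS]
    peaks, _ = fit_diffraction_peaks(pattern, init)
    truth = sorted(CELLULOSE_XRD_PEAKS, key=lambda p: p["center"])
    for fit, true in zip(peaks, truth):
        assert abs(fit.center - true["center"]) <= 0.05
        assert abs(fit.fwhm_deg - true["fwhm"]) <= 0.05 * true["fwhm"]


@pytest.mark.parametrize("peaks", [
    [dict(hkl="a", center=15.0, fwhm=1.5, eta=0.3, amplitude=80.0)],
    [dict(hkl="a", center=12.0, fwhm=1.0, eta=0.7, amplitude=50.0),
     dict(hkl="b", center=25.0, fwhm=2.5, eta=0.2, amplitude=90.0)],
    [dict(hkl="a", center=20.0, fwhm=0.8, eta=0.0, amplitude=120.0)],
    [dict(hkl="a", center=30.0, fwhm=3.0, eta=1.0, amplitude=40.0)],
    [dict(hkl="a", center=17.0, fwhm=1.2, eta=0.5, amplitude=200.0)],
])
def test_noiseless_pattern_recovery(peaks):
    pattern = generate_xrd_pattern(peaks=peaks, noise=0.0)
    init = [{"hkl": p["hkl"], "center": p["center"] + 0.2} for p in peaks]
    fitted, _ = fit_diffraction_peaks(pattern, init)
    for fit, true in zip(fitted, sorted(peaks, key=lambda p: p["center"])):
        assert fit.center == pytest.approx(true["center"], abs=1e-3)
        assert fit.fwhm_deg == pytest.approx(true["fwhm"], rel=1e-3)
        assert fit.amplitude == pytest.approx(true["amplitude"], rel=1e-3)


def test_pure_gaussian_identified():
    pattern = generate_xrd_pattern(
        peaks=[dict(hkl="g", center=18.0, fwhm=1.5, eta=0.0, amplitude=100.0)],
        noise=0.005, seed=8,
    )
    peaks, _ = fit_diffraction_peaks(pattern, [{"center": 18.0}])
    assert peaks[0].eta < 0.05


def test_zero_amplitude_peak_on_flat_background():
    pattern = generate_xrd_pattern(peaks=[], background=(0.0, 10.0),
                                   noise=0.005, seed=9)
    peaks, bg = fit_diffraction_peaks(pattern, [{"center": 20.0, "amplitude": 0.5}])
    assert peaks[0].amplitude <= 3.0 * (peaks[0].amplitude_err or 0.2)
    assert bg[1] == pytest.approx(10.0, rel=0.02)


def test_pattern_equals_background_for_zero_amplitude_truth():
    pattern = generate_xrd_pattern(
        peaks=[dict(hkl="z", center=20.0, fwhm=1.0, eta=0.5, amplitude=0.0)],
        background=(0.1, 5.0), noise=0.0,
    )
    assert np.allclose(pattern.counts, 0.1 * pattern.two_theta + 5.0)


def test_center_outside_grid_rejected():
    pattern = generate_xrd_pattern(noise=0.0)
    with pytest.raises(ValueError, match="outside"):
        fit_diffraction_peaks(pattern, [{"center": 80.0}])


def test_single_peak_matches_grid_search_oracle():
    """Dense center-grid oracle and the fitter agree within one grid step."""
    true = dict(hkl="a", center=21.3, fwhm=1.4, eta=0.5, amplitude=75.0)
    pattern = generate_xrd_pattern(peaks=[true], noise=0.0)
    x, y = pattern.two_theta, pattern.counts
    centers = np.arange(20.0, 23.0, 0.05)
    rss = []
    for c in centers:
        model = 10.0 + pseudo_voigt(x, c, true["fwhm"], true["eta"], true["amplitude"])
        rss.append(np.sum((model - y) ** 2))
    oracle = centers[int(np.argmin(rss))]
    peaks, _ = fit_diffraction_peaks(pattern, [{"center": 21.0}])
    assert abs(peaks[0].center - oracle) <= 0.05


# --- Bragg spacing -----------------------------------------------------------------


def test_bragg_worked_values():
    assert bragg_spacing(22.9) == pytest.approx(3.88, abs=0.005)
    assert bragg_spacing(14.8) == pytest.approx(5.99, abs=0.005)


def test_bragg_backscattering_limit():
    assert bragg_spacing(180.0) == pytest.approx(CU_KALPHA / 2.0, rel=1e-12)


def test_bragg_rejects_out_of_range():
    for bad in (0.0, -5.0, 181.0):
        with pytest.raises(ValueError):
            bragg_spacing(bad)


@settings(derandomize=True, max_examples=50)
@given(a=st.floats(1.0, 178.0), delta=st.floats(0.1, 1.0))
def test_bragg_strictly_decreasing(a, delta):
    assert bragg_spacing(a + delta) < bragg_spacing(a)


# --- Scherrer size -----------------------------------------------------------------


def test_scherrer_worked_value():
    """beta = 0.02832 rad at 2theta = 22.9 deg gives a 50.0 A crystallite."""
    assert scherrer_size((22.9, 0.02832)) == pytest.approx(50.0, abs=0.05)


def test_scherrer_inverse_proportionality():
    l1 = scherrer_size((22.9, 0.02))
    l2 = scherrer_size((22.9, 0.04))
    assert l1 == pytest.approx(2.0 * l2, rel=1e-12)


def test_scherrer_degrees_to_radians_conversion():
    """The classic failure mode: a DiffractionPeak stores FWHM in degrees and
    must be converted to radians before the Scherrer formula."""
    peak = DiffractionPeak(hkl="110", center=22.9, fwhm_deg=np.rad2deg(0.02832),
                           eta=0.5, amplitude=1.0)
    assert scherrer_size(peak) == pytest.approx(scherrer_size((22.9, 0.02832)),
                                                rel=1e-12)


@settings(derandomize=True, max_examples=50)
@given(l=st.floats(10.0, 500.0), two_theta=st.floats(5.0, 60.0))
def test_scherrer_inversion_identity(l, two_theta):
    theta = np.deg2rad(two_theta / 2.0)
    beta = 0.9 * CU_KALPHA / (l * np.cos(theta))
    assert scherrer_size((two_theta, beta)) == pytest.approx(l, rel=1e-9)


def test_scherrer_rejects_nonpositive_width():
    with pytest.raises(ValueError):
        scherrer_size((22.9, 0.0))


def test_crystallite_width_roundtrip_50A():
    """A pattern whose 110 width encodes a 50 A crystallite yields 50 +/- 1 A
    after refitting."""
    pattern = generate_xrd_pattern(noise=0.01, seed=14)
    init = [{"hkl": p["hkl"], "center": p["center"]} for p in CELLULOSE_XRD_PEAKS]
    peaks, _ = fit_diffraction_peaks(pattern, init)
    p110 = next(p for p in peaks if p.hkl == "110")
    assert abs(scherrer_size(p110) - 50.0) <= 1.0


# --- interfibrillar gap -------------------------------------------------------------


def test_gap_benchmark():
    assert interfibril_gap(67.0, 50.0)[0] == pytest.approx(17.0, rel=1e-12)


def test_gap_zero_for_touching_fibrils():
    assert interfibril_gap(50.0, 50.0)[0] == 0.0


def test_gap_error_quadrature():
    _, err = interfibril_gap(67.0, 50.0, 0.6, 1.0)
    assert err == pytest.approx(np.hypot(0.6, 1.0), rel=1e-12)
    assert err == pytest.approx(1.17, abs=0.01)


def test_gap_rejects_inconsistent_inputs():
    with pytest.raises(ValueError, match="inconsistent"):
        interfibril_gap(50.0, 67.0)


def test_peak_report_table():
    pattern = generate_xrd_pattern(noise=0.0)
    init = [{"hkl": p["hkl"], "center": p["center"]} for p in CELLULOSE_XRD_PEAKS]
    peaks, _ = fit_diffraction_peaks(pattern, init)
    table = peak_report(peaks)
    assert list(table["hkl"]) == ["100", "010", "11-2", "110"]
    assert table["d_hkl_A"].iloc[-1] == pytest.approx(3.88, abs=0.01)
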