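"""Spectral fitting, susceptibility, elastic-scan MSD and transitions."""

import numpy as np
import pytest

from fibrilwater.mdwater import elastic_intensity_gaussian
from fibrilwater.qens import (
    ElasticScan,
    QENSSpectrum,
    ResolutionModel,
    compare_models,
    compute_susceptibility,
    detect_transitions,
    fit_spectrum,
    msd_from_elastic,
    _segmented_rss,
)
from fibrilwater.synthetic import QENSGroundTruth, generate_elastic_scan, generate_qens_spectrum


# --- fit_spectrum -----------------------------------------------------------

NOISELESS_SETS = [
    dict(x=0.3, p=0.6, narrow_hwhm=1.0, broad_hwhm=10.0, c1=0.0, c2=0.0),
    dict(x=0.1, p=0.5, narrow_hwhm=2.0, broad_hwhm=25.0, c1=0.0, c2=0.001),
    dict(x=0.7, p=0.3, narrow_hwhm=0.5, broad_hwhm=15.0, c1=1e-5, c2=0.002),
    dict(x=0.5, p=0.8, narrow_hwhm=3.0, broad_hwhm=30.0, c1=0.0, c2=0.0),
    dict(x=0.2, p=0.4, narrow_hwhm=1.5, broad_hwhm=40.0, c1=-1e-5, c2=0.005),
    dict(x=0.4, p=0.5, narrow_hwhm=0.8, broad_hwhm=20.0, c1=0.0, c2=0.0005),
    dict(x=0.6, p=0.7, narrow_hwhm=2.5, broad_hwhm=12.0, c1=0.0, c2=0.0),
    dict(x=0.35, p=0.55, narrow_hwhm=4.0, broad_hwhm=35.0, c1=2e-5, c2=0.001),
    dict(x=0.15, p=0.25, narrow_hwhm=1.2, broad_hwhm=18.0, c1=0.0, c2=0.003),
    dict(x=0.45, p=0.65, narrow_hwhm=0.6, broad_hwhm=22.0, c1=0.0, c2=0.0),
]


@pytest.mark.parametrize("params", NOISELESS_SETS)
def test_noiseless_exact_recovery(params, e_grid, resolution):
    """Noiseless spectra are recovered to <= 0.1% relative in every parameter."""
    truth = QENSGroundTruth(noise=0.0, **params)
    spec = generate_qens_spectrum(truth, np.array([0.5]), e_grid)
    fit = fit_spectrum(spec, resolution, n_lorentzians=2).table.iloc[0]
    assert fit["success"]
    for key, expected in [("x", params["x"]), ("p", params["p"]),
                          ("gamma1", params["narrow_hwhm"]),
                          ("gamma2", params["broad_hwhm"])]:
        assert fit[key] == pytest.approx(expected, rel=1e-3), key


def test_pure_elastic_spectrum(e_grid, resolution):
    truth = QENSGroundTruth(x=1.0, p=0.5, narrow_hwhm=1.0, noise=0.0, c2=0.0)
    spec = generate_qens_spectrum(truth, np.array([0.5]), e_grid)
    fit = fit_spectrum(spec, resolution).table.iloc[0]
    assert fit["x"] >= 0.99
    # quasi-elastic amplitude consistent with zero
    assert fit["scale"] * (1.0 - fit["x"]) <= 0.01 * fit["scale"]


def test_resolution_curve_fits_as_elastic(e_grid, resolution):
    """A spectrum identical to the resolution line shape is purely elastic."""
    r = resolution.evaluate(e_grid)
    spec = QENSSpectrum(
        q=np.array([0.5]), e=e_grid, intensity=r[None, :],
        sigma=np.full((1, len(e_grid)), 1e-5), temperature=250.0,
    )
    fit = fit_spectrum(spec, resolution).table.iloc[0]
    assert fit["x"] >= 0.99


def test_information_criterion_prefers_two_components(e_grid, resolution):
    truth = QENSGroundTruth(x=0.3, p=0.5, narrow_hwhm=1.0, broad_hwhm=30.0,
                            noise=0.005, seed=11)
    spec = generate_qens_spectrum(truth, np.array([0.5, 0.7]), e_grid)
    _, _, preferred = compare_models(spec, resolution)
    assert preferred == 2


def test_gamma_ordering_convention(e_grid, resolution):
    """Components are always reported narrow-first regardless of the truth."""
    truth = QENSGroundTruth(x=0.3, p=0.2, narrow_hwhm=2.0, broad_hwhm=28.0, noise=0.0)
    spec = generate_qens_spectrum(truth, np.array([0.5]), e_grid)
    fit = fit_spectrum(spec, resolution).table.iloc[0]
    assert fit["gamma1"] <= fit["gamma2"]
    assert fit["p"] == pytest.approx(0.2, rel=1e-3)


def test_too_few_points_rejected(resolution):
    e = np.linspace(-120, 120, 49)
    spec = QENSSpectrum(q=np.array([0.5]), e=e, intensity=np.ones((1, 49)),
                        sigma=np.ones((1, 49)), temperature=250.0)
    with pytest.raises(ValueError, match="50 energy points"):
        fit_spectrum(spec, resolution, fit_window=(-100, 100))


# --- susceptibility ---------------------------------------------------------


def _flat_spectrum(e_grid, value, temperature):
    n = len(e_grid)
    return QENSSpectrum(
        q=np.array([0.5]), e=e_grid, intensity=np.full((1, n), value),
        sigma=np.full((1, n), 1e-3), temperature=temperature,
    )


def test_susceptibility_zero_for_zero_s(e_grid):
    chi = compute_susceptibility(_flat_spectrum(e_grid, 0.0, 250.0))
    assert np.all(chi.chi == 0.0)


def test_susceptibility_bose_factor_value(e_grid):
    """S=1, T=250 K, E=21.543 ueV: kB*T = 21543 ueV so chi = exp(0.001)-1."""
    chi = compute_susceptibility(_flat_spectrum(e_grid, 1.0, 250.0))
    val = np.interp(21.543, chi.e, chi.chi[0])
    assert val == pytest.approx(np.expm1(0.001), rel=1e-4)


def test_susceptibility_monotone_in_e(e_grid):
    chi = compute_susceptibility(_flat_spectrum(e_grid, 1.0, 250.0))
    assert np.all(np.diff(chi.chi[0]) > 0)
    assert np.all(chi.e > 0) and chi.e[-1] <= 100.0


def test_susceptibility_rejects_nonpositive_temperature(e_grid):
    with pytest.raises(ValueError, match="temperature"):
        compute_susceptibility(_flat_spectrum(e_grid, 1.0, -1.0))


@pytest.mark.parametrize("gammas", [[1.0, 3.0, 10.0, 30.0]])
def test_susceptibility_peak_moves_with_width(e_grid, resolution, gammas):
    """chi'' of a Lorentzian-broadened spectrum peaks at higher E for larger
    Gamma (the qualitative susceptibility-representation behaviour)."""
    from fibrilwater.lineshapes import lorentzian

    positions = []
    for g in gammas:
        n = len(e_grid)
        spec = QENSSpectrum(
            q=np.array([0.5]), e=e_grid,
            intensity=lorentzian(e_grid, g)[None, :],
            sigma=np.full((1, n), 1e-6), temperature=250.0,
        )
        chi = compute_susceptibility(spec)
        positions.append(chi.e[np.argmax(chi.chi[0])])
    assert np.all(np.diff(positions) > 0)


# --- MSD from elastic intensity --------------------------------------------


def _scan_from_msd(msd, q, scale=1.0):
    s_el = scale * elastic_intensity_gaussian(msd, q)
    return ElasticScan(t=np.array([100.0, 200.0]), q=q,
                       intensity=np.column_stack([s_el, s_el]))


def test_msd_zero_for_flat_elastic():
    q = np.linspace(0.5, 0.9, 5)
    scan = ElasticScan(t=np.array([100.0, 200.0]), q=q,
                       intensity=np.ones((5, 2)))
    msd, err = msd_from_elastic(scan, 100.0)
    assert msd == pytest.approx(0.0, abs=1e-12)


def test_msd_inverts_gaussian_approximation_exactly():
    q = np.linspace(0.5, 0.9, 5)
    msd, err = msd_from_elastic(_scan_from_msd(1.2, q), 100.0)
    assert msd == pytest.approx(1.2, abs=1e-6)


def test_msd_scale_invariance():
    q = np.linspace(0.5, 0.9, 7)
    m1, _ = msd_from_elastic(_scan_from_msd(0.8, q), 100.0)
    m2, _ = msd_from_elastic(_scan_from_msd(0.8, q, scale=37.0), 100.0)
    assert m1 == pytest.approx(m2, abs=1e-12)


def test_msd_roundtrip_with_gaussian_intensity_many_values():
    q = np.linspace(0.5, 0.9, 9)
    for msd_true in [0.1, 0.5, 1.0, 2.5, 5.0]:
        msd, _ = msd_from_elastic(_scan_from_msd(msd_true, q), 100.0)
        assert msd == pytest.approx(msd_true, abs=1e-6)


def test_msd_rejects_nonpositive_intensity():
    q = np.linspace(0.5, 0.9, 5)
    scan = ElasticScan(t=np.array([100.0, 200.0]), q=q,
                       intensity=-np.ones((5, 2)))
    with pytest.raises(ValueError, match="non-positive"):
        msd_from_elastic(scan, 100.0)


# --- transition detection ---------------------------------------------------


def test_transitions_recovered_from_noisy_scan():
    scan = generate_elastic_scan(
        np.array([0.5, 0.7, 0.9]), np.arange(10.0, 291.0, 5.0),
        transition_temps=(220.0, 260.0), noise=0.01, seed=7,
    )
    found = detect_transitions(scan, max_transitions=2)
    assert len(found) == 2
    assert abs(found[0][0] - 220.0) <= 5.0
    assert abs(found[1][0] - 260.0) <= 5.0


def test_no_transitions_in_flat_or_single_slope_scan():
    t = np.arange(10.0, 291.0, 10.0)
    flat = generate_elastic_scan(np.array([0.7]), t, step_depths=(0.0, 0.0),
                                 base_slope=0.0, noise=0.005, seed=3)
    slope = generate_elastic_scan(np.array([0.7]), t, step_depths=(0.0, 0.0),
                                  base_slope=1e-3, noise=0.005, seed=4)
    assert detect_transitions(flat, 2) == []
    assert detect_transitions(slope, 2) == []


def test_transitions_match_bruteforce_oracle():
    """Exhaustive double-loop breakpoint search gives the same segmentation."""
    t = np.linspace(100.0, 240.0, 15)
    y = 1.0 - 1e-3 * (t - 100.0) - 8e-3 * np.clip(t - 160.0, 0, None) \
        - 1.5e-2 * np.clip(t - 200.0, 0, None)
    rng = np.random.default_rng(5)
    y = y + rng.normal(0.0, 0.004, y.shape)
    scan = ElasticScan(t=t, q=np.array([0.7]), intensity=y[None, :])

    best_rss, best_pair = np.inf, None
    for i in range(2, 13):
        for j in range(i + 2, 13):
            rss, _ = _segmented_rss(t, y, [t[i], t[j]])
            if rss < best_rss:
                best_rss, best_pair = rss, (t[i], t[j])
    found = detect_transitions(scan, max_transitions=2)
    assert [round(b, 6) for b, _ in found] == [round(v, 6) for v in best_pair]


def test_transitions_need_enough_points():
    scan = ElasticScan(t=np.linspace(100, 200, 5), q=np.array([0.7]),
                       intensity=np.ones((1, 5)))
    with pytest.raises(ValueError, match="10 temperature"):
        detect_transitions(scan)
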