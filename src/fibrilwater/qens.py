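"""Quasi-elastic neutron scattering (QENS) analysis.

The measured dynamic structure factor of hydration water on a backscattering
spectrometer is modelled per momentum transfer Q as

    I(Q, E) = scale * [ x(Q) delta(E) + (1 - x(Q)) S(Q, E) ] (x) R(Q, E)
              + C1(Q) E + C2(Q)

where x is the elastic fraction, R the instrument resolution function,
(x) denotes convolution in energy transfer E, and the quasi-elastic part is
a one- or two-Lorentzian model

    S(Q, E) = p L(E; Gamma1) + (1 - p) L(E; Gamma2),   Gamma1 <= Gamma2,

with p the spectral weight of the narrow component.  The module also
converts spectra into the imaginary part of the dynamic susceptibility via
the Bose factor, extracts mean-square displacements from elastic-intensity
scans in the Gaussian approximation, and locates dynamical-transition
temperatures by segmented linear regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import lmfit
import numpy as np
import pandas as pd

from .constants import KB_UEV_PER_K
from .lineshapes import gaussian, lorentzian

__all__ = [
    "ResolutionModel",
    "QENSSpectrum",
    "SpectralFit",
    "SusceptibilityCurve",
    "ElasticScan",
    "convolve_with_resolution",
    "fit_spectrum",
    "compare_models",
    "compute_susceptibility",
    "msd_from_elastic",
    "detect_transitions",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ResolutionModel:
    """Instrument resolution in energy transfer.

    Either an analytic Gaussian of given FWHM (ueV), the default for a
    backscattering spectrometer quoted as "3.5 ueV FWHM", or a tabulated
    two-column curve (E, R) measured at low temperature.  The curve is
    renormalised to unit area on the analysis grid.
    """

    fwhm: float | None = 3.5
    curve: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.curve is None and (self.fwhm is None or self.fwhm <= 0):
            raise ValueError("analytic resolution requires a positive FWHM")
        if self.curve is not None:
            e, r = (np.asarray(a, float) for a in self.curve)
            if e.ndim != 1 or e.shape != r.shape or len(e) < 3:
                raise ValueError("tabulated resolution must be two equal 1-d columns")
            if np.any(np.diff(e) <= 0):
                raise ValueError("tabulated resolution grid must be increasing")
            self.curve = (e, r)

    def evaluate(self, e: np.ndarray) -> np.ndarray:
        """Resolution line shape on ``e``, renormalised to unit area."""
        e = np.asarray(e, float)
        if self.curve is not None:
            eg, rg = self.curve
            r = np.interp(e, eg, rg, left=0.0, right=0.0)
        else:
            r = gaussian(e, self.fwhm)
        area = np.trapezoid(r, e)
        if area <= 0:
            raise ValueError("resolution curve has non-positive area on this grid")
        return r / area

    def width_fwhm(self) -> float:
        """FWHM in ueV (measured numerically for tabulated curves)."""
        if self.curve is None:
            return float(self.fwhm)
        e, r = self.curve
        half = r.max() / 2.0
        above = np.where(r >= half)[0]
        return float(e[above[-1]] - e[above[0]])


@dataclass
class QENSSpectrum:
    """S(Q, E) with uncertainties at a single temperature.

    ``intensity`` and ``sigma`` are (nQ, nE) arrays on strictly increasing
    ``q`` (1/A) and ``e`` (ueV) grids; the energy grid must span both signs
    of energy transfer.
    """

    q: np.ndarray
    e: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    temperature: float
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.q = np.atleast_1d(np.asarray(self.q, float))
        self.e = np.asarray(self.e, float)
        self.intensity = np.atleast_2d(np.asarray(self.intensity, float))
        self.sigma = np.atleast_2d(np.asarray(self.sigma, float))
        if np.any(np.diff(self.q) <= 0) or np.any(np.diff(self.e) <= 0):
            raise ValueError("Q and E grids must be strictly increasing")
        if self.e[0] >= 0 or self.e[-1] <= 0:
            raise ValueError("energy grid must span both signs of energy transfer")
        if self.intensity.shape != (len(self.q), len(self.e)):
            raise ValueError("intensity shape does not match (nQ, nE)")
        if self.sigma.shape != self.intensity.shape or np.any(self.sigma <= 0):
            raise ValueError("uncertainties must be positive and match intensity")


@dataclass
class SpectralFit:
    """Per-Q parameters of the elastic + Lorentzian model.

    ``table`` columns: q, x, x_err, p, p_err, gamma1, gamma1_err, gamma2,
    gamma2_err, c1, c2, scale, redchi, aicc, success.  Components are sorted
    so gamma1 <= gamma2 and p always refers to the narrow component.
    """

    table: pd.DataFrame
    n_lorentzians: int
    temperature: float

    def narrow_component(self) -> pd.DataFrame:
        """(Q, Gamma, sigma_Gamma) of the narrow Lorentzian, converged Q only."""
        ok = self.table[self.table["success"]]
        return ok[["q", "gamma1", "gamma1_err"]].rename(
            columns={"gamma1": "gamma", "gamma1_err": "gamma_err"}
        )


@dataclass
class SusceptibilityCurve:
    """Imaginary dynamic susceptibility chi''(Q, E) on the positive-E side.

    The overall scale is arbitrary (the Bose-factor relation is a
    proportionality); only shapes and peak positions are meaningful.
    """

    q: np.ndarray
    e: np.ndarray
    chi: np.ndarray
    temperature: float


@dataclass
class ElasticScan:
    """Elastic intensity S_el(Q, T) versus temperature."""

    t: np.ndarray
    q: np.ndarray
    intensity: np.ndarray  # (nQ, nT)
    sigma: np.ndarray | None = None
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.q = np.atleast_1d(np.asarray(self.q, float))
        self.intensity = np.atleast_2d(np.asarray(self.intensity, float))
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if self.intensity.shape != (len(self.q), len(self.t)):
            raise ValueError("intensity shape does not match (nQ, nT)")


# ---------------------------------------------------------------------------
# resolution convolution
# ---------------------------------------------------------------------------


def _grid_step(e: np.ndarray) -> float:
    de = np.diff(e)
    if len(de) == 0 or not np.allclose(de, de[0], rtol=1e-8, atol=1e-12):
        raise ValueError("energy grid must be uniform for convolution")
    return float(de[0])


def convolve_with_resolution(
    e: np.ndarray, curve: np.ndarray, resolution: ResolutionModel
) -> np.ndarray:
    """Convolve ``curve`` (sampled on uniform grid ``e``) with the resolution.

    The kernel is sampled on the same step, renormalised to unit discrete
    area, and the input is zero-padded by the kernel half-length so that a
    unit-area input yields a unit-area output on the padded grid.  The
    returned array is on the input grid.
    """
    e = np.asarray(e, float)
    curve = np.asarray(curve, float)
    if curve.shape != e.shape:
        raise ValueError("curve and grid shapes differ")
    if not np.all(np.isfinite(curve)):
        raise ValueError("model curve must be finite")
    de = _grid_step(e)
    span = e[-1] - e[0]
    if resolution.width_fwhm() > span:
        raise ValueError("resolution is wider than the energy-grid span")
    kernel = _resolution_kernel(resolution, de, span)
    half = (len(kernel) - 1) // 2
    padded = np.concatenate([np.zeros(half), curve, np.zeros(half)])
    out = np.convolve(padded, kernel, mode="same") * de
    return out[half : half + len(curve)]


def _resolution_kernel(
    resolution: ResolutionModel, de: float, span: float
) -> np.ndarray:
    """Symmetric discrete kernel with unit area (sum * de == 1)."""
    if resolution.curve is not None:
        eg, _ = resolution.curve
        support = max(abs(eg[0]), abs(eg[-1]))
    else:
        sigma = resolution.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        support = 9.0 * sigma
    support = min(support, span)  # never wider than the data window
    n_half = max(1, int(np.ceil(support / de)))
    offsets = de * np.arange(-n_half, n_half + 1)
    k = resolution.evaluate(offsets)
    return k / (k.sum() * de)


# ---------------------------------------------------------------------------
# spectral fitting
# ---------------------------------------------------------------------------


def _spectral_model(
    e: np.ndarray,
    resolution_curve: np.ndarray,
    kernel: np.ndarray,
    de: float,
    scale: float,
    x: float,
    p: float,
    gamma1: float,
    gamma2: float | None,
    c1: float,
    c2: float,
) -> np.ndarray:
    """Evaluate the resolution-convolved elastic + Lorentzian model."""
    if gamma2 is None:
        qe = lorentzian(e, gamma1)
    else:
        qe = p * lorentzian(e, gamma1) + (1.0 - p) * lorentzian(e, gamma2)
    half = (len(kernel) - 1) // 2
    padded = np.concatenate([np.zeros(half), qe, np.zeros(half)])
    broadened = np.convolve(padded, kernel, mode="same")[half : half + len(e)] * de
    # delta (x) R == R itself: the elastic line is the resolution shape
    return scale * (x * resolution_curve + (1.0 - x) * broadened) + c1 * e + c2


def fit_spectrum(
    spectrum: QENSSpectrum,
    resolution: ResolutionModel,
    n_lorentzians: int = 2,
    fit_window: tuple[float, float] = (-100.0, 100.0),
) -> SpectralFit:
    """Weighted least-squares fit of the spectral model at every Q.

    Parameters are bounded (x, p in [0, 1]; widths positive); after each fit
    the two Lorentzians are relabelled so the narrow one comes first and p
    reports its weight.  Non-convergence at one Q is flagged without
    affecting the others.  The per-Q table carries a small-sample-corrected
    Akaike information criterion for one- versus two-component comparison.
    """
    if n_lorentzians not in (1, 2):
        raise ValueError("n_lorentzians must be 1 or 2")
    lo, hi = fit_window
    mask = (spectrum.e >= lo) & (spectrum.e <= hi)
    if mask.sum() < 50:
        raise ValueError("need at least 50 energy points inside the fit window")
    e = spectrum.e[mask]
    de = _grid_step(e)
    res_curve = resolution.evaluate(e)
    kernel = _resolution_kernel(resolution, de, e[-1] - e[0])

    rows = []
    for iq, qval in enumerate(spectrum.q):
        y = spectrum.intensity[iq, mask]
        s = spectrum.sigma[iq, mask]
        rows.append(
            _fit_one_q(qval, e, y, s, res_curve, kernel, de, n_lorentzians)
        )
    table = pd.DataFrame(rows)
    return SpectralFit(table=table, n_lorentzians=n_lorentzians,
                       temperature=spectrum.temperature)


def _fit_one_q(qval, e, y, s, res_curve, kernel, de, n_lorentzians) -> dict:
    params = lmfit.Parameters()
    # initial x from the ratio of the data peak to the (unit-area) resolution
    # peak, assuming the quasi-elastic part is broad and flat underneath
    y0 = max(float(y[np.argmin(np.abs(e))]), 1e-30)
    scale0 = max(np.trapezoid(np.clip(y, 0, None), e), 1e-30)
    x0 = float(np.clip(y0 / (scale0 * res_curve.max()), 0.05, 0.95))
    params.add("scale", value=scale0, min=1e-12)
    params.add("x", value=x0, min=0.0, max=1.0)
    params.add("gamma1", value=1.0, min=1e-4, max=5e3)
    if n_lorentzians == 2:
        params.add("p", value=0.5, min=0.0, max=1.0)
        params.add("gamma2", value=20.0, min=1e-4, max=5e3)
    params.add("c1", value=0.0)
    params.add("c2", value=float(np.median(y[:5])), min=-np.inf)

    def residual(pars):
        v = pars.valuesdict()
        model = _spectral_model(
            e, res_curve, kernel, de, v["scale"], v["x"],
            v.get("p", 1.0), v["gamma1"], v.get("gamma2"), v["c1"], v["c2"],
        )
        return (y - model) / s

    try:
        out = lmfit.minimize(residual, params, method="leastsq")
        success = bool(out.success)
    except Exception:  # pragma: no cover - lmfit failure path
        out, success = None, False

    row = {"q": float(qval), "success": success}
    if not success:
        for k in ("x", "p", "gamma1", "gamma2", "c1", "c2", "scale",
                  "redchi", "aicc"):
            row[k] = np.nan
            if k in ("x", "p", "gamma1", "gamma2"):
                row[k + "_err"] = np.nan
        return row

    v = out.params
    g1, g2 = v["gamma1"].value, (v["gamma2"].value if n_lorentzians == 2 else np.nan)
    g1e = v["gamma1"].stderr
    g2e = v["gamma2"].stderr if n_lorentzians == 2 else np.nan
    p = v["p"].value if n_lorentzians == 2 else 1.0
    pe = v["p"].stderr if n_lorentzians == 2 else np.nan
    if n_lorentzians == 2 and g1 > g2:  # relabel so the narrow component is first
        g1, g2, g1e, g2e = g2, g1, g2e, g1e
        p, pe = 1.0 - p, pe
    if v["c2"].value < 0:
        warnings.warn(f"negative fitted background at Q={qval:.2f}", stacklevel=3)
    n, k = len(e), out.nvarys
    aicc = out.aic + (2.0 * k * (k + 1)) / max(n - k - 1, 1)
    row.update(
        x=v["x"].value, x_err=v["x"].stderr, p=p, p_err=pe,
        gamma1=g1, gamma1_err=g1e, gamma2=g2, gamma2_err=g2e,
        c1=v["c1"].value, c2=v["c2"].value, scale=v["scale"].value,
        redchi=out.redchi, aicc=aicc,
    )
    return row


def compare_models(
    spectrum: QENSSpectrum,
    resolution: ResolutionModel,
    fit_window: tuple[float, float] = (-100.0, 100.0),
) -> tuple[SpectralFit, SpectralFit, int]:
    """Fit with one and two Lorentzians; return both and the preferred count.

    Preference is by the summed small-sample-corrected information criterion
    over converged Q values (lower is better).
    """
    fit1 = fit_spectrum(spectrum, resolution, 1, fit_window)
    fit2 = fit_spectrum(spectrum, resolution, 2, fit_window)
    a1 = fit1.table.loc[fit1.table.success, "aicc"].sum()
    a2 = fit2.table.loc[fit2.table.success, "aicc"].sum()
    return fit1, fit2, (2 if a2 < a1 else 1)


# ---------------------------------------------------------------------------
# susceptibility
# ---------------------------------------------------------------------------


def compute_susceptibility(
    spectrum: QENSSpectrum, e_max: float = 100.0
) -> SusceptibilityCurve:
    """Convert S(Q, E) to chi''(Q, E) on the positive-energy side.

    chi''(Q, E) = S(Q, E) * (exp(E / (kB T)) - 1), the Bose-factor
    normalisation with proportionality constant fixed to 1 (arbitrary
    units), restricted to 0 < E <= ``e_max`` ueV.
    """
    if spectrum.temperature <= 0:
        raise ValueError("temperature must be positive")
    mask = (spectrum.e > 0) & (spectrum.e <= e_max)
    e = spectrum.e[mask]
    bose = np.expm1(e / (KB_UEV_PER_K * spectrum.temperature))
    chi = spectrum.intensity[:, mask] * bose[None, :]
    return SusceptibilityCurve(q=spectrum.q.copy(), e=e, chi=chi,
                               temperature=spectrum.temperature)


# ---------------------------------------------------------------------------
# elastic-scan analysis
# ---------------------------------------------------------------------------


def msd_from_elastic(
    scan: ElasticScan,
    temperature: float,
    q_window: tuple[float, float] = (0.5, 0.9),
) -> tuple[float, float]:
    """Mean-square displacement from S_el(Q) in the Gaussian approximation.

    Fits ln S_el versus Q**2 (intercept free, so any overall intensity scale
    is absorbed) over the given Q window and returns (msd, msd_err) in A**2
    with MSD = -3 * slope.
    """
    it = int(np.argmin(np.abs(scan.t - temperature)))
    qmask = (scan.q >= q_window[0]) & (scan.q <= q_window[1])
    if qmask.sum() < 3:
        raise ValueError("need at least 3 Q points inside the window")
    s_el = scan.intensity[qmask, it]
    if np.any(s_el <= 0):
        raise ValueError("non-positive elastic intensity inside the window")
    q2 = scan.q[qmask] ** 2
    coeffs, cov = np.polyfit(q2, np.log(s_el), 1, cov=True)
    slope_err = float(np.sqrt(cov[0, 0]))
    return -3.0 * float(coeffs[0]), 3.0 * slope_err


def _segmented_rss(t, y, breaks):
    """Continuous piecewise-linear least squares; returns (rss, coeffs)."""
    cols = [np.ones_like(t), t] + [np.clip(t - b, 0.0, None) for b in breaks]
    design = np.column_stack(cols)
    coeffs, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(np.sum((design @ coeffs - y) ** 2))
    return rss, coeffs


def detect_transitions(
    scan: ElasticScan,
    max_transitions: int = 2,
    q_index: int | None = None,
) -> list[tuple[float, float]]:
    """Locate dynamical-transition temperatures in an elastic scan.

    Fits continuous segmented linear models with 0..max_transitions
    breakpoints placed on the temperature grid (exhaustive search) and
    selects the breakpoint count by small-sample-corrected AIC.  Returns
    sorted (temperature, uncertainty) pairs; the uncertainty is half the
    local grid spacing (the resolution of the breakpoint search).
    """
    t = scan.t
    n = len(t)
    if n < 10:
        raise ValueError("need at least 10 temperature points")
    y = scan.intensity[q_index] if q_index is not None else scan.intensity.mean(axis=0)
    # candidate breakpoints: interior points with >=2 points on each side
    candidates = list(range(2, n - 2))
    best = {"aicc": np.inf, "breaks": ()}
    for m in range(0, max_transitions + 1):
        if m == 0:
            combos = [()]
        else:
            combos = [
                c for c in combinations(candidates, m)
                if all(c[j + 1] - c[j] >= 2 for j in range(m - 1))
            ]
        k = 2 + 2 * m + 1  # line params + (slope change, location) per break + variance
        if n - k - 1 <= 0:
            raise ValueError("too few points for the requested segment count")
        for c in combos:
            rss, _ = _segmented_rss(t, y, t[list(c)])
            rss = max(rss, n * 1e-30)
            aicc = n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
            if aicc < best["aicc"]:
                best = {"aicc": aicc, "breaks": c}
    out = []
    for idx in best["breaks"]:
        half_step = 0.5 * max(t[idx + 1] - t[idx], t[idx] - t[idx - 1])
        out.append((float(t[idx]), float(half_step)))
    return sorted(out)
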