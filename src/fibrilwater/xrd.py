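"""Wide-angle X-ray diffraction: pseudo-Voigt peaks, Bragg spacings,
Scherrer crystallite sizes and the interfibrillar gap.

Diffraction peaks of cellulose I are fitted with pseudo-Voigt profiles
(eta * Lorentzian + (1 - eta) * Gaussian, shared FWHM) on a linear
background.  Peak positions give lattice spacings via Bragg's law
d = lambda / (2 sin theta); peak widths give crystallite dimensions via the
Scherrer equation L = 0.9 lambda / (beta_1/2 cos theta), with beta_1/2 the
FWHM in radians and theta half the scattering angle 2theta.  No instrument
broadening is deconvolved from beta_1/2, so L is a lower bound on the true
crystallite size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

from .lineshapes import pseudo_voigt

__all__ = [
    "XRDPattern",
    "DiffractionPeak",
    "fit_diffraction_peaks",
    "bragg_spacing",
    "scherrer_size",
    "interfibril_gap",
    "CU_KALPHA",
]

#: Cu K-alpha wavelength in Angstrom.
CU_KALPHA = 1.542


@dataclass
class XRDPattern:
    """Powder pattern: 2theta (degrees) vs counts, optional sigma."""

    two_theta: np.ndarray
    counts: np.ndarray
    sigma: np.ndarray | None = None
    wavelength: float = CU_KALPHA
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.two_theta = np.asarray(self.two_theta, float)
        self.counts = np.asarray(self.counts, float)
        if np.any(np.diff(self.two_theta) <= 0):
            raise ValueError("2theta grid must be strictly increasing")
        if self.two_theta[0] < 5.0 - 1e-9 or self.two_theta[-1] > 90.0 + 1e-9:
            raise ValueError("2theta grid must lie within 5-90 degrees")
        if self.counts.shape != self.two_theta.shape:
            raise ValueError("counts must match the 2theta grid")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, float)
            if self.sigma.shape != self.counts.shape or np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive and match counts")


@dataclass
class DiffractionPeak:
    """One fitted pseudo-Voigt reflection."""

    hkl: str
    center: float  # 2theta, degrees
    fwhm_deg: float
    eta: float
    amplitude: float
    center_err: float = np.nan
    fwhm_err: float = np.nan
    eta_err: float = np.nan
    amplitude_err: float = np.nan
    converged: bool = True

    @property
    def fwhm_rad(self) -> float:
        """FWHM converted degrees -> radians, as the Scherrer equation needs."""
        return float(np.deg2rad(self.fwhm_deg))


def fit_diffraction_peaks(
    pattern: XRDPattern,
    initial_peaks: list[dict],
) -> tuple[list[DiffractionPeak], tuple[float, float]]:
    """Simultaneous weighted fit of pseudo-Voigt peaks plus linear background.

    ``initial_peaks`` entries carry at least ``center`` (2theta degrees) and
    optionally ``hkl``, ``fwhm``, ``eta``, ``amplitude`` starting values.
    Returns the peaks sorted by center and the background (slope, offset).
    Non-convergence flags every peak and echoes the initial values.
    """
    if not initial_peaks:
        raise ValueError("need at least one initial peak")
    x, y = pattern.two_theta, pattern.counts
    s = pattern.sigma if pattern.sigma is not None else np.full_like(y, max(y.max(), 1.0) * 0.01)
    for pk in initial_peaks:
        if not (x[0] <= pk["center"] <= x[-1]):
            raise ValueError(f"initial center {pk['center']} outside the grid")

    params = lmfit.Parameters()
    for j, pk in enumerate(initial_peaks):
        amp0 = pk.get("amplitude")
        if amp0 is None:
            amp0 = max(float(np.interp(pk["center"], x, y) - np.median(y)), 1.0)
        params.add(f"c{j}", value=pk["center"], min=x[0], max=x[-1])
        params.add(f"w{j}", value=pk.get("fwhm", 1.0), min=1e-3, max=20.0)
        params.add(f"e{j}", value=pk.get("eta", 0.5), min=0.0, max=1.0)
        params.add(f"a{j}", value=amp0, min=0.0)
    params.add("bg_slope", value=0.0)
    params.add("bg_offset", value=float(np.median(y)))

    npk = len(initial_peaks)

    def model(pars):
        v = pars.valuesdict()
        out = v["bg_slope"] * x + v["bg_offset"]
        for j in range(npk):
            out = out + pseudo_voigt(x, v[f"c{j}"], v[f"w{j}"], v[f"e{j}"], v[f"a{j}"])
        return out

    def residual(pars):
        return (model(pars) - y) / s

    out = lmfit.minimize(residual, params, method="leastsq")
    ok = bool(out.success)
    v = out.params
    peaks = []
    for j, pk in enumerate(initial_peaks):
        if ok:
            peaks.append(
                DiffractionPeak(
                    hkl=pk.get("hkl", f"peak{j}"),
                    center=v[f"c{j}"].value, fwhm_deg=v[f"w{j}"].value,
                    eta=v[f"e{j}"].value, amplitude=v[f"a{j}"].value,
                    center_err=v[f"c{j}"].stderr or np.nan,
                    fwhm_err=v[f"w{j}"].stderr or np.nan,
                    eta_err=v[f"e{j}"].stderr or np.nan,
                    amplitude_err=v[f"a{j}"].stderr or np.nan,
                )
            )
        else:  # echo initial values, flagged
            peaks.append(
                DiffractionPeak(
                    hkl=pk.get("hkl", f"peak{j}"), center=pk["center"],
                    fwhm_deg=pk.get("fwhm", np.nan), eta=pk.get("eta", np.nan),
                    amplitude=pk.get("amplitude", np.nan), converged=False,
                )
            )
    peaks.sort(key=lambda p: p.center)
    bg = (v["bg_slope"].value, v["bg_offset"].value) if ok else (np.nan, np.nan)
    return peaks, bg


def bragg_spacing(two_theta: float, wavelength: float = CU_KALPHA) -> float:
    """Lattice spacing d = lambda / (2 sin theta) in Angstrom.

    ``two_theta`` is the full scattering angle in degrees; theta = 2theta/2.
    """
    if not 0.0 < two_theta <= 180.0:
        raise ValueError("2theta must lie in (0, 180] degrees")
    theta = np.deg2rad(two_theta / 2.0)
    return float(wavelength / (2.0 * np.sin(theta)))


def scherrer_size(
    peak: DiffractionPeak | tuple[float, float],
    wavelength: float = CU_KALPHA,
    shape_factor: float = 0.9,
) -> float:
    """Crystallite dimension L = K lambda / (beta_1/2 cos theta) in Angstrom.

    Accepts a fitted DiffractionPeak (FWHM stored in degrees, converted to
    radians here) or a raw (two_theta_deg, fwhm_rad) pair.
    """
    if isinstance(peak, DiffractionPeak):
        two_theta, beta = peak.center, peak.fwhm_rad
    else:
        two_theta, beta = peak
    if not 0.0 < two_theta < 180.0:
        raise ValueError("2theta must lie in (0, 180) degrees")
    if beta <= 0:
        raise ValueError("FWHM must be positive")
    theta = np.deg2rad(two_theta / 2.0)
    return float(shape_factor * wavelength / (beta * np.cos(theta)))


def interfibril_gap(
    repeat_distance: float,
    crystallite_width: float,
    repeat_err: float = 0.0,
    width_err: float = 0.0,
) -> tuple[float, float]:
    """Space between neighbouring microfibrils: center-to-center repeat
    distance (SANS) minus crystallite width (XRD), errors in quadrature."""
    if repeat_distance <= 0 or crystallite_width <= 0:
        raise ValueError("distances must be positive")
    gap = repeat_distance - crystallite_width
    if gap < 0:
        raise ValueError(
            "repeat distance smaller than crystallite width: inconsistent inputs"
        )
    return float(gap), float(np.hypot(repeat_err, width_err))


def peak_report(
    peaks: list[DiffractionPeak], wavelength: float = CU_KALPHA
) -> pd.DataFrame:
    """Per-peak table: hkl, center, FWHM (deg), d_hkl (A), L_hkl (A)."""
    rows = []
    for p in peaks:
        rows.append(
            {
                "hkl": p.hkl,
                "center_2theta_deg": p.center,
                "fwhm_deg": p.fwhm_deg,
                "eta": p.eta,
                "d_hkl_A": bragg_spacing(p.center, wavelength),
                "L_hkl_A": scherrer_size(p, wavelength) if p.fwhm_deg > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
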