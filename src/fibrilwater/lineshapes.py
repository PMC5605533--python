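"""Elementary line shapes shared by the scattering modules.

All energy-space shapes are parametrised by their width at half maximum
(HWHM for Lorentzians, FWHM for Gaussians, matching the conventions of the
scattering literature) and are normalised to unit area unless stated
otherwise.  Diffraction peaks use peak-height amplitude instead, which is
how diffraction fitting programs quote pseudo-Voigt intensities.
"""

from __future__ import annotations

import numpy as np

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gaussian(x: np.ndarray, fwhm: float, center: float = 0.0) -> np.ndarray:
    """Unit-area Gaussian with the given full width at half maximum."""
    if fwhm <= 0:
        raise ValueError("Gaussian FWHM must be positive")
    sigma = fwhm * _FWHM_TO_SIGMA
    z = (np.asarray(x, dtype=float) - center) / sigma
    return np.exp(-0.5 * z * z) / (sigma * np.sqrt(2.0 * np.pi))


def lorentzian(x: np.ndarray, hwhm: float, center: float = 0.0) -> np.ndarray:
    """Unit-area Lorentzian with the given half width at half maximum."""
    if hwhm <= 0:
        raise ValueError("Lorentzian HWHM must be positive")
    dx = np.asarray(x, dtype=float) - center
    return (hwhm / np.pi) / (dx * dx + hwhm * hwhm)


def gaussian_peak(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-height Gaussian (diffraction convention)."""
    if fwhm <= 0:
        raise ValueError("FWHM must be positive")
    return np.exp(-4.0 * np.log(2.0) * ((np.asarray(x, float) - center) / fwhm) ** 2)


def lorentzian_peak(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-height Lorentzian (diffraction convention)."""
    if fwhm <= 0:
        raise ValueError("FWHM must be positive")
    h = fwhm / 2.0
    dx = np.asarray(x, float) - center
    return h * h / (dx * dx + h * h)


def pseudo_voigt(
    x: np.ndarray, center: float, fwhm: float, eta: float, amplitude: float = 1.0
) -> np.ndarray:
    """Pseudo-Voigt peak: eta*Lorentzian + (1-eta)*Gaussian, shared FWHM.

    ``amplitude`` is the peak height at ``center``.  ``eta`` interpolates
    between a pure Gaussian (0) and a pure Lorentzian (1).
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError("pseudo-Voigt mixing eta must lie in [0, 1]")
    return amplitude * (
        eta * lorentzian_peak(x, center, fwhm)
        + (1.0 - eta) * gaussian_peak(x, center, fwhm)
    )


def correlation_peak(
    q: np.ndarray, scale: float, width: float, center: float
) -> np.ndarray:
    """Lorentzian correlation peak used for SANS interference maxima.

    I(Q) = A * (1/pi) * (w/2) / ((w/2)**2 + (Q - center)**2)

    with scale factor A, full width w and peak center.  The value at the
    center is 2A/(pi*w).
    """
    if width <= 0:
        raise ValueError("correlation-peak width must be positive")
    h = width / 2.0
    dq = np.asarray(q, float) - center
    return scale * (1.0 / np.pi) * h / (h * h + dq * dq)
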