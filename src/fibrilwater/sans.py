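"""Small-angle neutron scattering: power law plus correlation peak.

Reduced SANS intensity from a fibrillar material is modelled as

    I(Q) = (P * Q)**(-alpha) + B

(surface/mass-fractal power law with scale P, exponent alpha, flat
incoherent background B).  A hydrated sample additionally shows an
interference maximum between neighbouring microfibrils, modelled after
power-law subtraction by a Lorentzian correlation peak

    I(Q) = A * (1/pi) * (w/2) / ((w/2)**2 + (Q - sigma)**2)

whose center sigma maps to the real-space repeat distance d = 2*pi/sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

from .lineshapes import correlation_peak

__all__ = [
    "SANSProfile",
    "PowerLawFit",
    "CorrelationPeak",
    "power_law",
    "fit_power_law",
    "fit_correlation_peak",
    "peak_to_distance",
]


@dataclass
class SANSProfile:
    """Reduced I(Q) profile with uncertainties."""

    q: np.ndarray
    i: np.ndarray
    sigma: np.ndarray
    label: str = "synthetic"
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, float)
        self.i = np.asarray(self.i, float)
        self.sigma = np.asarray(self.sigma, float)
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("Q must be positive and strictly increasing")
        if self.i.shape != self.q.shape or self.sigma.shape != self.q.shape:
            raise ValueError("I and sigma must match the Q grid")
        if np.any(self.sigma <= 0):
            raise ValueError("uncertainties must be positive")


@dataclass
class PowerLawFit:
    """(P*Q)^-alpha + B fit result."""

    p: float
    alpha: float
    b: float
    p_err: float
    alpha_err: float
    b_err: float
    q_range: tuple[float, float]

    def evaluate(self, q: np.ndarray) -> np.ndarray:
        return power_law(q, self.p, self.alpha, self.b)


@dataclass
class CorrelationPeak:
    """Lorentzian correlation-peak fit result; ``found`` is False when the
    residual carries no significant peak (a dry-sample outcome, not an
    error)."""

    scale: float = np.nan
    width: float = np.nan
    center: float = np.nan
    scale_err: float = np.nan
    width_err: float = np.nan
    center_err: float = np.nan
    found: bool = True

    def evaluate(self, q: np.ndarray) -> np.ndarray:
        return correlation_peak(q, self.scale, self.width, self.center)


def power_law(q, p: float, alpha: float, b: float):
    """I(Q) = (P*Q)**(-alpha) + B."""
    return (p * np.asarray(q, float)) ** (-alpha) + b


def fit_power_law(
    profile: SANSProfile,
    q_range: tuple[float, float] | None = None,
    subtract_background: float | None = None,
    vary_background: bool = True,
) -> PowerLawFit:
    """Weighted fit of the power law over ``q_range``.

    ``subtract_background`` switches to the pre-subtraction convention: the
    given flat level is removed from the intensities first and B is then
    held at zero in the fit.  Points whose intensity is non-positive after
    subtraction are dropped with a warning-free mask (they carry no
    power-law information).

    ``vary_background=False`` holds B at zero without subtracting anything —
    appropriate when the fit window is restricted to low Q (a hydrated
    sample fitted below the correlation peak), where the power law exceeds
    any flat background by orders of magnitude and a free B only absorbs
    the peak's low-Q tail.
    """
    lo, hi = q_range if q_range is not None else (profile.q[0], profile.q[-1])
    mask = (profile.q >= lo) & (profile.q <= hi)
    q, i, s = profile.q[mask], profile.i[mask].copy(), profile.sigma[mask]
    if subtract_background is not None:
        i -= subtract_background
        keep = i > 0
        q, i, s = q[keep], i[keep], s[keep]
    if len(q) < 10:
        raise ValueError("need at least 10 points in the fitted Q range")

    # log-log slope over the low-Q half initialises alpha and P
    half = max(len(q) // 2, 2)
    slope, intercept = np.polyfit(np.log(q[:half]), np.log(np.clip(i[:half], 1e-300, None)), 1)
    alpha0 = max(-slope, 0.0)
    p0 = float(np.exp(-intercept / alpha0)) if alpha0 > 1e-6 else 1.0

    params = lmfit.Parameters()
    params.add("p", value=p0, min=1e-12)
    params.add("alpha", value=max(alpha0, 1e-3), min=0.0)
    if subtract_background is None and vary_background:
        params.add("b", value=max(float(i.min()) * 0.1, 1e-12), min=0.0)
    else:
        params.add("b", value=0.0, vary=False)

    def residual(pars):
        v = pars.valuesdict()
        return (power_law(q, v["p"], v["alpha"], v["b"]) - i) / s

    out = lmfit.minimize(residual, params, method="leastsq")
    v = out.params
    return PowerLawFit(
        p=v["p"].value, alpha=v["alpha"].value, b=v["b"].value,
        p_err=v["p"].stderr or np.nan,
        alpha_err=v["alpha"].stderr or np.nan,
        b_err=v["b"].stderr or np.nan if v["b"].vary else 0.0,
        q_range=(float(lo), float(hi)),
    )


def fit_correlation_peak(
    profile: SANSProfile,
    powerlaw: PowerLawFit,
    q_range: tuple[float, float] | None = None,
    refine_jointly: bool = True,
) -> tuple[CorrelationPeak, SANSProfile]:
    """Subtract the fitted power law and fit the residual with a Lorentzian
    correlation peak.

    Returns the peak parameters and the full residual profile.  When the
    residual shows no significant excess (e.g. a dry sample) a flagged
    no-peak result is returned instead of raising.

    With ``refine_jointly`` (default) the sequential subtract-then-fit
    result seeds one simultaneous weighted fit of power law plus peak over
    the whole profile.  The sequential stage alone leaves a small systematic
    bias because the peak's Lorentzian tails leak into the power-law fit
    window; the joint polish removes it while keeping the subtraction step
    as the initialisation and presentation device.
    """
    resid = profile.i - powerlaw.evaluate(profile.q)
    residual_profile = SANSProfile(
        q=profile.q.copy(), i=resid, sigma=profile.sigma.copy(),
        label=f"{profile.label}-residual",
    )
    lo, hi = q_range if q_range is not None else (profile.q[0], profile.q[-1])
    mask = (profile.q >= lo) & (profile.q <= hi)
    q, r, s = profile.q[mask], resid[mask], profile.sigma[mask]

    # a localized excess must rise above both the noise and any flat offset
    # left by the background; the offset is the weighted-least-squares flat
    # level of the residual, and 3-point smoothing suppresses one-point noise
    offset0 = float(np.sum(r / s**2) / np.sum(1.0 / s**2))
    z = np.convolve((r - offset0) / s, np.ones(3) / 3.0, mode="same")
    if np.all(r <= 0) or z.max() < 4.0:
        return CorrelationPeak(found=False), residual_profile

    i0 = int(np.argmax(z))
    center0, height0 = float(q[i0]), float(max(r[i0] - offset0, s[i0]))
    above = np.where(r - offset0 > height0 / 2.0)[0]
    width0 = max(float(q[above[-1]] - q[above[0]]), float(np.diff(q).min()))
    params = lmfit.Parameters()
    params.add("scale", value=height0 * np.pi * width0 / 2.0, min=0.0)
    params.add("width", value=width0, min=1e-6)
    params.add("center", value=center0, min=float(q[0]), max=float(q[-1]))
    params.add("offset", value=offset0)  # flat background left after subtraction

    def residual(pars):
        v = pars.valuesdict()
        model = correlation_peak(q, v["scale"], v["width"], v["center"]) + v["offset"]
        return (model - r) / s

    out = lmfit.minimize(residual, params, method="leastsq")
    v = out.params

    if refine_jointly:
        joint = lmfit.Parameters()
        joint.add("p", value=powerlaw.p, min=1e-12)
        joint.add("alpha", value=powerlaw.alpha, min=0.0)
        joint.add("b", value=max(powerlaw.b, max(v["offset"].value, 0.0), 0.0),
                  min=0.0)
        joint.add("scale", value=v["scale"].value, min=0.0)
        joint.add("width", value=v["width"].value, min=1e-6)
        joint.add("center", value=v["center"].value,
                  min=float(profile.q[0]), max=float(profile.q[-1]))

        def joint_residual(pars):
            w = pars.valuesdict()
            model = power_law(profile.q, w["p"], w["alpha"], w["b"]) + \
                correlation_peak(profile.q, w["scale"], w["width"], w["center"])
            return (model - profile.i) / profile.sigma

        out = lmfit.minimize(joint_residual, joint, method="leastsq")
        v = out.params
        residual_profile = SANSProfile(
            q=profile.q.copy(),
            i=profile.i - power_law(profile.q, v["p"].value, v["alpha"].value,
                                    v["b"].value),
            sigma=profile.sigma.copy(),
            label=f"{profile.label}-residual",
        )

    peak = CorrelationPeak(
        scale=v["scale"].value, width=v["width"].value, center=v["center"].value,
        scale_err=v["scale"].stderr or np.nan,
        width_err=v["width"].stderr or np.nan,
        center_err=v["center"].stderr or np.nan,
        found=True,
    )
    return peak, residual_profile


def peak_to_distance(center: float, center_err: float = 0.0) -> tuple[float, float]:
    """Real-space repeat distance d = 2*pi/center (A) with propagated error.

    The relative uncertainty is preserved: sigma_d = d * (sigma_c / center).
    """
    if center <= 0:
        raise ValueError("peak center must be positive")
    d = 2.0 * np.pi / center
    return float(d), float(d * center_err / center)
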