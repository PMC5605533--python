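"""Jump-diffusion analysis of the narrow quasi-elastic line width.

In the jump-diffusion picture a molecule resides at a site for a mean time
tau0 and then jumps; the half width at half maximum of the translational
Lorentzian disperses with momentum transfer as

    Gamma(Q) = (hbar / tau0) * [1 - 1 / (1 + D Q^2 tau0)]

which reduces to free diffusion Gamma = hbar D Q^2 at small Q and saturates
at hbar / tau0 at large Q.  The mean jump length follows from
l = sqrt(6 D tau0).

Internal units: D in A**2/ps, tau0 in ps, Gamma in ueV, Q in 1/A, so that
D * Q**2 * tau0 is dimensionless.  Reported D is in 1e-10 m**2/s (factor
100 from A**2/ps) and jump lengths in nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd

from .constants import A_PER_NM, HBAR_UEV_PS, d_to_report_units

__all__ = ["JumpDiffusionParams", "gamma_jump", "fit_jump_diffusion", "jump_length"]


@dataclass
class JumpDiffusionParams:
    """Fitted jump-diffusion parameters with first-order uncertainties.

    ``d`` is in A**2/ps (``d_report`` in 1e-10 m**2/s), ``tau0`` in ps and
    ``jump_length_nm`` in nm with l = sqrt(6 D tau0).  ``free_diffusion``
    tabulates the small-Q check Gamma ~ hbar D Q^2 against the data.
    """

    d: float
    d_err: float
    tau0: float
    tau0_err: float
    cov_d_tau0: float = 0.0
    free_diffusion: pd.DataFrame | None = None
    converged: bool = True

    @property
    def d_report(self) -> float:
        return d_to_report_units(self.d)

    @property
    def d_report_err(self) -> float:
        return d_to_report_units(self.d_err)

    @property
    def jump_length_nm(self) -> float:
        return jump_length(self.d_report, self.tau0)

    @property
    def jump_length_err_nm(self) -> float:
        """First-order propagation from the (D, tau0) covariance."""
        l = np.sqrt(6.0 * self.d * self.tau0)  # Angstrom
        if l == 0:
            return 0.0
        dl_dd = 3.0 * self.tau0 / l
        dl_dt = 3.0 * self.d / l
        var = (
            dl_dd**2 * self.d_err**2
            + dl_dt**2 * self.tau0_err**2
            + 2.0 * dl_dd * dl_dt * self.cov_d_tau0
        )
        return float(np.sqrt(max(var, 0.0))) / A_PER_NM

    def to_row(self, temperature: float | None = None) -> dict:
        """One row of a Table-1-style report (T, D, tau0, l)."""
        return {
            "temperature_K": temperature,
            "D_1e-10_m2_s": self.d_report,
            "D_err": self.d_report_err,
            "tau0_ps": self.tau0,
            "tau0_err": self.tau0_err,
            "jump_length_nm": self.jump_length_nm,
            "jump_length_err_nm": self.jump_length_err_nm,
        }


def gamma_jump(q, d: float, tau0: float):
    """Jump-diffusion HWHM (ueV) at momentum transfer ``q`` (1/A).

    ``d`` in A**2/ps, ``tau0`` in ps.  Vectorised over ``q``.
    """
    if tau0 <= 0:
        raise ValueError("residence time tau0 must be positive")
    if d < 0:
        raise ValueError("diffusion coefficient must be non-negative")
    q = np.asarray(q, float)
    if np.any(q < 0):
        raise ValueError("Q must be non-negative")
    out = (HBAR_UEV_PS / tau0) * (1.0 - 1.0 / (1.0 + d * q**2 * tau0))
    return out if out.ndim else float(out)


def fit_jump_diffusion(
    points: pd.DataFrame | np.ndarray,
    q_max: float = 0.9,
) -> JumpDiffusionParams:
    """Weighted fit of the jump-diffusion dispersion to (Q, Gamma, sigma) points.

    ``points`` is a DataFrame with columns (q, gamma, gamma_err) or an
    (n, 3) array.  Only points with Q <= ``q_max`` enter the fit — at higher
    Q coherent scattering from the crystalline matrix suppresses the
    apparent width.  Falls back to a coarse grid search if the optimiser
    fails to converge.
    """
    arr = (
        points[["q", "gamma", "gamma_err"]].to_numpy(float)
        if isinstance(points, pd.DataFrame)
        else np.asarray(points, float)
    )
    arr = arr[np.isfinite(arr).all(axis=1)]
    arr = arr[arr[:, 0] <= q_max]
    if len(arr) == 0:
        raise ValueError(f"no points at Q <= {q_max}")
    if len(arr) < 3:
        raise ValueError(
            f"jump-diffusion fit needs >= 3 points at Q <= {q_max}, got {len(arr)}"
        )
    q, g, ge = arr.T
    ge = np.where(ge > 0, ge, max(g.max(), 1.0) * 1e-6)

    # initial guesses from the two regimes: plateau ~ hbar/tau0,
    # small-Q slope ~ hbar*D
    tau0_0 = HBAR_UEV_PS / max(g.max(), 1e-6)
    d_0 = max(g[0] / (HBAR_UEV_PS * q[0] ** 2) * (1.0 + 1.0), 1e-5)

    params = lmfit.Parameters()
    params.add("d", value=d_0, min=0.0)
    params.add("tau0", value=tau0_0, min=1e-3)

    def residual(pars):
        v = pars.valuesdict()
        return (gamma_jump(q, v["d"], v["tau0"]) - g) / ge

    out = lmfit.minimize(residual, params, method="leastsq")
    converged = bool(out.success) and out.params["d"].stderr is not None
    if not converged:
        d_fit, tau0_fit = _grid_search(q, g, ge)
        return JumpDiffusionParams(
            d=d_fit, d_err=np.nan, tau0=tau0_fit, tau0_err=np.nan, converged=False
        )
    v = out.params
    cov = 0.0
    if out.covar is not None and out.covar.shape == (2, 2):
        cov = float(out.covar[0, 1])
    free = pd.DataFrame(
        {"q": q, "gamma": g, "gamma_free": HBAR_UEV_PS * v["d"].value * q**2}
    )
    return JumpDiffusionParams(
        d=v["d"].value,
        d_err=v["d"].stderr or np.nan,
        tau0=v["tau0"].value,
        tau0_err=v["tau0"].stderr or np.nan,
        cov_d_tau0=cov,
        free_diffusion=free,
    )


def _grid_search(q, g, ge, n: int = 200) -> tuple[float, float]:
    """Coarse (D, tau0) grid minimiser used as a non-convergence fallback."""
    d_grid = np.geomspace(1e-5, 1.0, n)
    tau_grid = np.geomspace(1.0, 1e4, n)
    best, best_dt = np.inf, (d_grid[0], tau_grid[0])
    for tau in tau_grid:
        model = (HBAR_UEV_PS / tau) * (
            1.0 - 1.0 / (1.0 + np.outer(d_grid, q**2) * tau)
        )
        chi2 = np.sum(((model - g[None, :]) / ge[None, :]) ** 2, axis=1)
        i = int(np.argmin(chi2))
        if chi2[i] < best:
            best, best_dt = chi2[i], (float(d_grid[i]), float(tau))
    return best_dt


def jump_length(d_report: float, tau0: float) -> float:
    """Mean jump length (nm) from D (1e-10 m**2/s) and tau0 (ps).

    l = sqrt(6 D tau0); with D in 1e-10 m**2/s = 1e-2 A**2/ps the product
    6 * D * tau0 is in units of 1e-2 A**2, hence l[nm] = sqrt(6 D tau0)/100.
    """
    if d_report < 0 or tau0 < 0:
        raise ValueError("D and tau0 must be non-negative")
    d_a2ps = d_report / 100.0
    return float(np.sqrt(6.0 * d_a2ps * tau0)) / A_PER_NM
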