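"""Water-dynamics analysis of center-of-mass trajectories.

Covers the simulation side of a bound-water study: mean-square displacement
MSD(t) = <[r(t) - r(0)]^2> (time-origin averaged), the Gaussian-approximation
elastic intensity S_el = exp(-Q^2 MSD / 3), per-molecule diffusion
coefficients from linear MSD fits (MSD = 6 D t), and the decomposition of
the per-molecule D distribution into slow and fast populations with a
two-Gaussian mixture.

Because physical diffusion coefficients are non-negative, sampled or
estimated D values are truncated at zero; the default mixture fit maximises
the likelihood of a mixture of at-zero-truncated Gaussians so the reported
component means and widths describe the underlying (un-truncated)
Gaussians.  A plain (untruncated) EM fit and a histogram-curve fit that
mirrors the usual figure presentation are also available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

from .constants import d_to_report_units

__all__ = [
    "TrajectorySet",
    "MSDSeries",
    "DiffusionSamples",
    "MixtureFit",
    "compute_msd",
    "elastic_intensity_gaussian",
    "per_molecule_diffusion",
    "fit_bimodal_gaussian",
]


@dataclass
class TrajectorySet:
    """Center-of-mass positions (A): array (n_molecules, n_frames, 3)."""

    positions: np.ndarray
    frame_interval: float  # ps
    temperature: float | None = None
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must be (n_molecules, n_frames, 3)")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def span(self) -> float:
        """Trajectory length in ps."""
        return (self.n_frames - 1) * self.frame_interval


@dataclass
class MSDSeries:
    """Time-origin-averaged MSD per lag, ensemble and per molecule."""

    lags: np.ndarray  # ps
    ensemble: np.ndarray  # (n_lags,)
    per_molecule: np.ndarray  # (n_molecules, n_lags)


@dataclass
class DiffusionSamples:
    """Per-molecule diffusion coefficients in 1e-10 m**2/s."""

    d: np.ndarray
    fit_window: tuple[float, float] | None = None
    quality: np.ndarray | None = None  # log-log MSD exponent; 1 = diffusive
    clipped: np.ndarray | None = None  # True where a negative slope was clipped to 0
    labels: np.ndarray | None = None  # generating component, when known

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, float)

    @property
    def nonlinear(self) -> np.ndarray | None:
        """True where the MSD exponent departs from diffusive by > 0.5."""
        if self.quality is None:
            return None
        return np.abs(self.quality - 1.0) > 0.5


@dataclass
class MixtureFit:
    """Two-Gaussian decomposition, components ordered by mean (m1 <= m2)."""

    w1: float
    m1: float
    s1: float
    w2: float
    m2: float
    s2: float
    loglik: float
    n_components: int = 2
    method: str = "mle-truncated"
    degenerate: bool = False

    def as_series(self) -> pd.Series:
        return pd.Series(
            {"w1": self.w1, "m1": self.m1, "s1": self.s1,
             "w2": self.w2, "m2": self.m2, "s2": self.s2}
        )


# ---------------------------------------------------------------------------
# MSD and diffusion coefficients
# ---------------------------------------------------------------------------


def compute_msd(traj: TrajectorySet, lags: np.ndarray | list[float]) -> MSDSeries:
    """MSD at the requested lag times, averaged over all valid time origins.

    Lags are snapped to the nearest frame multiple (with a warning when the
    requested lag is not one).  Lag 0 yields MSD 0 by construction.
    """
    lags = np.asarray(lags, float)
    if np.any(lags < 0) or np.any(lags > traj.span):
        raise ValueError("lags must lie within the trajectory span")
    steps = np.rint(lags / traj.frame_interval).astype(int)
    if not np.allclose(steps * traj.frame_interval, lags, atol=1e-9):
        warnings.warn("lags snapped to the nearest frame multiple", stacklevel=2)
    pos = traj.positions
    per_mol = np.empty((traj.n_molecules, len(steps)))
    for j, k in enumerate(steps):
        if k == 0:
            per_mol[:, j] = 0.0
            continue
        disp = pos[:, k:, :] - pos[:, :-k, :]
        per_mol[:, j] = np.mean(np.sum(disp * disp, axis=2), axis=1)
    return MSDSeries(
        lags=steps * traj.frame_interval,
        ensemble=per_mol.mean(axis=0),
        per_molecule=per_mol,
    )


def elastic_intensity_gaussian(msd: float | np.ndarray, q: float | np.ndarray):
    """Gaussian-approximation elastic intensity exp(-Q^2 MSD / 3).

    The proportionality constant is fixed to 1; use a free intercept when
    inverting (``msd_from_elastic`` does).
    """
    msd = np.asarray(msd, float)
    if np.any(msd < 0):
        raise ValueError("MSD must be non-negative")
    out = np.exp(-np.asarray(q, float) ** 2 * msd / 3.0)
    return out if out.ndim else float(out)


def per_molecule_diffusion(
    traj: TrajectorySet,
    window: tuple[float, float] = (10.0, 400.0),
    min_lags: int = 5,
    max_lags: int = 40,
) -> DiffusionSamples:
    """Diffusion coefficient per molecule from a linear fit of MSD vs lag.

    The MSD of each molecule is fitted over lags inside ``window`` (ps) with
    a free intercept; D = slope / 6, reported in 1e-10 m**2/s.  Negative
    slopes are clipped to zero and flagged.  The quality score is the
    log-log MSD exponent over the window (1 for diffusive motion, 2 for
    ballistic); ``nonlinear`` flags molecules whose exponent is outside
    [0.5, 1.5], i.e. whose motion the linear Einstein fit does not describe.
    """
    lo, hi = window
    if lo < 0 or hi > traj.span or lo >= hi:
        raise ValueError("fit window must lie within the trajectory span")
    step = traj.frame_interval
    k_lo, k_hi = int(np.ceil(lo / step)), int(np.floor(hi / step))
    ks = np.arange(max(k_lo, 1), k_hi + 1)
    if len(ks) > max_lags:
        ks = np.unique(np.linspace(ks[0], ks[-1], max_lags).round().astype(int))
    if len(ks) < min_lags:
        raise ValueError(f"fewer than {min_lags} lag points inside the window")
    series = compute_msd(traj, ks * step)
    t = series.lags
    d = np.empty(traj.n_molecules)
    quality = np.empty(traj.n_molecules)
    clipped = np.zeros(traj.n_molecules, dtype=bool)
    lin = np.column_stack([np.ones_like(t), t])
    log_t = np.log(t)
    for i in range(traj.n_molecules):
        y = series.per_molecule[i]
        c_lin, *_ = np.linalg.lstsq(lin, y, rcond=None)
        quality[i] = np.polyfit(log_t, np.log(np.clip(y, 1e-300, None)), 1)[0]
        slope = c_lin[1]
        if slope < 0:
            slope, clipped[i] = 0.0, True
        d[i] = d_to_report_units(slope / 6.0)  # slope in A**2/ps
    return DiffusionSamples(d=d, fit_window=(lo, hi), quality=quality, clipped=clipped)


# ---------------------------------------------------------------------------
# two-Gaussian mixture decomposition
# ---------------------------------------------------------------------------


def _truncated_mixture_nll(theta, x):
    """Negative log-likelihood of a 2-component at-zero-truncated Gaussian
    mixture; theta = (logit w1, m1, log s1, m2, log s2)."""
    w1 = 1.0 / (1.0 + np.exp(-theta[0]))
    m1, m2 = theta[1], theta[3]
    s1, s2 = np.exp(theta[2]), np.exp(theta[4])
    pdf1 = stats.norm.pdf(x, m1, s1) / max(stats.norm.sf(0.0, m1, s1), 1e-300)
    pdf2 = stats.norm.pdf(x, m2, s2) / max(stats.norm.sf(0.0, m2, s2), 1e-300)
    mix = w1 * pdf1 + (1.0 - w1) * pdf2
    return -float(np.sum(np.log(np.clip(mix, 1e-300, None))))


def _gmm_fit(x, n_components, seed, n_init=10):
    gm = GaussianMixture(
        n_components=n_components,
        n_init=n_init,
        random_state=seed,
        reg_covar=1e-10,
    )
    gm.fit(x.reshape(-1, 1))
    w = gm.weights_.ravel()
    m = gm.means_.ravel()
    s = np.sqrt(gm.covariances_.ravel())
    order = np.argsort(m)
    return w[order], m[order], s[order], float(gm.score(x.reshape(-1, 1)) * len(x))


def fit_bimodal_gaussian(
    samples: DiffusionSamples | np.ndarray,
    n_components: int = 2,
    method: str = "mle-truncated",
    seed: int = 0,
    bin_width: float = 0.1,
) -> MixtureFit:
    """Decompose a D distribution into slow and fast Gaussian populations.

    Methods
    -------
    ``"mle-truncated"`` (default)
        Maximum likelihood for a mixture of Gaussians truncated at zero,
        initialised from an EM fit with 10 restarts.  Appropriate because D
        samples are non-negative; the fitted (w, m, sigma) describe the
        un-truncated Gaussians, matching how such tables are reported.
    ``"em"``
        Plain Gaussian-mixture EM (scikit-learn, 10 restarts).
    ``"histogram"``
        Least-squares fit of two Gaussians to the density histogram
        (default bin width 0.1 in 1e-10 m**2/s), mirroring figure-style
        presentation.

    Components are ordered by mean.  Degenerate outcomes (a component
    collapsing onto almost no samples, or both components coinciding) are
    flagged rather than raised.
    """
    x = samples.d if isinstance(samples, DiffusionSamples) else np.asarray(samples, float)
    x = x[np.isfinite(x)]
    if len(x) < 50:
        raise ValueError("need at least 50 samples for a mixture fit")
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")

    if n_components == 1:
        m, s = float(x.mean()), float(x.std(ddof=1))
        ll = float(np.sum(stats.norm.logpdf(x, m, s)))
        return MixtureFit(1.0, m, s, 0.0, np.nan, np.nan, ll,
                          n_components=1, method="moments")

    w, m, s, ll = _gmm_fit(x, 2, seed)
    if method == "em":
        fit = MixtureFit(w[0], m[0], s[0], w[1], m[1], s[1], ll, method="em")
    elif method == "histogram":
        fit = _histogram_fit(x, bin_width, init=(w, m, s))
    elif method == "mle-truncated":
        theta0 = np.array(
            [np.log(w[0] / max(w[1], 1e-12)), m[0], np.log(max(s[0], 1e-6)),
             m[1], np.log(max(s[1], 1e-6))]
        )
        res = optimize.minimize(
            _truncated_mixture_nll, theta0, args=(x,), method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
        )
        t = res.x
        w1 = 1.0 / (1.0 + np.exp(-t[0]))
        comp = sorted(
            [(w1, t[1], np.exp(t[2])), (1.0 - w1, t[3], np.exp(t[4]))],
            key=lambda c: c[1],
        )
        fit = MixtureFit(
            comp[0][0], comp[0][1], comp[0][2],
            comp[1][0], comp[1][1], comp[1][2],
            -float(res.fun), method="mle-truncated",
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    # a mixture is only meaningfully bimodal when the means are separated by
    # more than the average component width (separation index >= 1)
    min_w = min(fit.w1, fit.w2)
    separation = abs(fit.m2 - fit.m1) / max(0.5 * (fit.s1 + fit.s2), 1e-300)
    fit.degenerate = bool(min_w < 0.02 or separation < 1.0)
    return fit


def _histogram_fit(x, bin_width, init):
    """Least-squares two-Gaussian fit to the density histogram."""
    import lmfit

    edges = np.arange(0.0, x.max() + bin_width, bin_width)
    if len(edges) < 6:
        edges = np.linspace(0.0, x.max(), 12)
    dens, edges = np.histogram(x, bins=edges, density=True)
    centers = 0.5 * (edges[1:] + edges[:-1])
    (w, m, s) = init
    params = lmfit.Parameters()
    params.add("w1", value=float(np.clip(w[0], 0.05, 0.95)), min=0.0, max=1.0)
    params.add("m1", value=float(m[0]))
    params.add("s1", value=float(max(s[0], bin_width / 2)), min=1e-4)
    params.add("m2", value=float(m[1]))
    params.add("s2", value=float(max(s[1], bin_width / 2)), min=1e-4)

    def model(pars):
        v = pars.valuesdict()
        return (
            v["w1"] * stats.norm.pdf(centers, v["m1"], v["s1"])
            + (1.0 - v["w1"]) * stats.norm.pdf(centers, v["m2"], v["s2"])
        )

    out = lmfit.minimize(lambda p: model(p) - dens, params, method="leastsq")
    v = out.params
    comp = sorted(
        [(v["w1"].value, v["m1"].value, v["s1"].value),
         (1.0 - v["w1"].value, v["m2"].value, v["s2"].value)],
        key=lambda c: c[1],
    )
    return MixtureFit(
        comp[0][0], comp[0][1], comp[0][2],
        comp[1][0], comp[1][1], comp[1][2],
        loglik=np.nan, method="histogram",
    )
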