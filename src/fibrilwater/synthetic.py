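"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here: QENS
spectra built from the resolution-convolved elastic + Lorentzian model with
jump-diffusion narrow widths, temperature scans of the elastic intensity
with two dynamical transitions, SANS power-law + correlation-peak profiles,
four-peak pseudo-Voigt diffraction patterns, and two-population Brownian
water (samples of D or full 3-D trajectories).  Each generator echoes its
ground truth on the returned object so round-trip tests can compare fitted
parameters against generating ones.

The default parameter sets are the study conditions for bound water on
crystalline cellulose: a backscattering spectrometer with 3.5 ueV FWHM
Gaussian resolution and a +/-100 ueV window; jump-diffusion water with
D = 0.86 and 1.77 x 1e-10 m**2/s at 250 and 265 K; dynamical transitions
near 220 and 260 K; a hydrated-sample SANS exponent 3.55 with a correlation
peak at 0.094 1/A; cellulose-I reflections near 14.8, 16.9, 20.7 and 22.9
degrees; and the three-temperature slow/fast water mixture statistics.

The noise model everywhere is relative Gaussian: sigma_i = level * max(I_i,
floor), a simple invertible stand-in for counting statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .constants import d_from_report_units
from .jumpdiff import gamma_jump
from .lineshapes import correlation_peak, lorentzian, pseudo_voigt
from .mdwater import DiffusionSamples, TrajectorySet
from .qens import ElasticScan, QENSSpectrum, ResolutionModel, convolve_with_resolution
from .sans import SANSProfile, power_law
from .xrd import XRDPattern

__all__ = [
    "QENSGroundTruth",
    "WaterPopulationSpec",
    "generate_qens_spectrum",
    "generate_elastic_scan",
    "generate_sans_profile",
    "generate_xrd_pattern",
    "generate_water_dynamics",
    "basis_like_truth",
    "water_population",
    "JUMP_DIFFUSION_CONDITIONS",
    "MIXTURE_CONDITIONS",
    "HYDRATED_SANS_CONDITIONS",
    "CELLULOSE_XRD_PEAKS",
]

#: Canonical jump-diffusion benchmark conditions for bound water
#: (temperature K -> D in A**2/ps, residence time tau0 in ps).
JUMP_DIFFUSION_CONDITIONS = {
    250.0: {"d_a2ps": 0.0086, "tau0_ps": 142.2},
    265.0: {"d_a2ps": 0.0177, "tau0_ps": 110.0},
}

#: Slow/fast bound-water mixture statistics (1e-10 m**2/s units):
#: temperature K -> (w1, m1, s1, w2, m2, s2), components ordered by mean.
MIXTURE_CONDITIONS = {
    213.0: (0.85, 0.25, 0.07, 0.15, 0.52, 0.18),
    243.0: (0.45, 0.27, 0.07, 0.55, 0.74, 0.43),
    263.0: (0.18, 0.44, 0.24, 0.82, 2.21, 1.76),
}

#: Hydrated-cellulose-type SANS profile: power-law exponent 3.55 with an
#: interfibrillar correlation peak at 0.094 1/A.  The scale P is chosen so
#: the power law dominates below 0.08 1/A and the peak appears as the
#: high-Q excess it is in such samples.
HYDRATED_SANS_CONDITIONS = {
    "p": 2.3, "alpha": 3.55, "b": 0.1,
    "peak": {"scale": 1.0, "width": 0.04, "center": 0.094},
}

#: Cellulose-I reflections: (hkl, 2theta degrees).  The 110 FWHM below
#: corresponds to a 50 A crystallite via the Scherrer equation.
CELLULOSE_XRD_PEAKS = [
    {"hkl": "100", "center": 14.8, "fwhm": 1.9, "eta": 0.5, "amplitude": 60.0},
    {"hkl": "010", "center": 16.9, "fwhm": 2.0, "eta": 0.5, "amplitude": 40.0},
    {"hkl": "11-2", "center": 20.7, "fwhm": 2.2, "eta": 0.5, "amplitude": 25.0},
    {"hkl": "110", "center": 22.9, "fwhm": 1.6224, "eta": 0.5, "amplitude": 100.0},
]


def _noise_sigma(intensity: np.ndarray, level: float, floor: float = 1e-12):
    """Relative Gaussian noise scale sigma_i = level * max(I_i, floor)."""
    eff = max(level, 1e-8)  # keep uncertainties strictly positive
    return eff * np.maximum(np.abs(intensity), floor)


# ---------------------------------------------------------------------------
# QENS spectra
# ---------------------------------------------------------------------------


@dataclass
class QENSGroundTruth:
    """Generating parameters of one synthetic QENS measurement.

    The narrow Lorentzian width is either fixed (``narrow_hwhm``, ueV) or
    follows jump diffusion (``d_a2ps`` in A**2/ps with ``tau0_ps``); exactly
    one of the two modes must be set.  ``x`` and ``p`` may be scalars or
    per-Q arrays.
    """

    x: float | np.ndarray = 0.3
    p: float | np.ndarray = 0.5
    narrow_hwhm: float | None = None
    d_a2ps: float | None = None
    tau0_ps: float | None = None
    broad_hwhm: float = 25.0
    c1: float = 0.0  # background slope, counts/ueV
    c2: float = 0.001  # background offset, counts
    resolution_fwhm: float = 3.5
    temperature: float = 250.0
    noise: float = 0.01
    seed: int = 0
    coherent_contamination: float = 0.0  # extra elastic intensity at Q > 1.1

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.x) < 0) or np.any(np.asarray(self.x) > 1):
            raise ValueError("elastic fraction x must lie in [0, 1]")
        if np.any(np.asarray(self.p) < 0) or np.any(np.asarray(self.p) > 1):
            raise ValueError("component weight p must lie in [0, 1]")
        jump = self.d_a2ps is not None or self.tau0_ps is not None
        if jump and self.narrow_hwhm is not None:
            raise ValueError("choose fixed narrow HWHM or jump diffusion, not both")
        if jump and (self.d_a2ps is None or self.tau0_ps is None or self.tau0_ps <= 0):
            raise ValueError("jump mode needs D and a positive tau0")
        if not jump and (self.narrow_hwhm is None or self.narrow_hwhm <= 0):
            raise ValueError("fixed mode needs a positive narrow HWHM")
        if self.broad_hwhm <= 0 or self.resolution_fwhm <= 0:
            raise ValueError("widths must be positive")

    def narrow_width(self, q: float) -> float:
        if self.narrow_hwhm is not None:
            return float(self.narrow_hwhm)
        return gamma_jump(q, self.d_a2ps, self.tau0_ps)


def basis_like_truth(temperature: float, **overrides) -> QENSGroundTruth:
    """Benchmark ground truth for one of the canonical temperatures.

    Uses the jump-diffusion conditions of :data:`JUMP_DIFFUSION_CONDITIONS`
    with plausible elastic fractions for a partly frozen hydration layer
    (more elastic scattering at the lower temperature).
    """
    cond = JUMP_DIFFUSION_CONDITIONS.get(float(temperature))
    if cond is None:
        raise KeyError(f"no canonical conditions at {temperature} K")
    defaults = dict(
        x=0.4 if temperature <= 250 else 0.2,
        p=0.5,
        d_a2ps=cond["d_a2ps"],
        tau0_ps=cond["tau0_ps"],
        broad_hwhm=25.0 if temperature <= 250 else 30.0,
        temperature=float(temperature),
    )
    defaults.update(overrides)
    return QENSGroundTruth(**defaults)


def generate_qens_spectrum(
    truth: QENSGroundTruth,
    q_grid: np.ndarray,
    e_grid: np.ndarray,
) -> QENSSpectrum:
    """Evaluate the spectral model with ``truth`` and add relative noise.

    The energy grid must be uniform (convolution contract) and span at
    least +/-100 ueV; Q values must lie in the instrument range 0.2-2.0
    1/A.  The returned spectrum carries the noise sigma as its uncertainty
    column and the ground truth as a dict for round-trip tests.
    """
    q_grid = np.atleast_1d(np.asarray(q_grid, float))
    e_grid = np.asarray(e_grid, float)
    de = np.diff(e_grid)
    if len(de) == 0 or not np.allclose(de, de[0], rtol=1e-8, atol=1e-12):
        raise ValueError("energy grid must be uniform")
    if e_grid[0] > -100.0 or e_grid[-1] < 100.0:
        raise ValueError("energy grid must span at least +/-100 ueV")
    if np.any(q_grid < 0.2) or np.any(q_grid > 2.0):
        raise ValueError("Q grid must lie within 0.2-2.0 1/A")

    resolution = ResolutionModel(fwhm=truth.resolution_fwhm)
    res_curve = resolution.evaluate(e_grid)
    x_arr = np.broadcast_to(np.asarray(truth.x, float), q_grid.shape)
    p_arr = np.broadcast_to(np.asarray(truth.p, float), q_grid.shape)

    rng = np.random.default_rng(truth.seed)
    intensity = np.empty((len(q_grid), len(e_grid)))
    sigma = np.empty_like(intensity)
    for i, q in enumerate(q_grid):
        x, p = x_arr[i], p_arr[i]
        clean = x * res_curve
        if x < 1.0:
            g1 = truth.narrow_width(q)
            qe = p * lorentzian(e_grid, g1) + (1.0 - p) * lorentzian(
                e_grid, truth.broad_hwhm
            )
            clean = clean + (1.0 - x) * convolve_with_resolution(
                e_grid, qe, resolution
            )
        clean = clean + truth.c1 * e_grid + truth.c2
        if truth.coherent_contamination > 0 and q > 1.1:
            clean = clean + truth.coherent_contamination * res_curve
        sig = _noise_sigma(clean, truth.noise)
        noisy = clean + rng.normal(0.0, 1.0, clean.shape) * sig * (truth.noise > 0)
        intensity[i], sigma[i] = noisy, sig

    return QENSSpectrum(
        q=q_grid, e=e_grid, intensity=intensity, sigma=sigma,
        temperature=truth.temperature,
        ground_truth={**asdict(truth)},
    )


# ---------------------------------------------------------------------------
# elastic scans
# ---------------------------------------------------------------------------


def generate_elastic_scan(
    q_grid: np.ndarray,
    t_grid: np.ndarray,
    transition_temps: tuple[float, float] = (220.0, 260.0),
    step_depths: tuple[float, float] = (2e-3, 6e-3),
    base_slope: float = 5e-4,
    noise: float = 0.0,
    seed: int = 0,
) -> ElasticScan:
    """Piecewise-linear elastic intensity with two dynamical transitions.

    The intensity decreases linearly in T with slope ``base_slope`` (per K)
    and picks up the extra slopes in ``step_depths`` above each transition
    temperature; the default makes the upper drop the sharper one.  Noise is
    relative Gaussian.  Before noise the curve is monotonically
    non-increasing in T and its second derivative is non-zero only at the
    two breakpoints.
    """
    q_grid = np.atleast_1d(np.asarray(q_grid, float))
    t_grid = np.asarray(t_grid, float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("temperature grid must be increasing")
    t1, t2 = transition_temps
    if not (t_grid[0] < t1 < t2 < t_grid[-1]):
        raise ValueError("transition temperatures must lie inside the T grid")
    d1, d2 = step_depths
    if d1 < 0 or d2 < 0 or base_slope < 0:
        raise ValueError("slopes must be non-negative")

    f = (
        1.0
        - base_slope * (t_grid - t_grid[0])
        - d1 * np.clip(t_grid - t1, 0.0, None)
        - d2 * np.clip(t_grid - t2, 0.0, None)
    )
    if np.any(f <= 0):
        raise ValueError("slopes too steep: elastic intensity would go negative")
    rng = np.random.default_rng(seed)
    intensity = np.tile(f, (len(q_grid), 1))
    sig = _noise_sigma(intensity, noise)
    if noise > 0:
        intensity = intensity + rng.normal(0.0, 1.0, intensity.shape) * sig
    return ElasticScan(
        t=t_grid, q=q_grid, intensity=intensity, sigma=sig,
        ground_truth={
            "transition_temps": (float(t1), float(t2)),
            "step_depths": (float(d1), float(d2)),
            "base_slope": float(base_slope),
            "noise": float(noise), "seed": int(seed),
        },
    )


# ---------------------------------------------------------------------------
# SANS profiles
# ---------------------------------------------------------------------------


def generate_sans_profile(
    p: float = HYDRATED_SANS_CONDITIONS["p"],
    alpha: float = HYDRATED_SANS_CONDITIONS["alpha"],
    b: float = HYDRATED_SANS_CONDITIONS["b"],
    peak: dict | None = None,
    q_grid: np.ndarray | None = None,
    noise: float = 0.01,
    seed: int = 0,
    label: str = "synthetic",
) -> SANSProfile:
    """Power law + optional Lorentzian correlation peak + relative noise.

    ``peak`` is a dict with keys scale, width, center (pass
    ``HYDRATED_SANS_CONDITIONS['peak']`` for the hydrated-type fixture, or
    None for a dry-type profile).  Default Q grid: 200 log-spaced points on
    0.003-0.4 1/A.
    """
    if alpha < 0:
        raise ValueError("power-law exponent must be non-negative")
    if q_grid is None:
        q_grid = np.geomspace(0.003, 0.4, 200)
    q_grid = np.asarray(q_grid, float)
    if np.any(q_grid <= 0):
        raise ValueError("Q grid must be positive")
    clean = power_law(q_grid, p, alpha, b)
    if peak is not None:
        clean = clean + correlation_peak(
            q_grid, peak["scale"], peak["width"], peak["center"]
        )
    sig = _noise_sigma(clean, noise)
    rng = np.random.default_rng(seed)
    i = clean + (rng.normal(0.0, 1.0, clean.shape) * sig if noise > 0 else 0.0)
    return SANSProfile(
        q=q_grid, i=i, sigma=sig, label=label,
        ground_truth={
            "p": float(p), "alpha": float(alpha), "b": float(b),
            "peak": dict(peak) if peak else None,
            "noise": float(noise), "seed": int(seed),
        },
    )


# ---------------------------------------------------------------------------
# XRD patterns
# ---------------------------------------------------------------------------


def generate_xrd_pattern(
    peaks: list[dict] | None = None,
    background: tuple[float, float] = (0.0, 10.0),
    two_theta_grid: np.ndarray | None = None,
    noise: float = 0.01,
    seed: int = 0,
) -> XRDPattern:
    """Sum of pseudo-Voigt peaks on a linear background, with noise.

    ``peaks`` entries carry center (2theta degrees), fwhm (degrees), eta and
    amplitude; default: the four cellulose-I reflections.
    """
    if peaks is None:
        peaks = CELLULOSE_XRD_PEAKS
    if two_theta_grid is None:
        two_theta_grid = np.arange(5.0, 40.0, 0.05)
    x = np.asarray(two_theta_grid, float)
    clean = background[0] * x + background[1]
    for pk in peaks:
        if not (x[0] <= pk["center"] <= x[-1]):
            raise ValueError(f"peak center {pk['center']} outside the grid")
        if pk["fwhm"] <= 0 or not 0.0 <= pk["eta"] <= 1.0:
            raise ValueError("need FWHM > 0 and eta in [0, 1]")
        clean = clean + pseudo_voigt(x, pk["center"], pk["fwhm"], pk["eta"], pk["amplitude"])
    sig = _noise_sigma(clean, noise)
    rng = np.random.default_rng(seed)
    counts = clean + (rng.normal(0.0, 1.0, clean.shape) * sig if noise > 0 else 0.0)
    return XRDPattern(
        two_theta=x, counts=counts, sigma=sig,
        ground_truth={"peaks": [dict(p) for p in peaks],
                      "background": tuple(background),
                      "noise": float(noise), "seed": int(seed)},
    )


# ---------------------------------------------------------------------------
# two-population water
# ---------------------------------------------------------------------------


@dataclass
class WaterPopulationSpec:
    """Two-Gaussian mixture of per-molecule D (1e-10 m**2/s units).

    Defaults mirror a 5 ns trajectory sampled every 2 ps; sampled D values
    are kept non-negative by rejection (re-draw), since diffusion
    coefficients are physical non-negative quantities while the nominal
    Gaussian components may carry small negative tail mass.
    """

    w1: float
    m1: float
    s1: float
    w2: float
    m2: float
    s2: float
    n_molecules: int = 1000
    frame_interval: float = 2.0  # ps
    n_frames: int = 2500
    seed: int = 0
    temperature: float | None = None

    def __post_init__(self) -> None:
        if abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("mixture weights must be non-negative")
        if self.s1 <= 0 or self.s2 <= 0:
            raise ValueError("mixture standard deviations must be positive")
        if self.n_molecules < 2:
            raise ValueError("need at least 2 molecules")

    @property
    def mean(self) -> float:
        """Analytic mixture mean (before truncation)."""
        return self.w1 * self.m1 + self.w2 * self.m2


def water_population(temperature: float, **overrides) -> WaterPopulationSpec:
    """Canonical slow/fast mixture spec at 213, 243 or 263 K."""
    row = MIXTURE_CONDITIONS.get(float(temperature))
    if row is None:
        raise KeyError(f"no canonical mixture at {temperature} K")
    w1, m1, s1, w2, m2, s2 = row
    kw = dict(w1=w1, m1=m1, s1=s1, w2=w2, m2=m2, s2=s2,
              temperature=float(temperature))
    kw.update(overrides)
    return WaterPopulationSpec(**kw)


def _sample_mixture(spec: WaterPopulationSpec, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Draw n non-negative D values with component labels (rejection)."""
    labels = rng.choice(2, size=n, p=[spec.w1, spec.w2])
    means = np.where(labels == 0, spec.m1, spec.m2)
    sds = np.where(labels == 0, spec.s1, spec.s2)
    d = rng.normal(means, sds)
    bad = d < 0
    while np.any(bad):
        d[bad] = rng.normal(means[bad], sds[bad])
        bad = d < 0
    return d, labels


def generate_water_dynamics(
    spec: WaterPopulationSpec, mode: str = "samples"
) -> DiffusionSamples | TrajectorySet:
    """Draw per-molecule D values or full Brownian trajectories.

    ``samples`` mode returns the D values (with generating labels) directly;
    ``trajectories`` mode draws D per molecule from the mixture and builds a
    3-D random walk whose per-step displacement variance is 2*D*dt per axis,
    so the ensemble obeys MSD = 6*D*t.
    """
    rng = np.random.default_rng(spec.seed)
    d_report, labels = _sample_mixture(spec, spec.n_molecules, rng)
    if mode == "samples":
        return DiffusionSamples(d=d_report, labels=labels)
    if mode != "trajectories":
        raise ValueError("mode must be 'samples' or 'trajectories'")
    if spec.n_frames < 10:
        raise ValueError("trajectory mode needs at least 10 frames")
    d_a2ps = d_from_report_units(d_report)
    step_sd = np.sqrt(2.0 * d_a2ps * spec.frame_interval)  # per axis, A
    steps = rng.normal(
        0.0, 1.0, (spec.n_molecules, spec.n_frames - 1, 3)
    ) * step_sd[:, None, None]
    pos = np.concatenate(
        [np.zeros((spec.n_molecules, 1, 3)), np.cumsum(steps, axis=1)], axis=1
    )
    return TrajectorySet(
        positions=pos, frame_interval=spec.frame_interval,
        temperature=spec.temperature,
        ground_truth={**asdict(spec), "labels": labels},
    )
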