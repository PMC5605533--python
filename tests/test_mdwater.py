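"""MSD, per-molecule diffusion and two-population mixture decomposition."""

import numpy as np
import pytest

from fibrilwater.constants import d_from_report_units
from fibrilwater.mdwater import (
    TrajectorySet,
    compute_msd,
    elastic_intensity_gaussian,
    fit_bimodal_gaussian,
    per_molecule_diffusion,
)
from fibrilwater.synthetic import (
    MIXTURE_CONDITIONS,
    WaterPopulationSpec,
    generate_water_dynamics,
    water_population,
)


def _single_population(d_report, n_molecules=500, n_frames=500, seed=2):
    return generate_water_dynamics(
        WaterPopulationSpec(
            w1=1.0, w2=0.0, m1=d_report, m2=d_report, s1=1e-9, s2=1e-9,
            n_molecules=n_molecules, n_frames=n_frames, seed=seed,
        ),
        mode="trajectories",
    )


# --- MSD ---------------------------------------------------------------------


def test_msd_zero_for_static_positions():
    pos = np.tile(np.array([1.0, -2.0, 3.0]), (4, 50, 1))
    msd = compute_msd(TrajectorySet(pos, 2.0), [0.0, 10.0, 40.0])
    assert np.all(msd.ensemble == 0.0)


def test_msd_matches_bruteforce_oracle():
    """Double-loop oracle over origins and molecules on a tiny instance."""
    rng = np.random.default_rng(0)
    pos = rng.normal(size=(5, 20, 3)).cumsum(axis=1)
    traj = TrajectorySet(pos, 1.0)
    lags = [1.0, 3.0, 7.0]
    series = compute_msd(traj, lags)
    for j, lag in enumerate(lags):
        k = int(lag)
        acc = []
        for m in range(5):
            for t0 in range(20 - k):
                acc.append(np.sum((pos[m, t0 + k] - pos[m, t0]) ** 2))
        assert series.ensemble[j] == pytest.approx(np.mean(acc), rel=1e-12)
        per_mol = [
            np.mean([np.sum((pos[m, t0 + k] - pos[m, t0]) ** 2)
                     for t0 in range(20 - k)])
            for m in range(5)
        ]
        assert np.allclose(series.per_molecule[:, j], per_mol, rtol=1e-12)


def test_msd_ballistic_closed_form():
    t = np.arange(100) * 2.0
    v = np.array([0.03, -0.01, 0.02])
    pos = (t[None, :, None] * v[None, None, :]).repeat(3, axis=0)
    traj = TrajectorySet(pos, 2.0)
    series = compute_msd(traj, [20.0, 80.0])
    v2 = np.sum(v**2)
    assert series.ensemble[0] == pytest.approx(v2 * 20.0**2, rel=1e-10)
    assert series.ensemble[1] == pytest.approx(v2 * 80.0**2, rel=1e-10)


def test_msd_einstein_relation_at_800ps():
    """Brownian molecules with D = 0.01 A^2/ps reach MSD = 6 D t = 48 A^2."""
    traj = _single_population(1.0, n_molecules=1000, n_frames=500, seed=2)
    series = compute_msd(traj, [800.0])
    per_mol = series.per_molecule[:, 0]
    se = per_mol.std(ddof=1) / np.sqrt(len(per_mol))
    assert abs(series.ensemble[0] - 48.0) <= 3.0 * se


def test_msd_lag_snapping_warns():
    traj = _single_population(1.0, n_molecules=5, n_frames=50)
    with pytest.warns(UserWarning, match="snapped"):
        compute_msd(traj, [3.0])  # frame interval is 2 ps


def test_msd_rejects_lag_beyond_span():
    traj = _single_population(1.0, n_molecules=5, n_frames=50)
    with pytest.raises(ValueError, match="span"):
        compute_msd(traj, [1e6])


# --- Gaussian-approximation elastic intensity ---------------------------------


def test_elastic_intensity_limits():
    assert elastic_intensity_gaussian(0.0, 1.0) == 1.0
    assert elastic_intensity_gaussian(3.0, 1.0) == pytest.approx(np.exp(-1.0))
    with pytest.raises(ValueError):
        elastic_intensity_gaussian(-1.0, 1.0)


# --- per-molecule diffusion -----------------------------------------------------


def test_per_molecule_diffusion_single_population():
    traj = _single_population(0.5, n_molecules=800, n_frames=1000, seed=6)
    samples = per_molecule_diffusion(traj)
    se = samples.d.std(ddof=1) / np.sqrt(len(samples.d))
    assert abs(samples.d.mean() - 0.5) <= 3.0 * se
    assert np.mean(samples.nonlinear) < 0.01


def test_ballistic_trajectory_flagged_nonlinear():
    t = np.arange(500) * 2.0
    pos = np.zeros((3, 500, 3))
    pos[:, :, 0] = 0.05 * t[None, :]
    samples = per_molecule_diffusion(TrajectorySet(pos, 2.0))
    assert np.all(samples.nonlinear)
    assert np.allclose(samples.quality, 2.0, atol=1e-6)


def test_window_outside_span_rejected():
    traj = _single_population(1.0, n_molecules=5, n_frames=50)
    with pytest.raises(ValueError, match="span"):
        per_molecule_diffusion(traj, window=(10.0, 5000.0))


# --- mixture sampling and fitting -----------------------------------------------


def test_sample_mean_matches_mixture_arithmetic():
    """At the lowest-temperature row the mixture mean is
    w1 m1 + w2 m2 = 0.2905; a large sample agrees within 3 SE."""
    spec = water_population(213.0, n_molecules=100000, seed=1)
    samples = generate_water_dynamics(spec, "samples")
    assert spec.mean == pytest.approx(0.2905, rel=1e-12)
    se = samples.d.std(ddof=1) / np.sqrt(len(samples.d))
    assert abs(samples.d.mean() - spec.mean) <= 3.0 * se


def test_sampling_moment_convergence_rate():
    """Sample-mean error shrinks roughly as n^(-1/2) against the analytic
    mean of the at-zero-truncated mixture."""
    from scipy import stats

    spec = water_population(243.0)
    truncated_mean = sum(
        w * stats.truncnorm.mean(-m / s, np.inf, loc=m, scale=s)
        for w, m, s in [(spec.w1, spec.m1, spec.s1), (spec.w2, spec.m2, spec.s2)]
    )
    errors = {}
    for n in (10**3, 10**4, 10**5):
        reps = []
        for seed in range(5):
            s = generate_water_dynamics(
                water_population(243.0, n_molecules=n, seed=seed), "samples")
            reps.append(s.d.mean() - truncated_mean)
        errors[n] = np.sqrt(np.mean(np.square(reps)))
    assert errors[10**4] < errors[10**3]
    assert errors[10**5] < errors[10**4]
    # within a factor ~3 of the n^(-1/2) prediction across two decades
    assert errors[10**3] / errors[10**5] == pytest.approx(10.0, rel=0.7)


def test_weights_must_sum_to_one():
    with pytest.raises(ValueError, match="sum to 1"):
        WaterPopulationSpec(w1=0.6, w2=0.6, m1=0.2, m2=0.5, s1=0.1, s2=0.1)


def test_mixture_recovery_low_temperature():
    samples = generate_water_dynamics(water_population(213.0, seed=1), "samples")
    fit = fit_bimodal_gaussian(samples, seed=1)
    assert abs(fit.w1 - 0.85) <= 0.05
    assert fit.m1 <= fit.m2


def test_single_gaussian_fitted_with_two_components():
    rng = np.random.default_rng(3)
    x = np.abs(rng.normal(1.0, 0.2, 2000))
    fit = fit_bimodal_gaussian(x, seed=3)
    assert max(fit.w1, fit.w2) >= 0.95 or fit.degenerate


def test_degenerate_identical_populations_flagged():
    spec = WaterPopulationSpec(w1=0.5, w2=0.5, m1=0.4, m2=0.4,
                               s1=1e-6, s2=1e-6, n_molecules=500, seed=4)
    samples = generate_water_dynamics(spec, "samples")
    fit = fit_bimodal_gaussian(samples, seed=4)
    assert fit.degenerate


def test_mixture_mle_consistency_with_replication():
    """Across replicated draws the truncation-aware MLE recovers every
    parameter of a known mixture within 3 SE of the replication spread."""
    truth = water_population(243.0)
    fits = []
    for seed in range(12):
        s = generate_water_dynamics(
            water_population(243.0, n_molecules=20000, seed=seed), "samples")
        fits.append(fit_bimodal_gaussian(s, seed=seed).as_series())
    import pandas as pd

    table = pd.DataFrame(fits)
    expected = dict(w1=truth.w1, m1=truth.m1, s1=truth.s1,
                    w2=truth.w2, m2=truth.m2, s2=truth.s2)
    for key, val in expected.items():
        se = table[key].std(ddof=1) / np.sqrt(len(table))
        assert abs(table[key].mean() - val) <= 3.0 * se + 0.01, key


def test_slow_weight_ordering_preserved_under_refit():
    """Refitted slow-population weights keep the 0.85 -> 0.45 -> 0.18 order."""
    fitted = []
    for temperature in (213.0, 243.0, 263.0):
        s = generate_water_dynamics(
            water_population(temperature, n_molecules=1000, seed=2), "samples")
        fitted.append(fit_bimodal_gaussian(s, seed=2).w1)
    assert fitted[0] > fitted[1] > fitted[2]


def test_trajectory_derived_weights_within_tolerance():
    """Mixture weights survive the trajectory -> per-molecule-D estimation
    chain to within +/-0.08 at 1000 molecules (estimator noise inflates the
    widths, not the weights)."""
    spec = water_population(243.0, n_molecules=1000, seed=5)
    traj = generate_water_dynamics(spec, "trajectories")
    samples = per_molecule_diffusion(traj)
    fit = fit_bimodal_gaussian(samples, seed=5)
    assert abs(fit.w1 - spec.w1) <= 0.08


def test_trajectory_reproducibility():
    spec = water_population(213.0, n_molecules=20, n_frames=50, seed=11)
    t1 = generate_water_dynamics(spec, "trajectories")
    t2 = generate_water_dynamics(spec, "trajectories")
    assert np.array_equal(t1.positions, t2.positions)
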