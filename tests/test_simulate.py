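"""Five-model trajectory generator: priors, per-model contracts, noise."""

from __future__ import annotations

import numpy as np
import pytest

from walkmmd import (
    MixtureSpec,
    ModelKind,
    SimulationPrior,
    add_localization_noise,
    generate_dataset,
    sample_prior,
    simulate_trajectory,
)

PRIOR = SimulationPrior()


def _ensemble_msd_exponent(model, alpha, n_traj=3000, n_pts=100, seed=0):
    """Log-log slope of the ensemble MSD from the origin.

    sBM and CTRW are weakly non-ergodic, so the exponent must be read from
    the ensemble MSD, not the time-averaged one.
    """
    rng = np.random.default_rng(seed)
    disp2 = np.zeros((n_traj, n_pts - 1))
    for i in range(n_traj):
        params = {"model": model, "N": n_pts, "D": 1.0, "alpha": alpha}
        traj = simulate_trajectory(model, params, PRIOR.dt, rng)
        disp2[i] = np.sum((traj.positions[1:] - traj.positions[0]) ** 2, axis=1)
    msd = disp2.mean(axis=0)
    lags = np.arange(1, n_pts)
    slope = np.polyfit(np.log(lags), np.log(msd), 1)[0]
    return slope


def test_prior_sampling_statistics():
    rng = np.random.default_rng(11)
    recs = [sample_prior(PRIOR, ModelKind.FBM, rng) for _ in range(20_000)]
    lengths = np.array([r["N"] for r in recs])
    logd = np.log10([r["D"] for r in recs])
    assert lengths.min() >= 7 and lengths.max() <= 25
    assert round(float(lengths.mean())) == 14
    assert abs(logd.mean() + 0.5) < 0.02
    assert abs(logd.std() - 0.5) < 0.02
    noise = np.array([r["noise_sd"] for r in recs])
    assert 0.015 <= noise.min() and noise.max() <= 0.040


def test_sample_prior_deterministic():
    a = sample_prior(PRIOR, ModelKind.OU, 42)
    b = sample_prior(PRIOR, ModelKind.OU, 42)
    assert a == b
    assert a["theta"] is not None and a["alpha"] is None


def test_alpha_validation():
    params = {"model": ModelKind.CTRW, "N": 10, "D": 1.0, "alpha": 1.5}
    with pytest.raises(ValueError, match="alpha"):
        simulate_trajectory(ModelKind.CTRW, params, PRIOR.dt)


def test_fbm_alpha_one_is_brownian():
    rng = np.random.default_rng(5)
    corrs = []
    for _ in range(2000):
        params = {"model": ModelKind.FBM, "N": 25, "D": 1.0, "alpha": 1.0}
        traj = simulate_trajectory(ModelKind.FBM, params, PRIOR.dt, rng)
        d = traj.displacements
        corrs.append(np.mean(d[:-1] * d[1:]) / np.mean(d * d))
    n_pairs = 2000 * 23 * 2
    assert abs(np.mean(corrs)) < 3.0 / np.sqrt(n_pairs)


def test_fbm_subdiffusive_anticorrelated():
    rng = np.random.default_rng(6)
    corrs = []
    for _ in range(500):
        params = {"model": ModelKind.FBM, "N": 25, "D": 1.0, "alpha": 0.4}
        traj = simulate_trajectory(ModelKind.FBM, params, PRIOR.dt, rng)
        d = traj.displacements
        corrs.append(np.mean(d[:-1] * d[1:]) / np.mean(d * d))
    # lag-1 autocorrelation of fGn: 2^(2H-1) - 1 < 0 for H < 1/2
    assert np.mean(corrs) < -0.1


def test_ou_stationary_variance():
    rng = np.random.default_rng(7)
    D, theta = 1.0, 0.8
    pts = []
    for _ in range(2000):
        params = {"model": ModelKind.OU, "N": 20, "D": D, "alpha": None, "theta": theta}
        traj = simulate_trajectory(ModelKind.OU, params, PRIOR.dt, rng)
        pts.append(traj.positions)
    var = np.concatenate(pts).var(axis=0).mean()
    want = D * PRIOR.dt / theta  # per-dimension stationary variance
    assert abs(var - want) / want < 0.1


def test_ctrw_has_repeated_positions():
    rng = np.random.default_rng(8)
    n_rep = 0
    for _ in range(100):
        params = {"model": ModelKind.CTRW, "N": 25, "D": 1.0, "alpha": 0.5}
        traj = simulate_trajectory(ModelKind.CTRW, params, PRIOR.dt, rng)
        steps = np.linalg.norm(traj.displacements, axis=1)
        n_rep += int(np.any(steps == 0.0))
    assert n_rep > 50  # waiting periods make repeats the norm


@pytest.mark.parametrize("model,alpha", [
    (ModelKind.FBM, 0.5),
    (ModelKind.FBM, 1.5),
    (ModelKind.SBM, 0.5),
    (ModelKind.SBM, 1.5),
    (ModelKind.LW, 1.5),
])
def test_ensemble_msd_exponent(model, alpha):
    slope = _ensemble_msd_exponent(model, alpha, seed=hash((model, alpha)) % 2**31)
    assert abs(slope - alpha) < 0.15, f"{model} alpha={alpha}: slope {slope:.3f}"


@pytest.mark.parametrize("model", [ModelKind.FBM, ModelKind.SBM, ModelKind.OU])
def test_doubling_d_doubles_msd(model):
    rng = np.random.default_rng(9)
    lag = 5
    msd = {}
    for D in (1.0, 2.0):
        vals = []
        for _ in range(4000):
            params = {"model": model, "N": lag + 1, "D": D, "alpha": 1.2, "theta": 0.5}
            if model is ModelKind.OU:
                params["alpha"] = None
            traj = simulate_trajectory(model, params, PRIOR.dt, rng)
            vals.append(np.sum((traj.positions[lag] - traj.positions[0]) ** 2))
        msd[D] = np.mean(vals)
    ratio = msd[2.0] / msd[1.0]
    assert 1.7 < ratio < 2.3, ratio


def test_noise_statistics():
    rng = np.random.default_rng(10)
    params = {"model": ModelKind.FBM, "N": 25, "D": 1.0, "alpha": 1.0}
    traj = simulate_trajectory(ModelKind.FBM, params, PRIOR.dt, rng)

    same = add_localization_noise(traj, 0.0, rng_seed=1)
    assert np.array_equal(same.positions, traj.positions)
    assert np.array_equal(same.meta["true_positions"], traj.positions)

    resid = []
    for seed in range(400):
        noisy = add_localization_noise(traj, 0.025, rng_seed=seed)
        resid.append(noisy.positions - traj.positions)
    resid = np.concatenate(resid).ravel()
    se = 0.025 / np.sqrt(2 * len(resid))
    assert abs(resid.std() - 0.025) < 3 * se


def test_generate_dataset_contracts():
    mix = MixtureSpec({ModelKind.FBM: 0.5, ModelKind.SBM: 0.5})
    g1 = generate_dataset(mix, 500, PRIOR, rng_seed=3)
    g2 = generate_dataset(mix, 500, PRIOR, rng_seed=3)
    assert all(np.array_equal(a.positions, b.positions) for a, b in zip(g1, g2))
    labels = {t.meta["model"] for t in g1}
    assert labels <= {"fBM", "sBM"}
    n_fbm = sum(t.meta["model"] == "fBM" for t in g1)
    # binomial 99.9% band around 250 of 500
    assert abs(n_fbm - 250) < 3.3 * np.sqrt(500 * 0.25)
    assert all(np.all(np.isfinite(t.positions)) for t in g1)
    assert all(7 <= len(t) <= 25 for t in g1)


def test_pure_mixture_and_validation():
    g = generate_dataset(MixtureSpec({ModelKind.FBM: 1.0}), 50, PRIOR, rng_seed=4)
    assert all(t.meta["model"] == "fBM" for t in g)
    with pytest.raises(ValueError, match="sum to 1"):
        MixtureSpec({ModelKind.FBM: 0.6, ModelKind.SBM: 0.6})
    with pytest.raises(ValueError, match="nu and delta"):
        MixtureSpec({ModelKind.FBM: 1.0}, nu=1.5)
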