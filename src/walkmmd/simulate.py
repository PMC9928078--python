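"""Synthetic trajectory generation from five canonical random-walk models.

The generator produces the labelled training and benchmarking data for the
whole pipeline: Levy walks (LW), scaled Brownian motion (sBM), the
Ornstein-Uhlenbeck process (OU), fractional Brownian motion (fBM) and the
continuous-time random walk (CTRW). Together these cover Gaussian and
non-Gaussian increments, stationarity and ageing, ergodic and weakly
non-ergodic behaviour, and continuous as well as discontinuous paths.

Default priors (shared by every model throughout the package):

* trajectory length ``N`` log-uniform on [7, 25] points (mean ~14);
* effective diffusivity ``D`` log-normal, ``<log10(D/D0)> = -0.5`` and
  ``sd = 0.5`` with ``D0 = 1 um^2/s``;
* OU relaxation rate ``theta`` log-uniform on [0.01, 1] (per time lapse);
* localization noise sd uniform on [0.015, 0.040] um, uncorrelated;
* time lapse ``dt = 0.0154 s`` (camera frame interval).

Anomalous-exponent ranges follow the AnDi-challenge conventions: fBM and sBM
``alpha ~ U[0.2, 1.8]``, CTRW ``alpha ~ U[0.2, 1.0]``, LW ``alpha ~ U[1.0,
2.0]``; OU has no anomalous exponent.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .trajectory import Trajectory, TrajectoryGroup


class ModelKind(str, enum.Enum):
    """The five canonical random-walk models."""

    LW = "LW"
    SBM = "sBM"
    OU = "OU"
    FBM = "fBM"
    CTRW = "CTRW"


MODEL_ORDER = (ModelKind.LW, ModelKind.SBM, ModelKind.OU, ModelKind.FBM, ModelKind.CTRW)

#: alpha prior bounds per model; None for OU (not an anomalous random walk).
ALPHA_RANGES = {
    ModelKind.FBM: (0.2, 1.8),
    ModelKind.SBM: (0.2, 1.8),
    ModelKind.CTRW: (0.2, 1.0),
    ModelKind.LW: (1.0, 2.0),
    ModelKind.OU: None,
}


@dataclass
class SimulationPrior:
    """Parameter priors shared by all five models."""

    length_low: int = 7
    length_high: int = 25
    D0: float = 1.0  # um^2/s, scale of the log-normal diffusivity prior
    logD_mean: float = -0.5  # log10 units
    logD_sd: float = 0.5
    theta_low: float = 0.01  # OU relaxation rate, per time lapse
    theta_high: float = 1.0
    noise_sd_low: float = 0.015  # um
    noise_sd_high: float = 0.040
    dt: float = 0.0154  # s
    alpha_ranges: dict = field(default_factory=lambda: dict(ALPHA_RANGES))

    def __post_init__(self) -> None:
        pairs = [
            (self.length_low, self.length_high),
            (self.theta_low, self.theta_high),
            (self.noise_sd_low, self.noise_sd_high),
        ]
        for low, high in pairs:
            if not (0 < low < high):
                raise ValueError(f"invalid prior bounds: {low} !< {high}")
        if self.D0 <= 0 or self.dt <= 0 or self.logD_sd <= 0:
            raise ValueError("D0, dt and logD_sd must be positive")


@dataclass
class MixtureSpec:
    """Model mixture for dataset generation and power experiments.

    ``fractions`` gives the share of each model in a generated set. For the
    two-set fBM/sBM power experiments, ``nu`` is the mixture contrast (set X
    receives fBM fraction ``0.5 + nu``, set Y ``0.5 - nu``) and ``delta`` the
    anomalous-exponent offset (``alpha = 1 - delta`` vs ``1 + delta``).
    """

    fractions: dict
    nu: float = 0.0
    delta: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture fractions must sum to 1, got {total}")
        if not (0.0 <= self.nu <= 1.0 and 0.0 <= self.delta <= 1.0):
            raise ValueError("nu and delta must lie in [0, 1]")
        self.fractions = {ModelKind(k): float(v) for k, v in self.fractions.items()}


def sample_prior(prior: SimulationPrior, model: ModelKind, rng_seed) -> dict:
    """Draw one parameter record (N, D, alpha, theta, noise_sd) from the prior.

    ``rng_seed`` may be an integer seed or a ``numpy.random.Generator``.
    """
    rng = np.random.default_rng(rng_seed)
    model = ModelKind(model)
    n = int(
        np.clip(
            round(np.exp(rng.uniform(np.log(prior.length_low), np.log(prior.length_high)))),
            prior.length_low,
            prior.length_high,
        )
    )
    D = prior.D0 * 10.0 ** rng.normal(prior.logD_mean, prior.logD_sd)
    rec = {
        "model": model,
        "N": n,
        "D": float(D),
        "noise_sd": float(rng.uniform(prior.noise_sd_low, prior.noise_sd_high)),
        "alpha": None,
        "theta": None,
    }
    rng_alpha = prior.alpha_ranges.get(model)
    if rng_alpha is not None:
        rec["alpha"] = float(rng.uniform(*rng_alpha))
    if model is ModelKind.OU:
        rec["theta"] = float(
            np.exp(rng.uniform(np.log(prior.theta_low), np.log(prior.theta_high)))
        )
    return rec


# --------------------------------------------------------------------------
# per-model position generators (noiseless, 2D, regular dt grid)
# --------------------------------------------------------------------------


def _fgn_cholesky(n_steps: int, hurst: float, rng) -> np.ndarray:
    """Exact fractional Gaussian noise: (n_steps, 2) unit-variance increments.

    Uses a Cholesky factorization of the fGn autocorrelation matrix; exact at
    any length and cheap for the short trajectories used here.
    """
    k = np.arange(n_steps)
    h2 = 2.0 * hurst
    rho = 0.5 * (
        np.abs(k + 1) ** h2 - 2.0 * np.abs(k) ** h2 + np.abs(k - 1) ** h2
    )
    cov = rho[np.abs(k[:, None] - k[None, :])]
    # jitter guards the marginally non-PD cases (alpha near 2)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(n_steps))
    return L @ rng.standard_normal((n_steps, 2))


def _simulate_fbm(n, D, alpha, dt, rng):
    steps = np.sqrt(2.0 * D * dt) * _fgn_cholesky(n - 1, alpha / 2.0, rng)
    return np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])


def _simulate_sbm(n, D, alpha, dt, rng):
    # K_alpha = D * dt^(1-alpha); per-dim increment var 2 K (t_i^a - t_{i-1}^a)
    t = np.arange(n) * dt
    var = 2.0 * D * dt ** (1.0 - alpha) * np.diff(t**alpha)
    steps = np.sqrt(var)[:, None] * rng.standard_normal((n - 1, 2))
    return np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])


def _simulate_ou(n, D, theta, dt, rng):
    # theta is a relaxation rate per time lapse; stationary per-dim variance
    # D*dt/theta; exact discretization with stationary start.
    s2 = D * dt / theta
    decay = np.exp(-theta)
    innov_sd = np.sqrt(s2 * (1.0 - decay**2))
    pos = np.empty((n, 2))
    pos[0] = np.sqrt(s2) * rng.standard_normal(2)
    for i in range(1, n):
        pos[i] = pos[i - 1] * decay + innov_sd * rng.standard_normal(2)
    return pos


def _simulate_ctrw(n, D, alpha, dt, rng):
    # heavy-tailed waiting times psi(tau) ~ tau^-(1+alpha), tau >= tau0;
    # Gaussian jumps with per-dim variance 2*D*dt (common diffusivity scale).
    tau0 = dt / 10.0
    t_total = (n - 1) * dt
    t_jump = 0.0
    jump_times = []
    while True:
        t_jump += tau0 * rng.uniform() ** (-1.0 / alpha)
        if t_jump > t_total:
            break
        jump_times.append(t_jump)
        if len(jump_times) > 100 * n:  # pathological draw guard
            break
    n_jumps = len(jump_times)
    jumps = np.sqrt(2.0 * D * dt) * rng.standard_normal((n_jumps, 2))
    pos_at_jump = np.vstack([np.zeros((1, 2)), np.cumsum(jumps, axis=0)])
    # position on the regular grid: piecewise constant between jumps
    grid = np.arange(n) * dt
    idx = np.searchsorted(jump_times, grid, side="right")
    return pos_at_jump[idx]


def _simulate_lw(n, D, alpha, dt, rng):
    # ballistic flights of constant speed, heavy-tailed durations with
    # exponent gamma = 3 - alpha (MSD ~ t^alpha for 1 < gamma < 2);
    # speed chosen so the one-frame displacement variance matches 2*D*dt.
    gamma = 3.0 - alpha
    tau0 = dt
    speed = 2.0 * np.sqrt(D / dt)
    t_total = (n - 1) * dt
    t = 0.0
    segs = []  # (t_start, t_end, velocity)
    while t < t_total:
        tau = tau0 * rng.uniform() ** (-1.0 / gamma)
        ang = rng.uniform(0.0, 2.0 * np.pi)
        v = speed * np.array([np.cos(ang), np.sin(ang)])
        segs.append((t, min(t + tau, t_total), v))
        t += tau
    pos = np.zeros((n, 2))
    grid = np.arange(n) * dt
    cur = np.zeros(2)
    for t0, t1, v in segs:
        inside = (grid > t0) & (grid <= t1)
        pos[inside] = cur[None, :] + (grid[inside, None] - t0) * v[None, :]
        cur = cur + (t1 - t0) * v
    return pos


def simulate_trajectory(model: ModelKind, params: dict, dt: float, rng_seed=None) -> Trajectory:
    """Simulate one noiseless trajectory of ``model`` with ``params``.

    ``params`` is a record as returned by :func:`sample_prior`. The trajectory
    carries its ground truth in ``meta``.
    """
    model = ModelKind(model)
    rng = np.random.default_rng(rng_seed)
    n, D = int(params["N"]), float(params["D"])
    alpha = params.get("alpha")
    rng_alpha = ALPHA_RANGES[model]
    if rng_alpha is not None:
        if alpha is None or not (rng_alpha[0] <= alpha <= rng_alpha[1]):
            raise ValueError(f"{model.value}: alpha {alpha} outside {rng_alpha}")
    if model is ModelKind.FBM:
        pos = _simulate_fbm(n, D, alpha, dt, rng)
    elif model is ModelKind.SBM:
        pos = _simulate_sbm(n, D, alpha, dt, rng)
    elif model is ModelKind.OU:
        pos = _simulate_ou(n, D, float(params["theta"]), dt, rng)
    elif model is ModelKind.CTRW:
        pos = _simulate_ctrw(n, D, alpha, dt, rng)
    elif model is ModelKind.LW:
        pos = _simulate_lw(n, D, alpha, dt, rng)
    else:  # pragma: no cover - closed enumeration
        raise ValueError(f"unknown model {model}")
    meta = {
        "model": model.value,
        "alpha": alpha,
        "D": D,
        "theta": params.get("theta"),
        "noise_sd": params.get("noise_sd"),
    }
    return Trajectory(pos, dt=dt, track_id=params.get("track_id", 0), meta=meta)


def add_localization_noise(traj: Trajectory, noise_sd: float, rng_seed=None) -> Trajectory:
    """Add i.i.d. centred Gaussian localization noise to every coordinate.

    The noiseless positions are retained in ``meta['true_positions']``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(rng_seed)
    if noise_sd == 0:
        noisy = traj.positions.copy()
    else:
        noisy = traj.positions + rng.normal(0.0, noise_sd, traj.positions.shape)
    meta = dict(traj.meta)
    meta["true_positions"] = traj.positions.copy()
    meta["noise_sd"] = noise_sd
    return Trajectory(noisy, dt=traj.dt, track_id=traj.track_id, meta=meta)


def generate_dataset(
    mixture: MixtureSpec,
    n: int,
    prior: SimulationPrior | None = None,
    rng_seed=None,
    noise: bool = True,
    label=None,
) -> TrajectoryGroup:
    """Generate ``n`` labelled (noisy) trajectories from a model mixture.

    Model counts are multinomial at the mixture fractions; the whole dataset
    is reproducible from ``rng_seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    prior = prior or SimulationPrior()
    rng = np.random.default_rng(rng_seed)
    models = list(mixture.fractions)
    probs = np.array([mixture.fractions[m] for m in models])
    assignments = rng.choice(len(models), size=n, p=probs)
    trajs = []
    for i, mi in enumerate(assignments):
        model = models[mi]
        params = sample_prior(prior, model, rng)
        params["track_id"] = i
        traj = simulate_trajectory(model, params, prior.dt, rng)
        if noise:
            traj = add_localization_noise(traj, params["noise_sd"], rng)
        trajs.append(traj)
    return TrajectoryGroup(trajs, label=label)
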