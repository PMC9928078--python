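"""Simulation experiments for calibrating and validating the MMD test.

The canonical benchmark compares two sets of simulated trajectories drawn
from fBM/sBM mixtures differing by a contrast ``nu``: set X holds an fBM
fraction ``0.5 + nu`` and set Y ``0.5 - nu`` (so ``nu = 0`` is the null,
identical 50/50 mixtures, and ``nu = 0.5`` the fully separated 100/0 vs
0/100 case). A second variant compares pure-fBM sets with anomalous
exponents ``1 - delta`` vs ``1 + delta``. Rejection probabilities over
repeated fresh draws estimate the test's type-I error (nu = delta = 0) and
its power.
"""

from __future__ import annotations

import numpy as np

from .features import classical_feature_table
from .mmd import MEDIAN, equalize_sizes, marginalize_by_length, permutation_test
from .simulate import MixtureSpec, ModelKind, SimulationPrior, generate_dataset

__all__ = [
    "mixture_pair",
    "simulate_contrast_pair",
    "rejection_rate",
]


def mixture_pair(nu: float):
    """(X, Y) mixture specs for the fBM/sBM contrast ``nu`` in [0, 0.5]."""
    if not 0 <= nu <= 0.5:
        raise ValueError("nu must lie in [0, 0.5]")
    mx = MixtureSpec({ModelKind.FBM: 0.5 + nu, ModelKind.SBM: 0.5 - nu}, nu=nu)
    my = MixtureSpec({ModelKind.FBM: 0.5 - nu, ModelKind.SBM: 0.5 + nu}, nu=nu)
    return mx, my


def simulate_contrast_pair(
    n: int,
    nu: float = 0.0,
    delta: float = 0.0,
    prior: SimulationPrior | None = None,
    rng_seed=None,
):
    """Two fresh trajectory groups for a power/type-I experiment.

    ``nu`` sets the fBM/sBM mixture contrast; alternatively ``delta`` sets
    the anomalous-exponent offset between two pure-fBM sets (alpha fixed at
    ``1 - delta`` vs ``1 + delta``). Only one of the two may be non-zero.
    """
    if nu and delta:
        raise ValueError("use either nu or delta, not both")
    prior = prior or SimulationPrior()
    rng = np.random.default_rng(rng_seed)
    if delta:
        pure = MixtureSpec({ModelKind.FBM: 1.0}, delta=delta)
        px = SimulationPrior(**{**_prior_kwargs(prior)})
        px.alpha_ranges = {**prior.alpha_ranges,
                           ModelKind.FBM: (1.0 - delta, 1.0 - delta)}
        py = SimulationPrior(**{**_prior_kwargs(prior)})
        py.alpha_ranges = {**prior.alpha_ranges,
                           ModelKind.FBM: (1.0 + delta, 1.0 + delta)}
        gx = generate_dataset(pure, n, px, rng_seed=rng.integers(2**31), label="X")
        gy = generate_dataset(pure, n, py, rng_seed=rng.integers(2**31), label="Y")
    else:
        mx, my = mixture_pair(nu)
        gx = generate_dataset(mx, n, prior, rng_seed=rng.integers(2**31), label="X")
        gy = generate_dataset(my, n, prior, rng_seed=rng.integers(2**31), label="Y")
    return gx, gy


def _prior_kwargs(p: SimulationPrior) -> dict:
    import dataclasses

    d = dataclasses.asdict(p)
    d["alpha_ranges"] = dict(p.alpha_ranges)
    return d


def rejection_rate(
    n_reps: int,
    n: int,
    nu: float = 0.0,
    delta: float = 0.0,
    featurize=None,
    kernel=MEDIAN,
    B: int = 500,
    beta: float = 0.05,
    prior: SimulationPrior | None = None,
    rng_seed=None,
):
    """Fraction of ``n_reps`` fresh-draw experiments rejecting H0.

    Each repetition simulates a new pair of sets of ``n`` trajectories,
    featurizes them (``featurize(group) -> (n, d)`` array; classical
    features by default), marginalizes by trajectory length, equalizes
    sizes, and runs the MMD permutation test.
    """
    featurize = featurize or classical_feature_table
    rng = np.random.default_rng(rng_seed)
    rejections = 0
    for _ in range(n_reps):
        gx, gy = simulate_contrast_pair(n, nu=nu, delta=delta, prior=prior,
                                        rng_seed=rng.integers(2**31))
        fx = featurize(gx)
        fy = featurize(gy)
        fx, fy = marginalize_by_length(fx, gx.lengths, fy, gy.lengths,
                                       rng_seed=rng.integers(2**31))
        fx, fy = equalize_sizes(fx, fy, rng_seed=rng.integers(2**31))
        res = permutation_test(fx, fy, kernel=kernel, B=B, beta=beta,
                               rng_seed=rng.integers(2**31))
        rejections += int(res.reject)
    return rejections / n_reps
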