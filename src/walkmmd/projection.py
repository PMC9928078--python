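"""Frozen parametric 2D projection of the 16D latent space.

The 2D map is learnt once, on simulated trajectories only, and then frozen:
applying it to new (e.g. experimental) data never refits anything, which
keeps the featurization independent of the data being tested. It is built in
two steps: a non-parametric UMAP neighbour embedding of the simulated latent
vectors, distilled into a small MLP regressor that becomes the reusable,
deterministic 16D -> 2D map.
"""

from __future__ import annotations

import numpy as np

MIN_FIT_SAMPLES = 10_000


class ProjectionModel:
    """Deterministic parametric 16D -> 2D map (standardize + MLP)."""

    def __init__(self, mean, sd, coefs, intercepts):
        self.mean = np.asarray(mean, dtype=float)
        self.sd = np.asarray(sd, dtype=float)
        self.coefs = [np.asarray(c, dtype=float) for c in coefs]
        self.intercepts = [np.asarray(b, dtype=float) for b in intercepts]

    def transform(self, latents: np.ndarray) -> np.ndarray:
        """Project (n, latent_dim) vectors to (n, 2); pure function."""
        h = (np.asarray(latents, dtype=float) - self.mean) / self.sd
        n_layers = len(self.coefs)
        for i, (W, b) in enumerate(zip(self.coefs, self.intercepts)):
            h = h @ W + b
            if i < n_layers - 1:
                h = np.maximum(h, 0.0)
        return h

    def state_arrays(self) -> dict:
        out = {"mean": self.mean, "sd": self.sd,
               "n_layers": np.array([len(self.coefs)])}
        for i, (W, b) in enumerate(zip(self.coefs, self.intercepts)):
            out[f"W{i}"] = W
            out[f"b{i}"] = b
        return out

    @classmethod
    def from_state_arrays(cls, arrays: dict) -> "ProjectionModel":
        n = int(arrays["n_layers"][0])
        return cls(
            arrays["mean"],
            arrays["sd"],
            [arrays[f"W{i}"] for i in range(n)],
            [arrays[f"b{i}"] for i in range(n)],
        )


def fit_projection_2d(
    latents: np.ndarray,
    rng_seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    min_samples: int = MIN_FIT_SAMPLES,
) -> ProjectionModel:
    """Learn the frozen 2D projection from simulated latent vectors.

    Runs UMAP (seeded) on the latent vectors, then fits an MLP regressor
    (two hidden layers, 64 and 32 units) from the standardized latents to
    the embedding coordinates. The returned model is deterministic and never
    refits; requires at least ``min_samples`` vectors so the embedding is a
    stable summary of the simulation prior.
    """
    import umap
    from sklearn.neural_network import MLPRegressor

    latents = np.asarray(latents, dtype=float)
    if len(latents) < min_samples:
        raise ValueError(
            f"need at least {min_samples} simulated latent vectors, got {len(latents)}"
        )
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=int(rng_seed),
    )
    embedding = reducer.fit_transform(latents)

    mean = latents.mean(axis=0)
    sd = latents.std(axis=0) + 1e-8
    z = (latents - mean) / sd
    net = MLPRegressor(
        hidden_layer_sizes=(64, 32),
        activation="relu",
        random_state=int(rng_seed),
        max_iter=400,
        early_stopping=False,
    )
    net.fit(z, embedding)
    return ProjectionModel(mean, sd, net.coefs_, net.intercepts_)
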