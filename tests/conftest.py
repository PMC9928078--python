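"""Shared fixtures: the reduced-scale trained encoder and held-out data.

Training is the expensive part of the suite (~2 min on one CPU), so the
encoder is trained once per session and shared by every test that needs it.
"""

from __future__ import annotations

import numpy as np
import pytest

from walkmmd import (
    EncoderConfig,
    MixtureSpec,
    SimulationPrior,
    build_model,
    generate_dataset,
    train_encoder,
)
from walkmmd.simulate import MODEL_ORDER

#: seed used by the session fixtures (fixed a priori)
SESSION_SEED = 20260101


@pytest.fixture(scope="session")
def trained_encoder():
    """Encoder trained at reduced scale (1e5 streamed trajectories).

    Returns ``(model, training_log)``.
    """
    cfg = EncoderConfig(seed=SESSION_SEED % 2**31, n_train_trajectories=100_000)
    model = build_model(cfg)
    model, log = train_encoder(model, config=cfg)
    return model, log


@pytest.fixture(scope="session")
def heldout_group():
    """1e4 fresh labelled trajectories from the uniform five-model mixture."""
    mixture = MixtureSpec({m: 0.2 for m in MODEL_ORDER})
    return generate_dataset(mixture, 10_000, SimulationPrior(),
                            rng_seed=SESSION_SEED + 7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
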