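"""Train a small encoder and inspect its latent summary statistics.

Trains the graph neural encoder on trajectories streamed from the simulation
prior (a reduced 20k-trajectory budget keeps this example to a couple of
minutes; the default configuration uses 100k), then encodes a held-out set
and reports the model-classification accuracy and the anomalous-exponent
error against the constant-prediction baseline.

Run with:  python examples/02_train_and_encode.py
"""

import numpy as np

from walkmmd import (
    EncoderConfig,
    MixtureSpec,
    build_model,
    encode,
    generate_dataset,
    save_model,
    train_encoder,
)
from walkmmd.encoder import MODEL_TO_INDEX, PRIOR_MEAN_ALPHA
from walkmmd.simulate import MODEL_ORDER, ModelKind

if __name__ == "__main__":
    config = EncoderConfig(n_train_trajectories=20_000, seed=0)
    model = build_model(config)
    model, log = train_encoder(model, verbose=True)
    print(f"trained on {log[-1]['n_seen']} trajectories; "
          f"loss {log[0]['loss']:.3f} -> {log[-1]['loss']:.3f}")

    mixture = MixtureSpec({m: 0.2 for m in MODEL_ORDER})
    heldout = generate_dataset(mixture, 5_000, rng_seed=123)
    table = encode(model, heldout)

    truth_model = np.array([MODEL_TO_INDEX[ModelKind(t.meta["model"])]
                            for t in heldout])
    acc = np.mean(np.argmax(table.model_probs, axis=1) == truth_model)
    print(f"model classification accuracy: {acc:.3f} (chance 0.2)")

    truth_alpha = np.array([np.nan if t.meta["alpha"] is None else t.meta["alpha"]
                            for t in heldout])
    mask = ~np.isnan(truth_alpha)
    mae = np.mean(np.abs(table.alpha_pred[mask] - truth_alpha[mask]))
    base = np.mean(np.abs(PRIOR_MEAN_ALPHA - truth_alpha[mask]))
    print(f"alpha MAE: {mae:.3f} (constant-prediction baseline {base:.3f})")

    save_model(model, "encoder_small.npz")
    print("saved to encoder_small.npz")
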