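"""Encoder construction, determinism, invariances, serialization, probing."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from walkmmd import (
    EncoderConfig,
    MixtureSpec,
    ModelKind,
    Trajectory,
    TrajectoryGroup,
    add_localization_noise,
    build_model,
    encode,
    generate_dataset,
    load_model,
    save_model,
    simulate_trajectory,
)
from walkmmd.encoder import _GraphBatch
from walkmmd.simulate import MODEL_ORDER

DT = 0.0154
UNIFORM = MixtureSpec({m: 0.2 for m in MODEL_ORDER})


@pytest.fixture(scope="module")
def calibrated_model():
    """Untrained encoder with frozen input statistics (forward pass works)."""
    model = build_model(EncoderConfig(seed=11))
    group = generate_dataset(UNIFORM, 512, rng_seed=11)
    model.calibrate(_GraphBatch(group.trajectories))
    return model


@pytest.fixture(scope="module")
def small_group():
    return generate_dataset(UNIFORM, 64, rng_seed=12)


def _fbm_group(alpha, n, rng_seed, label=None):
    rng = np.random.default_rng(rng_seed)
    trajs = []
    for i in range(n):
        params = {"model": ModelKind.FBM, "N": 20, "D": 0.3, "alpha": alpha,
                  "track_id": i}
        t = simulate_trajectory(ModelKind.FBM, params, DT, rng)
        trajs.append(add_localization_noise(t, 0.025, rng))
    return TrajectoryGroup(trajs, label=label)


def test_build_model_seeded():
    a = build_model(EncoderConfig(seed=3))
    b = build_model(EncoderConfig(seed=3))
    c = build_model(EncoderConfig(seed=4))
    pa, pb, pc = a.named_parameters(), b.named_parameters(), c.named_parameters()
    assert pa.keys() == pb.keys() == pc.keys()
    assert all(np.array_equal(pa[k].data, pb[k].data) for k in pa)
    assert any(not np.array_equal(pa[k].data, pc[k].data) for k in pa)


def test_config_validation():
    with pytest.raises(ValueError):
        EncoderConfig(latent_dim=0)
    with pytest.raises(ValueError):
        EncoderConfig(conv_layers=-1)


def test_forward_shapes(calibrated_model, small_group):
    batch = _GraphBatch(small_group.trajectories)
    latent, alpha, logits = calibrated_model.forward(batch)
    n = batch.n_graphs
    assert latent.data.shape == (n, 16)
    assert alpha.data.shape == (n, 1)
    assert logits.data.shape == (n, 5)
    assert np.all(np.isfinite(latent.data))


def test_forward_requires_calibration(small_group):
    model = build_model(EncoderConfig(seed=0))
    with pytest.raises(RuntimeError, match="calibrat"):
        model.forward(_GraphBatch(small_group.trajectories))


def test_encode_contract(calibrated_model, small_group):
    table = encode(calibrated_model, small_group)
    assert len(table) == len(small_group)
    assert table.latent.shape == (len(table), 16)
    assert np.allclose(table.model_probs.sum(axis=1), 1.0)
    assert np.all(table.model_probs >= 0)
    assert np.array_equal(np.sort(table.lengths), np.sort(small_group.lengths))
    with pytest.raises(ValueError, match="projection"):
        table.features("latent2d")
    assert table.features("latent") is table.latent
    with pytest.raises(ValueError, match="feature kind"):
        table.features("bogus")


def test_encode_deterministic_and_batch_independent(calibrated_model, small_group):
    t1 = encode(calibrated_model, small_group)
    t2 = encode(calibrated_model, small_group)
    assert np.array_equal(t1.latent, t2.latent)

    t3 = encode(calibrated_model, small_group, batch_size=7)
    assert np.allclose(t1.latent, t3.latent, atol=1e-10)

    rev = TrajectoryGroup(list(small_group)[::-1], label=small_group.label)
    t4 = encode(calibrated_model, rev)
    order = np.argsort(t1.track_ids.astype(int))
    order4 = np.argsort(t4.track_ids.astype(int))
    assert np.allclose(t1.latent[order], t4.latent[order4], atol=1e-10)


def test_latent_rigid_motion_invariance(calibrated_model, rng):
    pos = np.cumsum(rng.normal(size=(18, 2)), axis=0)
    theta = 0.8
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    g1 = TrajectoryGroup([Trajectory(pos, dt=DT, track_id=0)])
    g2 = TrajectoryGroup([Trajectory(pos @ rot.T + [3.0, -7.0], dt=DT, track_id=0)])
    t1 = encode(calibrated_model, g1)
    t2 = encode(calibrated_model, g2)
    assert np.allclose(t1.latent, t2.latent, atol=1e-9)


def test_encode_skips_degenerate(calibrated_model, caplog):
    good = Trajectory(np.cumsum(np.ones((10, 2)), axis=0)
                      + 0.1 * np.arange(10)[:, None] ** 2,
                      dt=DT, track_id="good")
    stuck = Trajectory(np.zeros((10, 2)), dt=DT, track_id="stuck")
    with caplog.at_level("WARNING"):
        table = encode(calibrated_model, TrajectoryGroup([good, stuck]))
    assert len(table) == 1
    assert table.track_ids[0] == "good"
    assert "stuck" in caplog.text


def test_save_load_round_trip(calibrated_model, small_group, tmp_path):
    path = tmp_path / "enc.npz"
    save_model(calibrated_model, path)
    loaded = load_model(path)
    pa = calibrated_model.named_parameters()
    pb = loaded.named_parameters()
    assert pa.keys() == pb.keys()
    for k in pa:
        assert np.array_equal(pa[k].data, pb[k].data), k
    t1 = encode(calibrated_model, small_group)
    t2 = encode(loaded, small_group)
    assert np.array_equal(t1.latent, t2.latent)
    assert np.array_equal(t1.model_probs, t2.model_probs)


def test_load_rejects_bad_files(calibrated_model, tmp_path):
    txt = tmp_path / "junk.npz"
    txt.write_text("not an archive")
    with pytest.raises(ValueError, match="not a valid encoder file"):
        load_model(txt)

    nometa = tmp_path / "nometa.npz"
    np.savez(nometa, a=np.zeros(3))
    with pytest.raises(ValueError, match="no metadata"):
        load_model(nometa)

    good = tmp_path / "enc.npz"
    save_model(calibrated_model, good)
    with np.load(good) as npz:
        arrays = {k: npz[k] for k in npz.files}

    import json
    meta = json.loads(bytes(arrays["meta_json"].tobytes()).decode())
    meta["version"] = "walkmmd-encoder-99"
    bad = dict(arrays)
    bad["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    wrong_version = tmp_path / "wrong_version.npz"
    np.savez(wrong_version, **bad)
    with pytest.raises(ValueError, match="version mismatch"):
        load_model(wrong_version)

    missing = {k: v for k, v in arrays.items() if k != "param:att_gate.0"}
    truncated = tmp_path / "truncated.npz"
    np.savez(truncated, **missing)
    with pytest.raises(ValueError, match="missing param:att_gate.0"):
        load_model(truncated)


def test_trained_model_metadata(trained_encoder, tmp_path):
    model, _ = trained_encoder
    assert model.trained
    assert model.prior_snapshot is not None
    assert model.prior_snapshot["dt"] == pytest.approx(DT)
    path = tmp_path / "trained.npz"
    save_model(model, path)
    loaded = load_model(path)
    assert loaded.trained
    assert list(loaded.prior_snapshot["alpha_ranges"]["fBM"]) == [0.2, 1.8]


def test_training_loss_decreases(trained_encoder):
    _, log = trained_encoder
    losses = np.array([rec["loss"] for rec in log])
    head = losses[:20].mean()
    tail = losses[-20:].mean()
    assert tail < 0.7 * head, (head, tail)


def test_latent_linear_probe_alpha(trained_encoder):
    """The 16D latents linearly separate slow from fast fBM."""
    model, _ = trained_encoder
    lo = encode(model, _fbm_group(0.4, 300, rng_seed=21))
    hi = encode(model, _fbm_group(1.6, 300, rng_seed=22))
    X = np.vstack([lo.latent, hi.latent])
    y = np.r_[np.zeros(len(lo)), np.ones(len(hi))]
    rng = np.random.default_rng(23)
    idx = rng.permutation(len(y))
    tr, te = idx[:400], idx[400:]
    clf = LogisticRegression(max_iter=2000).fit(X[tr], y[tr])
    acc = clf.score(X[te], y[te])
    assert acc > 0.8, acc

    # the alpha head itself orders the two sets correctly
    assert hi.alpha_pred.mean() > lo.alpha_pred.mean() + 0.3
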