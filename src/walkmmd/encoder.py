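"""Graph neural encoder: amortized simulation-based inference on trajectories.

The encoder maps a trajectory graph to a 16-dimensional vector of learnt
summary statistics. Architecture: node (6 -> 10) and edge (6 -> 16) embedding
perceptrons; three edge-conditioned GIN-style message-passing layers with 32
channels (sum aggregation; the published GIN update ignores edge attributes,
so messages are ``relu(h_src + W e)`` following the GINE variant); attention
pooling over nodes; concatenation of the global log-scale feature; a
perceptron to the 16D latent; and two task heads predicting the anomalous
diffusion exponent (masked out for OU, which is not an anomalous walk) and
the generating model among the five classes. Training minimises the
unweighted sum of the masked MSE and the cross-entropy, on trajectories
simulated on the fly from the prior.

The trained encoder is frozen and deterministic in evaluation mode; latent
vectors inherit the graph features' invariance to rigid motions, with the
overall spatial scale entering only through the log-scale channel.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .graph import DegenerateTrajectoryError, trajectory_to_graph
from .nn.autodiff import (
    Tensor,
    concat,
    gather,
    layer_norm,
    masked_mse,
    relu,
    segment_softmax,
    segment_sum,
    softmax,
    softmax_cross_entropy,
)
from .nn.layers import MLP, Adam, Linear
from .simulate import MODEL_ORDER, MixtureSpec, ModelKind, SimulationPrior, generate_dataset
from .trajectory import TrajectoryGroup

logger = logging.getLogger(__name__)

FORMAT_VERSION = "walkmmd-encoder-1"

MODEL_TO_INDEX = {m: i for i, m in enumerate(MODEL_ORDER)}
#: mean of the alpha priors pooled over the four anomalous models, used as
#: the constant-prediction baseline during evaluation
PRIOR_MEAN_ALPHA = 1.1

#: nonnegative, heavy-tailed feature columns that get log1p-compressed
#: before standardization (cumulative power sums and distances)
NODE_LOG_COLS = [1, 2, 3, 4, 5]
EDGE_LOG_COLS = [1, 2, 3, 4]


@dataclass
class EncoderConfig:
    """Architecture and training hyper-parameters."""

    node_embed_dim: int = 10
    edge_embed_dim: int = 16
    conv_layers: int = 3
    conv_channels: int = 32
    latent_dim: int = 16
    head_hidden: tuple = (64, 32)
    n_train_trajectories: int = 100_000
    batch_size: int = 256
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        dims = (self.node_embed_dim, self.edge_embed_dim, self.conv_layers,
                self.conv_channels, self.latent_dim, self.batch_size)
        if any(d <= 0 for d in dims):
            raise ValueError("all dimensions must be positive")


@dataclass
class LatentTable:
    """Per-trajectory encoder outputs for one group of trajectories."""

    track_ids: np.ndarray
    latent: np.ndarray  # (n, latent_dim)
    alpha_pred: np.ndarray  # (n,)
    model_probs: np.ndarray  # (n, 5) in MODEL_ORDER
    lengths: np.ndarray  # (n,) trajectory point counts
    label: object = None
    latent2d: np.ndarray | None = None  # (n, 2), present once projected

    def __len__(self) -> int:
        return len(self.track_ids)

    def features(self, kind: str = "latent2d") -> np.ndarray:
        """Feature matrix for testing: '"latent2d"' or '"latent"' (16D)."""
        if kind == "latent2d":
            if self.latent2d is None:
                raise ValueError("2D projection not computed for this table")
            return self.latent2d
        if kind == "latent":
            return self.latent
        raise ValueError(f"unknown feature kind {kind!r}")

    def to_dataframe(self):
        import pandas as pd

        d = {"track_id": self.track_ids, "length": self.lengths,
             "alpha_pred": self.alpha_pred}
        for j in range(self.latent.shape[1]):
            d[f"latent_{j}"] = self.latent[:, j]
        if self.latent2d is not None:
            d["latent2d_x"] = self.latent2d[:, 0]
            d["latent2d_y"] = self.latent2d[:, 1]
        for j, m in enumerate(MODEL_ORDER):
            d[f"p_{m.value}"] = self.model_probs[:, j]
        return pd.DataFrame(d)


class _GraphBatch:
    """Concatenated graphs of a list of trajectories (PyG-style batching)."""

    def __init__(self, trajectories, k=10):
        node_feats, edge_feats, srcs, tgts, gidx, scales = [], [], [], [], [], []
        labels_model, labels_alpha, lengths, ids = [], [], [], []
        offset = 0
        self.skipped = []
        for t in trajectories:
            try:
                g = trajectory_to_graph(t, k=k)
            except DegenerateTrajectoryError:
                self.skipped.append(t.track_id)
                continue
            node_feats.append(g.node_features)
            edge_feats.append(g.edge_features)
            srcs.append(g.edges[:, 0] + offset)
            tgts.append(g.edges[:, 1] + offset)
            gidx.append(np.full(g.num_nodes, len(scales)))
            scales.append(g.scale)
            m = t.meta.get("model")
            labels_model.append(MODEL_TO_INDEX[ModelKind(m)] if m else -1)
            a = t.meta.get("alpha")
            labels_alpha.append(np.nan if a is None else float(a))
            lengths.append(len(t))
            ids.append(t.track_id)
            offset += g.num_nodes
        if not scales:
            raise ValueError("no valid trajectory in batch")
        self.x = np.vstack(node_feats)
        self.e = np.vstack(edge_feats)
        self.src = np.concatenate(srcs)
        self.tgt = np.concatenate(tgts)
        self.graph_idx = np.concatenate(gidx)
        self.scale = np.array(scales)[:, None]
        self.n_graphs = len(scales)
        self.n_nodes = offset
        self.y_model = np.array(labels_model)
        self.y_alpha = np.array(labels_alpha)
        self.lengths = np.array(lengths)
        self.track_ids = np.array(ids, dtype=object)


class EncoderModel:
    """The GRATIN-style encoder with its parameters and frozen projection."""

    def __init__(self, config: EncoderConfig, rng_seed: int = 0):
        self.config = config
        self.rng_seed = int(rng_seed)
        rng = np.random.default_rng(rng_seed)
        c = config
        self.node_embed = MLP([6, c.conv_channels, c.node_embed_dim], rng)
        self.edge_embed = MLP([6, c.conv_channels, c.edge_embed_dim], rng)
        self.convs = []
        d_in = c.node_embed_dim
        for _ in range(c.conv_layers):
            layer = {
                "edge_proj": Linear(c.edge_embed_dim, d_in, rng),
                "mlp": MLP([d_in, c.conv_channels, c.conv_channels], rng),
                "eps": Tensor(np.zeros((1, 1)), requires_grad=True),
                # per-layer normalization keeps message passing well scaled
                "ln_gamma": Tensor(np.ones((1, c.conv_channels)), requires_grad=True),
                "ln_beta": Tensor(np.zeros((1, c.conv_channels)), requires_grad=True),
            }
            self.convs.append(layer)
            d_in = c.conv_channels
        self.att_gate = Linear(c.conv_channels, 1, rng)
        self.att_value = Linear(c.conv_channels, c.conv_channels, rng)
        self.latent_mlp = MLP([c.conv_channels + 1, c.head_hidden[0], c.latent_dim], rng)
        self.alpha_head = MLP([c.latent_dim, *c.head_hidden, 1], rng)
        self.model_head = MLP([c.latent_dim, *c.head_hidden, len(MODEL_ORDER)], rng)
        # input standardization, frozen at first training exposure
        self.node_stats = None  # (mean, sd) for node features
        self.edge_stats = None
        self.scale_stats = None
        self.prior_snapshot = None
        self.trained = False
        self.projection = None  # optional frozen 16D -> 2D map

    # ---- parameters -----------------------------------------------------

    def named_parameters(self):
        out = {}
        for name, mod in (("node_embed", self.node_embed),
                          ("edge_embed", self.edge_embed),
                          ("latent_mlp", self.latent_mlp),
                          ("alpha_head", self.alpha_head),
                          ("model_head", self.model_head)):
            for i, p in enumerate(mod.parameters):
                out[f"{name}.{i}"] = p
        for li, layer in enumerate(self.convs):
            for i, p in enumerate(layer["edge_proj"].parameters):
                out[f"conv{li}.edge_proj.{i}"] = p
            for i, p in enumerate(layer["mlp"].parameters):
                out[f"conv{li}.mlp.{i}"] = p
            out[f"conv{li}.eps"] = layer["eps"]
            out[f"conv{li}.ln_gamma"] = layer["ln_gamma"]
            out[f"conv{li}.ln_beta"] = layer["ln_beta"]
        for i, p in enumerate(self.att_gate.parameters):
            out[f"att_gate.{i}"] = p
        for i, p in enumerate(self.att_value.parameters):
            out[f"att_value.{i}"] = p
        return out

    def parameters(self):
        return list(self.named_parameters().values())

    # ---- forward --------------------------------------------------------

    @staticmethod
    def _compress(x: np.ndarray, e: np.ndarray):
        """log1p-compress the heavy-tailed nonnegative feature columns.

        The cumulative power sums (and distances) have power-law tails; raw
        z-scoring leaves outliers tens of standard deviations out, which
        stalls optimization. Compression is part of the frozen input
        transform, applied identically at calibration, training and
        evaluation.
        """
        x = x.copy()
        e = e.copy()
        x[:, NODE_LOG_COLS] = np.log1p(np.maximum(x[:, NODE_LOG_COLS], 0.0))
        e[:, EDGE_LOG_COLS] = np.log1p(np.maximum(e[:, EDGE_LOG_COLS], 0.0))
        return x, e

    def _standardize(self, batch: _GraphBatch):
        if self.node_stats is None:
            raise RuntimeError("model not calibrated; train or load it first")
        x, e = self._compress(batch.x, batch.e)
        x = (x - self.node_stats[0]) / self.node_stats[1]
        e = (e - self.edge_stats[0]) / self.edge_stats[1]
        s = (batch.scale - self.scale_stats[0]) / self.scale_stats[1]
        return x, e, s

    def calibrate(self, batch: _GraphBatch):
        """Freeze input standardization statistics from a calibration batch."""
        eps = 1e-8
        x, e = self._compress(batch.x, batch.e)
        self.node_stats = (x.mean(0), x.std(0) + eps)
        self.edge_stats = (e.mean(0), e.std(0) + eps)
        self.scale_stats = (batch.scale.mean(0), batch.scale.std(0) + eps)

    def forward(self, batch: _GraphBatch):
        """Return (latent, alpha_pred, model_logits) Tensors for a batch."""
        xd, ed, sd = self._standardize(batch)
        # mean aggregation keeps activations at unit scale regardless of
        # in-degree; plain sums grow with the fan-in and saturate the
        # attention softmax before training starts
        deg = np.bincount(batch.tgt, minlength=batch.n_nodes).astype(float)
        inv_deg = Tensor((1.0 / np.maximum(deg, 1.0))[:, None])
        h = self.node_embed(Tensor(xd))
        e = self.edge_embed(Tensor(ed))
        for layer in self.convs:
            msg = relu(gather(h, batch.src) + layer["edge_proj"](e))
            agg = inv_deg * segment_sum(msg, batch.tgt, batch.n_nodes)
            h = layer_norm(layer["mlp"]((Tensor(1.0) + layer["eps"]) * h + agg),
                           layer["ln_gamma"], layer["ln_beta"])
        score = self.att_gate(h)
        attn = segment_softmax(score, batch.graph_idx, batch.n_graphs)
        pooled = segment_sum(attn * self.att_value(h), batch.graph_idx, batch.n_graphs)
        latent = self.latent_mlp(concat([pooled, Tensor(sd)], axis=1))
        alpha = self.alpha_head(latent)
        logits = self.model_head(latent)
        return latent, alpha, logits


def build_model(config: EncoderConfig | None = None, rng_seed: int | None = None) -> EncoderModel:
    """Construct an untrained encoder with seeded initial parameters."""
    config = config or EncoderConfig()
    seed = config.seed if rng_seed is None else rng_seed
    return EncoderModel(config, rng_seed=seed)


def train_encoder(
    model: EncoderModel,
    prior: SimulationPrior | None = None,
    config: EncoderConfig | None = None,
    verbose: bool = False,
):
    """Train the encoder on trajectories simulated on the fly from the prior.

    Streams ``config.n_train_trajectories`` fresh trajectories (uniform over
    the five models) in batches, minimising masked-alpha MSE plus model
    cross-entropy with Adam. Returns ``(model, log)`` where ``log`` is a list
    of per-batch loss records; the model is marked trained (frozen).
    """
    prior = prior or SimulationPrior()
    config = config or model.config
    rng = np.random.default_rng(config.seed + 1)
    mixture = MixtureSpec({m: 0.2 for m in MODEL_ORDER})

    def make_batch(n, seed):
        group = generate_dataset(mixture, n, prior, rng_seed=seed)
        return _GraphBatch(group.trajectories)

    if model.node_stats is None:
        model.calibrate(make_batch(min(2048, config.n_train_trajectories),
                                   rng.integers(2**31)))
    model.prior_snapshot = dataclasses.asdict(prior)
    model.prior_snapshot["alpha_ranges"] = {
        ModelKind(k).value: v for k, v in prior.alpha_ranges.items()
    }

    opt = Adam(model.parameters(), lr=config.learning_rate)
    log = []
    n_done = 0
    while n_done < config.n_train_trajectories:
        n_batch = min(config.batch_size, config.n_train_trajectories - n_done)
        batch = make_batch(n_batch, rng.integers(2**31))
        _, alpha, logits = model.forward(batch)
        mask = ~np.isnan(batch.y_alpha)
        target = np.where(mask, batch.y_alpha, 0.0)
        loss_alpha = masked_mse(alpha, target[:, None], mask[:, None])
        loss_model = softmax_cross_entropy(logits, batch.y_model)
        loss = loss_alpha + loss_model
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"training diverged at trajectory {n_done}: loss={loss.data}"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()
        log.append({"n_seen": n_done + n_batch,
                    "loss_alpha": float(loss_alpha.data),
                    "loss_model": float(loss_model.data),
                    "loss": float(loss.data)})
        n_done += n_batch
        if verbose and len(log) % 50 == 0:
            logger.info("trained on %d trajectories, loss %.4f", n_done, loss.data)
    model.trained = True
    return model, log


def encode(model: EncoderModel, group: TrajectoryGroup, batch_size: int = 1024) -> LatentTable:
    """Encode a trajectory group into its per-trajectory latent table.

    Deterministic in evaluation mode; degenerate trajectories (zero scale)
    are skipped with their ids logged. If the model carries a frozen 2D
    projection it is applied as well.
    """
    lat, alph, probs, lens, ids = [], [], [], [], []
    trajs = list(group)
    for start in range(0, len(trajs), batch_size):
        batch = _GraphBatch(trajs[start:start + batch_size])
        if batch.skipped:
            logger.warning("skipped degenerate trajectories: %s", batch.skipped)
        latent, alpha, logits = model.forward(batch)
        lat.append(latent.data)
        alph.append(alpha.data[:, 0])
        probs.append(softmax(logits.data))
        lens.append(batch.lengths)
        ids.append(batch.track_ids)
    table = LatentTable(
        track_ids=np.concatenate(ids),
        latent=np.vstack(lat),
        alpha_pred=np.concatenate(alph),
        model_probs=np.vstack(probs),
        lengths=np.concatenate(lens),
        label=group.label,
    )
    if model.projection is not None:
        table.latent2d = model.projection.transform(table.latent)
    return table


# ---- serialization -------------------------------------------------------


def save_model(model: EncoderModel, path) -> None:
    """Serialize the encoder (and any projection) to an .npz archive."""
    arrays = {f"param:{k}": p.data for k, p in model.named_parameters().items()}
    arrays["node_mean"], arrays["node_sd"] = model.node_stats
    arrays["edge_mean"], arrays["edge_sd"] = model.edge_stats
    arrays["scale_mean"], arrays["scale_sd"] = model.scale_stats
    meta = {
        "version": FORMAT_VERSION,
        "config": dataclasses.asdict(model.config),
        "rng_seed": model.rng_seed,
        "prior_snapshot": model.prior_snapshot,
        "trained": model.trained,
        "has_projection": model.projection is not None,
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    if model.projection is not None:
        for k, v in model.projection.state_arrays().items():
            arrays[f"proj:{k}"] = v
    np.savez(path, **arrays)


def load_model(path) -> EncoderModel:
    """Load an encoder saved by :func:`save_model` (bit-exact round trip)."""
    from .projection import ProjectionModel

    try:
        with np.load(path, allow_pickle=False) as npz:
            arrays = {k: npz[k] for k in npz.files}
    except Exception as exc:
        raise ValueError(f"not a valid encoder file: {path} ({exc})") from exc
    if "meta_json" not in arrays:
        raise ValueError(f"not a valid encoder file: {path} (no metadata)")
    meta = json.loads(bytes(arrays["meta_json"].tobytes()).decode())
    if meta.get("version") != FORMAT_VERSION:
        raise ValueError(
            f"encoder format version mismatch: file has {meta.get('version')!r}, "
            f"this build reads {FORMAT_VERSION!r}"
        )
    cfg = EncoderConfig(**{k: tuple(v) if k == "head_hidden" else v
                           for k, v in meta["config"].items()})
    model = EncoderModel(cfg, rng_seed=meta["rng_seed"])
    params = model.named_parameters()
    for name, p in params.items():
        key = f"param:{name}"
        if key not in arrays:
            raise ValueError(f"corrupted encoder file: missing {key}")
        p.data = arrays[key]
    model.node_stats = (arrays["node_mean"], arrays["node_sd"])
    model.edge_stats = (arrays["edge_mean"], arrays["edge_sd"])
    model.scale_stats = (arrays["scale_mean"], arrays["scale_sd"])
    model.prior_snapshot = meta["prior_snapshot"]
    model.trained = meta["trained"]
    if meta.get("has_projection"):
        proj_arrays = {k[5:]: v for k, v in arrays.items() if k.startswith("proj:")}
        model.projection = ProjectionModel.from_state_arrays(proj_arrays)
    return model
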