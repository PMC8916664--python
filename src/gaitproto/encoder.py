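"""Multimodal prototyping encoder-decoder and its training loop.

The encoder f maps a unit step s = [s_pre, s_acc, s_rot] to a unit-norm
128-dimensional embedding v: three parallel sub-encoders (1-D convolutions
with 32, 64 and 128 filters, independently parameterized per modality)
feed a shared dense 256 layer and a dense 128 output, followed by L2
normalization.  The decoder g mirrors the encoder: dense 256, per-modality
dense heads, three transposed convolutions (128, 64, 32 filters) and a
channel projection, each modality block L2-normalized.

Training minimizes  L = L_triplet + lambda * L_proto:

* the multimodal triplet loss max(0, ||v_a - v_p||^2 - ||v_a - v_n||^2 + alpha)
  pulls same-subject embeddings together and pushes different-subject
  embeddings apart by a margin alpha;
* the prototyping loss is the mean over the 28 channels of the squared L2
  distance between the (per-channel unit-normalized) reconstruction and
  the subject's per-channel unit-normalized prototype, which regularizes
  the embedding against large within-subject step variation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .gait_signal import Prototype, UnitStep
from .layout import BLOCKS, N_CHANNELS


@dataclass
class EncoderConfig:
    conv_filters: tuple[int, int, int] = (32, 64, 128)
    dense_widths: tuple[int, int] = (256, 128)
    embedding_dim: int = 128
    kernel_size: int = 5
    stride: int = 2
    activation: str = "relu"
    alpha: float = 1.25
    lam: float = 1.0
    learning_rate: float = 1e-3
    epochs: int = 3
    batch_size: int = 64
    anchors_per_epoch: int | None = 1024
    T: int = 100
    seed: int = 0
    dtype: str = "float32"
    use_bias: bool = True

    def __post_init__(self) -> None:
        if tuple(self.conv_filters) != (32, 64, 128):
            raise ValueError("conv filter counts are fixed at (32, 64, 128)")
        if tuple(self.dense_widths) != (256, 128):
            raise ValueError("dense widths are fixed at (256, 128)")
        if self.embedding_dim != 128:
            raise ValueError("embedding dimension is fixed at 128")
        if self.alpha < 0 or self.lam < 0:
            raise ValueError("alpha and lambda must be non-negative")
        if self.activation != "relu":
            raise ValueError("only relu activation is supported")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


def conv_lengths(T: int, kernel: int, stride: int, n_layers: int = 3) -> list[int]:
    """Row counts after each 'same'-padded strided convolution, input first."""
    lengths = [T]
    for _ in range(n_layers):
        lengths.append(nn.same_pad(lengths[-1], kernel, stride)[2])
    return lengths


class Encoder:
    """f: (B, T, 28) unit steps -> (B, 128) unit-norm embeddings."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator) -> None:
        self.config = config
        k, s = config.kernel_size, config.stride
        dtype = config.np_dtype
        f1, f2, f3 = config.conv_filters
        self.lengths = conv_lengths(config.T, k, s)
        self.flat_width = self.lengths[-1] * f3
        bias = config.use_bias
        self.subs: list[list[nn.Layer]] = []
        for _, _, width in BLOCKS:
            self.subs.append([
                nn.Conv1d(width, f1, k, s, rng, bias=bias, dtype=dtype), nn.ReLU(),
                nn.Conv1d(f1, f2, k, s, rng, bias=bias, dtype=dtype), nn.ReLU(),
                nn.Conv1d(f2, f3, k, s, rng, bias=bias, dtype=dtype), nn.ReLU(),
            ])
        d1, d2 = config.dense_widths
        self.dense1 = nn.Dense(3 * self.flat_width, d1, rng, bias=bias, dtype=dtype)
        self.relu1 = nn.ReLU()
        self.dense2 = nn.Dense(d1, d2, rng, scale=np.sqrt(1.0 / d1), bias=bias,
                               dtype=dtype)
        self.norm = nn.L2Normalize()

    # -- plumbing ----------------------------------------------------------
    def named_layers(self) -> list[tuple[str, nn.Layer]]:
        out = []
        for (name, _, _), layers in zip(BLOCKS, self.subs):
            for i, layer in enumerate(layers):
                out.append((f"enc.{name}.{i}", layer))
        out += [("enc.dense1", self.dense1), ("enc.relu1", self.relu1),
                ("enc.dense2", self.dense2)]
        return out

    def params(self):
        return [p for _, l in self.named_layers() for p in l.params()]

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != self.config.T or x.shape[2] != N_CHANNELS:
            raise ValueError(
                f"expected input of shape (B, {self.config.T}, {N_CHANNELS}), "
                f"got {x.shape}"
            )
        x = x.astype(self.config.np_dtype, copy=False)
        feats = []
        B = x.shape[0]
        for (_, sl, _), layers in zip(BLOCKS, self.subs):
            h = np.ascontiguousarray(x[:, :, sl])
            for layer in layers:
                h = layer.forward(h)
            feats.append(h.reshape(B, -1))
        h = np.concatenate(feats, axis=1)
        h = self.relu1.forward(self.dense1.forward(h))
        self.pre_norm = self.dense2.forward(h)
        return self.norm.forward(self.pre_norm)

    def backward(self, gv: np.ndarray) -> np.ndarray:
        g = self.norm.backward(gv.astype(self.config.np_dtype, copy=False))
        g = self.dense2.backward(g)
        g = self.dense1.backward(self.relu1.backward(g))
        B = g.shape[0]
        gx = np.zeros((B, self.config.T, N_CHANNELS), dtype=g.dtype)
        L3 = self.lengths[-1]
        f3 = self.config.conv_filters[-1]
        for bi, ((_, sl, _), layers) in enumerate(zip(BLOCKS, self.subs)):
            gb = g[:, bi * self.flat_width : (bi + 1) * self.flat_width]
            h = gb.reshape(B, L3, f3)
            for layer in reversed(layers):
                h = layer.backward(h)
            gx[:, :, sl] = h
        return gx

    def lrp(self, R: np.ndarray, eps: float) -> np.ndarray:
        """Redistribute relevance R at the dense-128 output back to the input.

        The final L2 normalization carries no weighted connections, so
        relevance starts at the pre-normalization dense-128 layer.
        """
        R = self.dense2.lrp(R, eps)
        R = self.dense1.lrp(self.relu1.lrp(R, eps), eps)
        B = R.shape[0]
        out = np.zeros((B, self.config.T, N_CHANNELS), dtype=R.dtype)
        L3 = self.lengths[-1]
        f3 = self.config.conv_filters[-1]
        for bi, ((_, sl, _), layers) in enumerate(zip(BLOCKS, self.subs)):
            r = R[:, bi * self.flat_width : (bi + 1) * self.flat_width]
            r = r.reshape(B, L3, f3)
            for layer in reversed(layers):
                r = layer.lrp(r, eps)
            out[:, :, sl] = r
        return out

    def encode(self, steps: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Embed an (N, T, 28) stack of unit steps in batches."""
        outs = [
            self.forward(steps[i : i + batch_size])
            for i in range(0, steps.shape[0], batch_size)
        ]
        return np.concatenate(outs, axis=0)


class Decoder:
    """g: (B, 128) embeddings -> per-modality reconstructions, block-normalized."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator) -> None:
        self.config = config
        k, s = config.kernel_size, config.stride
        dtype = config.np_dtype
        f1, f2, f3 = config.conv_filters  # 32, 64, 128
        d1, d2 = config.dense_widths      # 256, 128
        lengths = conv_lengths(config.T, k, s)
        T, L1, L2, L3 = lengths
        self.L3, self.f3 = L3, f3
        self.flat_width = L3 * f3
        bias = config.use_bias
        self.dense1 = nn.Dense(config.embedding_dim, d1, rng, bias=bias, dtype=dtype)
        self.relu1 = nn.ReLU()
        self.heads: list[nn.Dense] = []
        self.subs: list[list[nn.Layer]] = []
        self.norms: list[nn.BlockL2Normalize] = []
        for _, _, width in BLOCKS:
            self.heads.append(nn.Dense(d1, self.flat_width, rng, bias=bias, dtype=dtype))
            self.subs.append([
                nn.ReLU(),
                nn.ConvTranspose1d(f3, f3, k, s, L3, L2, rng, bias=bias,
                                   dtype=dtype), nn.ReLU(),
                nn.ConvTranspose1d(f3, f2, k, s, L2, L1, rng, bias=bias,
                                   dtype=dtype), nn.ReLU(),
                nn.ConvTranspose1d(f2, f1, k, s, L1, T, rng, bias=bias,
                                   dtype=dtype), nn.ReLU(),
                nn.Conv1d(f1, width, 1, 1, rng, bias=bias, dtype=dtype),
            ])
            self.norms.append(nn.BlockL2Normalize())

    def named_layers(self) -> list[tuple[str, nn.Layer]]:
        out = [("dec.dense1", self.dense1)]
        for (name, _, _), head, layers in zip(BLOCKS, self.heads, self.subs):
            out.append((f"dec.head.{name}", head))
            for i, layer in enumerate(layers):
                out.append((f"dec.{name}.{i}", layer))
        return out

    def params(self):
        return [p for _, l in self.named_layers() for p in l.params()]

    def forward(self, v: np.ndarray) -> np.ndarray:
        if v.ndim != 2 or v.shape[1] != self.config.embedding_dim:
            raise ValueError(
                f"expected embeddings of shape (B, {self.config.embedding_dim}), "
                f"got {v.shape}"
            )
        v = v.astype(self.config.np_dtype, copy=False)
        h0 = self.relu1.forward(self.dense1.forward(v))
        B = v.shape[0]
        out = np.zeros((B, self.config.T, N_CHANNELS), dtype=v.dtype)
        for (_, sl, _), head, layers, norm in zip(
            BLOCKS, self.heads, self.subs, self.norms
        ):
            h = head.forward(h0).reshape(B, self.L3, self.f3)
            for layer in layers:
                h = layer.forward(h)
            out[:, :, sl] = norm.forward(h)
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B = gy.shape[0]
        gh0 = np.zeros((B, self.config.dense_widths[0]), dtype=self.config.np_dtype)
        for (_, sl, _), head, layers, norm in zip(
            BLOCKS, self.heads, self.subs, self.norms
        ):
            g = norm.backward(np.ascontiguousarray(
                gy[:, :, sl]).astype(self.config.np_dtype, copy=False))
            for layer in reversed(layers):
                g = layer.backward(g)
            gh0 += head.backward(g.reshape(B, -1))
        return self.dense1.backward(self.relu1.backward(gh0))


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def triplet_loss(v_anchor: np.ndarray, v_pos: np.ndarray, v_neg: np.ndarray,
                 alpha: float) -> float:
    """Hinged multimodal triplet loss for a single (anchor, pos, neg)."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    d_ap = float(np.sum((np.asarray(v_anchor) - np.asarray(v_pos)) ** 2))
    d_an = float(np.sum((np.asarray(v_anchor) - np.asarray(v_neg)) ** 2))
    return max(0.0, d_ap - d_an + alpha)


def _triplet_batch(va, vp, vn, alpha):
    """Per-row hinged losses and gradients w.r.t. each embedding."""
    diff_ap = va - vp
    diff_an = va - vn
    raw = (diff_ap ** 2).sum(axis=1) - (diff_an ** 2).sum(axis=1) + alpha
    active = (raw > 0.0).astype(va.dtype)[:, None]
    losses = np.maximum(raw, 0.0)
    gva = 2.0 * (vn - vp) * active
    gvp = -2.0 * diff_ap * active
    gvn = 2.0 * diff_an * active
    return losses, gva, gvp, gvn


def _normalize_channels(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-normalize each (sample, channel) time series of a (B, T, C) array."""
    norms = np.sqrt((x * x).sum(axis=1, keepdims=True))
    if np.any(norms == 0.0):
        raise ZeroDivisionError("zero-norm channel encountered during normalization")
    return x / norms, norms


def _proto_batch(recon: np.ndarray, protos: np.ndarray):
    """Per-sample prototyping losses and gradient w.r.t. the reconstruction.

    Both reconstruction and prototype are normalized per channel (length-T
    unit vectors) before the squared distance; the loss is the mean over
    the 28 channels.
    """
    r_hat, r_norm = _normalize_channels(recon)
    p_hat, _ = _normalize_channels(protos)
    diff = r_hat - p_hat
    losses = (diff ** 2).sum(axis=1).mean(axis=1)
    g_hat = 2.0 * diff / recon.shape[2]
    inner = (r_hat * g_hat).sum(axis=1, keepdims=True)
    g = (g_hat - r_hat * inner) / r_norm
    return losses, g


def prototype_loss(step: UnitStep, prototype: Prototype, encoder: Encoder,
                   decoder: Decoder) -> float:
    """Prototyping loss of a single unit step against its subject prototype."""
    recon = decoder.forward(encoder.forward(step.data[None]))
    losses, _ = _proto_batch(recon, prototype.data[None].astype(recon.dtype))
    return float(losses[0])


def reconstruction_loss(recon: np.ndarray, prototype: np.ndarray) -> float:
    """Prototyping loss from an already-computed (T, 28) reconstruction."""
    losses, _ = _proto_batch(recon[None].astype(float), prototype[None].astype(float))
    return float(losses[0])


def combined_loss(triplet_term: float, proto_term: float, lam: float) -> float:
    """L = L_triplet + lambda * L_proto."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    return triplet_term + lam * proto_term


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    encoder: Encoder
    decoder: Decoder
    config: EncoderConfig
    history: list[dict] = field(default_factory=list)

    def embed(self, steps: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.encoder.encode(steps, batch_size)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for name, layer in self.encoder.named_layers() + self.decoder.named_layers():
            for key, val in layer.state().items():
                arrays[f"{name}.{key}"] = val
        np.savez(path, **arrays)
        sidecar = path.with_suffix(".json")
        cfg = asdict(self.config)
        cfg["history"] = self.history
        sidecar.write_text(json.dumps(cfg, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        history = meta.pop("history", [])
        for key in ("conv_filters", "dense_widths"):
            meta[key] = tuple(meta[key])
        config = EncoderConfig(**meta)
        rng = np.random.default_rng(0)
        model = cls(Encoder(config, rng), Decoder(config, rng), config, history)
        npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
        with np.load(npz_path) as data:
            for name, layer in (model.encoder.named_layers()
                                + model.decoder.named_layers()):
                state = {
                    key: data[f"{name}.{key}"]
                    for key in layer.state()
                    if f"{name}.{key}" in data
                }
                layer.load_state(state)
        return model


def _subject_prototypes(train: dict[int, np.ndarray]) -> dict[int, np.ndarray]:
    return {a: arr.mean(axis=0) for a, arr in train.items()}


def train(train_steps: dict[int, np.ndarray], config: EncoderConfig) -> TrainedModel:
    """Train encoder and decoder on a {subject: (n, T, 28)} training split.

    Triplets are sampled uniformly: every training step serves as anchor
    (at most ``anchors_per_epoch`` per epoch), its positive is a different
    step of the same subject and its negative a random step of a random
    other subject.  Per-subject prototypes are precomputed once from the
    training split.  Deterministic given ``config.seed``.
    """
    subjects = sorted(train_steps)
    if len(subjects) < 2:
        raise ValueError("training requires at least 2 subjects to form negatives")
    for a in subjects:
        if train_steps[a].shape[0] < 2:
            raise ValueError(f"subject {a} has fewer than 2 steps; cannot form positives")
    dtype = config.np_dtype
    rng = np.random.default_rng(config.seed)
    encoder = Encoder(config, rng)
    decoder = Decoder(config, rng)
    protos = _subject_prototypes(train_steps)
    params = encoder.params() + decoder.params()
    opt = nn.Adam(params, lr=config.learning_rate)

    index = [(a, i) for a in subjects for i in range(train_steps[a].shape[0])]
    index = np.array(index)
    history: list[dict] = []
    B = config.batch_size
    for epoch in range(config.epochs):
        order = rng.permutation(len(index))
        if config.anchors_per_epoch is not None:
            order = order[: config.anchors_per_epoch]
        ep_trip, ep_proto, n_seen = 0.0, 0.0, 0
        for start in range(0, len(order), B):
            batch = index[order[start : start + B]]
            nb = len(batch)
            anchors = np.empty((nb, config.T, N_CHANNELS), dtype=dtype)
            positives = np.empty_like(anchors)
            negatives = np.empty_like(anchors)
            proto_batch = np.empty_like(anchors)
            for row, (a, i) in enumerate(batch):
                steps_a = train_steps[a]
                j = rng.integers(steps_a.shape[0] - 1)
                j = j + (j >= i)  # uniform over same-subject steps != i
                b = subjects[rng.integers(len(subjects) - 1)]
                if b == a:
                    b = subjects[-1]
                k = rng.integers(train_steps[b].shape[0])
                anchors[row] = steps_a[i]
                positives[row] = steps_a[j]
                negatives[row] = train_steps[b][k]
                proto_batch[row] = protos[a]
            X = np.concatenate([anchors, positives, negatives], axis=0)
            V = encoder.forward(X)
            va, vp, vn = V[:nb], V[nb : 2 * nb], V[2 * nb :]
            t_losses, gva, gvp, gvn = _triplet_batch(va, vp, vn, config.alpha)
            gV = np.concatenate([gva, gvp, gvn], axis=0) / nb
            p_mean = 0.0
            if config.lam > 0:
                recon = decoder.forward(va)
                p_losses, g_recon = _proto_batch(recon, proto_batch)
                p_mean = float(p_losses.mean())
                gva_proto = decoder.backward(g_recon * (config.lam / nb))
                gV[:nb] += gva_proto
            encoder.backward(gV)
            opt.step()
            opt.zero_grad()
            ep_trip += float(t_losses.sum())
            ep_proto += p_mean * nb
            n_seen += nb
        history.append({
            "epoch": epoch,
            "triplet": ep_trip / n_seen,
            "proto": ep_proto / n_seen,
            "total": ep_trip / n_seen + config.lam * (ep_proto / n_seen),
        })
    return TrainedModel(encoder, decoder, config, history)
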