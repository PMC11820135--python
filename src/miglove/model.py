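"""Transformer decoder for motor-imagery EEG spectra, with focal loss.

The classifier maps a per-epoch magnitude spectrum of shape (44 frequency
bins x 16 channels) to probabilities over {rest, fist}.  The 44 bins play
the role of sequence positions: a fixed sinusoidal positional encoding is
added, two self-attention encoder blocks follow, then global average
pooling over the bin axis and a small dense head.

The default layer graph is reproduced literally from the reference
architecture summary, including its asymmetry: the second encoder block has
no feed-forward sub-layer and no trailing layer normalization (attention ->
dropout -> residual add -> pooling).  ``ModelConfig.symmetric_blocks``
restores a conventional symmetric second block.  Per-layer parameter
counts under the default configuration:

====================  ======
multi_head_attention  17,168
dense (16->128)        2,176
dense_1 (128->16)      2,064
layer norms (x2)       32 each
multi_head_attention_2 17,168
dense_2 (16->128)      2,176
batch_normalization      512
layer_normalization_3    256
dense_3 (128->64)      8,256
batch_normalization_2    256
layer_normalization_4    128
dense_4 (64->2)          130
====================  ======

Training minimizes focal loss ``FL = -alpha_c (1 - p_c)^gamma log p_c``
(gamma 2, alpha proportional to inverse class frequency), which
down-weights easy examples so the minority "fist" class stays represented.
Class indices: 0 = rest, 1 = fist.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .preprocessing import EpochSet
from .spectral import N_BINS, SpectralFeature, featurize_epochs

__all__ = [
    "CLASSES", "ModelConfig", "FocalLossParams", "TrainingSchedule",
    "MIDecoder", "positional_encoding", "focal_loss", "build_model",
    "train", "save_checkpoint", "load_checkpoint",
]

#: Class index convention: decode_intent returns 1 when the subject intends
#: to close the hand.
CLASSES = ("rest", "fist")


def positional_encoding(seq_len: int, dim: int) -> np.ndarray:
    """Fixed sinusoidal positional encoding, shape ``(seq_len, dim)``.

    ``PE[pos, 2i] = sin(pos / 10000^(2i/dim))`` and
    ``PE[pos, 2i+1] = cos(pos / 10000^(2i/dim))``.
    """
    if dim % 2 != 0:
        raise ValueError("positional encoding dimension must be even")
    pos = np.arange(seq_len)[:, None]
    i = np.arange(dim // 2)[None, :]
    angle = pos / np.power(10000.0, 2 * i / dim)
    pe = np.empty((seq_len, dim))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


@dataclass(frozen=True)
class ModelConfig:
    seq_len: int = N_BINS
    embed_dim: int = 16
    n_heads: int = 4
    head_size: int = 64
    ffn_units: int = 128
    n_encoder_blocks: int = 2
    dropout_attention: float = 0.1
    dropout_ffn: float = 0.1
    dropout_head: float = 0.3
    head_units: tuple[int, ...] = (128, 64)
    n_classes: int = 2
    #: False reproduces the reference summary literally (second block has no
    #: feed-forward sub-layer); True builds symmetric encoder blocks.
    symmetric_blocks: bool = False
    #: Per-epoch z-normalization of the feature matrix across bins.
    normalize: bool = True


@dataclass(frozen=True)
class FocalLossParams:
    """gamma = 0 with unit alphas reduces the loss to cross-entropy."""

    gamma: float = 2.0
    alpha: tuple[float, ...] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if any(a <= 0 for a in self.alpha):
            raise ValueError("alpha entries must be positive")


@dataclass(frozen=True)
class TrainingSchedule:
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10        # early stopping on validation loss
    min_delta: float = 1e-4


def focal_loss(probabilities: np.ndarray, true_class: np.ndarray | int,
               params: FocalLossParams = FocalLossParams(),
               eps: float = 1e-7) -> float:
    """Mean focal loss of a batch (or a single example).

    ``FL = -alpha_c (1 - p_c)^gamma log p_c`` with ``p_c`` the probability
    assigned to the true class, clipped away from 0 and 1.
    """
    p = np.atleast_2d(np.asarray(probabilities, dtype=np.float64))
    y = np.atleast_1d(np.asarray(true_class, dtype=np.int64))
    if p.shape[0] != y.shape[0]:
        raise ValueError("one true class per probability row required")
    if np.any(p < -1e-9) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probabilities must be valid simplex points")
    alpha = np.asarray(params.alpha, dtype=np.float64)
    pc = np.clip(p[np.arange(len(y)), y], eps, 1.0 - eps)
    losses = -alpha[y] * (1.0 - pc) ** params.gamma * np.log(pc)
    # exact zero when the clip was the only thing keeping log(p) finite
    losses[p[np.arange(len(y)), y] >= 1.0] = 0.0
    return float(losses.mean())


def _focal_grad_wrt_logits(p: np.ndarray, y: np.ndarray,
                           params: FocalLossParams,
                           eps: float = 1e-7) -> np.ndarray:
    """d(mean FL)/d logits through the softmax, shape of ``p``."""
    n = p.shape[0]
    alpha = np.asarray(params.alpha, dtype=np.float64)
    pc = np.clip(p[np.arange(n), y], eps, 1.0 - eps)
    g = params.gamma
    # dL/dp_c
    dl_dpc = alpha[y] * (g * (1.0 - pc) ** (g - 1) * np.log(pc)
                         - (1.0 - pc) ** g / pc)
    # chain through softmax: dp_c/dz_j = p_c (delta_jc - p_j)
    onehot = np.zeros_like(p)
    onehot[np.arange(n), y] = 1.0
    return (dl_dpc * pc)[:, None] * (onehot - p) / n


class MIDecoder:
    """The trained (or trainable) motor-imagery classifier."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        self.classes = CLASSES[: config.n_classes]
        self.trained = False
        self.history: dict[str, list[float]] = {}
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(seed).spawn(1)[0])
        c = config
        self.pe = positional_encoding(c.seq_len, c.embed_dim)
        self.layers: dict[str, nn.Layer] = {}

        def add(name, layer):
            self.layers[name] = layer
            return layer

        add("multi_head_attention",
            nn.MultiHeadAttention(c.embed_dim, c.n_heads, c.head_size, rng))
        add("dropout_1", nn.Dropout(c.dropout_attention, self._dropout_rng))
        add("layer_normalization", nn.LayerNorm(c.embed_dim))
        add("dense", nn.Dense(c.embed_dim, c.ffn_units, rng))
        add("relu_ffn", nn.ReLU())
        add("dropout_2", nn.Dropout(c.dropout_ffn, self._dropout_rng))
        add("dense_1", nn.Dense(c.ffn_units, c.embed_dim, rng))
        add("layer_normalization_2", nn.LayerNorm(c.embed_dim))
        add("multi_head_attention_2",
            nn.MultiHeadAttention(c.embed_dim, c.n_heads, c.head_size, rng))
        add("dropout_3", nn.Dropout(c.dropout_attention, self._dropout_rng))
        if c.symmetric_blocks:
            add("layer_normalization_2b", nn.LayerNorm(c.embed_dim))
            add("dense_b", nn.Dense(c.embed_dim, c.ffn_units, rng))
            add("relu_ffn_b", nn.ReLU())
            add("dropout_2b", nn.Dropout(c.dropout_ffn, self._dropout_rng))
            add("dense_1b", nn.Dense(c.ffn_units, c.embed_dim, rng))
            add("layer_normalization_2c", nn.LayerNorm(c.embed_dim))
        add("dense_2", nn.Dense(c.embed_dim, c.head_units[0], rng))
        add("relu_head_1", nn.ReLU())
        add("batch_normalization", nn.BatchNorm(c.head_units[0]))
        add("dropout_4", nn.Dropout(c.dropout_head, self._dropout_rng))
        add("layer_normalization_3", nn.LayerNorm(c.head_units[0]))
        add("dense_3", nn.Dense(c.head_units[0], c.head_units[1], rng))
        add("relu_head_2", nn.ReLU())
        add("batch_normalization_2", nn.BatchNorm(c.head_units[1]))
        add("dropout_5", nn.Dropout(c.dropout_head, self._dropout_rng))
        add("layer_normalization_4", nn.LayerNorm(c.head_units[1]))
        add("dense_4", nn.Dense(c.head_units[1], c.n_classes, rng))

    # -- forward / backward -------------------------------------------------

    def _prepare(self, features: np.ndarray) -> np.ndarray:
        """Stack and (optionally) z-normalize feature matrices across bins."""
        x = np.asarray(features, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != (self.config.seq_len, self.config.embed_dim):
            raise ValueError(
                f"expected features of shape ({self.config.seq_len}, "
                f"{self.config.embed_dim}), got {x.shape[1:]}"
            )
        if self.config.normalize:
            mu = x.mean(axis=1, keepdims=True)
            sd = x.std(axis=1, keepdims=True)
            x = (x - mu) / np.where(sd > 0, sd, 1.0)
        return x

    def _forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        L = self.layers
        self._seq = []  # (layer, residual-source bookkeeping) for backward

        x0 = x + self.pe[None]
        a = L["dropout_1"].forward(
            L["multi_head_attention"].forward(x0, training), training)
        r1 = a + x0
        n1 = L["layer_normalization"].forward(r1, training)
        f = L["dropout_2"].forward(
            L["relu_ffn"].forward(
                L["dense"].forward(n1, training), training), training)
        f2 = L["dense_1"].forward(f, training)
        n2 = L["layer_normalization_2"].forward(f2 + n1, training)
        a2 = L["dropout_3"].forward(
            L["multi_head_attention_2"].forward(n2, training), training)
        h = a2 + n2
        if self.config.symmetric_blocks:
            n2b = L["layer_normalization_2b"].forward(h, training)
            fb = L["dropout_2b"].forward(
                L["relu_ffn_b"].forward(
                    L["dense_b"].forward(n2b, training), training), training)
            f2b = L["dense_1b"].forward(fb, training)
            h = L["layer_normalization_2c"].forward(f2b + n2b, training)
        pooled = h.mean(axis=1)                       # global average pooling
        self._pool_len = h.shape[1]
        z = L["dense_2"].forward(pooled, training)
        z = L["relu_head_1"].forward(z, training)
        z = L["batch_normalization"].forward(z, training)
        z = L["dropout_4"].forward(z, training)
        z = L["layer_normalization_3"].forward(z, training)
        z = L["dense_3"].forward(z, training)
        z = L["relu_head_2"].forward(z, training)
        z = L["batch_normalization_2"].forward(z, training)
        z = L["dropout_5"].forward(z, training)
        z = L["layer_normalization_4"].forward(z, training)
        return L["dense_4"].forward(z, training)

    def _backward(self, g_logits: np.ndarray) -> None:
        L = self.layers
        g = L["dense_4"].backward(g_logits)
        g = L["layer_normalization_4"].backward(g)
        g = L["dropout_5"].backward(g)
        g = L["batch_normalization_2"].backward(g)
        g = L["relu_head_2"].backward(g)
        g = L["dense_3"].backward(g)
        g = L["layer_normalization_3"].backward(g)
        g = L["dropout_4"].backward(g)
        g = L["batch_normalization"].backward(g)
        g = L["relu_head_1"].backward(g)
        g = L["dense_2"].backward(g)
        g = np.repeat(g[:, None, :], self._pool_len, axis=1) / self._pool_len
        if self.config.symmetric_blocks:
            g = L["layer_normalization_2c"].backward(g)
            g_res = g
            gb = L["dense_1b"].backward(g)
            gb = L["dropout_2b"].backward(gb)
            gb = L["relu_ffn_b"].backward(gb)
            gb = L["dense_b"].backward(gb)
            g = L["layer_normalization_2b"].backward(gb + g_res)
        g_h = g
        g_a2 = L["dropout_3"].backward(g_h)
        g_n2 = L["multi_head_attention_2"].backward(g_a2) + g_h
        g_r2 = L["layer_normalization_2"].backward(g_n2)
        g_f = L["dense_1"].backward(g_r2)
        g_f = L["dropout_2"].backward(g_f)
        g_f = L["relu_ffn"].backward(g_f)
        g_n1 = L["dense"].backward(g_f) + g_r2
        g_r1 = L["layer_normalization"].backward(g_n1)
        g_a = L["dropout_1"].backward(g_r1)
        # residual: x0 feeds both the attention input and the add
        _ = L["multi_head_attention"].backward(g_a)

    # -- public API ---------------------------------------------------------

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Class probabilities, rows summing to 1; order ``(rest, fist)``."""
        x = self._prepare(features)
        logits = self._forward(x, training=False)
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def count_params(self, layer_name: str | None = None) -> int:
        if layer_name is None:
            return sum(l.n_params() for l in self.layers.values())
        if layer_name not in self.layers:
            raise KeyError(
                f"unknown layer {layer_name!r}; known: {sorted(self.layers)}"
            )
        return self.layers[layer_name].n_params()

    def zero_grad(self) -> None:
        for l in self.layers.values():
            l.zero_grad()

    def get_weights(self) -> dict[str, dict[str, np.ndarray]]:
        out = {}
        for name, l in self.layers.items():
            d = {k: v.copy() for k, v in l.params.items()}
            if isinstance(l, nn.BatchNorm):
                d.update({f"running_{k}": v.copy()
                          for k, v in l.running.items()})
            if d:
                out[name] = d
        return out

    def set_weights(self, weights: dict[str, dict[str, np.ndarray]]) -> None:
        for name, d in weights.items():
            l = self.layers[name]
            for k, v in d.items():
                if k.startswith("running_"):
                    l.running[k[len("running_"):]] = v.copy()
                else:
                    l.params[k] = v.copy()


def build_model(config: ModelConfig | None = None, seed: int = 0) -> MIDecoder:
    """Construct an untrained decoder with the default architecture."""
    return MIDecoder(config or ModelConfig(), seed=seed)


def _labels_to_indices(labels: Sequence[str]) -> np.ndarray:
    idx = {c: i for i, c in enumerate(CLASSES)}
    try:
        return np.array([idx[l] for l in labels], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unknown class label {exc}; expected {CLASSES}")


def inverse_frequency_alpha(labels: Sequence[str]) -> tuple[float, ...]:
    """Focal-loss class weights proportional to inverse class frequency,
    normalized to mean 1 over the classes present."""
    y = _labels_to_indices(labels)
    counts = np.bincount(y, minlength=len(CLASSES)).astype(float)
    counts[counts == 0] = np.nan
    inv = len(y) / counts
    inv = inv / np.nanmean(inv)
    return tuple(float(a) if np.isfinite(a) else 1.0 for a in inv)


def train(decoder: MIDecoder, train_epochs: EpochSet, val_epochs: EpochSet,
          loss: FocalLossParams | None = None,
          schedule: TrainingSchedule | None = None,
          seed: int = 0) -> MIDecoder:
    """Train in place with Adam, early stopping on validation focal loss.

    Deterministic for fixed seeds and data (single-threaded NumPy).  The
    per-epoch history lands in ``decoder.history``.
    """
    schedule = schedule or TrainingSchedule()
    y_train = _labels_to_indices(train_epochs.labels)
    y_val = _labels_to_indices(val_epochs.labels)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data contains a single class")
    if loss is None:
        loss = FocalLossParams(gamma=2.0,
                               alpha=inverse_frequency_alpha(train_epochs.labels))
    x_train = decoder._prepare(featurize_epochs(train_epochs))
    x_val = decoder._prepare(featurize_epochs(val_epochs))

    rng = np.random.default_rng(seed)
    opt = nn.Adam(list(decoder.layers.values()), lr=schedule.learning_rate)
    history = {"train_loss": [], "val_loss": [], "val_accuracy": []}
    best_val = np.inf
    best_weights = decoder.get_weights()
    wait = 0
    n = len(y_train)
    for _epoch in range(schedule.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, schedule.batch_size):
            batch = order[start:start + schedule.batch_size]
            xb, yb = x_train[batch], y_train[batch]
            decoder.zero_grad()
            logits = decoder._forward(xb, training=True)
            z = logits - logits.max(axis=-1, keepdims=True)
            e = np.exp(z)
            p = e / e.sum(axis=-1, keepdims=True)
            losses.append(focal_loss(p, yb, loss))
            decoder._backward(_focal_grad_wrt_logits(p, yb, loss))
            opt.step()
        p_val = decoder.predict_proba(x_val)
        val_loss = focal_loss(p_val, y_val, loss)
        val_acc = float((p_val.argmax(axis=1) == y_val).mean())
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)
        if val_loss < best_val - schedule.min_delta:
            best_val = val_loss
            best_weights = decoder.get_weights()
            wait = 0
        else:
            wait += 1
            if wait >= schedule.patience:
                break
    decoder.set_weights(best_weights)
    decoder.trained = True
    decoder.history = history
    return decoder


def decode_intent(decoder: MIDecoder,
                  feature: SpectralFeature | np.ndarray,
                  threshold: float = 0.5) -> tuple[int, np.ndarray]:
    """Map one spectral feature to the intent bit ``s_t``.

    Returns ``(s_t, probabilities)`` with ``s_t = 1`` (close hand) iff
    ``P(fist) >= threshold``; an exact tie therefore decodes as fist.
    """
    values = feature.values if isinstance(feature, SpectralFeature) else feature
    p = decoder.predict_proba(values)[0]
    s_t = int(p[CLASSES.index("fist")] >= threshold)
    return s_t, p


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(decoder: MIDecoder, path: str | Path) -> None:
    """Single-archive checkpoint: config + class mapping + weights."""
    path = Path(path)
    meta = {
        "config": asdict(decoder.config),
        "classes": list(decoder.classes),
        "seed": decoder.seed,
        "trained": decoder.trained,
        "history": decoder.history,
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        import io as _io
        buf = _io.BytesIO()
        flat = {f"{layer}::{k}": v
                for layer, d in decoder.get_weights().items()
                for k, v in d.items()}
        np.savez(buf, **flat)
        zf.writestr("weights.npz", buf.getvalue())


def load_checkpoint(path: str | Path) -> MIDecoder:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        import io as _io
        with np.load(_io.BytesIO(zf.read("weights.npz"))) as z:
            flat = {k: z[k] for k in z.files}
    cfg_dict = meta["config"]
    cfg_dict["head_units"] = tuple(cfg_dict["head_units"])
    decoder = MIDecoder(ModelConfig(**cfg_dict), seed=meta["seed"])
    weights: dict[str, dict[str, np.ndarray]] = {}
    for key, v in flat.items():
        layer, k = key.split("::", 1)
        weights.setdefault(layer, {})[k] = v
    decoder.set_weights(weights)
    decoder.trained = meta["trained"]
    decoder.history = meta["history"]
    return decoder
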