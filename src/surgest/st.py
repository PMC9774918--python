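"""Short-term (ST) spatiotemporal feature extraction.

A 3D-convolutional encoder maps an 8-frame volume to a D-dimensional
embedding.  Two heads share it:

* **ST model 1** (self-supervised): a 6-layer transposed-convolution decoder
  reconstructs the *next* frame after the volume (next-frame pretext task,
  MSE loss).  No gesture labels are used.
* **ST model 2** (supervised): a fully connected softmax head classifies the
  volume's gesture (categorical cross-entropy).

Both are trained in two phases: a warm-up that optimises only the head while
the encoder is frozen, then a fine-tuning phase over all weights, each with
Adam.  Defaults follow the reference protocol (15 warm-up epochs at lr 1e-4,
30 fine-tune epochs at lr 1e-5, batch size 10); desk-scale runs pass smaller
epoch counts and larger rates suited to the tiny encoder.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .decomposition import Volume

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class EncoderConfig:
    """Encoder variant and geometry.

    ``inception3d_reference`` is an Inception-style 3D network with a 1024-d
    global-pooled embedding (224x224 input); ``tiny`` is a 4-block 3D conv
    stack with a 64-d embedding for CPU-scale experiments (any spatial size
    that is a multiple of 8).
    """

    variant: str = "tiny"
    embedding_dim: int | None = None  # default: 64 tiny, 1024 reference
    in_channels: int = 3
    ts: int = 8
    frame_size: int = 64
    weights_path: str | None = None

    def __post_init__(self):
        if self.variant not in ("tiny", "inception3d_reference"):
            raise ValueError(f"unknown encoder variant {self.variant!r}")
        if self.embedding_dim is None:
            self.embedding_dim = 1024 if self.variant == "inception3d_reference" else 64
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")
        if self.variant == "tiny" and self.frame_size % 8:
            raise ValueError("tiny encoder requires frame_size to be a multiple of 8")


@dataclass
class DecoderConfig:
    """Six transposed-conv layers upsampling a projected seed map to (W, H).

    Every layer but the last applies ReLU then batch normalisation; the last
    applies a sigmoid, so outputs live in (0, 1).
    """

    embedding_dim: int = 64
    out_size: int = 64
    out_channels: int = 3
    seed_size: int = 2
    seed_channels: int = 64
    channels: tuple[int, ...] = (48, 32, 24, 16, 8, 3)
    strides: tuple[int, ...] = (1, 2, 2, 2, 2, 2)

    def __post_init__(self):
        if len(self.channels) != len(self.strides):
            raise ValueError("channels and strides must have equal length")
        if self.channels[-1] != self.out_channels:
            raise ValueError("last channel count must equal out_channels")
        size = self.seed_size * int(np.prod(self.strides))
        if size != self.out_size:
            raise ValueError(
                f"strides {self.strides} upsample seed {self.seed_size} to {size}, "
                f"not out_size {self.out_size}"
            )

    @classmethod
    def reference(cls) -> "DecoderConfig":
        return cls(embedding_dim=1024, out_size=224, seed_size=1, seed_channels=512,
                   channels=(256, 128, 64, 32, 16, 3), strides=(7, 2, 2, 2, 2, 2))

    @classmethod
    def for_size(cls, out_size: int, embedding_dim: int, out_channels: int = 3
                 ) -> "DecoderConfig":
        """Six-layer schedule for a given square output size.

        224 uses the reference seed/stride plan; other sizes must be
        multiples of 32 (seed = out_size/32, then five 2x upsamplings).
        """
        if out_size == 224:
            cfg = cls.reference()
            cfg.embedding_dim = embedding_dim
            return cfg
        strides = [1] * 6
        remaining = out_size
        for i in range(5, 0, -1):
            if remaining % 2 == 0 and remaining > 1:
                strides[i] = 2
                remaining //= 2
        return cls(embedding_dim=embedding_dim, out_size=out_size,
                   out_channels=out_channels, seed_size=remaining,
                   seed_channels=64, channels=(48, 32, 24, 16, 8, out_channels),
                   strides=tuple(strides))


@dataclass
class TrainConfig:
    """Two-phase ST schedule and LT schedule (reference defaults)."""

    warmup_epochs: int = 15
    finetune_epochs: int = 30
    lt_epochs: int = 30
    lr_warmup: float = 1e-4
    lr_finetune: float = 1e-5
    lr_lt: float = 1e-5
    batch_size: int = 10
    seed: int = 0


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------

class TinyEncoder3d(nn.Module):
    """Four conv3d+ReLU blocks (spatial stride 2 each, temporal 8->1),
    global average pooling, optional linear projection to D."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        c = cfg.in_channels
        self.body = nn.Sequential(
            nn.Conv3d(c, 8, 3, stride=(1, 2, 2), padding=1, rng=rng), nn.ReLU(),
            nn.Conv3d(8, 16, 3, stride=2, padding=1, rng=rng), nn.ReLU(),
            nn.Conv3d(16, 32, 3, stride=2, padding=1, rng=rng), nn.ReLU(),
            nn.Conv3d(32, 64, 3, stride=2, padding=1, rng=rng), nn.ReLU(),
            nn.GlobalAvgPool3d(),
        )
        self.proj = nn.Linear(64, cfg.embedding_dim, rng) if cfg.embedding_dim != 64 else None

    def forward(self, x, train=False):
        y = self.body.forward(x, train=train)
        return self.proj.forward(y, train=train) if self.proj is not None else y

    def backward(self, dy):
        if self.proj is not None:
            dy = self.proj.backward(dy)
        return self.body.backward(dy)


class InceptionBlock3d(nn.Module):
    """Inception-style mixing block: parallel 1x1x1, two 1x1x1->3x3x3 towers
    and a 1x1x1 projection branch, concatenated along channels."""

    def __init__(self, c_in, b0, b1_red, b1, b2_red, b2, b3, rng):
        self.branch0 = nn.Sequential(nn.Conv3d(c_in, b0, 1, rng=rng), nn.ReLU())
        self.branch1 = nn.Sequential(
            nn.Conv3d(c_in, b1_red, 1, rng=rng), nn.ReLU(),
            nn.Conv3d(b1_red, b1, 3, padding=1, rng=rng), nn.ReLU(),
        )
        self.branch2 = nn.Sequential(
            nn.Conv3d(c_in, b2_red, 1, rng=rng), nn.ReLU(),
            nn.Conv3d(b2_red, b2, 3, padding=1, rng=rng), nn.ReLU(),
        )
        self.branch3 = nn.Sequential(nn.Conv3d(c_in, b3, 1, rng=rng), nn.ReLU())
        self._splits = (b0, b1, b2, b3)
        self.c_out = sum(self._splits)

    def forward(self, x, train=False):
        outs = [b.forward(x, train=train)
                for b in (self.branch0, self.branch1, self.branch2, self.branch3)]
        return np.concatenate(outs, axis=1)

    def backward(self, dy):
        edges = np.cumsum((0,) + self._splits)
        dx = None
        for branch, lo, hi in zip(
            (self.branch0, self.branch1, self.branch2, self.branch3), edges[:-1], edges[1:]
        ):
            d = branch.backward(np.ascontiguousarray(dy[:, lo:hi]))
            dx = d if dx is None else dx + d
        return dx


class InceptionEncoder3d(nn.Module):
    """Inception-style 3D encoder with a 1024-d global-pooled embedding
    (the reference short-term backbone; 224x224x8 input)."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.stem = nn.Sequential(
            nn.Conv3d(cfg.in_channels, 64, 7, stride=2, padding=3, rng=rng), nn.ReLU(),
            nn.AvgPool3d((1, 2, 2)),
            nn.Conv3d(64, 64, 1, rng=rng), nn.ReLU(),
            nn.Conv3d(64, 192, 3, padding=1, rng=rng), nn.ReLU(),
            nn.AvgPool3d((1, 2, 2)),
        )
        self.mix1 = InceptionBlock3d(192, 64, 96, 128, 16, 32, 32, rng)     # -> 256
        self.mix2 = InceptionBlock3d(256, 128, 128, 192, 32, 96, 64, rng)   # -> 480
        self.pool1 = nn.AvgPool3d((2, 2, 2))
        self.mix3 = InceptionBlock3d(480, 256, 160, 320, 32, 128, 128, rng)  # -> 832
        self.pool2 = nn.AvgPool3d((2, 2, 2))
        self.final = nn.Sequential(
            nn.Conv3d(832, cfg.embedding_dim, 1, rng=rng), nn.ReLU(),
            nn.GlobalAvgPool3d(),
        )
        self._order = [self.stem, self.mix1, self.mix2, self.pool1,
                       self.mix3, self.pool2, self.final]

    def forward(self, x, train=False):
        for m in self._order:
            x = m.forward(x, train=train)
        return x

    def backward(self, dy):
        for m in reversed(self._order):
            dy = m.backward(dy)
        return dy


def build_encoder(cfg: EncoderConfig, seed: int = 0) -> nn.Module:
    rng = np.random.default_rng(seed)
    if cfg.variant == "tiny":
        enc = TinyEncoder3d(cfg, rng)
    else:
        enc = InceptionEncoder3d(cfg, rng)
    if cfg.weights_path:
        state = dict(np.load(cfg.weights_path))
        enc.load_state_dict(state)
    return enc


# ---------------------------------------------------------------------------
# decoder and models
# ---------------------------------------------------------------------------

class Decoder(nn.Module):
    def __init__(self, cfg: DecoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.proj = nn.Linear(cfg.embedding_dim,
                              cfg.seed_channels * cfg.seed_size ** 2, rng)
        layers: list[nn.Module] = []
        c_prev = cfg.seed_channels
        n = len(cfg.channels)
        for i, (c_out, s) in enumerate(zip(cfg.channels, cfg.strides)):
            if s == 1:
                layers.append(nn.Conv2d(c_prev, c_out, 3, padding=1, rng=rng))
            else:
                layers.append(nn.ConvTranspose2d(c_prev, c_out, s, rng=rng))
            if i < n - 1:
                layers.append(nn.ReLU())
                layers.append(nn.BatchNorm2d(c_out))
            else:
                layers.append(nn.Sigmoid())
            c_prev = c_out
        self.body = nn.Sequential(*layers)

    def forward(self, emb, train=False):
        emb = np.asarray(emb, dtype=np.float32)
        if emb.shape[-1] != self.cfg.embedding_dim:
            raise ValueError(
                f"expected embeddings of length {self.cfg.embedding_dim}, "
                f"got {emb.shape[-1]}"
            )
        z = self.proj.forward(emb, train=train)
        z = z.reshape(-1, self.cfg.seed_channels, self.cfg.seed_size, self.cfg.seed_size)
        return self.body.forward(z, train=train)

    def backward(self, dy):
        dz = self.body.backward(dy)
        return self.proj.backward(dz.reshape(dz.shape[0], -1))


class STModel1(nn.Module):
    """Encoder + decoder for the next-frame pretext task."""

    def __init__(self, encoder: nn.Module, decoder: Decoder):
        self.encoder = encoder
        self.decoder = decoder

    def forward(self, x, train=False):
        return self.decoder.forward(self.encoder.forward(x, train=train), train=train)

    def backward(self, dy):
        return self.encoder.backward(self.decoder.backward(dy))


class STModel2(nn.Module):
    """Encoder + fully connected softmax head over G gesture classes."""

    def __init__(self, encoder: nn.Module, embedding_dim: int, n_classes: int,
                 rng: np.random.Generator):
        self.encoder = encoder
        self.n_classes = n_classes
        self.head = nn.Linear(embedding_dim, n_classes, rng)

    def forward(self, x, train=False):
        return self.head.forward(self.encoder.forward(x, train=train), train=train)

    def backward(self, dy):
        return self.encoder.backward(self.head.backward(dy))


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def volumes_to_batch(volumes: list[Volume] | list[np.ndarray]) -> np.ndarray:
    """Stack volumes into a (B, C, TS, H, W) float32 batch."""
    arrs = [v.frames if isinstance(v, Volume) else np.asarray(v) for v in volumes]
    return np.ascontiguousarray(np.stack(arrs).transpose(0, 4, 1, 2, 3), dtype=np.float32)


def encode_volume(volume: Volume | np.ndarray, encoder: nn.Module) -> np.ndarray:
    """Embed one volume; deterministic given fixed weights."""
    return encode_volumes([volume], encoder)[0]


def encode_volumes(volumes, encoder: nn.Module, batch_size: int = 64) -> np.ndarray:
    out = []
    for i in range(0, len(volumes), batch_size):
        out.append(encoder.forward(volumes_to_batch(volumes[i : i + batch_size])))
    emb = np.concatenate(out, axis=0)
    if not np.all(np.isfinite(emb)):
        raise FloatingPointError("non-finite values in embeddings")
    return emb


def decode_next_frame(embedding: np.ndarray, decoder: Decoder) -> np.ndarray:
    """Predicted next frame (H, W, C) with pixels in (0, 1)."""
    emb = np.atleast_2d(np.asarray(embedding, dtype=np.float32))
    frame = decoder.forward(emb)[0]
    return np.ascontiguousarray(frame.transpose(1, 2, 0))


def classify_volume(embedding: np.ndarray, model: STModel2) -> np.ndarray:
    """Class probability vector of a single embedding under the softmax head."""
    emb = np.atleast_2d(np.asarray(embedding, dtype=np.float32))
    return nn.softmax(model.head.forward(emb))[0]


def volume_label(prob: np.ndarray) -> int:
    """Argmax label; ties broken by lowest index."""
    prob = np.asarray(prob)
    if prob.ndim != 1 or not np.all(np.isfinite(prob)):
        raise ValueError("expected a finite 1-D probability vector")
    return int(np.argmax(prob))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def train_st_model1(model: STModel1, pairs: list[tuple[Volume, np.ndarray]],
                    cfg: TrainConfig) -> list[dict]:
    """Two-phase next-frame training; returns a per-epoch loss history."""
    if not pairs:
        raise ValueError("empty training set for the next-frame pretext task")
    rng = np.random.default_rng(cfg.seed)
    history: list[dict] = []

    def run_phase(phase: str, epochs: int, lr: float, update_encoder: bool):
        nn.set_trainable(model.encoder, update_encoder)
        opt = nn.Adam(model.parameters(), lr=lr)
        for epoch in range(epochs):
            losses = []
            for idx in _batches(len(pairs), cfg.batch_size, rng):
                batch = [pairs[i] for i in idx]
                x = volumes_to_batch([p[0] for p in batch])
                y = np.ascontiguousarray(
                    np.stack([p[1] for p in batch]).transpose(0, 3, 1, 2), dtype=np.float32
                )
                if update_encoder:
                    pred = model.forward(x, train=True)
                else:
                    emb = model.encoder.forward(x)
                    pred = model.decoder.forward(emb, train=True)
                loss, dpred = nn.mse_loss(pred, y)
                opt.zero_grad()
                if update_encoder:
                    model.backward(dpred)
                else:
                    model.decoder.backward(dpred)
                opt.step()
                losses.append(loss)
            history.append({"phase": phase, "epoch": epoch, "loss": float(np.mean(losses))})
        nn.set_trainable(model.encoder, True)

    run_phase("warmup", cfg.warmup_epochs, cfg.lr_warmup, update_encoder=False)
    run_phase("finetune", cfg.finetune_epochs, cfg.lr_finetune, update_encoder=True)
    return history


def train_st_model2(model: STModel2, volumes: list[Volume], cfg: TrainConfig) -> list[dict]:
    """Two-phase supervised volume-classification training."""
    if not volumes:
        raise ValueError("empty training set for supervised volume classification")
    labels = np.array([v.label for v in volumes])
    if any(v.label is None for v in volumes):
        raise ValueError("all volumes must be labeled")
    if labels.min() < 0 or labels.max() >= model.n_classes:
        raise ValueError(
            f"labels outside vocabulary [0, {model.n_classes}): "
            f"range [{labels.min()}, {labels.max()}]"
        )
    if len(np.unique(labels)) < 2:
        logger.warning("single-class training set; the classifier will be degenerate")
    rng = np.random.default_rng(cfg.seed)
    history: list[dict] = []

    def run_phase(phase: str, epochs: int, lr: float, update_encoder: bool):
        nn.set_trainable(model.encoder, update_encoder)
        opt = nn.Adam(model.parameters(), lr=lr)
        for epoch in range(epochs):
            losses, hits, total = [], 0, 0
            for idx in _batches(len(volumes), cfg.batch_size, rng):
                x = volumes_to_batch([volumes[i] for i in idx])
                y = labels[idx]
                if update_encoder:
                    logits = model.forward(x, train=True)
                else:
                    emb = model.encoder.forward(x)
                    logits = model.head.forward(emb, train=True)
                loss, dlogits = nn.cross_entropy_with_logits(logits, y)
                opt.zero_grad()
                if update_encoder:
                    model.backward(dlogits)
                else:
                    model.head.backward(dlogits)
                opt.step()
                losses.append(loss)
                hits += int((logits.argmax(axis=1) == y).sum())
                total += len(y)
            history.append({"phase": phase, "epoch": epoch,
                            "loss": float(np.mean(losses)), "accuracy": hits / total})
        nn.set_trainable(model.encoder, True)

    run_phase("warmup", cfg.warmup_epochs, cfg.lr_warmup, update_encoder=False)
    run_phase("finetune", cfg.finetune_epochs, cfg.lr_finetune, update_encoder=True)
    return history


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, module: nn.Module, meta: dict | None = None) -> None:
    """Weights as .npz plus a JSON sidecar with config/phase metadata."""
    path = Path(path)
    np.savez_compressed(path, **module.state_dict())
    sidecar = path.with_suffix(path.suffix + ".json") if path.suffix != ".npz" \
        else path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta or {}, indent=2, default=str))


def load_checkpoint(path: str | Path, module: nn.Module) -> dict:
    path = Path(path)
    with np.load(path) as data:
        module.load_state_dict(dict(data))
    sidecar = path.with_suffix(".json")
    return json.loads(sidecar.read_text()) if sidecar.exists() else {}


def history_to_csv(history: list[dict], path: str | Path) -> None:
    pd.DataFrame(history).to_csv(path, index=False)
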