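"""Long-term (LT) temporal model.

A clip's NS volume embeddings form a token sequence.  A learned linear
projection maps each D-dimensional embedding to d_model, three transformer
blocks mix the tokens with single-head scaled dot-product self-attention

    A = softmax(Q K^T / sqrt(d_k)) V,

where Q, K, V are projections of the *same* tokens, and the block output is
post-norm residual: LN(t + FFN(LN(t + SelfAttn(t)))).  No positional
encoding is added — the block stack is permutation-equivariant, and order
information enters only through the final flatten, after which a one-hidden-
layer MLP with softmax produces the clip-level gesture distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .st import TrainConfig


@dataclass
class AttentionParams:
    """Q/K/V projection matrices sharing the output dimension d_k."""

    wq: np.ndarray
    wk: np.ndarray
    wv: np.ndarray

    def __post_init__(self):
        self.wq = np.asarray(self.wq, dtype=np.float32)
        self.wk = np.asarray(self.wk, dtype=np.float32)
        self.wv = np.asarray(self.wv, dtype=np.float32)
        if not (self.wq.shape == self.wk.shape == self.wv.shape):
            raise ValueError("Q, K, V projections must share their shape")

    @property
    def d_k(self) -> int:
        return self.wq.shape[1]


@dataclass
class TransformerConfig:
    """LT geometry: reference defaults sized for 1024-d embeddings."""

    n_classes: int
    embedding_dim: int = 1024
    ns: int = 8
    num_blocks: int = 3
    d_model: int = 256
    d_k: int | None = None  # defaults to d_model (required for the residual)
    ff_width: int = 512
    mlp_hidden: int = 128

    def __post_init__(self):
        if self.d_k is None:
            self.d_k = self.d_model
        if self.num_blocks < 1 or self.d_model < 1 or self.d_k < 1:
            raise ValueError("num_blocks, d_model and d_k must be >= 1")
        if self.d_k != self.d_model:
            raise ValueError("d_k must equal d_model for the residual connection")

    @classmethod
    def tiny(cls, n_classes: int, embedding_dim: int = 64, ns: int = 8) -> "TransformerConfig":
        return cls(n_classes=n_classes, embedding_dim=embedding_dim, ns=ns,
                   d_model=32, ff_width=64, mlp_hidden=32)


def scaled_dot_product_self_attention(tokens: np.ndarray, params: AttentionParams,
                                      return_weights: bool = False):
    """Single-sequence self-attention: softmax(QK^T/sqrt(d_k)) V.

    ``tokens`` is (NS, d_in); Q, K and V are all derived from it.  Rows of
    the attention-weight matrix sum to one.
    """
    tokens = np.asarray(tokens, dtype=np.float64)  # analysis path: full precision
    if tokens.ndim != 2 or not np.all(np.isfinite(tokens)):
        raise ValueError("tokens must be a finite (NS, d) matrix")
    q = tokens @ params.wq.astype(np.float64)
    k = tokens @ params.wk.astype(np.float64)
    v = tokens @ params.wv.astype(np.float64)
    weights = nn.softmax(q @ k.T / np.sqrt(params.d_k), axis=-1)
    out = weights @ v
    return (out, weights) if return_weights else out


class SelfAttention(nn.Module):
    """Batched single-head scaled dot-product self-attention (no biases)."""

    def __init__(self, d_model: int, d_k: int, rng: np.random.Generator):
        self.d_model, self.d_k = d_model, d_k
        init = lambda: nn.layers.glorot_uniform(rng, d_model, d_k, (d_model, d_k))
        self.wq = nn.Parameter(init())
        self.wk = nn.Parameter(init())
        self.wv = nn.Parameter(init())

    def forward(self, x, train=False):
        # x: (B, N, d_model)
        q = x @ self.wq.value
        k = x @ self.wk.value
        v = x @ self.wv.value
        p = nn.softmax(q @ k.transpose(0, 2, 1) / np.sqrt(self.d_k), axis=-1)
        self._cache = (x, q, k, v, p)
        return (p @ v).astype(np.float32)

    def backward(self, dy):
        x, q, k, v, p = self._cache
        scale = 1.0 / np.sqrt(self.d_k)
        dp = dy @ v.transpose(0, 2, 1)
        dv = p.transpose(0, 2, 1) @ dy
        ds = p * (dp - (dp * p).sum(axis=-1, keepdims=True))
        dq = (ds @ k) * scale
        dk = (ds.transpose(0, 2, 1) @ q) * scale
        self.wq.grad += np.einsum("bnd,bnk->dk", x, dq)
        self.wk.grad += np.einsum("bnd,bnk->dk", x, dk)
        self.wv.grad += np.einsum("bnd,bnk->dk", x, dv)
        return (dq @ self.wq.value.T + dk @ self.wk.value.T
                + dv @ self.wv.value.T).astype(np.float32)

    def params_view(self) -> AttentionParams:
        return AttentionParams(self.wq.value, self.wk.value, self.wv.value)


class TransformerBlock(nn.Module):
    """Post-norm block: LN(t + FFN(LN(t + SelfAttn(t))))."""

    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        self.attn = SelfAttention(cfg.d_model, cfg.d_k, rng)
        self.ln1 = nn.LayerNorm(cfg.d_model)
        self.ff1 = nn.Linear(cfg.d_model, cfg.ff_width, rng)
        self.relu = nn.ReLU()
        self.ff2 = nn.Linear(cfg.ff_width, cfg.d_model, rng)
        self.ln2 = nn.LayerNorm(cfg.d_model)

    def forward(self, x, train=False):
        t1 = self.ln1.forward(x + self.attn.forward(x, train=train), train=train)
        f = self.ff2.forward(self.relu.forward(self.ff1.forward(t1, train=train),
                                               train=train), train=train)
        return self.ln2.forward(t1 + f, train=train)

    def backward(self, dy):
        d = self.ln2.backward(dy)
        dt1 = d + self.ff1.backward(self.relu.backward(self.ff2.backward(d)))
        dx_plus = self.ln1.backward(dt1)
        return dx_plus + self.attn.backward(dx_plus)


class LTModel(nn.Module):
    """Input projection, transformer blocks, flatten, MLP softmax head."""

    def __init__(self, cfg: TransformerConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.proj = nn.Linear(cfg.embedding_dim, cfg.d_model, rng)
        self.blocks = [TransformerBlock(cfg, rng) for _ in range(cfg.num_blocks)]
        self.hidden = nn.Linear(cfg.ns * cfg.d_model, cfg.mlp_hidden, rng)
        self.relu = nn.ReLU()
        self.out = nn.Linear(cfg.mlp_hidden, cfg.n_classes, rng)

    def forward(self, x, train=False):
        # x: (B, NS, D) -> logits (B, G)
        cfg = self.cfg
        if x.ndim != 3 or x.shape[1] != cfg.ns or x.shape[2] != cfg.embedding_dim:
            raise ValueError(
                f"expected (B, {cfg.ns}, {cfg.embedding_dim}) embeddings, got {x.shape}"
            )
        t = self.proj.forward(np.asarray(x, dtype=np.float32), train=train)
        for block in self.blocks:
            t = block.forward(t, train=train)
        flat = t.reshape(t.shape[0], cfg.ns * cfg.d_model)
        return self.out.forward(
            self.relu.forward(self.hidden.forward(flat, train=train), train=train),
            train=train,
        )

    def backward(self, dy):
        dflat = self.hidden.backward(self.relu.backward(self.out.backward(dy)))
        dt = dflat.reshape(-1, self.cfg.ns, self.cfg.d_model)
        for block in reversed(self.blocks):
            dt = block.backward(dt)
        return self.proj.backward(dt)

    def transform_tokens(self, x: np.ndarray) -> np.ndarray:
        """Run only the projection + block stack (used by equivariance tests)."""
        t = self.proj.forward(np.asarray(x, dtype=np.float32))
        for block in self.blocks:
            t = block.forward(t)
        return t


def save_embedding_sequences(path, sequences: np.ndarray, meta: dict | None = None) -> None:
    """Write (N, NS, D) embedding sequences as an .npy tensor with a JSON
    sidecar recording shape, dtype and provenance."""
    import json
    from pathlib import Path

    sequences = np.asarray(sequences, dtype=np.float32)
    path = Path(path)
    np.save(path, sequences)
    path = path if path.suffix == ".npy" else path.with_suffix(path.suffix + ".npy")
    sidecar = {"shape": list(sequences.shape), "dtype": str(sequences.dtype)}
    sidecar.update(meta or {})
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_embedding_sequences(path) -> tuple[np.ndarray, dict]:
    import json
    from pathlib import Path

    path = Path(path)
    path = path if path.suffix == ".npy" else path.with_suffix(path.suffix + ".npy")
    arr = np.load(path)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return arr, meta


def classify_clip(embeddings: np.ndarray, model: LTModel) -> np.ndarray:
    """Clip-level class probabilities from the NS volume embeddings."""
    emb = np.asarray(embeddings, dtype=np.float32)
    if emb.ndim == 2:
        emb = emb[None]
    return nn.softmax(model.forward(emb))[0]


def train_lt(model: LTModel, sequences: np.ndarray, labels: np.ndarray,
             cfg: TrainConfig) -> list[dict]:
    """Cross-entropy training of the LT model on (N, NS, D) embedding
    sequences; the ST encoder is never touched here."""
    sequences = np.asarray(sequences, dtype=np.float32)
    labels = np.asarray(labels)
    if len(sequences) == 0:
        raise ValueError("empty training set for the LT model")
    if len(sequences) != len(labels):
        raise ValueError("sequences and labels differ in length")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.lr_lt)
    history = []
    for epoch in range(cfg.lt_epochs):
        order = rng.permutation(len(sequences))
        losses, hits = [], 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            logits = model.forward(sequences[idx], train=True)
            loss, dlogits = nn.cross_entropy_with_logits(logits, labels[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            hits += int((logits.argmax(axis=1) == labels[idx]).sum())
        history.append({"phase": "lt", "epoch": epoch,
                        "loss": float(np.mean(losses)), "accuracy": hits / len(order)})
    return history
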