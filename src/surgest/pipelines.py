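"""Model variants and the clip-, gesture- and frame-level prediction paths.

Three variants share the decomposition and the 3D encoder:

* **C3Dargmx** — supervised ST model 2 only; a clip's NS volume probability
  vectors are summed (then renormalised) and the argmax gives the clip label.
* **C3DTrans** — supervised ST model 2 embeddings feed the transformer (LT),
  which predicts the clip gesture.
* **SSC3DTrans** — the self-supervised ST model 1 encoder (next-frame
  pretext, trained on ALL video regardless of annotation budget) feeds the
  transformer, which is trained on the labelled fraction only.

Gesture-level prediction tiles an annotated interval with 80%-overlapping
clips and sums their class probabilities; online per-frame prediction uses a
strictly causal rolling window of the last TL frames.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .decomposition import (
    Clip,
    DecompositionConfig,
    FrameSequence,
    GestureTranscript,
    extract_volumes,
    label_clips_from_transcript,
    next_frame_pairs,
)
from .lt import LTModel, TransformerConfig, train_lt
from .st import (
    Decoder,
    DecoderConfig,
    EncoderConfig,
    STModel1,
    STModel2,
    TrainConfig,
    build_encoder,
    encode_volumes,
    load_checkpoint,
    save_checkpoint,
    train_st_model1,
    train_st_model2,
)

logger = logging.getLogger(__name__)

VARIANT_NAMES = ("C3Dargmx", "C3DTrans", "SSC3DTrans")


@dataclass
class ModelVariant:
    name: str
    st_model: nn.Module  # STModel2 (supervised) or STModel1 (self-supervised)
    lt: LTModel | None
    config: DecompositionConfig
    annotation_budget: float = 1.0
    # resolved architecture configs, populated by build_variant for persistence
    encoder_cfg: EncoderConfig | None = None
    decoder_cfg: DecoderConfig | None = None
    lt_cfg: TransformerConfig | None = None

    def __post_init__(self):
        if self.name not in VARIANT_NAMES:
            raise ValueError(f"unknown variant {self.name!r}; expected one of {VARIANT_NAMES}")
        if self.name == "C3Dargmx":
            if self.lt is not None or not isinstance(self.st_model, STModel2):
                raise ValueError("C3Dargmx uses ST model 2 and no LT model")
        elif self.name == "C3DTrans":
            if self.lt is None or not isinstance(self.st_model, STModel2):
                raise ValueError("C3DTrans pairs ST model 2 with a trained LT model")
        elif self.name == "SSC3DTrans":
            if self.lt is None or not isinstance(self.st_model, STModel1):
                raise ValueError("SSC3DTrans pairs ST model 1 with a trained LT model")

    @property
    def encoder(self) -> nn.Module:
        return self.st_model.encoder


def aggregate_probs(prob_rows: np.ndarray) -> np.ndarray:
    """Sum probability vectors and renormalise (argmax-invariant rescale)."""
    total = np.asarray(prob_rows, dtype=np.float64).sum(axis=0)
    return (total / total.sum()).astype(np.float32)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_clips(variant: ModelVariant, clips: list[Clip],
                  batch_size: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and labels for a list of clips."""
    if not clips:
        return np.zeros((0, 0), dtype=np.float32), np.zeros(0, dtype=int)
    cfg = variant.config
    ns = cfg.ns
    volumes = [v for c in clips for v in extract_volumes(c, cfg)]
    emb = encode_volumes(volumes, variant.encoder, batch_size=batch_size)
    if variant.name == "C3Dargmx":
        vol_probs = nn.softmax(variant.st_model.head.forward(emb))
        vol_probs = vol_probs.reshape(len(clips), ns, -1)
        probs = np.stack([aggregate_probs(p) for p in vol_probs])
    else:
        seqs = emb.reshape(len(clips), ns, -1)
        out = []
        for i in range(0, len(seqs), batch_size):
            out.append(nn.softmax(variant.lt.forward(seqs[i : i + batch_size])))
        probs = np.concatenate(out, axis=0)
    return probs, probs.argmax(axis=1)


def predict_clip(variant: ModelVariant, clip: Clip) -> tuple[np.ndarray, int]:
    """Probability vector and argmax label for a single clip."""
    if len(clip.frames) != variant.config.tl:
        raise ValueError(
            f"clip has {len(clip.frames)} frames; expected TL={variant.config.tl}"
        )
    probs, labels = predict_clips(variant, [clip])
    return probs[0], int(labels[0])


def gesture_instance_probs(variant: ModelVariant, frames: np.ndarray,
                           overlap: float = 0.8) -> np.ndarray:
    """Summed clip probabilities over an interval tiled with overlapping clips."""
    cfg = variant.config
    n = len(frames)
    if n < cfg.tl:
        raise ValueError(f"gesture interval of {n} frames shorter than minimum TL={cfg.tl}")
    step = max(int(round(cfg.tl * (1.0 - overlap))), 1)
    clips = [
        Clip("instance", s, frames[s : s + cfg.tl])
        for s in range(0, n - cfg.tl + 1, step)
    ]
    probs, _ = predict_clips(variant, clips)
    return aggregate_probs(probs)


def predict_gesture_instance(variant: ModelVariant, frames: np.ndarray,
                             overlap: float = 0.8) -> int:
    """Label of a whole gesture instance via argmax of summed clip probabilities."""
    return int(np.argmax(gesture_instance_probs(variant, frames, overlap=overlap)))


def rolling_online_predict(variant: ModelVariant, seq: FrameSequence,
                           batch_size: int = 64) -> np.ndarray:
    """Strictly causal per-frame labels: frame n is predicted from
    frames [n-TL+1, n]; the first TL-1 frames are back-filled with the
    first available prediction."""
    cfg = variant.config
    n = len(seq)
    if n < cfg.tl:
        raise ValueError(f"sequence of {n} frames shorter than TL={cfg.tl}")
    clips = [
        Clip(seq.trial_id, s, seq.frames[s : s + cfg.tl])
        for s in range(0, n - cfg.tl + 1)
    ]
    _, labels = predict_clips(variant, clips, batch_size=batch_size)
    out = np.empty(n, dtype=int)
    out[cfg.tl - 1 :] = labels
    out[: cfg.tl - 1] = labels[0]
    return out


def export_frame_predictions(path, frame_true: np.ndarray, frame_pred: np.ndarray) -> None:
    """CSV (frame_index, true_label, predicted_label) behind ribbon plots."""
    pd.DataFrame({
        "frame_index": np.arange(len(frame_pred)),
        "true_label": np.asarray(frame_true, dtype=int),
        "predicted_label": np.asarray(frame_pred, dtype=int),
    }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# training orchestration
# ---------------------------------------------------------------------------

def select_budget_segments(trials: list[tuple[FrameSequence, GestureTranscript]],
                           budget: float, seed: int) -> list[GestureTranscript]:
    """Keep a seeded random fraction of annotated segments (not clips),
    emulating partially annotated data."""
    if not (0.0 < budget <= 1.0):
        raise ValueError(f"annotation budget must be in (0, 1], got {budget}")
    segments = [
        (i, s, e, g) for i, (_, t) in enumerate(trials) for (s, e, g) in t.intervals
    ]
    n_keep = max(int(round(budget * len(segments))), 1)
    rng = np.random.default_rng(seed)
    keep = set(map(int, rng.choice(len(segments), size=n_keep, replace=False)))
    reduced = []
    for i, (_, t) in enumerate(trials):
        kept = [
            (s, e, g) for j, (ti, s, e, g) in enumerate(segments)
            if ti == i and j in keep
        ]
        reduced.append(GestureTranscript(t.trial_id, t.task_id, kept))
    return reduced


def _labeled_volumes(clips: list[Clip], config: DecompositionConfig,
                     volume_stride: int) -> list:
    vols = []
    for c in clips:
        vols.extend(extract_volumes(c, config)[::volume_stride])
    return vols


def _sub_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] & 0x7FFFFFFF)


def build_variant(name: str,
                  trials: list[tuple[FrameSequence, GestureTranscript]],
                  n_classes: int,
                  config: DecompositionConfig,
                  *,
                  budget: float = 1.0,
                  seed: int = 0,
                  encoder_cfg: EncoderConfig | None = None,
                  decoder_cfg: DecoderConfig | None = None,
                  lt_cfg: TransformerConfig | None = None,
                  train_cfg: TrainConfig | None = None,
                  volume_stride: int = 1,
                  pretext_stride: int = 1,
                  clip_stride: int = 1) -> tuple[ModelVariant, dict]:
    """Train a model variant end to end on a set of annotated trials.

    ``volume_stride``/``pretext_stride``/``clip_stride`` thin the heavily
    overlapping training sets for scaled-down CPU runs (1 keeps everything).
    """
    if name not in VARIANT_NAMES:
        raise ValueError(f"unknown variant {name!r}; expected one of {VARIANT_NAMES}")
    if not trials:
        raise ValueError("no training trials")
    size = trials[0][0].frames.shape[1]
    encoder_cfg = encoder_cfg or EncoderConfig(frame_size=size)
    train_cfg = train_cfg or TrainConfig()
    reduced = select_budget_segments(trials, budget, _sub_seed(seed, 0))
    labeled_clips = [
        clip
        for (seq, _), transcript in zip(trials, reduced)
        for clip in label_clips_from_transcript(seq, transcript, config)
    ][::clip_stride]
    if not labeled_clips:
        raise ValueError("no labeled clips available under the given budget")

    histories: dict[str, list] = {}
    encoder = build_encoder(encoder_cfg, seed=_sub_seed(seed, 1))
    rng = np.random.default_rng(_sub_seed(seed, 2))

    if name == "SSC3DTrans":
        decoder_cfg = decoder_cfg or DecoderConfig.for_size(
            size, encoder_cfg.embedding_dim
        )
        st_model: nn.Module = STModel1(encoder, Decoder(decoder_cfg, rng))
        # pretext training always consumes ALL video, unlabeled
        pairs = [
            p for (seq, _) in trials for p in next_frame_pairs(seq, config, stride=pretext_stride)
        ]
        st_cfg = TrainConfig(**{**asdict(train_cfg), "seed": _sub_seed(seed, 3)})
        histories["st"] = train_st_model1(st_model, pairs, st_cfg)
    else:
        st_model = STModel2(encoder, encoder_cfg.embedding_dim, n_classes, rng)
        volumes = _labeled_volumes(labeled_clips, config, volume_stride)
        st_cfg = TrainConfig(**{**asdict(train_cfg), "seed": _sub_seed(seed, 3)})
        histories["st"] = train_st_model2(st_model, volumes, st_cfg)

    lt_model = None
    if name in ("C3DTrans", "SSC3DTrans"):
        lt_cfg = lt_cfg or TransformerConfig.tiny(
            n_classes, embedding_dim=encoder_cfg.embedding_dim, ns=config.ns
        )
        lt_model = LTModel(lt_cfg, seed=_sub_seed(seed, 4))
        seqs = []
        for clip in labeled_clips:
            vols = extract_volumes(clip, config)
            seqs.append(encode_volumes(vols, encoder))
        x = np.stack(seqs)
        y = np.array([c.label for c in labeled_clips])
        lt_train = TrainConfig(**{**asdict(train_cfg), "seed": _sub_seed(seed, 5)})
        histories["lt"] = train_lt(lt_model, x, y, lt_train)

    variant = ModelVariant(name, st_model, lt_model, config, annotation_budget=budget,
                           encoder_cfg=encoder_cfg, decoder_cfg=decoder_cfg,
                           lt_cfg=lt_cfg)
    return variant, histories


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_variant(out_dir: str | Path, variant: ModelVariant,
                 encoder_cfg: EncoderConfig | None = None, n_classes: int | None = None,
                 decoder_cfg: DecoderConfig | None = None,
                 lt_cfg: TransformerConfig | None = None) -> None:
    encoder_cfg = encoder_cfg or variant.encoder_cfg
    decoder_cfg = decoder_cfg or variant.decoder_cfg
    lt_cfg = lt_cfg or variant.lt_cfg
    if encoder_cfg is None:
        raise ValueError("encoder config unknown; pass encoder_cfg explicitly")
    if n_classes is None:
        if isinstance(variant.st_model, STModel2):
            n_classes = variant.st_model.n_classes
        elif lt_cfg is not None:
            n_classes = lt_cfg.n_classes
        else:
            raise ValueError("n_classes unknown; pass it explicitly")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "variant": variant.name,
        "n_classes": n_classes,
        "annotation_budget": variant.annotation_budget,
        "decomposition": asdict(variant.config),
        "encoder": asdict(encoder_cfg),
        "decoder": asdict(decoder_cfg) if decoder_cfg else None,
        "transformer": asdict(lt_cfg) if lt_cfg else None,
    }
    save_checkpoint(out_dir / "st.npz", variant.st_model, meta)
    if variant.lt is not None:
        save_checkpoint(out_dir / "lt.npz", variant.lt, meta)
    (out_dir / "variant.json").write_text(json.dumps(meta, indent=2))


def load_variant(out_dir: str | Path) -> ModelVariant:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "variant.json").read_text())
    config = DecompositionConfig(**meta["decomposition"])
    encoder_cfg = EncoderConfig(**meta["encoder"])
    encoder = build_encoder(encoder_cfg, seed=0)
    rng = np.random.default_rng(0)
    if meta["variant"] == "SSC3DTrans":
        decoder_cfg = DecoderConfig(**meta["decoder"])
        st_model: nn.Module = STModel1(encoder, Decoder(decoder_cfg, rng))
    else:
        st_model = STModel2(encoder, encoder_cfg.embedding_dim, meta["n_classes"], rng)
    load_checkpoint(out_dir / "st.npz", st_model)
    lt_model = None
    if meta["transformer"]:
        lt_model = LTModel(TransformerConfig(**meta["transformer"]), seed=0)
        load_checkpoint(out_dir / "lt.npz", lt_model)
    return ModelVariant(meta["variant"], st_model, lt_model, config,
                        annotation_budget=meta.get("annotation_budget", 1.0))
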