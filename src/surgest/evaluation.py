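"""Trial-disjoint cross-validation and classification metrics.

Folds partition *trials* (never clips), so no clip or gesture instance of a
test trial can leak into training.  Metrics are accuracy, macro-averaged F1
(classes absent from both truth and prediction are excluded) and a G x G
confusion matrix with rows = truth.  Reported values are percentages and are
averaged over folds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score

from .decomposition import (
    DecompositionConfig,
    FrameSequence,
    GestureTranscript,
    label_clips_from_transcript,
)
from .pipelines import build_variant, predict_clips, predict_gesture_instance
from .st import TrainConfig

logger = logging.getLogger(__name__)


@dataclass
class FoldSplit:
    folds: list[list[str]]
    seed: int

    def __post_init__(self):
        flat = [t for fold in self.folds for t in fold]
        if len(flat) != len(set(flat)):
            raise ValueError("folds are not pairwise disjoint")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError(f"fold sizes differ by more than 1: {sizes}")

    @property
    def k(self) -> int:
        return len(self.folds)


def kfold_by_trial(trial_ids: list[str], k: int, seed: int = 0) -> FoldSplit:
    """Seeded shuffle then round-robin assignment of trials to k folds."""
    if len(trial_ids) < k:
        raise ValueError(f"cannot split {len(trial_ids)} trials into {k} folds")
    rng = np.random.default_rng(seed)
    order = [trial_ids[i] for i in rng.permutation(len(trial_ids))]
    folds: list[list[str]] = [[] for _ in range(k)]
    for i, trial in enumerate(order):
        folds[i % k].append(trial)
    return FoldSplit(folds, seed)


@dataclass
class EvalReport:
    """Accuracy and macro F1 in percent, plus the confusion matrix."""

    accuracy: float
    f1: float
    confusion: np.ndarray
    labels: list[int] = field(default_factory=list)
    n: int = 0

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "f1": self.f1, "n": self.n,
                "labels": list(self.labels),
                "confusion": np.asarray(self.confusion).tolist()}


def evaluate_clips(y_true, y_pred, labels: list[int] | None = None) -> EvalReport:
    """Accuracy, macro F1 and confusion matrix for two label sequences."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    if len(y_true) == 0:
        raise ValueError("empty label sequences")
    observed = sorted(set(np.concatenate([y_true, y_pred]).tolist()))
    if labels is not None:
        dropped = [c for c in labels if c not in observed]
        if dropped:
            logger.info("classes %s absent from truth and prediction; excluded from F1", dropped)
    acc = accuracy_score(y_true, y_pred)
    f1 = f1_score(y_true, y_pred, labels=observed, average="macro", zero_division=0)
    cm = confusion_matrix(y_true, y_pred, labels=observed)
    return EvalReport(accuracy=100.0 * acc, f1=100.0 * f1, confusion=cm,
                      labels=observed, n=len(y_true))


def _clip_level_eval(variant, test_trials, config) -> EvalReport:
    clips = [
        c for (seq, transcript) in test_trials
        for c in label_clips_from_transcript(seq, transcript, config)
    ]
    if not clips:
        raise ValueError("no labeled clips in the test fold")
    _, pred = predict_clips(variant, clips)
    return evaluate_clips([c.label for c in clips], pred)


def _gesture_level_eval(variant, test_trials, config) -> tuple[EvalReport, int]:
    y_true, y_pred, skipped = [], [], 0
    for seq, transcript in test_trials:
        for (s, e, g) in transcript.intervals:
            if e - s < config.tl:
                skipped += 1
                continue
            y_true.append(g)
            y_pred.append(predict_gesture_instance(variant, seq.frames[s:e]))
    if skipped:
        logger.warning("%d gesture instances shorter than TL=%d skipped", skipped, config.tl)
    return evaluate_clips(y_true, y_pred), skipped


def cross_validate(variant_name: str,
                   trials: list[tuple[FrameSequence, GestureTranscript]],
                   n_classes: int,
                   config: DecompositionConfig,
                   *,
                   k: int = 5,
                   budget: float = 1.0,
                   seed: int = 0,
                   train_cfg: TrainConfig | None = None,
                   **build_kwargs) -> dict:
    """k-fold trial-disjoint cross-validation of one model variant.

    Returns per-fold and mean clip-level and gesture-level reports, plus the
    fold assignment used.
    """
    split = kfold_by_trial([seq.trial_id for seq, _ in trials], k, seed)
    by_id = {seq.trial_id: (seq, t) for seq, t in trials}
    result: dict = {"folds": split.folds, "clip": [], "gesture": [], "skipped_gestures": 0}
    for fold_idx, test_ids in enumerate(split.folds):
        test_set = set(test_ids)
        train_trials = [by_id[t] for t in by_id if t not in test_set]
        test_trials = [by_id[t] for t in test_ids]
        train_id_set = {seq.trial_id for seq, _ in train_trials}
        assert train_id_set.isdisjoint(test_set), "test-set leakage across folds"
        variant, _ = build_variant(
            variant_name, train_trials, n_classes, config,
            budget=budget, seed=seed + fold_idx, train_cfg=train_cfg, **build_kwargs,
        )
        result["clip"].append(_clip_level_eval(variant, test_trials, config))
        gesture_report, skipped = _gesture_level_eval(variant, test_trials, config)
        result["gesture"].append(gesture_report)
        result["skipped_gestures"] += skipped
    for level in ("clip", "gesture"):
        reports = result[level]
        result[f"{level}_mean"] = {
            "accuracy": float(np.mean([r.accuracy for r in reports])),
            "f1": float(np.mean([r.f1 for r in reports])),
        }
    return result


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def save_report(result: dict, out_dir: str | Path) -> None:
    """Write cross-validation results as JSON + per-fold CSVs, and confusion
    matrices as labelled CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "folds": result["folds"],
        "clip": [r.to_dict() for r in result["clip"]],
        "gesture": [r.to_dict() for r in result["gesture"]],
        "clip_mean": result["clip_mean"],
        "gesture_mean": result["gesture_mean"],
        "skipped_gestures": result["skipped_gestures"],
    }
    (out_dir / "report.json").write_text(json.dumps(payload, indent=2))
    rows = []
    for level in ("clip", "gesture"):
        for i, r in enumerate(result[level]):
            rows.append({"level": level, "fold": i, "accuracy": r.accuracy,
                         "f1": r.f1, "n": r.n})
        rows.append({"level": level, "fold": "mean",
                     "accuracy": result[f"{level}_mean"]["accuracy"],
                     "f1": result[f"{level}_mean"]["f1"], "n": ""})
    pd.DataFrame(rows).to_csv(out_dir / "report.csv", index=False)
    for level in ("clip", "gesture"):
        for i, r in enumerate(result[level]):
            cm = pd.DataFrame(r.confusion,
                              index=[f"true_{c}" for c in r.labels],
                              columns=[f"pred_{c}" for c in r.labels])
            cm.to_csv(out_dir / f"confusion_{level}_fold{i}.csv")
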