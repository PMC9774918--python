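"""Reproducible desk-scale experiments on synthetic gesture data.

These functions define the package's reference study conditions — dataset
sizes, schedules and strides chosen once for single-CPU runtimes — and are
what ``scripts/acceptance.py`` and the end-to-end tests execute.  Problem
sizes are deliberately small (tens of trials, 32–64 px frames, single-digit
epoch counts at learning rates suited to the tiny encoder); the reference
protocol defaults in :class:`surgest.st.TrainConfig` remain unchanged.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from sklearn.linear_model import LogisticRegression

from . import nn
from .decomposition import (
    DecompositionConfig,
    extract_volumes,
    label_clips_from_transcript,
    next_frame_pairs,
)
from .evaluation import evaluate_clips, kfold_by_trial
from .lt import LTModel, TransformerConfig, train_lt
from .pipelines import (
    _labeled_volumes,
    _sub_seed,
    build_variant,
    predict_clips,
    select_budget_segments,
)
from .st import (
    Decoder,
    DecoderConfig,
    EncoderConfig,
    STModel1,
    STModel2,
    TrainConfig,
    build_encoder,
    encode_volumes,
    train_st_model1,
    train_st_model2,
)
from .synthetic import generate_dataset, make_motion_only_pair, pt_like_spec


def desk_schedule(seed: int = 0) -> TrainConfig:
    """Scaled-down two-phase schedule for the tiny encoder on synthetic data."""
    return TrainConfig(warmup_epochs=2, finetune_epochs=10,
                       lr_warmup=1e-3, lr_finetune=1e-3,
                       lt_epochs=25, lr_lt=3e-4, batch_size=10, seed=seed)


def _config_for(frame_size: int) -> DecompositionConfig:
    return DecompositionConfig(width=frame_size, height=frame_size, subsample_factor=1)


def _split_by_fold(trials, k: int, seed: int, test_fold: int = 0):
    split = kfold_by_trial([seq.trial_id for seq, _ in trials], k, seed)
    test_ids = set(split.folds[test_fold])
    train = [t for t in trials if t[0].trial_id not in test_ids]
    test = [t for t in trials if t[0].trial_id in test_ids]
    return train, test


def label_recovery(seed: int = 0, n_trials: int = 20, frame_size: int = 64,
                   variant: str = "C3DTrans") -> dict:
    """Train a tiny-config variant on a 5-class synthetic task and measure
    clip-level accuracy on a held-out (trial-disjoint) fold."""
    spec = pt_like_spec(frame_size=frame_size)
    trials = generate_dataset(spec, n_trials=n_trials, seed=_sub_seed(seed, 11))
    config = _config_for(frame_size)
    train_trials, test_trials = _split_by_fold(trials, k=5, seed=_sub_seed(seed, 12))
    model, _ = build_variant(
        variant, train_trials, spec.n_classes, config,
        seed=_sub_seed(seed, 13), train_cfg=desk_schedule(),
        volume_stride=4, clip_stride=2,
    )
    clips = [c for (s, t) in test_trials for c in label_clips_from_transcript(s, t, config)]
    _, pred = predict_clips(model, clips)
    report = evaluate_clips([c.label for c in clips], pred)
    return {"clip_accuracy": report.accuracy, "f1": report.f1, "n_clips": report.n,
            "n_trials": n_trials, "n_classes": spec.n_classes}


def motion_only_discrimination(seed: int = 0, n_trials: int = 8,
                               frame_size: int = 32) -> dict:
    """Two classes that differ only in temporal direction: compare the 3D
    pipeline against a single-frame logistic-regression baseline.

    Single frames are uninformative by construction, so the baseline should
    sit near 50% while the 3D-conv pipeline exceeds it.
    """
    spec = make_motion_only_pair(frame_size=frame_size)
    trials = generate_dataset(spec, n_trials=n_trials, seed=_sub_seed(seed, 21))
    config = _config_for(frame_size)
    train_trials, test_trials = _split_by_fold(trials, k=4, seed=_sub_seed(seed, 22))
    model, _ = build_variant(
        "C3Dargmx", train_trials, spec.n_classes, config,
        seed=_sub_seed(seed, 23), train_cfg=desk_schedule(),
        volume_stride=4, clip_stride=2,
    )
    test_clips = [c for (s, t) in test_trials for c in label_clips_from_transcript(s, t, config)]
    _, pred = predict_clips(model, test_clips)
    acc3d = evaluate_clips([c.label for c in test_clips], pred).accuracy

    # single-frame baseline: logistic regression on each clip's centre frame
    def frame_features(clips):
        mid = config.tl // 2
        return np.stack([c.frames[mid, ::2, ::2, 0].ravel() for c in clips])

    train_clips = [c for (s, t) in train_trials for c in label_clips_from_transcript(s, t, config)]
    baseline = LogisticRegression(max_iter=500, random_state=_sub_seed(seed, 24) % 2**31)
    baseline.fit(frame_features(train_clips), [c.label for c in train_clips])
    acc1f = 100.0 * baseline.score(frame_features(test_clips), [c.label for c in test_clips])
    return {"pipeline3d_accuracy": acc3d, "single_frame_accuracy": acc1f,
            "chance": 100.0 / spec.n_classes, "n_clips": len(test_clips)}


def annotation_budget_robustness(seed: int = 0, n_seeds: int = 5, n_trials: int = 8,
                                 frame_size: int = 32,
                                 budgets: tuple[float, float] = (1.0, 0.6)) -> dict:
    """Accuracy drop from full to reduced annotation, for the supervised
    (C3DTrans) and self-supervised (SSC3DTrans) variants.

    The self-supervised short-term encoder always trains on all video, so
    only its transformer sees fewer labels; the supervised encoder is
    retrained per budget.  Results are averaged over ``n_seeds`` model
    seeds on a fixed trial split.
    """
    full, reduced_budget = budgets
    spec = pt_like_spec(frame_size=frame_size)
    trials = generate_dataset(spec, n_trials=n_trials, seed=_sub_seed(seed, 31))
    config = _config_for(frame_size)
    train_trials, test_trials = _split_by_fold(trials, k=4, seed=_sub_seed(seed, 32))
    test_clips = [c for (s, t) in test_trials for c in label_clips_from_transcript(s, t, config)]
    y_true = np.array([c.label for c in test_clips])
    g = spec.n_classes
    schedule = desk_schedule()

    def budget_clips(budget, run_seed):
        segs = select_budget_segments(train_trials, budget, _sub_seed(run_seed, 0))
        return [c for (s, _), t2 in zip(train_trials, segs)
                for c in label_clips_from_transcript(s, t2, config)][::2]

    def embed(encoder, clips):
        return np.stack([encode_volumes(extract_volumes(c, config), encoder) for c in clips])

    def lt_accuracy(encoder, clips, run_seed):
        x = embed(encoder, clips)
        y = np.array([c.label for c in clips])
        model = LTModel(TransformerConfig.tiny(g, 64, config.ns), seed=_sub_seed(run_seed, 4))
        train_lt(model, x, y, replace(schedule, seed=_sub_seed(run_seed, 5)))
        pred = nn.softmax(model.forward(embed(encoder, test_clips))).argmax(axis=1)
        return 100.0 * float(np.mean(pred == y_true))

    accs: dict[str, list[float]] = {"C3DTrans_100": [], "C3DTrans_60": [],
                                    "SSC3DTrans_100": [], "SSC3DTrans_60": []}
    for i in range(n_seeds):
        run_seed = _sub_seed(seed, 100 + i)
        # self-supervised encoder: one pretext training per seed, all video
        enc_ss = build_encoder(EncoderConfig(frame_size=frame_size), _sub_seed(run_seed, 1))
        m1 = STModel1(enc_ss, Decoder(DecoderConfig.for_size(frame_size, 64),
                                      np.random.default_rng(_sub_seed(run_seed, 2))))
        pairs = [p for (s, _) in train_trials for p in next_frame_pairs(s, config, stride=2)]
        train_st_model1(m1, pairs, replace(schedule, seed=_sub_seed(run_seed, 3)))
        for budget, tag in ((full, "100"), (reduced_budget, "60")):
            clips = budget_clips(budget, run_seed)
            # supervised encoder retrained under this budget
            enc_sup = build_encoder(EncoderConfig(frame_size=frame_size), _sub_seed(run_seed, 1))
            m2 = STModel2(enc_sup, 64, g, np.random.default_rng(_sub_seed(run_seed, 2)))
            train_st_model2(m2, _labeled_volumes(clips, config, 4),
                            replace(schedule, seed=_sub_seed(run_seed, 3)))
            accs[f"C3DTrans_{tag}"].append(lt_accuracy(enc_sup, clips, run_seed))
            accs[f"SSC3DTrans_{tag}"].append(lt_accuracy(enc_ss, clips, run_seed))

    mean = {k: float(np.mean(v)) for k, v in accs.items()}
    return {
        **{f"acc_{k}": v for k, v in mean.items()},
        "drop_C3DTrans": mean["C3DTrans_100"] - mean["C3DTrans_60"],
        "drop_SSC3DTrans": mean["SSC3DTrans_100"] - mean["SSC3DTrans_60"],
        "per_seed": accs,
        "n_seeds": n_seeds,
    }
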