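"""Grammar-driven synthetic gesture videos.

Each trial renders a fixed gesture grammar (mirroring the ideal orderings of
the two box-trainer tasks: a 10-element sequence over 5 gestures for the
peg-transfer-like task, a 4-element sequence over 4 gestures for the
knot-tying-like task).  Every gesture class is a *motion primitive* — a
constant-velocity sweep, a circular orbit, a vertical oscillation, a
grow–shrink pulsation — applied to an identical-looking bright disc on a dark
background, so classes are separable from how the object moves, not from any
single frame.  Durations are drawn per instance, and additive Gaussian pixel
noise (clipped to [0, 1]) decorrelates repeated gestures.

Frames are produced directly on the subsampled timeline (nominal 5 fps), so
decomposition configs for synthetic data use ``subsample_factor=1``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .decomposition import FrameSequence, GestureTranscript

PRIMITIVES = ("sweep_e", "sweep_w", "sweep_ne", "circle", "oscillate_v",
              "oscillate_h", "pulse")


@dataclass
class GestureClassSpec:
    """One gesture class: a named motion primitive plus a duration range."""

    name: str
    primitive: str
    duration_range: tuple[int, int] = (15, 45)
    reverse_time: bool = False  # render the primitive, then flip frame order

    def __post_init__(self):
        if self.primitive not in PRIMITIVES:
            raise ValueError(f"unknown primitive {self.primitive!r}")
        lo, hi = self.duration_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad duration range {self.duration_range}")


@dataclass
class SyntheticTaskSpec:
    """A synthetic task: vocabulary, grammar and rendering parameters."""

    name: str
    classes: list[GestureClassSpec]
    grammar: list[int]
    frame_size: int = 64
    object_radius: float = 6.0
    intensity: float = 0.85
    background: float = 0.10
    noise: float = 0.02
    fps: float = 5.0

    def __post_init__(self):
        self.validate()

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def validate(self, min_trainable_duration: int = 15) -> None:
        problems = []
        if not self.classes:
            problems.append("no gesture classes")
        if not self.grammar:
            problems.append("empty grammar")
        for g in self.grammar:
            if not (0 <= g < len(self.classes)):
                problems.append(f"grammar element {g} outside vocabulary")
        if self.grammar and not any(
            self.classes[g].duration_range[0] >= min_trainable_duration
            for g in self.grammar if 0 <= g < len(self.classes)
        ):
            problems.append(
                f"no grammar gesture guarantees duration >= {min_trainable_duration}"
            )
        if not (0.0 <= self.noise < 0.5):
            problems.append(f"noise level {self.noise} outside [0, 0.5)")
        if self.frame_size < 16:
            problems.append("frame_size < 16")
        if problems:
            raise ValueError("invalid synthetic task spec: " + "; ".join(problems))


def pt_like_spec(**overrides) -> SyntheticTaskSpec:
    """Five-class task with the 10-element peg-transfer-style grammar.

    Vocabulary order: reach-left, reach-right, transfer, place-left,
    place-right; the grammar interleaves reaches and placements with two
    transfers, as in the ideal task ordering.
    """
    classes = [
        GestureClassSpec("RP(L)", "sweep_e"),
        GestureClassSpec("RP(R)", "sweep_w"),
        GestureClassSpec("TP", "circle"),
        GestureClassSpec("PP(L)", "oscillate_v"),
        GestureClassSpec("PP(R)", "pulse"),
    ]
    grammar = [0, 3, 1, 4, 0, 2, 4, 1, 2, 3]
    return replace(SyntheticTaskSpec("PT", classes, grammar), **overrides)


def kt_like_spec(**overrides) -> SyntheticTaskSpec:
    """Four-class task with the linear knot-tying-style grammar."""
    classes = [
        GestureClassSpec("RN", "sweep_ne"),
        GestureClassSpec("ON", "circle"),
        GestureClassSpec("CL", "oscillate_h"),
        GestureClassSpec("PS", "pulse"),
    ]
    return replace(SyntheticTaskSpec("KT", classes, [0, 1, 2, 3]), **overrides)


def make_motion_only_pair(frame_size: int = 64, duration_range: tuple[int, int] = (15, 45),
                          noise: float = 0.02) -> SyntheticTaskSpec:
    """Two classes with identical per-frame appearance: a left-to-right sweep
    and the *same frames in reverse order*.

    Any single frame carries no class information by construction; only the
    temporal direction distinguishes the classes.
    """
    classes = [
        GestureClassSpec("sweep_fwd", "sweep_e", duration_range),
        GestureClassSpec("sweep_rev", "sweep_e", duration_range, reverse_time=True),
    ]
    return SyntheticTaskSpec("MOTION2", classes, [0, 1, 0, 1, 0, 1],
                             frame_size=frame_size, noise=noise)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _render_disc(frames: np.ndarray, xs, ys, radii, intensity: float) -> None:
    """Draw a soft-edged disc per frame (in place)."""
    size = frames.shape[1]
    grid = np.arange(size, dtype=np.float32)
    for i in range(len(frames)):
        dy = grid[:, None] - ys[i]
        dx = grid[None, :] - xs[i]
        dist = np.sqrt(dx * dx + dy * dy)
        mask = np.clip(radii[i] + 0.5 - dist, 0.0, 1.0)
        frames[i] += intensity * mask[:, :, None]


def _primitive_track(primitive: str, duration: int, size: int, radius: float,
                     rng: np.random.Generator):
    """Return per-frame (x, y, r) for one gesture instance."""
    u = np.arange(duration, dtype=np.float32) / max(duration - 1, 1)  # phase in [0, 1]
    m = radius + 2.0  # margin keeping the object inside the frame
    lo, hi = m, max(size - 1 - m, m)  # degenerate (tiny frame): centre track
    r = np.full(duration, radius, dtype=np.float32)
    if primitive in ("sweep_e", "sweep_w"):
        y = np.full(duration, rng.uniform(lo, hi), dtype=np.float32)
        x = lo + u * (hi - lo)
        if primitive == "sweep_w":
            x = hi - u * (hi - lo)
        return x, y, r
    if primitive == "sweep_ne":
        x = lo + u * (hi - lo)
        y = hi - u * (hi - lo)
        return x, y, r
    if primitive == "circle":
        cx = rng.uniform(size * 0.4, size * 0.6)
        cy = rng.uniform(size * 0.4, size * 0.6)
        rho = rng.uniform(size * 0.18, size * 0.28)
        a0 = rng.uniform(0.0, 2 * np.pi)
        x = np.clip(cx + rho * np.cos(a0 + 2 * np.pi * u), lo, hi)
        y = np.clip(cy + rho * np.sin(a0 + 2 * np.pi * u), lo, hi)
        return x.astype(np.float32), y.astype(np.float32), r
    if primitive in ("oscillate_v", "oscillate_h"):
        fixed = np.full(duration, rng.uniform(lo, hi), dtype=np.float32)
        center = rng.uniform(size * 0.35, size * 0.65)
        amp = rng.uniform(size * 0.15, size * 0.25)
        wave = np.clip(center + amp * np.sin(2 * np.pi * 2 * u), lo, hi).astype(np.float32)
        return (fixed, wave, r) if primitive == "oscillate_v" else (wave, fixed, r)
    if primitive == "pulse":
        plo, phi = lo + radius, max(hi - radius, lo + radius)
        x = np.full(duration, rng.uniform(plo, phi), dtype=np.float32)
        y = np.full(duration, rng.uniform(plo, phi), dtype=np.float32)
        r = radius * (1.0 + 0.7 * np.sin(2 * np.pi * 1.5 * u)).astype(np.float32)
        return x, y, np.clip(r, 1.5, None)
    raise ValueError(f"unknown primitive {primitive!r}")


def render_gesture(cls: GestureClassSpec, duration: int, spec: SyntheticTaskSpec,
                   rng: np.random.Generator) -> np.ndarray:
    """Noise-free frames (duration, S, S, 3) of one gesture instance."""
    size = spec.frame_size
    frames = np.full((duration, size, size, 3), spec.background, dtype=np.float32)
    x, y, r = _primitive_track(cls.primitive, duration, size, spec.object_radius, rng)
    _render_disc(frames, x, y, r, spec.intensity - spec.background)
    if cls.reverse_time:
        frames = frames[::-1].copy()
    return frames


def generate_trial(spec: SyntheticTaskSpec, seed: int | np.random.Generator,
                   trial_id: str = "trial_000") -> tuple[FrameSequence, GestureTranscript]:
    """Render one trial following the spec's grammar; reproducible from seed."""
    spec.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chunks, intervals, cursor = [], [], 0
    for cls_idx in spec.grammar:
        cls = spec.classes[cls_idx]
        lo, hi = cls.duration_range
        duration = int(rng.integers(lo, hi + 1))
        chunks.append(render_gesture(cls, duration, spec, rng))
        intervals.append((cursor, cursor + duration, cls_idx))
        cursor += duration
    frames = np.concatenate(chunks, axis=0)
    if spec.noise > 0:
        frames = frames + rng.normal(0.0, spec.noise, size=frames.shape).astype(np.float32)
    frames = np.clip(frames, 0.0, 1.0)
    seq = FrameSequence(trial_id=trial_id, task_id=spec.name, frames=frames, fps=spec.fps)
    transcript = GestureTranscript(trial_id=trial_id, task_id=spec.name, intervals=intervals)
    return seq, transcript


def generate_dataset(spec: SyntheticTaskSpec, n_trials: int = 40, seed: int = 0
                     ) -> list[tuple[FrameSequence, GestureTranscript]]:
    """n_trials independent trials with per-trial seeds spawned from the master seed."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_trials)
    return [
        generate_trial(spec, np.random.default_rng(children[i]),
                       trial_id=f"{spec.name}_{i:03d}")
        for i in range(n_trials)
    ]


def export_trial_png(seq: FrameSequence, out_dir: str | Path) -> Path:
    """Write a trial as a directory of numbered PNG frames."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        iio.imwrite(out_dir / f"frame_{i:05d}.png",
                    (np.clip(frame, 0, 1) * 255).astype(np.uint8))
    return out_dir
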