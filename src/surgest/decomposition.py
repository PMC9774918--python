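"""Video preprocessing and two-level decomposition into clips and volumes.

A trial video is subsampled in time (25 -> 5 fps by default), rescaled to a
fixed spatial size and split into overlapping *clips* (TL frames, advancing
by ``clip_step``), each of which decomposes into overlapping *volumes*
(TS frames, advancing by ``volume_step``).  Clips are the unit of gesture
classification; volumes are the input unit of the short-term 3D encoder.

Conventions used throughout the package: frame indices are 0-based on the
SUBSAMPLED timeline, and annotation intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

logger = logging.getLogger(__name__)

TRANSCRIPT_COLUMNS = ["trial_id", "task", "start_frame", "end_frame", "label"]


@dataclass
class DecompositionConfig:
    """Clip/volume geometry.

    Defaults: 15-frame clips every 3 frames, 8-frame volumes every frame
    (so NS = 8 volumes per clip), 224x224 frames, 5-fold temporal
    subsampling (25 -> 5 fps).
    """

    tl: int = 15
    ts: int = 8
    clip_step: int = 3
    volume_step: int = 1
    width: int = 224
    height: int = 224
    subsample_factor: int = 5

    def __post_init__(self):
        if not (1 <= self.ts <= self.tl):
            raise ValueError(f"need 1 <= TS <= TL, got TS={self.ts}, TL={self.tl}")
        if self.clip_step < 1 or self.volume_step < 1 or self.subsample_factor < 1:
            raise ValueError("steps and subsample factor must be >= 1")
        if self.ns < 1:
            raise ValueError("derived NS must be >= 1")

    @property
    def ns(self) -> int:
        """Number of volumes per clip."""
        return (self.tl - self.ts) // self.volume_step + 1


@dataclass
class FrameSequence:
    """A trial's preprocessed frames: (N, H, W, C) float32 in [0, 1]."""

    trial_id: str
    task_id: str
    frames: np.ndarray
    fps: float = 5.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 4 or len(self.frames) < 1:
            raise ValueError("frames must be a non-empty (N, H, W, C) array")
        lo, hi = float(self.frames.min()), float(self.frames.max())
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValueError(f"pixel values must lie in [0, 1]; got range [{lo}, {hi}]")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class Clip:
    trial_id: str
    start_frame: int
    frames: np.ndarray  # (TL, H, W, C), a view into the parent sequence
    label: int | None = None


@dataclass
class Volume:
    trial_id: str
    start_frame: int  # absolute index into the subsampled sequence
    frames: np.ndarray  # (TS, H, W, C)
    label: int | None = None


@dataclass
class GestureTranscript:
    """Annotated gesture intervals of one trial, half-open [start, end)."""

    trial_id: str
    task_id: str
    intervals: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self):
        prev_end = None
        for s, e, _ in self.intervals:
            if s >= e:
                raise ValueError(f"empty or inverted interval [{s}, {e}) in {self.trial_id}")
        for s0, e0, _ in self.intervals:
            for s1, e1, _ in self.intervals:
                if (s0, e0) != (s1, e1) and s0 < e1 and s1 < e0:
                    raise ValueError(f"overlapping intervals in {self.trial_id}")
        del prev_end

    @property
    def labels(self) -> list[int]:
        return [g for _, _, g in self.intervals]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def subsample_and_rescale(raw_frames: Sequence[np.ndarray] | np.ndarray,
                          config: DecompositionConfig,
                          trial_id: str = "trial",
                          task_id: str = "custom",
                          raw_fps: float = 25.0) -> FrameSequence:
    """Keep every k-th raw frame, resize to (H, W), scale pixels to [0, 1].

    Grayscale frames are replicated to three channels.
    """
    n_raw = len(raw_frames)
    if n_raw < 1:
        raise ValueError("no frames in input")
    k = config.subsample_factor
    kept = []
    for idx in range(0, n_raw, k):
        frame = np.asarray(raw_frames[idx])
        if frame.dtype == np.uint8:
            frame = frame.astype(np.float32) / 255.0
        else:
            frame = frame.astype(np.float32)
        if frame.ndim == 2:
            frame = np.repeat(frame[:, :, None], 3, axis=2)
        elif frame.shape[2] == 1:
            frame = np.repeat(frame, 3, axis=2)
        if frame.shape[:2] != (config.height, config.width):
            frame = resize(frame, (config.height, config.width), order=1,
                           preserve_range=True, anti_aliasing=False)
        kept.append(np.clip(frame, 0.0, 1.0).astype(np.float32))
    return FrameSequence(trial_id=trial_id, task_id=task_id,
                         frames=np.stack(kept), fps=raw_fps / k)


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def extract_clips(seq: FrameSequence, config: DecompositionConfig) -> list[Clip]:
    """Clips at starts 0, clip_step, 2*clip_step, ...; trailing frames dropped."""
    n = len(seq)
    if n < config.tl:
        return []
    return [
        Clip(seq.trial_id, s, seq.frames[s : s + config.tl])
        for s in range(0, n - config.tl + 1, config.clip_step)
    ]


def extract_volumes(clip: Clip, config: DecompositionConfig) -> list[Volume]:
    """The NS volumes of a clip, at relative offsets 0, volume_step, ..."""
    tl = len(clip.frames)
    if config.ts > tl:
        raise ValueError(f"volume length TS={config.ts} exceeds clip length {tl}")
    return [
        Volume(clip.trial_id, clip.start_frame + off,
               clip.frames[off : off + config.ts], label=clip.label)
        for off in range(0, tl - config.ts + 1, config.volume_step)
    ]


def label_clips_from_transcript(seq: FrameSequence, transcript: GestureTranscript,
                                config: DecompositionConfig) -> list[Clip]:
    """Extract labeled clips independently within each annotated interval.

    Clip extraction restarts at every interval start, so no clip ever
    straddles a gesture boundary; intervals shorter than TL contribute
    nothing (logged).
    """
    n = len(seq)
    clips: list[Clip] = []
    for (start, end, gesture) in transcript.intervals:
        if start < 0 or end > n:
            raise ValueError(
                f"interval [{start}, {end}) of trial {transcript.trial_id} "
                f"exceeds sequence length {n}"
            )
        if end - start < config.tl:
            logger.warning(
                "interval [%d, %d) of trial %s shorter than TL=%d; no clips",
                start, end, transcript.trial_id, config.tl,
            )
            continue
        for s in range(start, end - config.tl + 1, config.clip_step):
            clips.append(Clip(seq.trial_id, s, seq.frames[s : s + config.tl], label=gesture))
    return clips


def next_frame_pairs(seq: FrameSequence,
                     config: DecompositionConfig,
                     stride: int = 1) -> list[tuple[Volume, np.ndarray]]:
    """(volume, successor frame) pairs for the next-frame pretext task.

    Volumes are drawn from the whole sequence without labels; the last
    volume (no successor) is excluded.  ``stride`` thins the pair list for
    scaled-down training runs (1 keeps every volume start).
    """
    n = len(seq)
    ts = config.ts
    pairs = []
    for s in range(0, n - ts, stride):
        pairs.append((Volume(seq.trial_id, s, seq.frames[s : s + ts]), seq.frames[s + ts]))
    return pairs


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"(\d+)")


def _numeric_key(path: Path):
    m = _NUM_RE.findall(path.stem)
    return (int(m[-1]) if m else 0, path.name)


def load_frame_dir(path: str | Path) -> list[np.ndarray]:
    """Load a directory of numerically ordered PNG/JPEG frames."""
    path = Path(path)
    files = sorted(
        (p for p in path.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg"}),
        key=_numeric_key,
    )
    if not files:
        raise ValueError(f"no image frames found in {path}")
    return [iio.imread(p) for p in files]


def load_video(path: str | Path) -> list[np.ndarray]:
    """Load frames from a video container, if an imageio plugin can decode it."""
    try:
        return list(iio.imiter(path))
    except Exception as exc:  # pragma: no cover - depends on installed plugins
        raise RuntimeError(
            f"could not decode {path}: no suitable imageio plugin; "
            "provide a directory of PNG/JPEG frames instead"
        ) from exc


def write_transcripts_csv(transcripts: Iterable[GestureTranscript], path: str | Path) -> None:
    """CSV with header trial_id,task,start_frame,end_frame,label.

    Coordinates are subsampled-timeline, 0-based, half-open (stated in a
    leading comment line).
    """
    rows = [
        {"trial_id": t.trial_id, "task": t.task_id,
         "start_frame": s, "end_frame": e, "label": g}
        for t in transcripts for (s, e, g) in t.intervals
    ]
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# frame coordinates: subsampled timeline, 0-based, half-open [start, end)\n")
        pd.DataFrame(rows, columns=TRANSCRIPT_COLUMNS).to_csv(fh, index=False)


def read_transcripts_csv(path: str | Path) -> list[GestureTranscript]:
    df = pd.read_csv(path, comment="#")
    out = []
    for (trial, task), grp in df.groupby(["trial_id", "task"], sort=False):
        intervals = [
            (int(r.start_frame), int(r.end_frame), int(r.label))
            for r in grp.itertuples()
        ]
        out.append(GestureTranscript(str(trial), str(task), intervals))
    return out


def write_transcripts_json(transcripts: Iterable[GestureTranscript], path: str | Path) -> None:
    payload = [
        {"trial_id": t.trial_id, "task": t.task_id,
         "intervals": [{"start_frame": s, "end_frame": e, "label": g}
                       for (s, e, g) in t.intervals]}
        for t in transcripts
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_transcripts_json(path: str | Path) -> list[GestureTranscript]:
    payload = json.loads(Path(path).read_text())
    return [
        GestureTranscript(
            str(t["trial_id"]), str(t["task_id"]) if "task_id" in t else str(t.get("task", "custom")),
            [(int(i["start_frame"]), int(i["end_frame"]), int(i["label"]))
             for i in t["intervals"]],
        )
        for t in payload
    ]
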