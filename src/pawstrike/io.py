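"""Clip and sidecar-file I/O.

A 1-s clip of wheel-cage video is represented as a :class:`FrameStack`:
30 grayscale frames at 30 frames/s, intensities normalized to [0, 1].
Clips arrive either from a video file (segmented into consecutive
non-overlapping seconds) or from the synthetic renderer.  Labels (integer
foot strikes per second, i.e. Hz) and per-minute wheel-turn counts travel
in UTF-8 comma-delimited CSV sidecars.

Lossless containers (multi-page TIFF, NPZ) are first-class and round-trip
bit-exactly; AVI/MP4 are decoded through imageio when a suitable plugin is
present and rejected with a typed error otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FPS = 30  # frames per second; one FrameStack is exactly one second

__all__ = [
    "FPS",
    "FrameStack",
    "LabeledClip",
    "WheelTurnSeries",
    "SchemaError",
    "VideoFormatError",
    "FrameRateError",
    "read_video_as_clips",
    "load_labels",
    "load_wheel_counts",
    "write_labels",
    "write_wheel_counts",
    "save_clip",
    "load_clip",
    "save_dataset",
    "load_dataset",
]


class SchemaError(ValueError):
    """A CSV sidecar violates its schema; the message names the offense."""


class VideoFormatError(IOError):
    """The file cannot be decoded into frames in this environment."""


class FrameRateError(ValueError):
    """Source frame rate differs from the expected rate; no silent resampling."""


@dataclass
class FrameStack:
    """One second of video: a (30, height, width) intensity grid in [0, 1].

    ``origin`` records provenance as (source id, 0-based start-second
    index); the clip covers the half-open interval [t, t+1) seconds.
    """

    pixels: np.ndarray
    fps: int = FPS
    origin: tuple[str, int] = ("", 0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[0] != self.fps:
            raise ValueError(
                f"FrameStack needs shape ({self.fps}, H, W), got {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("non-finite pixel values")
        lo, hi = float(self.pixels.min(initial=0.0)), float(self.pixels.max(initial=0.0))
        if lo < 0.0 or hi > 1.0 + 1e-6:
            raise ValueError(f"pixel intensities must lie in [0, 1], got [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


@dataclass
class LabeledClip:
    """A FrameStack with its integer foot-strike-frequency label (Hz)."""

    stack: FrameStack
    label: int
    mouse_id: str = ""
    bout_id: str = ""

    def __post_init__(self) -> None:
        if int(self.label) != self.label or self.label < 0:
            raise ValueError(f"label must be a nonnegative integer Hz, got {self.label}")
        self.label = int(self.label)


@dataclass
class WheelTurnSeries:
    """Per-minute wheel-turn counts for one 2-h bout (120 minutes)."""

    bout_id: str
    turns: np.ndarray

    def __post_init__(self) -> None:
        self.turns = np.asarray(self.turns, dtype=np.int64)
        if self.turns.ndim != 1:
            raise ValueError("turns must be a 1-D per-minute series")
        if np.any(self.turns < 0):
            raise ValueError("wheel-turn counts must be nonnegative")

    @property
    def n_minutes(self) -> int:
        return len(self.turns)


# ---------------------------------------------------------------------------
# video -> FrameStacks


def _to_gray01(frames: np.ndarray) -> np.ndarray:
    """Collapse color to luminance and normalize integer intensities to [0,1]."""
    frames = np.asarray(frames)
    if np.issubdtype(frames.dtype, np.integer):
        frames = frames.astype(np.float32) / np.iinfo(frames.dtype).max
    if frames.ndim == 4:  # (t, h, w, c)
        if frames.shape[-1] == 1:
            frames = frames[..., 0]
        else:
            weights = np.array([0.299, 0.587, 0.114], dtype=np.float64)
            frames = frames[..., :3] @ weights
    return np.clip(frames.astype(np.float32), 0.0, 1.0)


def _resize_area(frames: np.ndarray, target_size: tuple[int, int]) -> np.ndarray:
    """Downscale with local-mean (area) interpolation to avoid aliasing."""
    th, tw = target_size
    t, h, w = frames.shape
    if (h, w) == (th, tw):
        return frames
    if h % th == 0 and w % tw == 0:
        fh, fw = h // th, w // tw
        return frames.reshape(t, th, fh, tw, fw).mean(axis=(2, 4))
    from skimage.transform import resize

    out = resize(
        frames.transpose(1, 2, 0), (th, tw), order=1, anti_aliasing=(th < h or tw < w),
        preserve_range=True,
    ).transpose(2, 0, 1)
    return out.astype(np.float32)


def _read_frames(path: Path) -> tuple[np.ndarray, float | None]:
    """All frames of a file as an array, plus the container fps if declared."""
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        import tifffile

        return tifffile.imread(path), None
    if suffix in {".npz"}:
        with np.load(path, allow_pickle=False) as z:
            return z["frames"], float(z["fps"]) if "fps" in z else None
    if suffix in {".npy"}:
        return np.load(path, allow_pickle=False), None
    if suffix in {".avi", ".mp4", ".mov", ".mkv"}:
        import imageio.v2 as iio

        try:
            reader = iio.get_reader(path)
        except Exception as exc:  # plugin missing or undecodable stream
            raise VideoFormatError(
                f"cannot decode {path.name}: no ffmpeg-capable imageio plugin "
                f"is available ({exc})"
            ) from exc
        meta = reader.get_meta_data()
        frames = np.stack([np.asarray(f) for f in reader])
        reader.close()
        return frames, meta.get("fps")
    raise VideoFormatError(f"unsupported container: {path.name}")


def read_video_as_clips(
    path,
    target_size: tuple[int, int] | None = None,
    fps_expected: int = FPS,
) -> list[FrameStack]:
    """Segment a video file into consecutive non-overlapping 1-s FrameStacks.

    Frames are collapsed to grayscale, resized (area interpolation) and
    normalized to [0, 1].  A trailing partial second is dropped and logged.
    The source frame rate must equal ``fps_expected``; mismatches raise
    :class:`FrameRateError` rather than silently resampling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frames, declared_fps = _read_frames(path)
    if declared_fps is not None and round(declared_fps) != fps_expected:
        raise FrameRateError(
            f"{path.name}: source rate {declared_fps} fps != expected {fps_expected} fps"
        )
    frames = _to_gray01(frames)
    if target_size is not None:
        frames = _resize_area(frames, target_size)
    n_full = frames.shape[0] // fps_expected
    dropped = frames.shape[0] - n_full * fps_expected
    if dropped:
        logger.warning("%s: dropped %d trailing frames (< 1 s)", path.name, dropped)
    return [
        FrameStack(
            frames[t * fps_expected : (t + 1) * fps_expected],
            fps=fps_expected,
            origin=(path.stem, t),
        )
        for t in range(n_full)
    ]


# ---------------------------------------------------------------------------
# label CSVs: clip_id,mouse_id,bout_id,second_index,freq_hz

LABEL_COLUMNS = ["clip_id", "mouse_id", "bout_id", "second_index", "freq_hz"]


def load_labels(path, n_classes: int | None = None) -> pd.DataFrame:
    """Validated label records from a CSV sidecar.

    Raises :class:`SchemaError` for a missing column, a non-integer or
    negative label, a label at or above ``n_classes``, or duplicate
    clip ids — naming the offending row.
    """
    df = pd.read_csv(path, dtype={"clip_id": str, "mouse_id": str, "bout_id": str})
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        return df[LABEL_COLUMNS]
    freq = pd.to_numeric(df["freq_hz"], errors="coerce")
    bad = df.index[freq.isna() | (freq != freq.round()) | (freq < 0)]
    if len(bad):
        raise SchemaError(
            f"{path}: row {bad[0]}: freq_hz={df.loc[bad[0], 'freq_hz']!r} "
            "is not a nonnegative integer"
        )
    df["freq_hz"] = freq.astype(int)
    if n_classes is not None:
        over = df.index[df["freq_hz"] >= n_classes]
        if len(over):
            raise SchemaError(
                f"{path}: row {over[0]}: label {df.loc[over[0], 'freq_hz']} "
                f">= n_classes={n_classes}"
            )
    dup = df["clip_id"].duplicated()
    if dup.any():
        raise SchemaError(
            f"{path}: row {dup.idxmax()}: duplicate clip_id {df.loc[dup.idxmax(), 'clip_id']!r}"
        )
    return df[LABEL_COLUMNS]


def write_labels(records: Iterable[dict] | pd.DataFrame, path) -> None:
    df = pd.DataFrame(records)
    df[LABEL_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# wheel-turn CSVs: bout_id,minute_index,turns


def load_wheel_counts(path) -> list[WheelTurnSeries]:
    """Per-bout wheel-turn series; gaps become 0-turn minutes, with a log line."""
    df = pd.read_csv(path, dtype={"bout_id": str})
    for col in ("bout_id", "minute_index", "turns"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    if (df["turns"] < 0).any():
        row = int(df.index[df["turns"] < 0][0])
        raise SchemaError(f"{path}: row {row}: negative turn count")
    out = []
    for bout_id, grp in df.groupby("bout_id", sort=True):
        n_minutes = int(grp["minute_index"].max()) + 1
        turns = np.zeros(n_minutes, dtype=np.int64)
        turns[grp["minute_index"].to_numpy(dtype=int)] = grp["turns"].to_numpy(dtype=int)
        if len(grp) < n_minutes:
            logger.warning(
                "%s: bout %s has %d missing minute(s), filled with 0",
                path, bout_id, n_minutes - len(grp),
            )
        out.append(WheelTurnSeries(bout_id=str(bout_id), turns=turns))
    return out


def write_wheel_counts(series: Sequence[WheelTurnSeries], path) -> None:
    rows = [
        {"bout_id": s.bout_id, "minute_index": m, "turns": int(t)}
        for s in series
        for m, t in enumerate(s.turns)
    ]
    pd.DataFrame(rows, columns=["bout_id", "minute_index", "turns"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# lossless clip containers


def save_clip(stack: FrameStack, path) -> None:
    """Write one clip losslessly (.tif multi-page or .npz)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, stack.pixels.astype(np.float32))
    elif path.suffix.lower() == ".npz":
        np.savez_compressed(path, frames=stack.pixels.astype(np.float32), fps=stack.fps)
    else:
        raise VideoFormatError(f"unsupported output container: {path.name}")


def load_clip(path) -> FrameStack:
    clips = read_video_as_clips(path)
    if len(clips) != 1:
        raise VideoFormatError(f"{path}: expected exactly one 1-s clip")
    return clips[0]


def save_dataset(clips: Sequence[LabeledClip], out_dir) -> Path:
    """Write clips as one NPZ plus the label CSV; returns the label path.

    The NPZ holds a single (n, 30, H, W) float32 array; the CSV carries
    clip_id, provenance and the ground-truth frequency of each clip.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pixels = np.stack([c.stack.pixels for c in clips]).astype(np.float32)
    np.savez_compressed(out_dir / "clips.npz", clips=pixels, fps=FPS)
    records = [
        {
            "clip_id": f"clip{idx:05d}",
            "mouse_id": c.mouse_id,
            "bout_id": c.bout_id,
            "second_index": c.stack.origin[1],
            "freq_hz": c.label,
        }
        for idx, c in enumerate(clips)
    ]
    label_path = out_dir / "labels.csv"
    write_labels(records, label_path)
    return label_path


def load_dataset(data_dir, n_classes: int | None = None) -> list[LabeledClip]:
    data_dir = Path(data_dir)
    with np.load(data_dir / "clips.npz", allow_pickle=False) as z:
        pixels = z["clips"]
    labels = load_labels(data_dir / "labels.csv", n_classes=n_classes)
    if len(labels) != len(pixels):
        raise SchemaError(
            f"{data_dir}: {len(pixels)} clips but {len(labels)} label rows"
        )
    return [
        LabeledClip(
            stack=FrameStack(
                pixels[i], origin=(row.clip_id, int(row.second_index))
            ),
            label=int(row.freq_hz),
            mouse_id=row.mouse_id,
            bout_id=row.bout_id,
        )
        for i, row in enumerate(labels.itertuples(index=False))
    ]
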