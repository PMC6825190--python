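"""Ordered color frame sequences and lossless frame-directory I/O.

A :class:`FrameSequence` is the raw input to marker tracking: an ordered stack
of H x W x 3 RGB frames (uint8, 0-255) with a frame rate and per-frame
timestamps. The canonical on-disk representation is a directory of
zero-padded PNG files plus a ``frames.json`` sidecar carrying the frame rate
and any metadata (including synthetic ground truth); PNG round-trips pixels
exactly. Lossy video containers (MP4/AVI) are accepted for *reading* only,
through imageio, when an ffmpeg plugin is available.

Pixel coordinate convention throughout the package: 0-based, x = column
increasing rightwards, y = row increasing downwards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v2 as iio
import numpy as np

from .exceptions import EmptyInputError, FormatError

_SIDECAR_NAME = "frames.json"


@dataclass
class FrameSequence:
    """An ordered stack of RGB frames with timing information.

    Parameters
    ----------
    pixels : ndarray, shape (n_frames, height, width, 3), uint8
        Frame data in RGB channel order.
    frame_rate : float
        Frames per second; must be positive.
    timestamps : ndarray, shape (n_frames,), optional
        Seconds from start; defaults to ``arange(n) / frame_rate``.
        Must be strictly increasing.
    metadata : dict
        Free-form sidecar payload (e.g. ``pixels_per_mm``, synthetic ground
        truth). Serialised alongside the frames on write.
    """

    pixels: np.ndarray
    frame_rate: float
    timestamps: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4 or self.pixels.shape[-1] != 3:
            raise FormatError(
                f"expected (n, h, w, 3) frame stack, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise FormatError(f"frames must be uint8, got {self.pixels.dtype}")
        if len(self.pixels) == 0:
            raise EmptyInputError("frame sequence contains no frames")
        if not self.frame_rate > 0:
            raise FormatError("frame_rate must be positive")
        if self.timestamps is None:
            self.timestamps = np.arange(len(self.pixels)) / self.frame_rate
        else:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != (len(self.pixels),):
                raise FormatError("one timestamp per frame required")
            if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
                raise FormatError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.pixels)

    @property
    def frame_shape(self) -> tuple[int, int]:
        """(height, width) of every frame."""
        return self.pixels.shape[1], self.pixels.shape[2]

    def __len__(self) -> int:
        return len(self.pixels)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.pixels[i]


def write_frames(frames: FrameSequence, path: str | Path) -> Path:
    """Write a sequence losslessly as numbered PNGs plus a JSON sidecar.

    Returns the directory path. Pixel values round-trip exactly through
    :func:`read_frames`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    width = max(6, len(str(frames.n_frames - 1)))
    for i, frame in enumerate(frames.pixels):
        iio.imwrite(path / f"frame_{i:0{width}d}.png", frame)
    sidecar = {
        "frame_rate": frames.frame_rate,
        "n_frames": frames.n_frames,
        "timestamps": frames.timestamps.tolist(),
        "metadata": frames.metadata,
    }
    (path / _SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1))
    return path


def read_frames(path: str | Path, frame_rate: float | None = None) -> FrameSequence:
    """Read a frame directory (lossless) or a video file (lossy containers).

    For directories, ``frames.json`` supplies the frame rate and metadata when
    present; otherwise ``frame_rate`` must be given. For video files the
    container's reported rate is used unless overridden.
    """
    path = Path(path)
    if path.is_dir():
        return _read_frame_directory(path, frame_rate)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    return _read_video(path, frame_rate)


def _read_frame_directory(path: Path, frame_rate: float | None) -> FrameSequence:
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff", ".bmp"}
    )
    if not files:
        raise EmptyInputError(f"no image files in {path}")
    stack = []
    for p in files:
        img = np.asarray(iio.imread(p))
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        if img.shape[-1] == 4:  # drop alpha
            img = img[..., :3]
        stack.append(img)
    shapes = {a.shape for a in stack}
    if len(shapes) > 1:
        raise FormatError(f"frames of differing sizes in {path}: {sorted(shapes)}")
    pixels = np.stack(stack).astype(np.uint8)

    metadata: dict = {}
    timestamps = None
    sidecar = path / _SIDECAR_NAME
    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        frame_rate = frame_rate or payload.get("frame_rate")
        metadata = payload.get("metadata", {})
        if payload.get("timestamps") is not None:
            timestamps = np.asarray(payload["timestamps"], dtype=float)
            if len(timestamps) != len(pixels):
                timestamps = None  # sidecar stale relative to files on disk
    if frame_rate is None:
        raise FormatError(
            f"no frame rate: {path} has no {_SIDECAR_NAME} and none was supplied"
        )
    return FrameSequence(pixels, float(frame_rate), timestamps, metadata)


def _read_video(path: Path, frame_rate: float | None) -> FrameSequence:
    try:
        reader = iio.get_reader(path)
    except Exception as exc:  # missing plugin or corrupt container
        raise FormatError(f"cannot read video {path}: {exc}") from exc
    with reader:
        meta = reader.get_meta_data()
        stack = [np.asarray(f)[..., :3] for f in reader]
    if not stack:
        raise EmptyInputError(f"video {path} contains no frames")
    if len({a.shape for a in stack}) > 1:
        raise FormatError(f"video {path} has frames of differing sizes")
    rate = frame_rate or meta.get("fps")
    if rate is None:
        raise FormatError(f"video {path} reports no frame rate and none was supplied")
    return FrameSequence(np.stack(stack).astype(np.uint8), float(rate))
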