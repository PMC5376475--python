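"""Frame loading, smoothing and frame-difference foreground detection.

The segmentation pipeline watches an operating room with several wall-mounted,
synchronized cameras.  Everything downstream works on per-camera grayscale
frame sequences: frames are smoothed with a small Gaussian filter to suppress
sensor noise, and the moving foreground (staff, instruments, materials) is
detected by thresholding the absolute difference between consecutive smoothed
frames.  Frame differencing only fires on the *contour* of moving objects,
which turns out to be exactly the support on which optical-flow words are
informative.

Alternative foreground detectors (e.g. codebook-based texture/colour models)
can be supplied through the :class:`ForegroundDetector` protocol.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import imageio.v2 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "FrameSequence",
    "ForegroundMask",
    "ForegroundDetector",
    "FrameDiffDetector",
    "SynchronizationError",
    "load_frame_sequences",
    "to_grayscale",
    "gaussian_kernel",
    "gaussian_blur",
    "frame_difference_mask",
]

#: ITU-R BT.601 luma weights used for colour -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


class SynchronizationError(ValueError):
    """Raised when per-camera sources disagree on frame count."""


@dataclass
class FrameSequence:
    """An ordered grayscale frame sequence from one camera.

    Parameters
    ----------
    camera_id:
        Index of the camera in ``[0, n_cameras)``.
    frames:
        Array of shape ``(n_frames, height, width)``, 8-bit intensities.
    fps:
        Frames per second of the recording (nominal 24 for the real setup).
    """

    camera_id: int
    frames: np.ndarray
    fps: int
    timestamps: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, height, width) array")
        if len(self.frames) < 2:
            raise ValueError("a frame sequence needs at least two frames")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.timestamps is None:
            self.timestamps = np.arange(len(self.frames)) / float(self.fps)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def n_seconds(self) -> int:
        """Number of whole seconds covered (trailing partial second dropped)."""
        return self.n_frames // self.fps


@dataclass
class ForegroundMask:
    """Boolean foreground map for one frame transition (True = moving)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


class ForegroundDetector(Protocol):
    """Plug-in interface: anything mapping a frame pair to a mask."""

    def __call__(self, prev: np.ndarray, curr: np.ndarray) -> ForegroundMask: ...


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert an ``(h, w)`` or ``(h, w, 3/4)`` frame to 8-bit grayscale."""
    frame = np.asarray(frame)
    if frame.ndim == 2:
        gray = frame
    elif frame.ndim == 3:
        gray = frame[..., :3] @ _LUMA
    else:
        raise ValueError(f"cannot interpret frame of shape {frame.shape}")
    return np.clip(np.round(gray), 0, 255).astype(np.uint8)


_FRAME_NUM = re.compile(r"(\d+)")


def _numeric_key(path: Path) -> tuple:
    nums = _FRAME_NUM.findall(path.stem)
    return (int(nums[-1]) if nums else 0, path.name)


def _read_source(source: str | Path) -> list[np.ndarray]:
    source = Path(source)
    if source.is_dir():
        files = sorted(
            (p for p in source.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}),
            key=_numeric_key,
        )
        if not files:
            raise IOError(f"no image frames found in {source}")
        return [to_grayscale(iio.imread(f)) for f in files]
    if not source.exists():
        raise IOError(f"source does not exist: {source}")
    try:
        reader = iio.get_reader(source)
        frames = [to_grayscale(np.asarray(im)) for im in reader]
    except Exception as exc:  # pragma: no cover - depends on codecs present
        raise IOError(f"cannot decode video source {source}: {exc}") from exc
    if not frames:
        raise IOError(f"no frames decoded from {source}")
    return frames


def load_frame_sequences(paths: Sequence[str | Path], fps: int = 24) -> list[FrameSequence]:
    """Load synchronized per-camera sources into grayscale frame sequences.

    Each entry of ``paths`` is either a directory of numbered image frames or
    a video container file.  All cameras must contribute the same number of
    frames; a mismatch raises :class:`SynchronizationError`.
    """
    all_frames = [_read_source(p) for p in paths]
    counts = {len(f) for f in all_frames}
    if len(counts) > 1:
        raise SynchronizationError(
            f"sources are not synchronized: frame counts {sorted(len(f) for f in all_frames)}"
        )
    return [
        FrameSequence(camera_id=i, frames=np.stack(frames), fps=fps)
        for i, frames in enumerate(all_frames)
    ]


def gaussian_kernel(kernel_size: int = 7, sigma: float | None = None) -> np.ndarray:
    """Normalized 2-D Gaussian kernel of odd side ``kernel_size``.

    ``sigma`` defaults to ``0.3 * ((kernel_size - 1) * 0.5 - 1) + 0.8``, the
    conventional choice that makes the kernel's effective support match its
    side length (0.8 + 0.15 * (k - 3) for odd k).
    """
    if kernel_size <= 0 or kernel_size % 2 == 0:
        raise ValueError("kernel_size must be an odd positive integer")
    if sigma is None:
        sigma = 0.3 * ((kernel_size - 1) * 0.5 - 1) + 0.8
    r = kernel_size // 2
    x = np.arange(-r, r + 1, dtype=float)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    g /= g.sum()
    return np.outer(g, g)


def gaussian_blur(frame: np.ndarray, kernel_size: int = 7, sigma: float | None = None) -> np.ndarray:
    """Smooth one frame with a ``kernel_size`` x ``kernel_size`` Gaussian.

    Border pixels use edge replication.  Returns float64; the pipeline keeps
    smoothed frames in float to avoid re-quantization before differencing.
    """
    kernel = gaussian_kernel(kernel_size, sigma)
    return ndimage.convolve(np.asarray(frame, dtype=float), kernel, mode="nearest")


def frame_difference_mask(
    prev: np.ndarray,
    curr: np.ndarray,
    diff_threshold: float = 15.0,
    morph_cleanup: bool = False,
) -> ForegroundMask:
    """Foreground = pixels whose absolute intensity change exceeds a threshold.

    ``diff_threshold`` is in intensity units out of 255.  The operation is
    symmetric in its two arguments.  ``morph_cleanup`` optionally applies a
    3x3 binary opening to remove isolated specks; off by default to keep the
    detector as plain as possible.
    """
    prev = np.asarray(prev, dtype=float)
    curr = np.asarray(curr, dtype=float)
    if prev.shape != curr.shape:
        raise ValueError(f"frame shapes differ: {prev.shape} vs {curr.shape}")
    mask = np.abs(curr - prev) > diff_threshold
    if morph_cleanup:
        mask = ndimage.binary_opening(mask, structure=np.ones((3, 3), dtype=bool))
    return ForegroundMask(mask=mask)


@dataclass
class FrameDiffDetector:
    """Frame-difference foreground detector over pre-smoothed frames."""

    diff_threshold: float = 15.0
    morph_cleanup: bool = False

    def __call__(self, prev: np.ndarray, curr: np.ndarray) -> ForegroundMask:
        return frame_difference_mask(prev, curr, self.diff_threshold, self.morph_cleanup)
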