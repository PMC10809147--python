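"""Core image containers and multi-page TIFF I/O.

The whole pipeline trades in :class:`FrameSequence` objects — a ``T x H x W``
stack of nonnegative floating-point intensities with the two pieces of
acquisition metadata every downstream stage needs: the pixel size (um) and
the frame interval (s).  Intensities are kept on the camera's native scale
after load (no rescaling to [0, 1]) because microdomain detection uses
*relative* thresholds and must see the original dynamic range.

Coordinate convention: pixel indices are 0-based ``(row, col) = (y, x)``;
a pixel's center sits at integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError

__all__ = [
    "FrameSequence",
    "ChannelPair",
    "LabelSequence",
    "read_tiff_sequence",
    "write_tiff_sequence",
    "split_dual_view",
]


@dataclass
class FrameSequence:
    """A time-lapse intensity stack.

    Parameters
    ----------
    data
        ``(T, H, W)`` array of finite, nonnegative intensities.  Cast to
        float64 on construction.
    pixel_size_um
        Lateral pixel size in micrometers (> 0).
    frame_interval_s
        Time between consecutive frames in seconds (> 0).
    t0_index
        Frame index corresponding to acquisition start (default 0).
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    t0_index: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"expected a (T, H, W) stack, got shape {self.data.shape}")
        t, h, w = self.data.shape
        if t < 1 or h < 1 or w < 1:
            raise FormatError(f"degenerate stack shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("intensities must be finite")
        if np.any(self.data < 0):
            raise FormatError("intensities must be nonnegative")
        if not (self.pixel_size_um > 0):
            raise FormatError("pixel_size_um must be > 0")
        if not (self.frame_interval_s > 0):
            raise FormatError("frame_interval_s must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def times(self) -> np.ndarray:
        """Acquisition time (s) of each frame relative to ``t0_index``."""
        return (np.arange(self.n_frames) - self.t0_index) * self.frame_interval_s

    def with_data(self, data: np.ndarray) -> "FrameSequence":
        """Copy of this sequence carrying new pixel data, same metadata."""
        return replace(self, data=np.asarray(data, dtype=float))

    def copy(self) -> "FrameSequence":
        return replace(self, data=self.data.copy())


@dataclass
class ChannelPair:
    """Two spectrally complementary channels acquired simultaneously."""

    ch1: FrameSequence
    ch2: FrameSequence

    def __post_init__(self):
        if self.ch1.data.shape != self.ch2.data.shape:
            raise FormatError(
                f"channel shapes differ: {self.ch1.data.shape} vs {self.ch2.data.shape}"
            )
        for attr in ("pixel_size_um", "frame_interval_s", "t0_index"):
            if getattr(self.ch1, attr) != getattr(self.ch2, attr):
                raise FormatError(f"channel metadata differs in {attr!r}")


@dataclass
class LabelSequence:
    """Per-frame instance labels: 0 = background, k > 0 = cell k of that frame."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError("labels must be (T, H, W)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("labels must be integer-typed")
        if self.labels.min() < 0:
            raise FormatError("labels must be nonnegative")


def read_tiff_sequence(
    path, pixel_size_um: float, frame_interval_s: float, t0_index: int = 0
) -> FrameSequence:
    """Load a multi-page grayscale TIFF as a :class:`FrameSequence`.

    Single-page files become a ``T = 1`` sequence.  Values are cast to
    float without rescaling.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        data = tifffile.imread(str(path))
    except ValueError as exc:  # tifffile raises ValueError on ragged pages
        raise FormatError(f"inconsistent TIFF pages in {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3 or data.dtype == object:
        raise FormatError(f"{path}: expected a stack of same-shape grayscale pages")
    return FrameSequence(
        data=data.astype(float),
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        t0_index=t0_index,
    )


def write_tiff_sequence(seq: FrameSequence, path, dtype=None) -> None:
    """Write a sequence as a multi-page TIFF.

    By default float32 pages are written; pass an integer ``dtype`` to
    round-trip integer data bit-exactly.
    """
    path = Path(path)
    data = seq.data
    if dtype is not None:
        data = data.astype(dtype)
    else:
        data = data.astype(np.float32)
    tifffile.imwrite(str(path), data)


def split_dual_view(raw: FrameSequence, layout: str = "left-right") -> ChannelPair:
    """Split a combined dual-emission camera frame into its two channels.

    Beam-splitter ("Dual-View") setups project both emission bands onto one
    camera chip side by side; this slices each frame in half.

    Parameters
    ----------
    layout
        ``"left-right"`` (split along width) or ``"top-bottom"`` (height).
    """
    t, h, w = raw.data.shape
    if layout == "left-right":
        if w % 2:
            raise FormatError(f"width {w} is odd; cannot split left-right")
        a, b = raw.data[:, :, : w // 2], raw.data[:, :, w // 2 :]
    elif layout == "top-bottom":
        if h % 2:
            raise FormatError(f"height {h} is odd; cannot split top-bottom")
        a, b = raw.data[:, : h // 2, :], raw.data[:, h // 2 :, :]
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return ChannelPair(ch1=raw.with_data(a.copy()), ch2=raw.with_data(b.copy()))
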