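"""Cell instance segmentation, frame-to-frame tracking, and centered ROI
extraction.

Segmentation is pluggable.  The default backend is classical: Gaussian
smoothing, Otsu thresholding, hole filling, watershed splitting on the
distance transform, and a size filter.  A callable backend (e.g. an
adapter around a learned instance-segmentation model) can be passed
instead; it must map a 2-D frame to a label image.

Tracking links detections between consecutive frames by solving the
optimal bipartite assignment on Euclidean centroid distance (Hungarian
algorithm), gated by a maximum displacement, with bridging of short
detection gaps.  Each surviving track is turned into a
:class:`CellTrace`: a fixed-size ROI sub-stack in which the cell is kept
centered by per-frame *integer* translations, so pixel intensities are
preserved exactly for the relative thresholds used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage import filters, measure, morphology, segmentation
from skimage.feature import peak_local_max

from .errors import DegenerateInputError
from .image_model import FrameSequence

__all__ = [
    "CellDetection",
    "Track",
    "CellTrace",
    "segment_frame",
    "link_tracks",
    "extract_roi",
]


@dataclass
class CellDetection:
    """One segmented cell instance in one frame."""

    frame: int
    label: int
    centroid: tuple[float, float]  # (y, x)
    mask: np.ndarray  # full-frame binary
    boundary: np.ndarray  # (M, 2) closed polyline of (y, x) points


@dataclass
class Track:
    """A cell followed across frames."""

    id: int
    detections: list[CellDetection]

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections])

    @property
    def frame_span(self) -> tuple[int, int]:
        f = self.frames
        return int(f[0]), int(f[-1])

    def __len__(self) -> int:
        return len(self.detections)


@dataclass
class CellTrace:
    """One tracked cell as a centered ROI sub-sequence.

    ``roi.data[s]`` corresponds to source frame ``frames[s]``; the cell
    mask centroid sits within 1 px of the ROI center in every retained
    frame.  ``offset_per_frame[s]`` is the (y, x) translation that was
    applied to source coordinates, i.e. ``roi_coord = src_coord - offset``.
    """

    roi: FrameSequence
    masks: np.ndarray  # (S, h, w) bool
    boundaries: list[np.ndarray]  # per-frame (M, 2) polylines in ROI coordinates
    frames: np.ndarray  # (S,) source frame indices
    source_track: int
    offset_per_frame: np.ndarray  # (S, 2) int

    @property
    def roi_center(self) -> tuple[float, float]:
        h, w = self.roi.frame_shape
        return ((h - 1) / 2.0, (w - 1) / 2.0)


def _trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Longest closed iso-contour of a binary mask, as (y, x) points."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise DegenerateInputError("mask has no boundary contour")
    boundary = max(contours, key=len) - 1.0
    return boundary


def segment_frame(
    frame: np.ndarray,
    backend: "str | Callable[[np.ndarray], np.ndarray]" = "threshold",
    min_area_px: int = 50,
    smooth_sigma: float = 1.5,
    split_min_distance: int = 10,
    frame_index: int = 0,
) -> list[CellDetection]:
    """Segment cell instances in a single frame.

    Returns one :class:`CellDetection` per instance (empty list for a
    blank/constant frame).  ``backend`` may be the string ``"threshold"``
    for the built-in classical pipeline or any callable mapping the frame
    to an integer label image (0 = background).
    """
    frame = np.asarray(frame, dtype=float)
    if callable(backend):
        labels = np.asarray(backend(frame))
    elif backend == "threshold":
        if frame.std() == 0:
            return []
        smoothed = ndimage.gaussian_filter(frame, smooth_sigma)
        thr = filters.threshold_otsu(smoothed)
        binary = smoothed > thr
        if not binary.any() or binary.all():
            return []
        binary = ndimage.binary_fill_holes(binary)
        # watershed split of touching cells on the distance transform
        dist = ndimage.distance_transform_edt(binary)
        peaks = peak_local_max(dist, min_distance=split_min_distance, labels=binary)
        if len(peaks) == 0:
            labels, _ = ndimage.label(binary)
        else:
            markers = np.zeros(frame.shape, dtype=int)
            markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
            labels = segmentation.watershed(-dist, markers, mask=binary)
    else:
        raise ValueError(f"unknown segmentation backend {backend!r}")

    detections = []
    out_label = 0
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        out_label += 1
        mask = labels == region.label
        detections.append(
            CellDetection(
                frame=frame_index,
                label=out_label,
                centroid=tuple(region.centroid),
                mask=mask,
                boundary=_trace_boundary(mask),
            )
        )
    return detections


def link_tracks(
    detections_per_frame: Sequence[list[CellDetection]],
    max_disp_px: float,
    min_frames: int = 1,
    max_gap: int = 2,
) -> list[Track]:
    """Link per-frame detections into tracks.

    Consecutive-frame correspondences are the minimum-total-displacement
    bipartite matching (Hungarian algorithm) with matches beyond
    ``max_disp_px`` per elapsed frame rejected.  A track missing from up
    to ``max_gap`` consecutive frames is kept alive and re-linked; tracks
    with fewer than ``min_frames`` detections are discarded.
    """
    if max_disp_px <= 0:
        raise ValueError("max_disp_px must be > 0")
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")

    BIG = 1e12
    active: list[dict] = []  # each: {"dets": [...], "last_frame": int}
    finished: list[list[CellDetection]] = []

    for t, dets in enumerate(detections_per_frame):
        # retire tracks whose gap exceeded max_gap
        still_active = []
        for tr in active:
            if t - tr["last_frame"] > max_gap + 1:
                finished.append(tr["dets"])
            else:
                still_active.append(tr)
        active = still_active

        if dets:
            if active:
                cost = np.full((len(active), len(dets)), BIG)
                for i, tr in enumerate(active):
                    cy, cx = tr["dets"][-1].centroid
                    gap = t - tr["last_frame"]
                    gate = max_disp_px * gap
                    for j, d in enumerate(dets):
                        dist = np.hypot(d.centroid[0] - cy, d.centroid[1] - cx)
                        if dist <= gate:
                            cost[i, j] = dist
                rows, cols = linear_sum_assignment(cost)
                matched_dets = set()
                for i, j in zip(rows, cols):
                    if cost[i, j] < BIG:
                        active[i]["dets"].append(dets[j])
                        active[i]["last_frame"] = t
                        matched_dets.add(j)
            else:
                matched_dets = set()
            for j, d in enumerate(dets):
                if j not in matched_dets:
                    active.append({"dets": [d], "last_frame": t})

    finished.extend(tr["dets"] for tr in active)
    tracks = [
        Track(id=i, detections=dets)
        for i, dets in enumerate(d for d in finished if len(d) >= min_frames)
    ]
    return tracks


def extract_roi(seq: FrameSequence, track: Track, pad_px: int = 5) -> CellTrace:
    """Cut a fixed-size, cell-centered ROI sub-sequence along a track.

    The ROI size is the maximal bounding box over the track plus
    ``pad_px`` on each side.  Per frame, the integer translation closest
    to the mask centroid re-centers the cell; out-of-field pixels are 0.

    Raises
    ------
    DegenerateInputError
        If the ROI would be larger than the source frames.
    """
    if not track.detections:
        raise ValueError("track has no detections")
    H, W = seq.frame_shape

    heights, widths = [], []
    for d in track.detections:
        ys, xs = np.nonzero(d.mask)
        heights.append(ys.max() - ys.min() + 1)
        widths.append(xs.max() - xs.min() + 1)
    h = int(max(heights)) + 2 * pad_px
    w = int(max(widths)) + 2 * pad_px
    if h > H or w > W:
        raise DegenerateInputError(f"ROI {h}x{w} exceeds source frame {H}x{W}")

    cy0, cx0 = (h - 1) / 2.0, (w - 1) / 2.0
    roi_frames, roi_masks, roi_boundaries, offsets, frames = [], [], [], [], []
    for d in track.detections:
        oy = int(round(d.centroid[0] - cy0))
        ox = int(round(d.centroid[1] - cx0))
        roi_frames.append(_shifted_crop(seq.data[d.frame], oy, ox, h, w))
        roi_masks.append(_shifted_crop(d.mask.astype(float), oy, ox, h, w) > 0.5)
        roi_boundaries.append(d.boundary - np.array([oy, ox], dtype=float))
        offsets.append((oy, ox))
        frames.append(d.frame)

    return CellTrace(
        roi=seq.with_data(np.stack(roi_frames)),
        masks=np.stack(roi_masks),
        boundaries=roi_boundaries,
        frames=np.array(frames),
        source_track=track.id,
        offset_per_frame=np.array(offsets, dtype=int),
    )


def _shifted_crop(frame: np.ndarray, oy: int, ox: int, h: int, w: int) -> np.ndarray:
    """Crop frame[oy:oy+h, ox:ox+w] with zero fill outside the frame."""
    out = np.zeros((h, w), dtype=frame.dtype)
    y0, y1 = max(oy, 0), min(oy + h, frame.shape[0])
    x0, x1 = max(ox, 0), min(ox + w, frame.shape[1])
    if y0 < y1 and x0 < x1:
        out[y0 - oy : y1 - oy, x0 - ox : x1 - ox] = frame[y0:y1, x0:x1]
    return out
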