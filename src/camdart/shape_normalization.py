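"""Polar shape normalization: map an arbitrary (star-convex) cell outline
onto a circular template.

For each frame, the cell centroid becomes the origin of a polar
coordinate system.  The boundary samples ``(r_o, theta)_{i=1..N}`` define
a per-angle radial scaling ``T: (r_o, theta) -> (c * r_av, theta)`` with
``r_av = mean_i r_o,i`` the mean outline radius and ``c`` a constant
scale factor.  The transformed image is produced via the inverse map:
each template pixel at polar position ``(r', theta)`` samples the source
at radius ``r = r' * r_o(theta) / (c * r_av)`` along the same angle,
using nearest-neighbor interpolation for both the angular lookup of
``r_o(theta)`` and the image resampling.  Angles are preserved exactly;
only the radial coordinate is stretched, so the relative position of
intracellular signals with respect to the membrane and a contact point
is comparable across cells of different shape.

Outlines must be star-convex about the centroid; for outlines with
multiple boundary crossings per ray the outermost crossing is used and a
warning is emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from matplotlib.path import Path as MplPath

from ._geometry import TWO_PI, cartesian_from_polar, polar_from_cartesian
from .detection_tracking import CellTrace
from .errors import GeometryError
from .image_model import FrameSequence

__all__ = ["PolarOutline", "RadialMap", "outline_to_polar", "normalize_frame", "normalize_trace"]


@dataclass
class PolarOutline:
    """Cell boundary in polar coordinates about the cell centroid.

    ``radii``/``angles`` are the boundary samples sorted by angle;
    ``r_av`` is their mean radius; ``scale_c`` the constant template
    scale factor.
    """

    origin: tuple[float, float]  # (y, x)
    radii: np.ndarray
    angles: np.ndarray
    scale_c: float = 1.0

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        n = self.radii.size
        if n < 8:
            raise GeometryError(f"outline needs >= 8 samples, got {n}")
        if np.any(self.radii <= 0):
            raise GeometryError("all outline radii must be > 0 (centroid outside outline?)")
        order = np.argsort(self.angles)
        self.radii = self.radii[order]
        self.angles = self.angles[order]
        gaps = np.diff(np.concatenate([self.angles, [self.angles[0] + TWO_PI]]))
        if gaps.max() >= TWO_PI / 4:
            raise GeometryError(f"angular gap {gaps.max():.3f} rad too large (>= pi/2)")

    @property
    def n_samples(self) -> int:
        return self.radii.size

    @property
    def r_av(self) -> float:
        return float(self.radii.mean())

    @property
    def template_radius(self) -> float:
        return self.scale_c * self.r_av

    def radius_at(self, theta) -> np.ndarray:
        """Boundary radius at arbitrary angles, nearest sampled angle."""
        return self.radii[_nearest_angle_index(self.angles, theta)]


@dataclass
class RadialMap:
    """The angle-preserving radial scaling ``(r, theta) -> (r', theta)``.

    ``forward`` maps source radii to template radii at given angles;
    ``inverse`` maps template radii back to source radii.  Monotone in r
    for every angle by construction (pure scaling per angle).
    """

    outline: PolarOutline
    template_radius: float

    def forward(self, r, theta):
        return np.asarray(r, dtype=float) * self.template_radius / self.outline.radius_at(theta)

    def inverse(self, r_prime, theta):
        return np.asarray(r_prime, dtype=float) * self.outline.radius_at(theta) / self.template_radius


def _nearest_angle_index(sorted_angles: np.ndarray, theta) -> np.ndarray:
    """Index of the circularly nearest sample angle for each query angle."""
    theta = np.asarray(theta, dtype=float) % TWO_PI
    n = sorted_angles.size
    idx = np.searchsorted(sorted_angles, theta)
    lo = (idx - 1) % n
    hi = idx % n
    d_lo = np.abs(theta - sorted_angles[lo])
    d_lo = np.minimum(d_lo, TWO_PI - d_lo)
    d_hi = np.abs(theta - sorted_angles[hi])
    d_hi = np.minimum(d_hi, TWO_PI - d_hi)
    return np.where(d_lo <= d_hi, lo, hi)


def outline_to_polar(
    boundary: np.ndarray,
    centroid: tuple[float, float],
    scale_c: float = 1.0,
    n_samples: "int | None" = None,
) -> PolarOutline:
    """Convert a closed boundary polyline to polar boundary samples.

    Parameters
    ----------
    boundary
        (M, 2) array of (y, x) vertices; first == last point allowed.
    centroid
        (y, x) origin of the polar system; must lie inside the boundary.
    n_samples
        If given, resample to this many uniformly spaced angles (taking
        the outermost crossing within each angular bin, with a warning if
        the outline is not star-convex).

    Raises
    ------
    GeometryError
        If the centroid lies outside the polygon.
    """
    boundary = np.asarray(boundary, dtype=float)
    if boundary.ndim != 2 or boundary.shape[1] != 2:
        raise ValueError("boundary must be an (M, 2) polyline")
    verts = boundary
    if np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    if not MplPath(verts).contains_point(centroid):
        raise GeometryError(f"centroid {centroid} lies outside the boundary polygon")

    dy = verts[:, 0] - centroid[0]
    dx = verts[:, 1] - centroid[1]
    r, theta = polar_from_cartesian(dy, dx)
    if np.any(r <= 0):
        raise GeometryError("boundary vertex coincides with the centroid")

    if n_samples is not None:
        r, theta = _resample_outermost(r, theta, n_samples)

    return PolarOutline(origin=tuple(centroid), radii=r, angles=theta, scale_c=scale_c)


def _resample_outermost(r: np.ndarray, theta: np.ndarray, n: int):
    """Resample (r, theta) samples to n uniform angular bins.

    Within each bin the outermost (max-r) crossing wins; a warning is
    emitted if multiple crossings with clearly different radii share a
    bin (non-star-convex outline).  Empty bins are filled by circular
    linear interpolation.
    """
    bins = (theta / (TWO_PI / n)).astype(int) % n
    out = np.full(n, np.nan)
    folded = False
    for b in range(n):
        sel = r[bins == b]
        if sel.size:
            out[b] = sel.max()
            if sel.size > 1 and sel.max() - sel.min() > 0.15 * sel.max():
                folded = True
    if folded:
        warnings.warn(
            "outline is not star-convex about the centroid; using the outermost "
            "boundary crossing per angle",
            stacklevel=3,
        )
    centers = (np.arange(n) + 0.5) * (TWO_PI / n)
    if np.isnan(out).any():
        good = ~np.isnan(out)
        if good.sum() < 8:
            raise GeometryError("too few angular bins populated by boundary samples")
        out = np.interp(centers, centers[good], out[good], period=TWO_PI)
    return out, centers


def normalize_frame(
    frame: np.ndarray,
    mask: np.ndarray,
    outline: PolarOutline,
    template_radius: "float | None" = None,
    center: "tuple[float, float] | None" = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Map one cell frame onto the circular template.

    Every output pixel inside the template disk (radius
    ``template_radius``, default ``c * r_av``, centered at ``center``,
    default the frame center) samples the source image at the radially
    back-scaled position along the same polar angle (nearest pixel).
    Pixels outside the disk are 0.  Returns ``(image, disk_mask)``.
    """
    frame = np.asarray(frame, dtype=float)
    H, W = frame.shape
    if template_radius is None:
        template_radius = outline.template_radius
    if center is None:
        center = ((H - 1) / 2.0, (W - 1) / 2.0)

    yy, xx = np.mgrid[0:H, 0:W]
    r_prime, theta = polar_from_cartesian(yy - center[0], xx - center[1])
    disk = r_prime <= template_radius

    rmap = RadialMap(outline, template_radius)
    r_src = rmap.inverse(r_prime[disk], theta[disk])
    dy, dx = cartesian_from_polar(r_src, theta[disk])
    sy = np.rint(outline.origin[0] + dy).astype(int)
    sx = np.rint(outline.origin[1] + dx).astype(int)
    inside = (sy >= 0) & (sy < H) & (sx >= 0) & (sx < W)

    out = np.zeros_like(frame)
    vals = np.zeros(disk.sum())
    vals[inside] = frame[sy[inside], sx[inside]]
    out[disk] = vals
    return out, disk


def normalize_trace(
    trace: CellTrace,
    scale_c: float = 1.0,
    n_boundary_samples: int = 360,
) -> tuple[CellTrace, list[PolarOutline], float]:
    """Shape-normalize every frame of a cell trace onto one shared template.

    The template radius is ``scale_c`` times the trace-median ``r_av`` so
    that all frames share a single circle and temporal dynamics stay
    comparable.  Returns the normalized trace, the per-frame outlines
    used, and the template radius (px).
    """
    h, w = trace.roi.frame_shape
    center = ((h - 1) / 2.0, (w - 1) / 2.0)

    outlines = []
    for s in range(len(trace.frames)):
        mask = trace.masks[s]
        ys, xs = np.nonzero(mask)
        centroid = (float(ys.mean()), float(xs.mean()))
        try:
            outline = outline_to_polar(
                trace.boundaries[s], centroid, scale_c=scale_c, n_samples=n_boundary_samples
            )
        except GeometryError as exc:
            raise GeometryError(f"frame {int(trace.frames[s])}: {exc}") from exc
        outlines.append(outline)

    template_radius = scale_c * float(np.median([o.r_av for o in outlines]))
    if template_radius >= min(h, w) / 2.0:
        raise GeometryError(
            f"template radius {template_radius:.1f} px does not fit the {h}x{w} ROI"
        )

    frames_out, masks_out, boundaries_out = [], [], []
    circle_theta = np.linspace(0, TWO_PI, n_boundary_samples, endpoint=False)
    circ_dy, circ_dx = cartesian_from_polar(template_radius, circle_theta)
    circle = np.stack([center[0] + circ_dy, center[1] + circ_dx], axis=1)
    for s, outline in enumerate(outlines):
        img, disk = normalize_frame(
            trace.roi.data[s], trace.masks[s], outline, template_radius=template_radius, center=center
        )
        frames_out.append(img)
        masks_out.append(disk)
        boundaries_out.append(circle.copy())

    return (
        CellTrace(
            roi=trace.roi.with_data(np.stack(frames_out)),
            masks=np.stack(masks_out),
            boundaries=boundaries_out,
            frames=trace.frames.copy(),
            source_track=trace.source_track,
            offset_per_frame=trace.offset_per_frame.copy(),
        ),
        outlines,
        template_radius,
    )
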