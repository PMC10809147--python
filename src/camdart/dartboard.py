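"""Dartboard projection: spatio-temporal aggregation of microdomains
across a cell population.

After shape normalization every cell is a disk, so cells can be overlaid
once two alignments are applied: a rotation that brings each cell's
bead-contact direction onto a common reference angle, and a time shift
that puts each cell's contact moment at t = 0.  Events are then binned
on an *equal-area* polar grid — a central "bullseye" disk surrounded by
``n_rings`` annuli of identical area, each divided into ``n_segments``
equal angular segments — and within time bins.  Counts are normalised by
segment area, bin duration and number of cells, yielding microdomain
densities per area unit per second that are directly comparable between
the bullseye, inner and outer rings.

Equal-area ring radii: ``r_k = R * sqrt(b^2 + k * (1 - b^2) / n_rings)``
for ``k = 1..n_rings`` with ``b`` the bullseye radius fraction.

Clock convention for bead contacts: positions are given on a clock face
overlaid on the image (12 = up, 3 = right, clockwise), mapped to the
mathematical angle ``pi/2 - clock * pi/6``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geometry import TWO_PI, polar_from_cartesian

__all__ = [
    "BeadContact",
    "DartboardGeometry",
    "DartboardAccumulator",
    "AlignedEvent",
    "clock_to_angle",
    "align_domains",
    "assign_segment",
    "accumulate",
    "moving_average_densities",
    "render_dartboard",
    "read_bead_contacts",
    "write_bead_contacts",
]

DEFAULT_REFERENCE_ANGLE = 0.0  # aligned contact direction = clock 3 ("east")


@dataclass
class BeadContact:
    """Per-cell stimulation event: when and where the bead touched.

    ``clock_position`` is in (0, 12] on the clock scale (fractional hours
    allowed).
    """

    cell_id: int
    contact_frame: int
    clock_position: float

    def __post_init__(self):
        if not (0 < self.clock_position <= 12):
            raise ValueError(f"clock_position must be in (0, 12], got {self.clock_position}")


def clock_to_angle(clock_position: float) -> float:
    """Map a clock position (1-12) to radians: 12 -> pi/2, 3 -> 0, 6 -> 3*pi/2."""
    if not (0 < clock_position <= 12):
        raise ValueError(f"clock_position must be in (0, 12], got {clock_position}")
    return float((np.pi / 2 - clock_position * np.pi / 6) % TWO_PI)


@dataclass
class DartboardGeometry:
    """Equal-area ring x segment polar grid.

    Ring index 0 is the bullseye (one segment); rings 1..n_rings are the
    annuli, each split into ``n_segments`` equal wedges.  ``radius`` is
    the board radius R (px or relative units — areas scale accordingly).
    """

    n_segments: int = 12
    n_rings: int = 5
    bullseye_frac: float = 0.2
    radius: float = 1.0

    def __post_init__(self):
        if self.n_segments < 1 or self.n_rings < 1:
            raise ValueError("need at least 1 segment and 1 ring")
        if not (0 < self.bullseye_frac < 1):
            raise ValueError("bullseye_frac must be in (0, 1)")
        if not self.radius > 0:
            raise ValueError("radius must be > 0")

    @property
    def ring_radii(self) -> np.ndarray:
        """Outer radius of bullseye and each annulus: r_0 = b*R, ..., r_n = R."""
        b2 = self.bullseye_frac**2
        k = np.arange(self.n_rings + 1)
        return self.radius * np.sqrt(b2 + k * (1.0 - b2) / self.n_rings)

    @property
    def bullseye_area(self) -> float:
        return float(np.pi * (self.bullseye_frac * self.radius) ** 2)

    @property
    def annulus_area(self) -> float:
        """Area of each (equal-area) annulus."""
        return float(np.pi * self.radius**2 * (1.0 - self.bullseye_frac**2) / self.n_rings)

    @property
    def segment_areas(self) -> np.ndarray:
        """(n_rings + 1, n_segments) area per cell of the counts grid.

        Row 0 holds the bullseye in column 0 (NaN elsewhere).
        """
        areas = np.full((self.n_rings + 1, self.n_segments), np.nan)
        areas[0, 0] = self.bullseye_area
        areas[1:, :] = self.annulus_area / self.n_segments
        return areas

    @property
    def total_area(self) -> float:
        return float(np.pi * self.radius**2)


@dataclass
class AlignedEvent:
    """A microdomain in the population-aligned frame of reference."""

    t_rel_s: float
    r_frac: float  # radial position / template radius, in [0, 1]
    theta_aligned: float
    cell_id: int = 0


def align_domains(
    series,
    contact: BeadContact,
    board_center: tuple[float, float],
    template_radius: float,
    frame_interval_s: float,
    reference_angle: float = DEFAULT_REFERENCE_ANGLE,
) -> list[AlignedEvent]:
    """Rotate and time-shift one cell's microdomains into the common frame.

    Each domain centroid (in shape-normalized ROI coordinates) is
    expressed in polar coordinates about ``board_center``, rotated so the
    bead-contact direction lands on ``reference_angle``, and time-shifted
    so contact is t = 0.  Radii are normalised by the template radius and
    clipped to [0, 1].
    """
    contact_angle = clock_to_angle(contact.clock_position)
    events = []
    for domain in series.all_domains():
        r, theta = polar_from_cartesian(
            domain.centroid[0] - board_center[0], domain.centroid[1] - board_center[1]
        )
        r_frac = float(r / template_radius)
        if r_frac > 1.0:
            r_frac = 1.0
        events.append(
            AlignedEvent(
                t_rel_s=float((domain.frame - contact.contact_frame) * frame_interval_s),
                r_frac=r_frac,
                theta_aligned=float((theta - contact_angle + reference_angle) % TWO_PI),
                cell_id=series.cell_id,
            )
        )
    return events


def assign_segment(
    r_frac: float,
    theta_aligned: float,
    geom: DartboardGeometry,
    reference_angle: float = DEFAULT_REFERENCE_ANGLE,
) -> tuple[int, int]:
    """Map an aligned event to its (ring, segment) cell.

    Ring 0 is the bullseye (segment 0 by convention).  Segment 0 is
    *centered* on the reference contact direction, so "near contact" is a
    single wedge.  ``r_frac > 1`` is clipped to the outermost ring with a
    warning.
    """
    if r_frac < 0:
        raise ValueError("r_frac must be >= 0")
    if r_frac > 1.0:
        warnings.warn(f"r_frac {r_frac:.3f} > 1; clipping to the outer ring", stacklevel=2)
        r_frac = 1.0
    if r_frac < geom.bullseye_frac:
        return 0, 0
    edges = geom.ring_radii / geom.radius  # relative: [b, ..., 1]
    ring = int(np.searchsorted(edges, r_frac, side="right"))
    ring = min(max(ring, 1), geom.n_rings)
    seg_width = TWO_PI / geom.n_segments
    seg = int(((theta_aligned - reference_angle + seg_width / 2) % TWO_PI) // seg_width)
    return ring, seg % geom.n_segments


@dataclass
class DartboardAccumulator:
    """Counts and densities on the (time bin x ring x segment) grid."""

    counts: np.ndarray  # (n_bins, n_rings + 1, n_segments) int
    geom: DartboardGeometry
    time_bins: list[tuple[float, float]]
    n_cells: int

    @property
    def densities(self) -> np.ndarray:
        """Counts per area unit per second per cell; NaN on unused cells."""
        durations = np.array([hi - lo for lo, hi in self.time_bins])
        return self.counts / (
            self.geom.segment_areas[None, :, :] * durations[:, None, None] * self.n_cells
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per (time bin, ring, segment)."""
        rows = []
        dens = self.densities
        areas = self.geom.segment_areas
        for b, (lo, hi) in enumerate(self.time_bins):
            for ring in range(self.geom.n_rings + 1):
                segs = [0] if ring == 0 else range(self.geom.n_segments)
                for seg in segs:
                    rows.append(
                        {
                            "bin_start_s": lo,
                            "bin_end_s": hi,
                            "ring": ring,
                            "segment": seg,
                            "count": int(self.counts[b, ring, seg]),
                            "area": areas[ring, seg],
                            "density": dens[b, ring, seg],
                            "n_cells": self.n_cells,
                        }
                    )
        return pd.DataFrame(rows)


def accumulate(
    events: list[AlignedEvent],
    geom: DartboardGeometry,
    time_bins: list[tuple[float, float]],
    n_cells: int,
    reference_angle: float = DEFAULT_REFERENCE_ANGLE,
) -> DartboardAccumulator:
    """Bin aligned events from a cell population into the dartboard grid.

    Events outside every time bin are ignored.  Bins must not overlap.

    Raises
    ------
    ValueError
        If ``n_cells < 1`` or bins overlap.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    bins = sorted(time_bins)
    for (a0, a1), (b0, b1) in zip(bins, bins[1:]):
        if b0 < a1:
            raise ValueError(f"time bins overlap: {(a0, a1)} and {(b0, b1)}")
    counts = np.zeros((len(time_bins), geom.n_rings + 1, geom.n_segments), dtype=int)
    for ev in events:
        for b, (lo, hi) in enumerate(time_bins):
            if lo <= ev.t_rel_s < hi:
                ring, seg = assign_segment(ev.r_frac, ev.theta_aligned, geom, reference_angle)
                counts[b, ring, seg] += 1
                break
    return DartboardAccumulator(counts=counts, geom=geom, time_bins=list(time_bins), n_cells=n_cells)


def moving_average_densities(acc: DartboardAccumulator, window_s: float) -> np.ndarray:
    """Centered moving average of the densities over time, per board cell.

    Requires uniform fine time bins no wider than ``window_s``.  Edges
    are averaged over the bins actually inside the window (shrinking
    window), so a constant series is unchanged.
    """
    widths = np.array([hi - lo for lo, hi in acc.time_bins])
    if not np.allclose(widths, widths[0]):
        raise ValueError("moving average requires uniform time bins")
    bin_w = widths[0]
    if window_s < bin_w:
        raise ValueError("window must cover at least one bin")
    half = int(round(window_s / bin_w)) // 2
    dens = acc.densities
    out = np.empty_like(dens)
    n = dens.shape[0]
    import warnings as _warnings

    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN board cells
            out[i] = np.nanmean(dens[lo:hi], axis=0)
    return out


def render_dartboard(
    acc: DartboardAccumulator,
    bin_index: int = 0,
    ax=None,
    cmap: str = "inferno",
    vmax: "float | None" = None,
    reference_angle: float = DEFAULT_REFERENCE_ANGLE,
):
    """Polar heatmap of one time bin's densities.

    The contact direction is marked with an arrow at ``reference_angle``.
    Returns ``(fig, ax)``; the wedge mesh values can be read back from
    ``ax.collections[0].get_array()`` (rings x segments, bullseye drawn
    separately as a filled disk whose color encodes its density).
    """
    import matplotlib.pyplot as plt
    from matplotlib import cm as mcm
    from matplotlib.colors import Normalize

    dens = acc.densities[bin_index]
    geom = acc.geom
    ring_dens = dens[1:, :]  # (n_rings, n_segments)
    bullseye = dens[0, 0]

    if ax is None:
        fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    else:
        fig = ax.figure

    if vmax is None:
        finite = np.concatenate([ring_dens.ravel(), [bullseye]])
        vmax = float(np.nanmax(finite)) if np.nanmax(finite) > 0 else 1.0
    norm = Normalize(vmin=0.0, vmax=vmax)

    seg_width = TWO_PI / geom.n_segments
    theta_edges = reference_angle - seg_width / 2 + seg_width * np.arange(geom.n_segments + 1)
    r_edges = geom.ring_radii
    ax.pcolormesh(theta_edges, r_edges, ring_dens, cmap=cmap, norm=norm, shading="flat")
    ax.fill_between(
        np.linspace(0, TWO_PI, 100),
        0,
        geom.bullseye_frac * geom.radius,
        color=plt.get_cmap(cmap)(norm(bullseye)),
    )
    ax.annotate(
        "",
        xy=(reference_angle, geom.radius),
        xytext=(reference_angle, geom.radius * 1.25),
        arrowprops={"arrowstyle": "->", "color": "black"},
    )
    lo, hi = acc.time_bins[bin_index]
    ax.set_title(f"{lo:g}-{hi:g} s after contact")
    ax.set_yticklabels([])
    fig.colorbar(
        mcm.ScalarMappable(norm=norm, cmap=cmap), ax=ax, label="domains / area / s / cell"
    )
    return fig, ax


def read_bead_contacts(path) -> list[BeadContact]:
    """Read the bead-contact sidecar CSV (cell_id, contact_frame, clock_position)."""
    df = pd.read_csv(path)
    required = {"cell_id", "contact_frame", "clock_position"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"bead-contact file {path} lacks columns: {sorted(missing)}")
    return [
        BeadContact(
            cell_id=int(row.cell_id),
            contact_frame=int(row.contact_frame),
            clock_position=float(row.clock_position),
        )
        for row in df.itertuples()
    ]


def write_bead_contacts(contacts: list[BeadContact], path) -> None:
    pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in contacts],
            "contact_frame": [c.contact_frame for c in contacts],
            "clock_position": [c.clock_position for c in contacts],
        }
    ).to_csv(path, index=False)
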