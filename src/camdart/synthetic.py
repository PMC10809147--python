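"""Synthetic ratiometric live-cell videos with known ground truth.

The generator emulates the structure of a bead-stimulation experiment:
roughly convex cells (radial Fourier perturbations of a circle, so they
are star-convex by construction) that drift and deform slowly; two
spectrally complementary channels — ch1 rises at Ca2+ events (Fluo-4
like), ch2 falls (Fura Red like) and additionally bleaches with a
biexponential decay; transient bright microdomain events placed at a
10x (configurable) higher rate near the bead-contact point than
elsewhere in the cell; and Gaussian read noise with optional Poisson
shot noise.  All randomness flows from a single seed, so outputs are
bit-reproducible.

Every quantity a pipeline stage estimates (masks, boundaries, event
positions and times, channel mean traces, bleaching parameters) is
recorded in the :class:`GroundTruth`, enabling parameter-recovery tests
with no external data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from ._geometry import TWO_PI, angular_distance, cartesian_from_polar
from .dartboard import BeadContact, clock_to_angle
from .errors import PipelineError
from .image_model import ChannelPair, FrameSequence, write_tiff_sequence

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "SyntheticDataset",
    "generate_dataset",
    "scripted_event_placement",
]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic bead-stimulation recording.

    Defaults describe a desk-scale rendition of a ratiometric T-cell
    experiment: ~17 s at 10 frames/s, cells of radius ~18 px
    (~6.6 um at 0.368 um/px), event amplitude 3x the cell mean, near- vs
    far-from-contact event rates in a 10:1 ratio, Gaussian read noise at
    5% of the cell mean, and biexponential bleaching of ch2 only.
    """

    n_cells: int = 4
    image_size: "tuple[int, int] | None" = None  # auto grid layout when None
    n_frames: int = 170
    frame_interval_s: float = 0.1
    pixel_size_um: float = 0.368
    # cell geometry
    cell_radius_px: float = 18.0
    cell_radius_jitter: float = 2.0
    shape_harmonics: list = field(default_factory=lambda: [(3, 0.06), (5, 0.03)])
    deform_amp: float = 0.3  # relative temporal modulation of harmonic amplitudes
    deform_period_s: float = 8.0
    drift_px_per_frame: tuple[float, float] = (0.03, 0.05)
    # stimulation
    contact_frame: int = 10
    contact_clock: "float | None" = None  # None -> random integer hour per cell
    # microdomain event model
    rate_near_per_s: float = 1.0
    rate_far_per_s: float = 0.1
    near_clock_halfwidth: float = 1.0  # clock hours
    near_r_min: float = 0.6
    spot_sigma_px: float = 1.5
    spot_amplitude: float = 3.0  # x cell mean (ch1)
    ch2_dip_fraction: float = 0.4  # ch2 loses this fraction of the ch1 spot shape
    event_duration_frames: int = 3
    scripted_events: list = field(default_factory=list)  # (cell, frame, clock, r_frac)
    # intensities
    cell_mean_ch1: float = 100.0
    cell_mean_ch2: float = 150.0
    background: float = 10.0
    # degradation
    bleach_params: tuple = (0.3, 0.4, 2.0, 0.3, 10.0)  # (a, b1, tau1, b2, tau2), ch2 only
    noise_sigma: float = 5.0
    poisson_noise: bool = False
    channel_shift: tuple[float, float] = (0.0, 0.0)  # (dy, dx) misalignment of ch2
    allow_concave: bool = False  # for negative testing of shape normalization
    seed: int = 0

    def validate(self):
        if self.n_cells < 1 or self.n_frames < 1:
            raise PipelineError("need at least one cell and one frame")
        amp = sum(a for _, a in self.shape_harmonics) * (1 + self.deform_amp)
        if amp >= 0.5 and not self.allow_concave:
            raise PipelineError(
                f"shape harmonic amplitudes sum to {amp:.2f}; outline may not be "
                "star-convex (set allow_concave=True to force)"
            )
        if self.rate_near_per_s < 0 or self.rate_far_per_s < 0:
            raise PipelineError("event rates must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator knows about what it drew."""

    labels: np.ndarray  # (T, H, W) int, 0 background, c+1 for cell index c
    boundaries: list  # boundaries[cell][frame] -> (M, 2) polyline
    centroids: np.ndarray  # (n_cells, T, 2)
    events: pd.DataFrame  # event_id, cell, frame_start/end, y, x, clock_pos, r_frac, near
    channel_means: pd.DataFrame  # frame, cell, ch1_mean, ch2_mean (pre-noise)
    template_radii: np.ndarray  # (n_cells,) mean outline radius


@dataclass
class SyntheticDataset:
    pair: ChannelPair
    truth: GroundTruth
    contacts: list
    spec: SyntheticSpec


def _boundary_radius(spec, base_radius, phases, t_s, theta):
    """Outline radius r(theta, t) of one cell."""
    r = np.full_like(np.asarray(theta, dtype=float), float(base_radius))
    mod = 1.0 + spec.deform_amp * np.sin(TWO_PI * t_s / spec.deform_period_s + phases[-1])
    for (order, amp), phase in zip(spec.shape_harmonics, phases[:-1]):
        r += base_radius * amp * mod * np.cos(order * np.asarray(theta) + phase)
    return r


def _layout(spec, rng):
    """Cell grid positions and the implied image size."""
    spacing = int(np.ceil(4.5 * (spec.cell_radius_px + spec.cell_radius_jitter)))
    n_cols = int(np.ceil(np.sqrt(spec.n_cells)))
    n_rows = int(np.ceil(spec.n_cells / n_cols))
    margin = spacing // 2
    centers = np.array(
        [
            (margin + spacing * (i // n_cols), margin + spacing * (i % n_cols))
            for i in range(spec.n_cells)
        ],
        dtype=float,
    )
    auto = (margin + spacing * (n_rows - 1) + margin, margin + spacing * (n_cols - 1) + margin)
    size = spec.image_size if spec.image_size is not None else auto
    return centers, size


def scripted_event_placement(
    centroid: tuple[float, float],
    boundary_radius,
    clock_position: float,
    r_frac: float,
    frame: int,
    mask: "np.ndarray | None" = None,
) -> tuple[float, float, int]:
    """Place an event at a given polar location relative to a cell.

    ``boundary_radius`` is either a scalar (circular cell) or a callable
    ``theta -> r``.  The returned (y, x) lies at ``r_frac`` of the
    boundary radius along the clock direction.  If a ``mask`` is supplied
    and the position falls outside it (concave cell), the radius is
    reduced in 10% steps with a warning.
    """
    if not (0 <= r_frac <= 1):
        raise ValueError("r_frac must be in [0, 1]")
    theta = clock_to_angle(clock_position)
    r_b = boundary_radius(theta) if callable(boundary_radius) else float(boundary_radius)
    frac = r_frac
    while True:
        dy, dx = cartesian_from_polar(frac * r_b, theta)
        y, x = centroid[0] + float(dy), centroid[1] + float(dx)
        if mask is None or mask[int(round(y)), int(round(x))]:
            return y, x, frame
        if frac < 0.05:
            raise PipelineError("could not place event inside the cell mask")
        import warnings

        warnings.warn("scripted event outside mask; retrying at reduced radius", stacklevel=2)
        frac *= 0.9


def _sample_events(spec, rng, cell, contact_clock, n_frames):
    """Poisson event times/positions in (frame, clock, r_frac, near) form."""
    events = []
    contact_angle = clock_to_angle(contact_clock)
    half_angle = spec.near_clock_halfwidth * np.pi / 6
    dt = spec.frame_interval_s
    active = np.arange(spec.contact_frame, n_frames)
    # near-contact region: within +/- half an hour band, outer radii
    p_near = spec.rate_near_per_s * dt
    p_far = spec.rate_far_per_s * dt
    for f in active:
        for _ in range(rng.poisson(p_near)):
            d_clock = rng.uniform(-spec.near_clock_halfwidth, spec.near_clock_halfwidth)
            clock = (contact_clock + d_clock - 1e-9) % 12 or 12.0
            r_frac = rng.uniform(spec.near_r_min, 0.9)
            events.append((int(f), clock, r_frac, True))
        for _ in range(rng.poisson(p_far)):
            # area-uniform over the cell, rejecting the near region
            for _attempt in range(100):
                clock = rng.uniform(0, 12) or 12.0
                r_frac = 0.9 * np.sqrt(rng.uniform())
                theta = clock_to_angle(clock)
                in_near = (
                    angular_distance(theta, contact_angle) <= half_angle
                    and r_frac >= spec.near_r_min
                )
                if not in_near:
                    break
            events.append((int(f), clock, r_frac, False))
    return events


def generate_dataset(spec: SyntheticSpec, outdir: "Path | str | None" = None) -> SyntheticDataset:
    """Render the synthetic recording described by ``spec``.

    Returns the channel pair, ground truth and bead-contact list; when
    ``outdir`` is given, also writes ``ch1.tif``, ``ch2.tif``,
    ``bead_contacts.csv``, ``ground_truth_events.csv`` and a JSON echo of
    the spec.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    centers0, (H, W) = _layout(spec, rng)
    T = spec.n_frames

    radii = spec.cell_radius_px + rng.uniform(-1, 1, spec.n_cells) * spec.cell_radius_jitter
    phases = [rng.uniform(0, TWO_PI, len(spec.shape_harmonics) + 1) for _ in range(spec.n_cells)]
    drift_dir = rng.choice([-1.0, 1.0], size=(spec.n_cells, 2))
    if spec.contact_clock is None:
        clocks = rng.integers(1, 13, spec.n_cells).astype(float)
    else:
        clocks = np.full(spec.n_cells, float(spec.contact_clock))
    contacts = [
        BeadContact(cell_id=c, contact_frame=spec.contact_frame, clock_position=clocks[c])
        for c in range(spec.n_cells)
    ]

    # precompute per-cell, per-frame centroids and reject cells leaving the field
    drift = np.asarray(spec.drift_px_per_frame)
    centroids = np.empty((spec.n_cells, T, 2))
    for c in range(spec.n_cells):
        for t in range(T):
            centroids[c, t] = centers0[c] + drift_dir[c] * drift * t
    r_max = radii.max() * (1 + sum(a for _, a in spec.shape_harmonics)) + 2
    if (
        centroids[..., 0].min() < r_max
        or centroids[..., 1].min() < r_max
        or centroids[..., 0].max() > H - r_max
        or centroids[..., 1].max() > W - r_max
    ):
        raise PipelineError("cells drift outside the field of view; enlarge image_size")
    for c1 in range(spec.n_cells):
        for c2 in range(c1 + 1, spec.n_cells):
            gap = np.linalg.norm(centroids[c1] - centroids[c2], axis=1).min()
            if gap < radii[c1] + radii[c2] + 4:
                raise PipelineError(f"cells {c1} and {c2} would overlap")

    theta_poly = np.linspace(0, TWO_PI, 180, endpoint=False)

    labels = np.zeros((T, H, W), dtype=np.int16)
    boundaries = [[None] * T for _ in range(spec.n_cells)]
    ch1 = np.full((T, H, W), spec.background, dtype=float)
    ch2 = np.full((T, H, W), spec.background, dtype=float)

    a, b1, t1, b2, t2 = spec.bleach_params
    times = np.arange(T) * spec.frame_interval_s
    f_bleach = a + b1 * np.exp(-times / t1) + b2 * np.exp(-times / t2)
    bleach_factor = f_bleach / f_bleach[0]

    # event bookkeeping
    event_rows = []
    event_id = 0
    spots_by_frame: dict[int, list] = {}

    def register_event(cell, f0, clock, r_frac, near):
        nonlocal event_id
        # position fixed relative to the cell at its first frame; follows drift
        def pos_at(t):
            theta = clock_to_angle(clock)
            r_b = _boundary_radius(spec, radii[cell], phases[cell], t * spec.frame_interval_s, theta)
            dy, dx = cartesian_from_polar(r_frac * float(r_b), theta)
            return centroids[cell, t, 0] + float(dy), centroids[cell, t, 1] + float(dx)

        f_end = min(f0 + spec.event_duration_frames - 1, T - 1)
        for f in range(f0, f_end + 1):
            spots_by_frame.setdefault(f, []).append((cell, pos_at(f)))
        y0, x0 = pos_at(f0)
        event_rows.append(
            {
                "event_id": event_id,
                "cell": cell,
                "frame_start": f0,
                "frame_end": f_end,
                "y": y0,
                "x": x0,
                "clock_position": clock,
                "r_frac": r_frac,
                "near_contact": near,
            }
        )
        event_id += 1

    for c in range(spec.n_cells):
        for f0, clock, r_frac, near in _sample_events(spec, rng, c, clocks[c], T):
            register_event(c, f0, clock, r_frac, near)
    for cell, f0, clock, r_frac in spec.scripted_events:
        register_event(int(cell), int(f0), float(clock), float(r_frac), True)

    mean_rows = []
    yy, xx = np.mgrid[0:H, 0:W]
    for t in range(T):
        t_s = t * spec.frame_interval_s
        frame_ch1 = ch1[t]
        frame_ch2 = ch2[t]
        for c in range(spec.n_cells):
            r_theta = _boundary_radius(spec, radii[c], phases[c], t_s, theta_poly)
            dy, dx = cartesian_from_polar(r_theta, theta_poly)
            poly_y = centroids[c, t, 0] + dy
            poly_x = centroids[c, t, 1] + dx
            rr, cc = draw_polygon(poly_y, poly_x, shape=(H, W))
            labels[t, rr, cc] = c + 1
            boundaries[c][t] = np.stack([poly_y, poly_x], axis=1)
            frame_ch1[rr, cc] = spec.cell_mean_ch1
            frame_ch2[rr, cc] = spec.background + (
                spec.cell_mean_ch2 - spec.background
            ) * bleach_factor[t]
        for cell, (ey, ex) in spots_by_frame.get(t, []):
            g = np.exp(
                -((yy - ey) ** 2 + (xx - ex) ** 2) / (2 * spec.spot_sigma_px**2)
            )
            frame_ch1 += spec.spot_amplitude * spec.cell_mean_ch1 * g
            frame_ch2 -= spec.ch2_dip_fraction * spec.spot_amplitude * spec.background * g
        np.clip(frame_ch2, 0.0, None, out=frame_ch2)
        for c in range(spec.n_cells):
            m = labels[t] == c + 1
            mean_rows.append(
                {
                    "frame": t,
                    "cell": c,
                    "ch1_mean": float(frame_ch1[m].mean()),
                    "ch2_mean": float(frame_ch2[m].mean()),
                }
            )

    if spec.poisson_noise:
        ch1 = rng.poisson(np.clip(ch1, 0, None)).astype(float)
        ch2 = rng.poisson(np.clip(ch2, 0, None)).astype(float)
    if spec.noise_sigma > 0:
        ch1 = ch1 + rng.normal(0, spec.noise_sigma, ch1.shape)
        ch2 = ch2 + rng.normal(0, spec.noise_sigma, ch2.shape)
    np.clip(ch1, 0.0, None, out=ch1)
    np.clip(ch2, 0.0, None, out=ch2)

    if any(spec.channel_shift):
        ch2 = np.stack(
            [ndimage.shift(f, spec.channel_shift, order=1, mode="nearest") for f in ch2]
        )
        np.clip(ch2, 0.0, None, out=ch2)

    meta = dict(pixel_size_um=spec.pixel_size_um, frame_interval_s=spec.frame_interval_s)
    pair = ChannelPair(
        ch1=FrameSequence(ch1, **meta),
        ch2=FrameSequence(ch2, **meta),
    )
    truth = GroundTruth(
        labels=labels,
        boundaries=boundaries,
        centroids=centroids,
        events=pd.DataFrame(
            event_rows,
            columns=[
                "event_id",
                "cell",
                "frame_start",
                "frame_end",
                "y",
                "x",
                "clock_position",
                "r_frac",
                "near_contact",
            ],
        ),
        channel_means=pd.DataFrame(mean_rows),
        template_radii=radii.copy(),
    )
    dataset = SyntheticDataset(pair=pair, truth=truth, contacts=contacts, spec=spec)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_tiff_sequence(pair.ch1, outdir / "ch1.tif")
        write_tiff_sequence(pair.ch2, outdir / "ch2.tif")
        sidecar = pd.DataFrame(
            {
                "cell_id": [c.cell_id for c in contacts],
                "contact_frame": [c.contact_frame for c in contacts],
                "clock_position": [c.clock_position for c in contacts],
                # approximate cell position at contact time, used to pair
                # contacts with discovered tracks in batch processing
                "approx_y": [centroids[c.cell_id, c.contact_frame, 0] for c in contacts],
                "approx_x": [centroids[c.cell_id, c.contact_frame, 1] for c in contacts],
            }
        )
        sidecar.to_csv(outdir / "bead_contacts.csv", index=False)
        truth.events.to_csv(outdir / "ground_truth_events.csv", index=False)
        truth.channel_means.to_csv(outdir / "ground_truth_channel_means.csv", index=False)
        echo = dataclasses.asdict(spec)
        echo["image_size"] = list((H, W))
        (outdir / "synthetic_spec.json").write_text(json.dumps(echo, indent=2, default=list))
    return dataset
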