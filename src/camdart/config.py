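"""Pipeline configuration.

One flat YAML file drives a batch run; unknown keys are rejected so typos
cannot silently fall back to defaults, and the resolved configuration is
written next to the outputs of every run for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # --- input ---
    input_ch1: "str | None" = None  # multi-page TIFF path (or combined dual-view)
    input_ch2: "str | None" = None  # second channel; None with dual_view_layout set
    bead_contacts: "str | None" = None  # sidecar CSV path
    output_dir: str = "camdart_out"
    group_label: str = "group"
    pixel_size_um: float = 0.368
    frame_interval_s: float = 0.1
    dual_view_layout: "str | None" = None  # left-right | top-bottom | None

    # --- postprocessing ---
    register_mode: str = "first_frame"  # first_frame | per_frame | none
    register_model: str = "translation"  # translation | affine
    ratio_clip_lo: "float | None" = None
    ratio_clip_hi: "float | None" = None
    background_mode: str = "percentile"  # roi | percentile | constant | none
    background_percentile: float = 1.0
    background_constant: float = 0.0
    bleach_mode: str = "additive"  # none | additive | multiplicative | biexp
    bleach_channel: str = "ch2"  # ch1 | ch2 | both

    # --- deconvolution ---
    deconvolve: str = "none"  # none | lucy_richardson
    psf: str = "gaussian:1.5"  # gaussian:<sigma> | path to single-page TIFF
    lr_iterations: int = 10

    # --- detection & tracking ---
    seg_backend: str = "threshold"
    min_area_px: int = 150
    max_disp_px: float = 20.0
    min_frames: "int | None" = None  # None -> frames spanning 1 s pre to 15 s post contact
    max_gap: int = 2
    roi_pad_px: int = 6

    # --- shape normalization ---
    shape_norm: bool = True
    scale_factor_c: float = 1.0
    n_boundary_samples: int = 360

    # --- microdomain detection ---
    threshold: float = 2.0
    min_size: int = 4
    max_size: int = 200
    connectivity: int = 8
    window_pre_s: float = 1.0
    window_post_s: float = 15.0
    min_active_frames: int = 1

    # --- dartboard ---
    n_segments: int = 12
    n_rings: int = 5
    bullseye_frac: float = 0.2
    time_bins: list = field(default_factory=lambda: [[0.0, 5.0], [5.0, 10.0], [10.0, 15.0]])

    # --- misc ---
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def resolved_min_frames(self) -> int:
        """Default track-length gate: the analysis window's frame count."""
        if self.min_frames is not None:
            return self.min_frames
        return int(round((self.window_pre_s + self.window_post_s) / self.frame_interval_s))
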