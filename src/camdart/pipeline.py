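"""Batch pipeline: the stage functions behind the command-line interface.

Each stage reads its inputs from, and writes its outputs to, a fixed
directory layout under ``config.output_dir``::

    input/          ch1.tif, ch2.tif, bead_contacts.csv   (simulate or user data)
    postprocessed/  ratio.tif, ch1_corrected.tif, ch2_corrected.tif
    tracks/         cell_<k>_roi.tif, cell_<k>_mask.tif, tracks.csv
    normalized/     cell_<k>.tif, cell_<k>_mask.tif, normalized_meta.csv
    domains/        cell_<k>_domains.csv, group_per_cell.csv, group_timepoints.csv
    dartboard/      dartboard.csv, dartboard_bin<k>.png
    pipeline.log, resolved_config.yaml

Stages are individually re-runnable; ``run_pipeline`` simply chains them,
so stage-wise and end-to-end execution produce identical outputs.
Per-cell failures (segmentation, normalization) are logged and the cell
is excluded from group statistics rather than aborting the batch.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import dartboard as db
from . import detection_tracking as dt
from . import microdomain as md
from . import postprocess as pp
from . import shape_normalization as sn
from .config import PipelineConfig
from .deconvolution import PointSpreadFunction, deconvolve_sequence, gaussian_psf
from .errors import PipelineError
from .image_model import ChannelPair, FrameSequence, read_tiff_sequence, split_dual_view, write_tiff_sequence

__all__ = [
    "stage_simulate",
    "stage_postprocess",
    "stage_track",
    "stage_normalize",
    "stage_detect",
    "stage_dartboard",
    "run_pipeline",
]

log = logging.getLogger("camdart")


def _setup_logging(outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    target = str((outdir / "pipeline.log").resolve())
    for h in list(log.handlers):
        if isinstance(h, logging.FileHandler):
            if h.baseFilename == target:
                log.setLevel(logging.INFO)
                return
            log.removeHandler(h)
            h.close()
    handler = logging.FileHandler(target)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)


def _timed(name):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            log.info("stage %-12s %.2f s", name, time.perf_counter() - self.t0)

    return _Timer()


def _load_psf(cfg: PipelineConfig) -> PointSpreadFunction:
    if cfg.psf.startswith("gaussian:"):
        return gaussian_psf(float(cfg.psf.split(":", 1)[1]))
    seq = read_tiff_sequence(cfg.psf, 1.0, 1.0)
    kernel = seq.data[0]
    return PointSpreadFunction(kernel / kernel.sum(), provenance="file")


def stage_simulate(cfg: PipelineConfig, spec=None) -> Path:
    """Generate a synthetic recording into ``output_dir/input``."""
    from .synthetic import SyntheticSpec, generate_dataset

    outdir = Path(cfg.output_dir)
    _setup_logging(outdir)
    if spec is None:
        spec = SyntheticSpec(seed=cfg.seed, frame_interval_s=cfg.frame_interval_s)
    with _timed("simulate"):
        generate_dataset(spec, outdir / "input")
    return outdir / "input"


def _load_input_pair(cfg: PipelineConfig) -> ChannelPair:
    meta = dict(pixel_size_um=cfg.pixel_size_um, frame_interval_s=cfg.frame_interval_s)
    indir = Path(cfg.output_dir) / "input"
    ch1_path = cfg.input_ch1 or (indir / "ch1.tif")
    if not Path(ch1_path).exists():
        raise PipelineError(f"missing input channel: {ch1_path}")
    raw = read_tiff_sequence(ch1_path, **meta)
    if cfg.dual_view_layout:
        return split_dual_view(raw, cfg.dual_view_layout)
    ch2_path = cfg.input_ch2 or (indir / "ch2.tif")
    if not Path(ch2_path).exists():
        raise PipelineError(f"missing input channel: {ch2_path}")
    return ChannelPair(ch1=raw, ch2=read_tiff_sequence(ch2_path, **meta))


def _cell_masks_from_channels(pair: ChannelPair, cfg: PipelineConfig) -> np.ndarray:
    """Rough per-frame foreground masks used only for bleaching correction."""
    from skimage import filters

    combined = pair.ch1.data + pair.ch2.data
    masks = np.empty(combined.shape, dtype=bool)
    for t in range(combined.shape[0]):
        thr = filters.threshold_otsu(combined[t])
        masks[t] = combined[t] > thr
    return masks


def stage_postprocess(cfg: PipelineConfig) -> Path:
    """Registration, background subtraction, deconvolution, bleaching
    correction and ratio computation."""
    outdir = Path(cfg.output_dir)
    _setup_logging(outdir)
    pair = _load_input_pair(cfg)
    stage_dir = outdir / "postprocessed"
    stage_dir.mkdir(parents=True, exist_ok=True)

    with _timed("postprocess"):
        ch1, ch2 = pair.ch1, pair.ch2
        if cfg.register_mode != "none":
            if cfg.register_mode == "first_frame":
                tf = pp.register_channels(ch1.data[0], ch2.data[0], model=cfg.register_model)
                ch2 = pp.apply_transform(ch2, tf, mode="first_frame")
                log.info("registration offset (first frame): %s", tf.offset)
            elif cfg.register_mode == "per_frame":
                tfs = [
                    pp.register_channels(f1, f2, model=cfg.register_model)
                    for f1, f2 in zip(ch1.data, ch2.data)
                ]
                ch2 = pp.apply_transform(ch2, tfs, mode="per_frame")
            else:
                raise PipelineError(f"unknown register_mode {cfg.register_mode!r}")

        if cfg.background_mode != "none":
            if cfg.background_mode == "constant":
                bg1 = bg2 = cfg.background_constant
            else:
                bg1 = pp.estimate_background(ch1, mode="percentile", percentile=cfg.background_percentile)
                bg2 = pp.estimate_background(ch2, mode="percentile", percentile=cfg.background_percentile)
            ch1 = pp.subtract_background(ch1, bg1)
            ch2 = pp.subtract_background(ch2, bg2)

        if cfg.deconvolve != "none":
            psf = _load_psf(cfg)
            ch1 = deconvolve_sequence(ch1, cfg.deconvolve, psf=psf, n_iter=cfg.lr_iterations)
            ch2 = deconvolve_sequence(ch2, cfg.deconvolve, psf=psf, n_iter=cfg.lr_iterations)

        if cfg.bleach_mode != "none":
            masks = _cell_masks_from_channels(ChannelPair(ch1=ch1, ch2=ch2), cfg)
            targets = {"ch1": ch1, "ch2": ch2} if cfg.bleach_channel == "both" else {
                cfg.bleach_channel: {"ch1": ch1, "ch2": ch2}[cfg.bleach_channel]
            }
            for name, seq in targets.items():
                if cfg.bleach_mode == "additive":
                    corrected = pp.correct_bleaching_additive(seq, masks)
                elif cfg.bleach_mode == "multiplicative":
                    corrected = pp.correct_bleaching_multiplicative(seq, masks)
                elif cfg.bleach_mode == "biexp":
                    corrected, model = pp.correct_bleaching_biexponential(seq, masks)
                    log.info("biexponential bleach fit %s: params=%s", name, model.params)
                else:
                    raise PipelineError(f"unknown bleach_mode {cfg.bleach_mode!r}")
                if name == "ch1":
                    ch1 = corrected
                else:
                    ch2 = corrected

        clip = None
        if cfg.ratio_clip_lo is not None and cfg.ratio_clip_hi is not None:
            clip = (cfg.ratio_clip_lo, cfg.ratio_clip_hi)
        ratio = pp.compute_ratio(ChannelPair(ch1=ch1, ch2=ch2), clip=clip)

        write_tiff_sequence(ch1, stage_dir / "ch1_corrected.tif")
        write_tiff_sequence(ch2, stage_dir / "ch2_corrected.tif")
        write_tiff_sequence(ratio, stage_dir / "ratio.tif")
    return stage_dir


def stage_track(cfg: PipelineConfig) -> Path:
    """Segment, link and extract centered per-cell ROI traces."""
    outdir = Path(cfg.output_dir)
    _setup_logging(outdir)
    meta = dict(pixel_size_um=cfg.pixel_size_um, frame_interval_s=cfg.frame_interval_s)
    post = outdir / "postprocessed"
    ratio = read_tiff_sequence(post / "ratio.tif", **meta)
    ch1 = read_tiff_sequence(post / "ch1_corrected.tif", **meta)
    ch2 = read_tiff_sequence(post / "ch2_corrected.tif", **meta)
    seg_source = ch1.with_data(ch1.data + ch2.data)

    stage_dir = outdir / "tracks"
    stage_dir.mkdir(parents=True, exist_ok=True)
    with _timed("track"):
        detections = [
            dt.segment_frame(
                frame, backend=cfg.seg_backend, min_area_px=cfg.min_area_px, frame_index=t
            )
            for t, frame in enumerate(seg_source.data)
        ]
        tracks = dt.link_tracks(
            detections,
            max_disp_px=cfg.max_disp_px,
            min_frames=min(cfg.resolved_min_frames(), seg_source.n_frames),
            max_gap=cfg.max_gap,
        )
        if not tracks:
            raise PipelineError("no cells tracked in the input")

        rows = []
        for track in tracks:
            try:
                trace = dt.extract_roi(ratio, track, pad_px=cfg.roi_pad_px)
            except PipelineError as exc:
                log.warning("track %d: ROI extraction failed (%s); skipped", track.id, exc)
                continue
            write_tiff_sequence(trace.roi, stage_dir / f"cell_{track.id}_roi.tif")
            write_tiff_sequence(
                trace.roi.with_data(trace.masks.astype(float)),
                stage_dir / f"cell_{track.id}_mask.tif",
            )
            for s, d in enumerate(track.detections):
                rows.append(
                    {
                        "track_id": track.id,
                        "frame": d.frame,
                        "centroid_y": d.centroid[0],
                        "centroid_x": d.centroid[1],
                        "area_px": int(d.mask.sum()),
                        "offset_y": trace.offset_per_frame[s, 0],
                        "offset_x": trace.offset_per_frame[s, 1],
                    }
                )
        if not rows:
            raise PipelineError("all tracked cells failed ROI extraction")
        pd.DataFrame(rows).to_csv(stage_dir / "tracks.csv", index=False)
        log.info("tracked %d cells", len({r['track_id'] for r in rows}))
    return stage_dir


def _load_traces(cfg: PipelineConfig, stage: str):
    """Rebuild CellTrace objects from a stage directory (tracks or normalized)."""
    outdir = Path(cfg.output_dir)
    meta = dict(pixel_size_um=cfg.pixel_size_um, frame_interval_s=cfg.frame_interval_s)
    stage_dir = outdir / stage
    tracks_df = pd.read_csv(outdir / "tracks" / "tracks.csv")
    traces = {}
    for track_id, group in tracks_df.groupby("track_id"):
        roi_path = stage_dir / f"cell_{track_id}_roi.tif"
        if stage == "normalized":
            roi_path = stage_dir / f"cell_{track_id}.tif"
        if not roi_path.exists():
            continue
        roi = read_tiff_sequence(roi_path, **meta)
        masks = read_tiff_sequence(
            stage_dir / f"cell_{track_id}_mask.tif", **meta
        ).data > 0.5
        traces[int(track_id)] = dt.CellTrace(
            roi=roi,
            masks=masks,
            boundaries=[dt._trace_boundary(m) for m in masks],
            frames=group["frame"].to_numpy(),
            source_track=int(track_id),
            offset_per_frame=group[["offset_y", "offset_x"]].to_numpy(),
        )
    return traces


def stage_normalize(cfg: PipelineConfig) -> Path:
    """Shape-normalize every tracked cell onto its circular template."""
    outdir = Path(cfg.output_dir)
    _setup_logging(outdir)
    traces = _load_traces(cfg, "tracks")
    stage_dir = outdir / "normalized"
    stage_dir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    with _timed("normalize"):
        for track_id, trace in traces.items():
            if not cfg.shape_norm:
                normalized, template_radius = trace, float("nan")
            else:
                try:
                    normalized, _, template_radius = sn.normalize_trace(
                        trace, scale_c=cfg.scale_factor_c, n_boundary_samples=cfg.n_boundary_samples
                    )
                except PipelineError as exc:
                    log.warning("cell %d: shape normalization failed (%s); skipped", track_id, exc)
                    continue
            write_tiff_sequence(normalized.roi, stage_dir / f"cell_{track_id}.tif")
            write_tiff_sequence(
                normalized.roi.with_data(normalized.masks.astype(float)),
                stage_dir / f"cell_{track_id}_mask.tif",
            )
            h, w = normalized.roi.frame_shape
            meta_rows.append(
                {
                    "track_id": track_id,
                    "template_radius_px": template_radius,
                    "center_y": (h - 1) / 2.0,
                    "center_x": (w - 1) / 2.0,
                }
            )
    if not meta_rows:
        raise PipelineError("shape normalization failed for every cell")
    pd.DataFrame(meta_rows).to_csv(stage_dir / "normalized_meta.csv", index=False)
    return stage_dir


def _match_contacts_to_tracks(cfg: PipelineConfig, track_ids, tracks_df):
    """Pair bead contacts with tracks.

    If the sidecar provides ``approx_y``/``approx_x`` columns, each
    contact is matched to the track whose centroid at the contact frame
    is nearest; otherwise contacts are paired with tracks in sorted-id
    order.
    """
    path = cfg.bead_contacts or (Path(cfg.output_dir) / "input" / "bead_contacts.csv")
    if not Path(path).exists():
        raise PipelineError(f"missing bead-contact sidecar: {path}")
    df = pd.read_csv(path)
    contacts = {}
    if {"approx_y", "approx_x"} <= set(df.columns):
        for row in df.itertuples():
            best, best_d = None, np.inf
            for tid in track_ids:
                sub = tracks_df[tracks_df.track_id == tid]
                i = (sub.frame - row.contact_frame).abs().idxmin()
                d = np.hypot(
                    sub.loc[i, "centroid_y"] - row.approx_y,
                    sub.loc[i, "centroid_x"] - row.approx_x,
                )
                if d < best_d:
                    best, best_d = tid, d
            if best is not None and best not in contacts:
                contacts[best] = db.BeadContact(
                    cell_id=best,
                    contact_frame=int(row.contact_frame),
                    clock_position=float(row.clock_position),
                )
    else:
        rows = list(df.itertuples())
        for tid, row in zip(sorted(track_ids), rows):
            contacts[tid] = db.BeadContact(
                cell_id=tid,
                contact_frame=int(row.contact_frame),
                clock_position=float(row.clock_position),
            )
    return contacts


def stage_detect(cfg: PipelineConfig) -> Path:
    """Detect microdomains per cell and compute group statistics."""
    outdir = Path(cfg.output_dir)
    _setup_logging(outdir)
    stage = "normalized" if cfg.shape_norm else "tracks"
    traces = _load_traces(cfg, stage)
    tracks_df = pd.read_csv(outdir / "tracks" / "tracks.csv")
    contacts = _match_contacts_to_tracks(cfg, list(traces), tracks_df)

    stage_dir = outdir / "domains"
    stage_dir.mkdir(parents=True, exist_ok=True)
    summaries = []
    with _timed("detect"):
        for track_id, trace in traces.items():
            contact = contacts.get(track_id)
            if contact is None:
                log.warning("cell %d: no bead contact assigned; skipped", track_id)
                continue
            series = md.detect_in_trace(
                trace.roi.data,
                trace.masks,
                trace.frames,
                cell_id=track_id,
                threshold=cfg.threshold,
                min_size=cfg.min_size,
                max_size=cfg.max_size,
                connectivity=cfg.connectivity,
            )
            rows = []
            for domain in series.all_domains():
                rows.append(
                    {
                        "frame": domain.frame,
                        "t_rel_s": (domain.frame - contact.contact_frame) * cfg.frame_interval_s,
                        "centroid_y": domain.centroid[0],
                        "centroid_x": domain.centroid[1],
                        "area_px": domain.area_px,
                        "mean_rel": domain.mean_rel_intensity,
                        "max_rel": domain.max_rel_intensity,
                    }
                )
            pd.DataFrame(
                rows,
                columns=[
                    "frame",
                    "t_rel_s",
                    "centroid_y",
                    "centroid_x",
                    "area_px",
                    "mean_rel",
                    "max_rel",
                ],
            ).to_csv(stage_dir / f"cell_{track_id}_domains.csv", index=False)
            summaries.append(
                md.summarize_cell(
                    series,
                    contact.contact_frame,
                    cfg.frame_interval_s,
                    window=(cfg.window_pre_s, cfg.window_post_s),
                    min_active_frames=cfg.min_active_frames,
                )
            )
        if not summaries:
            raise PipelineError("no cells with bead contacts to analyse")
        group = md.aggregate_group(summaries)
        group["per_cell"].to_csv(stage_dir / "group_per_cell.csv", index=False)
        group["timepoints"].to_csv(stage_dir / "group_timepoints.csv", index=False)
        log.info(
            "group %s: %d cells, activated fraction %.2f",
            cfg.group_label,
            group["n_cells"],
            group["activated_fraction"],
        )
    return stage_dir


def stage_dartboard(cfg: PipelineConfig) -> Path:
    """Aggregate aligned microdomains into dartboard densities and plots."""
    outdir = Path(cfg.output_dir)
    _setup_logging(outdir)
    meta = pd.read_csv(outdir / "normalized" / "normalized_meta.csv")
    tracks_df = pd.read_csv(outdir / "tracks" / "tracks.csv")
    contacts = _match_contacts_to_tracks(cfg, meta.track_id.tolist(), tracks_df)

    stage_dir = outdir / "dartboard"
    stage_dir.mkdir(parents=True, exist_ok=True)
    geom = db.DartboardGeometry(
        n_segments=cfg.n_segments, n_rings=cfg.n_rings, bullseye_frac=cfg.bullseye_frac
    )
    time_bins = [tuple(b) for b in cfg.time_bins]
    events = []
    n_cells = 0
    with _timed("dartboard"):
        for row in meta.itertuples():
            contact = contacts.get(int(row.track_id))
            if contact is None:
                continue
            domains_path = outdir / "domains" / f"cell_{int(row.track_id)}_domains.csv"
            if not domains_path.exists():
                continue
            n_cells += 1
            domains = pd.read_csv(domains_path)
            series = md.DomainTimeSeries(cell_id=int(row.track_id), domains_by_frame={})
            for d in domains.itertuples():
                series.domains_by_frame.setdefault(int(d.frame), []).append(
                    md.Microdomain(
                        frame=int(d.frame),
                        pixels=np.empty((0, 2)),
                        centroid=(d.centroid_y, d.centroid_x),
                        area_px=int(d.area_px),
                        mean_rel_intensity=d.mean_rel,
                        max_rel_intensity=d.max_rel,
                    )
                )
            events.extend(
                db.align_domains(
                    series,
                    contact,
                    board_center=(row.center_y, row.center_x),
                    template_radius=row.template_radius_px,
                    frame_interval_s=cfg.frame_interval_s,
                )
            )
        if n_cells == 0:
            raise PipelineError("no cells available for dartboard aggregation")
        acc = db.accumulate(events, geom, time_bins, n_cells=n_cells)
        acc.to_frame().to_csv(stage_dir / "dartboard.csv", index=False)
        import matplotlib

        matplotlib.use("Agg")
        for b in range(len(time_bins)):
            fig, _ = db.render_dartboard(acc, bin_index=b)
            fig.savefig(stage_dir / f"dartboard_bin{b}.png", dpi=120)
            import matplotlib.pyplot as plt

            plt.close(fig)
    return stage_dir


def run_pipeline(cfg: PipelineConfig, simulate: bool = False, spec=None) -> Path:
    """Run all stages in order; returns the output directory."""
    outdir = Path(cfg.output_dir)
    _setup_logging(outdir)
    cfg.to_yaml(outdir / "resolved_config.yaml")
    if simulate:
        stage_simulate(cfg, spec=spec)
    stage_postprocess(cfg)
    stage_track(cfg)
    stage_normalize(cfg)
    stage_detect(cfg)
    stage_dartboard(cfg)
    return outdir
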