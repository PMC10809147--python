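"""Channel registration, ratio computation, background subtraction and
bleaching correction.

Ratiometric Ca2+ imaging acquires two indicators with opposite Ca2+
response (e.g. Fluo-4 rising, Fura Red falling); the per-pixel ratio
cancels dye-loading and illumination artifacts but requires the two
channels to be spatially aligned first.  This module provides:

* intensity-based rigid/affine registration of the two channels
  (phase-correlation initialisation followed by local refinement of an
  affine transform under normalized cross-correlation),
* ratio computation with optional value clipping,
* background subtraction, and
* three bleaching corrections: frame-wise additive, frame-wise
  multiplicative (both normalise the mean intensity over the cell mask to
  a constant target), and a biexponential-fit based additive correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from .errors import DegenerateInputError, FitError
from .image_model import ChannelPair, FrameSequence

__all__ = [
    "AffineTransform2D",
    "BleachModel",
    "register_channels",
    "apply_transform",
    "estimate_background",
    "subtract_background",
    "compute_ratio",
    "correct_bleaching_additive",
    "correct_bleaching_multiplicative",
    "fit_biexponential",
    "correct_bleaching_biexponential",
]


@dataclass
class AffineTransform2D:
    """Affine map from fixed-image coordinates into moving-image coordinates.

    ``apply`` uses pull-style resampling: the output (aligned) pixel at
    ``p = (y, x)`` is sampled from the moving image at ``matrix @ p + offset``.
    """

    matrix: np.ndarray
    offset: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(self.matrix)) <= 1e-9:
            raise ValueError("affine matrix is singular")

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2))

    @classmethod
    def translation(cls, dy: float, dx: float) -> "AffineTransform2D":
        """Transform whose application shifts image content by (+dy, +dx)."""
        return cls(np.eye(2), [-dy, -dx])

    @classmethod
    def rotation(cls, angle_rad: float, center: tuple[float, float]) -> "AffineTransform2D":
        """Rotation of the image content by ``angle_rad`` about ``center`` (y, x)."""
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        m = np.array([[c, -s], [s, c]])  # inverse rotation in (y, x) order
        center = np.asarray(center, dtype=float)
        return cls(m, center - m @ center)

    def apply(self, image: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
        return ndimage.affine_transform(
            image, self.matrix, offset=self.offset, order=order, mode="constant", cval=cval
        )

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return AffineTransform2D(other.matrix @ self.matrix, other.matrix @ self.offset + other.offset)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """NCC over the pixels where both images are defined (finite)."""
    valid = np.isfinite(a) & np.isfinite(b)
    if valid.sum() < 16:
        return 0.0
    a = a[valid] - a[valid].mean()
    b = b[valid] - b[valid].mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def register_channels(
    fixed: np.ndarray,
    moving: np.ndarray,
    model: str = "affine",
    upsample_factor: int = 50,
) -> AffineTransform2D:
    """Estimate the transform aligning ``moving`` onto ``fixed``.

    Phase correlation provides a subpixel translation initialisation;
    for ``model="affine"`` a local Powell refinement of the full 6-parameter
    affine then maximises normalized cross-correlation.

    Parameters
    ----------
    model
        ``"translation"`` (phase correlation only) or ``"affine"``.

    Raises
    ------
    DegenerateInputError
        If either image is constant.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving frames must have the same shape")
    if fixed.std() == 0 or moving.std() == 0:
        raise DegenerateInputError("cannot register a constant image")

    shift, _, _ = phase_cross_correlation(
        fixed, moving, upsample_factor=upsample_factor, normalization=None
    )
    # pull-style offset: sampling moving at p - shift aligns it to fixed
    offset0 = -np.asarray(shift, dtype=float)
    center = (np.asarray(fixed.shape, dtype=float) - 1) / 2.0

    def euclidean(p):
        # (angle, ty, tx) about the image center
        c, s = np.cos(p[0]), np.sin(p[0])
        m = np.array([[c, -s], [s, c]])
        return AffineTransform2D(m, center - m @ center + p[1:])

    def cost_euclidean(p):
        return -_ncc(fixed, euclidean(p).apply(moving, cval=np.nan))

    res = optimize.minimize(
        cost_euclidean,
        np.concatenate([[0.0], offset0]),
        method="Powell",
        options={"xtol": 1e-5, "ftol": 1e-9, "maxiter": 2000},
    )
    best = euclidean(res.x)
    if model == "translation":
        res_t = optimize.minimize(
            lambda p: cost_euclidean(np.concatenate([[0.0], p])),
            offset0,
            method="Powell",
            options={"xtol": 1e-5, "ftol": 1e-9},
        )
        return AffineTransform2D(np.eye(2), res_t.x)
    if model != "affine":
        raise ValueError(f"unknown registration model {model!r}")

    # local affine polish around the euclidean solution; kept only if it
    # genuinely improves the similarity
    def cost_affine(p):
        return -_ncc(fixed, AffineTransform2D(p[:4].reshape(2, 2), p[4:]).apply(moving, cval=np.nan))

    p0 = np.concatenate([best.matrix.ravel(), best.offset])
    res_a = optimize.minimize(
        cost_affine, p0, method="Powell", options={"xtol": 1e-5, "ftol": 1e-9, "maxiter": 2000}
    )
    if res_a.fun < res.fun - 1e-6 and np.linalg.norm(res_a.x[:4] - p0[:4]) < 0.1:
        return AffineTransform2D(res_a.x[:4].reshape(2, 2), res_a.x[4:])
    return best


def apply_transform(
    seq: FrameSequence,
    tf: "AffineTransform2D | list[AffineTransform2D]",
    mode: str = "first_frame",
    order: int = 1,
) -> FrameSequence:
    """Resample a sequence under an affine transform.

    ``mode="first_frame"`` applies one transform to every frame (the
    default, time-efficient registration strategy); ``mode="per_frame"``
    expects one transform per frame.  Out-of-domain pixels are zero.
    """
    if mode == "first_frame":
        if not isinstance(tf, AffineTransform2D):
            raise ValueError("first_frame mode expects a single AffineTransform2D")
        tfs = [tf] * seq.n_frames
    elif mode == "per_frame":
        if isinstance(tf, AffineTransform2D) or len(tf) != seq.n_frames:
            raise ValueError(f"per_frame mode expects a list of {seq.n_frames} transforms")
        tfs = list(tf)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = np.stack([t.apply(frame, order=order) for t, frame in zip(tfs, seq.data)])
    return seq.with_data(np.clip(out, 0, None))


def estimate_background(
    seq: FrameSequence,
    mode: str = "percentile",
    percentile: float = 1.0,
    roi: "tuple[slice, slice] | None" = None,
    per_frame: bool = False,
):
    """Estimate the background level from the darkest pixels or a user ROI.

    Returns a scalar, or a length-T array when ``per_frame`` is true.
    """
    if mode == "percentile":
        region = seq.data
    elif mode == "roi":
        if roi is None:
            raise ValueError("roi mode requires a (slice, slice) region")
        region = seq.data[:, roi[0], roi[1]]
    else:
        raise ValueError(f"unknown background mode {mode!r}")
    if per_frame:
        return np.percentile(region.reshape(seq.n_frames, -1), percentile, axis=1)
    return float(np.percentile(region, percentile))


def subtract_background(seq: FrameSequence, bg) -> FrameSequence:
    """Subtract a scalar or per-frame background, clipping at zero."""
    bg = np.asarray(bg, dtype=float)
    if np.any(bg < 0):
        raise ValueError("background must be nonnegative")
    if bg.ndim == 1:
        if bg.shape[0] != seq.n_frames:
            raise ValueError("per-frame background length must equal T")
        bg = bg[:, None, None]
    elif bg.ndim != 0:
        raise ValueError("background must be a scalar or per-frame vector")
    return seq.with_data(np.clip(seq.data - bg, 0.0, None))


def compute_ratio(
    pair: ChannelPair,
    clip: "tuple[float, float] | None" = None,
    eps: float = 1e-9,
) -> FrameSequence:
    """Per-pixel ch1/ch2 ratio.

    Pixels where the denominator is <= ``eps`` are set to 0 rather than
    NaN/Inf — zero can never be a microdomain because detection thresholds
    sit above 1x the cell mean.  Optional ``clip=(lo, hi)`` saturates the
    ratio to the value range of interest (masked pixels stay 0).
    """
    num, den = pair.ch1.data, pair.ch2.data
    valid = den > eps
    ratio = np.zeros_like(num)
    np.divide(num, den, out=ratio, where=valid)
    if clip is not None:
        lo, hi = clip
        if not lo < hi:
            raise ValueError("clip requires lo < hi")
        ratio = np.clip(ratio, lo, hi)
        ratio[~valid] = 0.0
    return pair.ch1.with_data(ratio)


def _masked_means(seq: FrameSequence, masks: np.ndarray) -> np.ndarray:
    masks = np.asarray(masks, dtype=bool)
    if masks.shape != seq.data.shape:
        raise ValueError("masks must match the sequence shape (T, H, W)")
    means = np.empty(seq.n_frames)
    for t in range(seq.n_frames):
        m = masks[t]
        if not m.any():
            raise DegenerateInputError(f"empty cell mask in frame {t}")
        means[t] = seq.data[t][m].mean()
    return means


def correct_bleaching_additive(
    seq: FrameSequence, masks: np.ndarray, target_mean: "float | None" = None
) -> FrameSequence:
    """Frame-wise additive bleaching correction.

    Adds a per-frame offset so that the mean intensity over the cell mask
    equals ``target_mean`` (default: the first frame's masked mean) in
    every frame.  The offset is applied to all pixels of the frame.
    """
    means = _masked_means(seq, masks)
    if target_mean is None:
        target_mean = means[0]
    if not target_mean > 0:
        raise ValueError("target_mean must be > 0")
    offsets = target_mean - means
    return seq.with_data(np.clip(seq.data + offsets[:, None, None], 0.0, None))


def correct_bleaching_multiplicative(
    seq: FrameSequence, masks: np.ndarray, target_mean: "float | None" = None
) -> FrameSequence:
    """Frame-wise multiplicative correction: scales each frame so the masked
    mean equals ``target_mean``."""
    means = _masked_means(seq, masks)
    if np.any(means <= 0):
        raise DegenerateInputError("multiplicative correction requires positive masked means")
    if target_mean is None:
        target_mean = means[0]
    if not target_mean > 0:
        raise ValueError("target_mean must be > 0")
    factors = target_mean / means
    return seq.with_data(seq.data * factors[:, None, None])


@dataclass
class BleachModel:
    """Fitted bleaching model.

    ``kind`` is one of ``additive``, ``multiplicative``, ``biexponential``.
    For the biexponential kind, ``params = (a, b1, tau1, b2, tau2)`` of
    ``f(t) = a + b1*exp(-t/tau1) + b2*exp(-t/tau2)`` with ``tau1 <= tau2``.
    """

    kind: str
    params: tuple = ()
    target_mean: "float | None" = None
    residual: float = 0.0

    def evaluate(self, t) -> np.ndarray:
        if self.kind != "biexponential":
            raise ValueError("evaluate() is defined for the biexponential kind")
        a, b1, t1, b2, t2 = self.params
        t = np.asarray(t, dtype=float)
        return a + b1 * np.exp(-t / t1) + b2 * np.exp(-t / t2)


def _biexp(t, a, b1, t1, b2, t2):
    return a + b1 * np.exp(-t / t1) + b2 * np.exp(-t / t2)


def fit_biexponential(times: np.ndarray, values: np.ndarray) -> BleachModel:
    """Least-squares biexponential fit of a bleaching trace.

    Fits ``f(t) = a + b1*exp(-t/tau1) + b2*exp(-t/tau2)`` with both decay
    constants constrained positive.  The two exponential terms are
    exchange-degenerate; the result is reported with ``tau1 <= tau2``.
    Several initialisations spanning the observation window are tried and
    the best residual wins.

    Raises
    ------
    FitError
        If no initialisation converges.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 6:
        raise ValueError("need at least 6 samples to fit a biexponential")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    span = t[-1] - t[0]
    a0 = float(y[-1])
    amp = float(y[0] - y[-1])
    if abs(amp) < 1e-12 * max(1.0, abs(a0)):
        # flat trace: both amplitudes vanish, taus irrelevant
        return BleachModel("biexponential", (float(y.mean()), 0.0, span / 10, 0.0, span), residual=float(np.linalg.norm(y - y.mean())))

    lb = [-np.inf, -np.inf, 1e-9, -np.inf, 1e-9]
    ub = [np.inf, np.inf, np.inf, np.inf, np.inf]
    best = None
    tau_grid = [
        (span / 20, span / 2),
        (span / 50, span / 5),
        (span / 10, span),
        (span / 5, span * 2),
    ]
    for t1g, t2g in tau_grid:
        p0 = [a0, amp / 2, t1g, amp / 2, t2g]
        try:
            popt, _ = optimize.curve_fit(_biexp, t, y, p0=p0, bounds=(lb, ub), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        resid = float(np.linalg.norm(y - _biexp(t, *popt)))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise FitError("biexponential fit did not converge", {"n": t.size, "span": span})
    popt, resid = best
    a, b1, t1, b2, t2 = popt
    if t1 > t2:
        b1, t1, b2, t2 = b2, t2, b1, t1
    return BleachModel("biexponential", (float(a), float(b1), float(t1), float(b2), float(t2)), residual=resid)


def correct_bleaching_biexponential(
    seq: FrameSequence, masks: np.ndarray, model: "BleachModel | None" = None
) -> tuple[FrameSequence, BleachModel]:
    """Biexponential-fit based additive correction.

    Fits (or reuses) a biexponential model of the masked mean trace and
    subtracts the fitted decay ``f(t) - f(0)`` from each frame, restoring
    every frame's expected mean to the initial level.
    """
    times = np.arange(seq.n_frames) * seq.frame_interval_s
    if model is None:
        means = _masked_means(seq, masks)
        model = fit_biexponential(times, means)
    decay = model.evaluate(times) - model.evaluate(0.0)
    corrected = seq.with_data(np.clip(seq.data - decay[:, None, None], 0.0, None))
    return corrected, model
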