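"""Pixel-to-pixel parametric perfusion maps with a motion gate.

Every pixel of the recording is treated as its own ROI and characterized by
the same curve analysis used for manual ROIs, yielding a maximum-ingress or
maximum-egress image ("heat map").  Pixel-wise analysis presupposes that a
pixel images the same piece of tissue in every frame, so recordings with
even minimal movement (peristalsis, pulse) are detected and refused rather
than corrected: the motion gate estimates a global translation per frame by
phase cross-correlation of band-passed frames and rejects the recording when
any frame moves more than a threshold (default 1 px) from the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path as FsPath

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import difference_of_gaussians
from skimage.registration import phase_cross_correlation

from .curves import AnalysisConfig, analyze_curve
from .io import (BackgroundStats, FluorescenceVideo, PerfusionCurve,
                 pixel_level_background)

__all__ = [
    "MotionReport",
    "ParametricMap",
    "MotionRejectedError",
    "assess_motion",
    "compute_parametric_map",
    "render_heatmap",
    "save_map_tiff",
    "motion_report_csv",
]

MAP_FEATURES = ("max_ingress", "max_egress")


class MotionRejectedError(RuntimeError):
    """Raised when pixel-wise mapping is requested on a moving recording."""

    def __init__(self, max_shift: float, threshold: float):
        self.max_shift = max_shift
        self.threshold = threshold
        super().__init__(
            f"recording moves up to {max_shift:.2f} px (threshold {threshold:g} px); "
            "pixel-to-pixel mapping refused")


@dataclass
class MotionReport:
    """Per-frame translation estimates vs the reference frame."""

    shifts: np.ndarray  # T x 2, (rows, cols) px
    max_shift: float
    motion_ok: bool
    threshold: float
    reference_index: int
    notes: list = field(default_factory=list)


@dataclass
class ParametricMap:
    """Per-pixel feature image (i/s) with validity mask and motion verdict."""

    feature: str
    values: np.ndarray  # H x W, NaN where invalid
    valid_mask: np.ndarray
    motion: MotionReport

    def __post_init__(self) -> None:
        if self.feature not in MAP_FEATURES:
            raise ValueError(f"feature must be one of {MAP_FEATURES}")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("valid pixels must hold finite values")


def _reference_frame_index(video: FluorescenceVideo) -> int:
    """First frame at or after the global ingress begin of the mean-intensity
    curve; falls back to frame 0 when no onset is found.

    The slope-noise level is estimated robustly (scaled MAD) from the whole
    mean-intensity slope series so the bolus transient does not inflate it.
    """
    mean_curve = video.frames.mean(axis=(1, 2))
    t = video.timestamps
    s = np.empty_like(mean_curve)
    s[1:-1] = (mean_curve[2:] - mean_curve[:-2]) / (t[2:] - t[:-2])
    s[0], s[-1] = s[1], s[-2]
    slope_sd = 1.4826 * float(np.median(np.abs(s - np.median(s))))
    bg = BackgroundStats(mean=float(mean_curve.mean()), sd=0.0,
                         slope_sd=slope_sd, n_pixels=1)
    from .curves import detect_ingress_begin

    curve = PerfusionCurve(roi_id=0, location="body", t=t, intensity=mean_curve)
    t_begin, ok = detect_ingress_begin(curve, bg)
    if not ok:
        return 0
    return int(np.searchsorted(t, t_begin))


def _shift_improves_match(ref_bp: np.ndarray, frm_bp: np.ndarray,
                          shift: np.ndarray, margin: int = 5) -> bool:
    """True when applying ``shift`` to the frame raises its correlation with
    the reference; guards the estimator against degenerate scenes where the
    correlation surface is flat along some direction."""
    moved = ndimage.shift(frm_bp, shift, order=1, mode="nearest")
    sl = (slice(margin, -margin), slice(margin, -margin))
    a, b0, b1 = ref_bp[sl].ravel(), frm_bp[sl].ravel(), moved[sl].ravel()

    def _corr(x, y):
        xs, ys = x - x.mean(), y - y.mean()
        denom = np.sqrt((xs * xs).sum() * (ys * ys).sum())
        return float((xs * ys).sum() / denom) if denom > 0 else 0.0

    return _corr(a, b1) > _corr(a, b0) + 1e-9


def assess_motion(video: FluorescenceVideo, threshold: float = 1.0,
                  upsample_factor: int = 50, median_window: int = 9) -> MotionReport:
    """Estimate per-frame global translation and gate on the maximum shift.

    Translations are estimated sequentially: each frame is registered to its
    predecessor by sub-pixel phase cross-correlation of band-passed
    (difference-of-Gaussians) frames, and the increments are accumulated into
    a trajectory relative to the reference frame.  Adjacent frames sit at
    nearly the same bolus phase, so the evolving region contrast of the dye
    transit cannot masquerade as motion — only the static tissue texture
    drives each increment, and per-frame estimation errors telescope out of
    the cumulative sum.  Because genuine bulk motion is persistent while
    estimation noise is not, the trajectory is median-filtered over
    ``median_window`` frames before the maximum shift is taken.

    Near-constant frames (degenerate input) contribute zero increments with
    a QC note.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ref_idx = _reference_frame_index(video)
    notes: list[str] = []
    T = video.n_frames
    increments = np.zeros((T, 2))
    n_flat = 0
    prev_bp = None
    for k in range(T):
        frame = video.frames[k]
        if float(frame.std()) < 1e-12:
            n_flat += 1
            prev_bp = None
            continue
        frm_bp = difference_of_gaussians(frame, 1.0, 4.0)
        if prev_bp is not None:
            shift, _, _ = phase_cross_correlation(prev_bp, frm_bp,
                                                  upsample_factor=upsample_factor,
                                                  normalization=None)
            if shift.any() and not _shift_improves_match(prev_bp, frm_bp, shift):
                # no actual evidence of displacement (aperture-degenerate or
                # structureless pair): treat as stationary
                shift = np.zeros(2)
            increments[k] = shift
        prev_bp = frm_bp
    if n_flat:
        notes.append(f"{n_flat} near-constant frames assigned zero shift")
    cum = np.cumsum(increments, axis=0)
    if median_window > 1:
        cum = ndimage.median_filter(cum, size=(median_window, 1), mode="nearest")
    shifts = cum - cum[ref_idx]
    max_shift = float(np.max(np.hypot(shifts[:, 0], shifts[:, 1])))
    return MotionReport(shifts=shifts, max_shift=max_shift,
                        motion_ok=max_shift <= threshold,
                        threshold=threshold, reference_index=ref_idx, notes=notes)


def compute_parametric_map(video: FluorescenceVideo, feature: str,
                           bg: BackgroundStats,
                           cfg: AnalysisConfig = AnalysisConfig(),
                           motion_threshold: float = 1.0,
                           motion: MotionReport | None = None,
                           spatial_preaverage: bool = False) -> ParametricMap:
    """Analyze every pixel as an ROI and image the requested slope feature.

    The control-ROI background statistics are rescaled to single-pixel noise
    before thresholding (a pixel is noisier than an ROI mean by sqrt(area)).
    Recordings failing the motion gate are refused with
    :class:`MotionRejectedError`, naming the maximum estimated shift.
    ``spatial_preaverage`` applies a 3x3 spatial mean first, trading
    resolution for per-pixel noise; off by default.
    """
    if feature not in MAP_FEATURES:
        raise ValueError(f"feature must be one of {MAP_FEATURES}")
    if motion is None:
        motion = assess_motion(video, threshold=motion_threshold)
    if not motion.motion_ok:
        raise MotionRejectedError(motion.max_shift, motion.threshold)
    frames = video.frames
    if spatial_preaverage:
        from scipy import ndimage

        frames = ndimage.uniform_filter(frames, size=(1, 3, 3))
    bg_px = pixel_level_background(bg)
    H, W = video.frame_shape
    values = np.full((H, W), np.nan)
    valid = np.zeros((H, W), dtype=bool)
    t = video.timestamps
    for r in range(H):
        for c in range(W):
            curve = PerfusionCurve(roi_id=0, location="body", t=t,
                                   intensity=frames[:, r, c])
            feats = analyze_curve(curve, bg_px, cfg)
            if feats.valid.get(feature, False):
                values[r, c] = getattr(feats, feature)
                valid[r, c] = True
    return ParametricMap(feature=feature, values=values, valid_mask=valid,
                         motion=motion)


def render_heatmap(pmap: ParametricMap, path, cmap: str = "turbo",
                   vmax: float | None = None, dpi: int = 120) -> FsPath:
    """False-color rendering: blue (low) through green/yellow to red (high).

    Magnitudes are shown on a per-map scale from 0 to the 99th percentile of
    valid absolute values (so a negative-signed egress map renders with the
    same low-blue / high-red semantics); invalid pixels are neutral gray, and
    the color bar is labelled in i/s.
    """
    if not pmap.valid_mask.any():
        raise ValueError("cannot render an all-invalid map")
    mag = np.abs(pmap.values)
    if vmax is None:
        vmax = float(np.nanpercentile(mag[pmap.valid_mask], 99))
    display = np.ma.masked_array(mag, mask=~pmap.valid_mask)
    colormap = plt.get_cmap(cmap).copy()
    colormap.set_bad("0.65")
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(display, cmap=colormap, vmin=0.0, vmax=max(vmax, 1e-12),
                   interpolation="nearest")
    label = "|maximum egress| (i/s)" if pmap.feature == "max_egress" \
        else "maximum ingress (i/s)"
    fig.colorbar(im, ax=ax, label=label)
    ax.set_title(f"parametric map: {pmap.feature}")
    ax.set_xticks([])
    ax.set_yticks([])
    path = FsPath(path)
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return path


def save_map_tiff(pmap: ParametricMap, path) -> FsPath:
    """Write the value image as 32-bit float TIFF (invalid pixels NaN)."""
    path = FsPath(path)
    tifffile.imwrite(path, pmap.values.astype(np.float32))
    return path


def motion_report_csv(report: MotionReport, path) -> FsPath:
    path = FsPath(path)
    pd.DataFrame({
        "frame": np.arange(report.shifts.shape[0]),
        "shift_row_px": report.shifts[:, 0],
        "shift_col_px": report.shifts[:, 1],
    }).to_csv(path, index=False)
    return path
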