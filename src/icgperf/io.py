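"""Video and ROI input/output plus per-ROI curve extraction.

Fluorescence recordings are grayscale frame stacks (multi-page TIFF or a
container video readable by imageio).  Regions of interest (ROIs) are closed
polygons in a small JSON dialect; each ROI is labelled ``body``, ``apex`` or
``control``, with exactly one control ROI per set.  The control ROI sits on a
signal-free surgical drape and supplies autofluorescence / noise statistics.

Pixel conventions: row-major frames, origin top-left, 0-based indices.
Polygon vertices are (x=column, y=row); a pixel belongs to a polygon iff its
center ``(col + 0.5, row + 0.5)`` lies inside it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path as FsPath

import numpy as np
import tifffile
from matplotlib.path import Path as MplPath

__all__ = [
    "FluorescenceVideo",
    "Roi",
    "RoiSet",
    "PerfusionCurve",
    "BackgroundStats",
    "load_video",
    "save_video",
    "load_roi_set",
    "save_roi_set",
    "rasterize_polygon",
    "extract_curve",
    "background_stats",
    "scale_background",
    "pixel_level_background",
    "export_curves_csv",
]


@dataclass
class FluorescenceVideo:
    """A T x H x W stack of non-negative intensities with frame timestamps."""

    frames: np.ndarray
    timestamps: np.ndarray
    frame_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        T = self.frames.shape[0]
        if T < 2:
            raise ValueError("a video needs at least 2 frames")
        if self.timestamps.shape != (T,):
            raise ValueError("timestamps length must match frame count")
        if not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("intensities must be finite")
        if self.frames.min() < 0:
            raise ValueError("intensities must be non-negative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class Roi:
    """One region of interest: an id, a location label and a pixel mask."""

    id: int
    location: str
    mask: np.ndarray
    color: str = "#1f77b4"
    polygon: list | None = None

    def __post_init__(self) -> None:
        if self.location not in ("body", "apex", "control"):
            raise ValueError(f"unknown ROI location {self.location!r}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise ValueError(f"ROI {self.id}: mask must be a non-empty 2-D boolean array")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class RoiSet:
    """An ordered ROI collection with exactly one control region."""

    rois: list[Roi]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.rois]
        if len(ids) != len(set(ids)):
            raise ValueError("ROI ids must be unique within a set")
        n_control = sum(r.location == "control" for r in self.rois)
        if n_control != 1:
            raise ValueError(f"an ROI set needs exactly one control ROI, got {n_control}")
        shapes = {r.mask.shape for r in self.rois}
        if len(shapes) > 1:
            raise ValueError("all ROI masks must share one frame shape")

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    @property
    def control(self) -> Roi:
        return next(r for r in self.rois if r.location == "control")

    @property
    def tissue(self) -> list[Roi]:
        return [r for r in self.rois if r.location != "control"]

    def counts(self) -> dict[str, int]:
        out = {"body": 0, "apex": 0, "control": 0}
        for r in self.rois:
            out[r.location] += 1
        return out

    def require_pouch_scheme(self) -> None:
        """Pouch analyses need at least one apex and one body ROI."""
        c = self.counts()
        if c["apex"] < 1 or c["body"] < 1:
            raise ValueError("pouch analysis requires >=1 apex and >=1 body ROI")


@dataclass
class PerfusionCurve:
    """Mean ROI intensity over time; ``smoothed`` is filled by curve analysis."""

    roi_id: int
    location: str
    t: np.ndarray
    intensity: np.ndarray
    smoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.t.shape != self.intensity.shape:
            raise ValueError("t and intensity must have equal length")

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass
class BackgroundStats:
    """Autofluorescence statistics from the control ROI.

    ``slope_sd`` is the standard deviation of the finite-difference slope of
    the raw control curve (i/s); it calibrates the ingress-begin threshold.
    ``n_pixels`` records the control ROI area so the stats can be rescaled to
    ROIs of a different size (see :func:`scale_background`).
    """

    mean: float
    sd: float
    slope_sd: float
    n_pixels: int = 1
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# video I/O


def save_video(video: FluorescenceVideo, path, dtype: str | None = None,
               sidecar: bool = True) -> FsPath:
    """Write a multi-page grayscale TIFF plus a plain-text metadata sidecar.

    By default the in-memory dtype is preserved so a write→load round trip is
    bit-identical; pass ``dtype="uint16"`` for quantized 16-bit export.
    """
    path = FsPath(path)
    data = video.frames
    if dtype is not None:
        if np.issubdtype(np.dtype(dtype), np.integer):
            info = np.iinfo(dtype)
            data = np.clip(np.rint(data), info.min, info.max)
        data = data.astype(dtype)
    tifffile.imwrite(path, data, photometric="minisblack")
    if sidecar:
        lines = [f"frame_rate: {video.frame_rate!r}",
                 f"n_frames: {video.n_frames}",
                 f"duration: {video.duration!r}"]
        for k, v in video.meta.items():
            lines.append(f"{k}: {v}")
        path.with_suffix(path.suffix + ".meta.txt").write_text("\n".join(lines) + "\n")
    return path


def _read_sidecar_frame_rate(path: FsPath) -> float | None:
    sidecar = path.with_suffix(path.suffix + ".meta.txt")
    if not sidecar.exists():
        return None
    for line in sidecar.read_text().splitlines():
        if line.startswith("frame_rate:"):
            return float(line.split(":", 1)[1])
    return None


def load_video(path, frame_rate_override: float | None = None) -> FluorescenceVideo:
    """Read a multi-page TIFF or container video as a grayscale stack.

    RGB/overlay sources are reduced to their first channel (the fluorescence
    signal channel in overlay recordings).  Timestamps are ``k / frame_rate``;
    the rate comes from an override, a metadata sidecar, or fails loudly.
    """
    path = FsPath(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        frames = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        frames = iio.imread(path)
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4:  # T x H x W x C -> first channel
        frames = frames[..., 0]
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError(f"{path}: expected a frame stack, got shape {frames.shape}")
    rate = frame_rate_override
    if rate is None:
        rate = _read_sidecar_frame_rate(path)
    if rate is None:
        raise ValueError(f"{path}: no timing metadata; pass frame_rate_override")
    t = np.arange(frames.shape[0]) / float(rate)
    return FluorescenceVideo(frames.astype(float), t, float(rate),
                             meta={"path": str(path), "bit_depth": str(frames.dtype)})


# ---------------------------------------------------------------------------
# ROI I/O


def rasterize_polygon(polygon, frame_shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside the closed polygon."""
    H, W = frame_shape
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise ValueError("polygon must be a list of >=3 (x, y) vertices")
    if poly[:, 0].min() < 0 or poly[:, 0].max() > W or poly[:, 1].min() < 0 or poly[:, 1].max() > H:
        raise ValueError("polygon extends outside the frame")
    cols, rows = np.meshgrid(np.arange(W) + 0.5, np.arange(H) + 0.5)
    pts = np.column_stack([cols.ravel(), rows.ravel()])
    return MplPath(poly).contains_points(pts).reshape(H, W)


def load_roi_set(path, frame_shape: tuple[int, int] | None = None) -> RoiSet:
    """Read an ROI JSON file and rasterize its polygons onto the frame grid."""
    doc = json.loads(FsPath(path).read_text())
    shape = tuple(frame_shape) if frame_shape is not None else tuple(doc["frame_shape"])
    rois = []
    for spec in doc["rois"]:
        mask = rasterize_polygon(spec["polygon"], shape)
        if not mask.any():
            raise ValueError(f"ROI {spec['id']}: polygon covers no pixel centers")
        rois.append(Roi(id=int(spec["id"]), location=spec["location"], mask=mask,
                        color=spec.get("color", "#1f77b4"), polygon=spec["polygon"]))
    return RoiSet(rois)


def save_roi_set(roi_set: RoiSet, path) -> FsPath:
    path = FsPath(path)
    shape = roi_set.rois[0].mask.shape
    doc = {"frame_shape": list(shape), "rois": []}
    for r in roi_set:
        if r.polygon is None:
            raise ValueError(f"ROI {r.id} has no polygon; only polygon ROIs are serializable")
        doc["rois"].append({"id": r.id, "location": r.location,
                            "polygon": [list(map(float, p)) for p in r.polygon],
                            "color": r.color})
    path.write_text(json.dumps(doc, indent=1))
    return path


# ---------------------------------------------------------------------------
# curve extraction


def extract_curve(video: FluorescenceVideo, roi: Roi) -> PerfusionCurve:
    """Perfusion-time curve: per-frame arithmetic mean intensity over the mask.

    No background subtraction is applied: all slope indicators are invariant
    to constant offsets, and the control ROI serves QC only.
    """
    if roi.mask.shape != video.frame_shape:
        raise ValueError("ROI mask shape does not match the video frame")
    series = video.frames[:, roi.mask].mean(axis=1)
    return PerfusionCurve(roi_id=roi.id, location=roi.location,
                          t=video.timestamps.copy(), intensity=series)


def _raw_slope(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    s = np.empty_like(y)
    s[1:-1] = (y[2:] - y[:-2]) / (t[2:] - t[:-2])
    s[0] = (y[1] - y[0]) / (t[1] - t[0])
    s[-1] = (y[-1] - y[-2]) / (t[-1] - t[-2])
    return s


def background_stats(video: FluorescenceVideo, control_roi: Roi) -> BackgroundStats:
    """Mean, noise sd and slope-noise sd of the control (drape) curve."""
    if control_roi.location != "control":
        raise ValueError("background_stats needs the control ROI")
    curve = extract_curve(video, control_roi)
    y, t = curve.intensity, curve.t
    notes: list[str] = []
    sd = float(np.std(y, ddof=1))
    slope_sd = float(np.std(_raw_slope(t, y), ddof=1)) if y.size >= 3 else 0.0
    # QC: a drifting control suggests stray light or dye contamination
    trend = np.polyfit(t, y, 1)[0] if y.size >= 2 else 0.0
    if abs(trend) * (t[-1] - t[0]) > 3.0 * max(sd, 1e-12):
        notes.append(f"control ROI drifts ({trend:+.3g} i/s); background stats may be biased")
    return BackgroundStats(mean=float(np.mean(y)), sd=sd, slope_sd=slope_sd,
                           n_pixels=control_roi.n_pixels, notes=notes)


def scale_background(bg: BackgroundStats, n_pixels: int) -> BackgroundStats:
    """Rescale control-ROI noise statistics to an ROI of ``n_pixels``.

    Under per-pixel independent noise, the sd of an n-pixel mean scales as
    1/sqrt(n); this converts stats measured on the control ROI to the noise
    level expected for a target ROI of a different size.
    """
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    f = np.sqrt(bg.n_pixels / n_pixels)
    return replace(bg, sd=bg.sd * f, slope_sd=bg.slope_sd * f, n_pixels=n_pixels)


def pixel_level_background(bg: BackgroundStats) -> BackgroundStats:
    """Control stats rescaled to a single-pixel ROI (for parametric maps)."""
    return scale_background(bg, 1)


def export_curves_csv(curves: list[PerfusionCurve], path) -> FsPath:
    """Long-format CSV: roi_id, location, time_s, intensity_raw, intensity_smooth."""
    import pandas as pd

    rows = []
    for c in curves:
        sm = c.smoothed if c.smoothed is not None else np.full(c.n, np.nan)
        rows.append(pd.DataFrame({
            "roi_id": c.roi_id, "location": c.location, "time_s": c.t,
            "intensity_raw": c.intensity, "intensity_smooth": sm,
        }))
    path = FsPath(path)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    return path
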