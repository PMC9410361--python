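"""Ground-truthed synthetic ICG-NIRF video generator.

Clinical fluorescence recordings of bowel perfusion are not publicly
available, so every downstream stage of the package is exercised on synthetic
videos whose kinetics are known in closed form.  Each tissue region follows a
gamma-variate bolus-transit curve

    I(t) = B                                          for t <= t0
    I(t) = B + A * tau**alpha * exp(alpha * (1 - tau)),  tau = (t - t0) / tp

the standard indicator-dilution form: baseline autofluorescence ``B``, an
inflow (ingress) phase after dye arrival ``t0``, a peak of exactly ``B + A``
at ``t0 + tp``, and an outflow (egress) tail whose sharpness is set by
``alpha``.  Detector noise is additive Gaussian per pixel; a drape region has
zero amplitude and provides the negative control.  Impaired perfusion at the
pouch apex — the pattern seen adjacent to leaking anastomoses — is emulated
by shrinking the apex amplitude (factor ``f_A``) and stretching its
time-to-peak (factor ``f_tp``), which depresses both inflow and outflow
slopes.

Ground truth is always evaluated on the noiseless analytic curve, never on
rendered frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path as FsPath

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import FluorescenceVideo, Roi, RoiSet

__all__ = [
    "KineticParams",
    "RegionLayout",
    "GroundTruth",
    "CohortEntry",
    "gamma_variate_curve",
    "gamma_variate_slope",
    "analytic_curve_features",
    "default_pouch_layout",
    "make_gain_field",
    "apply_apex_impairment",
    "build_roi_set",
    "render_video",
    "generate_cohort",
    "inject_motion",
]

#: feature names carried by ground truth, in export order
FEATURE_NAMES = ("t_ingress_begin", "t_max", "i_max",
                 "ingress", "max_ingress", "egress", "max_egress")


@dataclass(frozen=True)
class KineticParams:
    """Gamma-variate bolus kinetics for one region.

    baseline
        Autofluorescence level B (arbitrary detector intensity units, >= 0).
    amplitude
        Peak rise A above baseline (i, >= 0); the noiseless peak is B + A.
    t_arrival
        Dye arrival time t0 (s, >= 0); the curve equals B for t <= t0.
    time_to_peak
        tp (s, > 0); the peak sits at t0 + tp.
    shape
        Dimensionless alpha (> 0) controlling rise/washout sharpness.
    noise_sd
        Per-pixel additive Gaussian detector noise sd (i, >= 0).
    """

    baseline: float = 5.0
    amplitude: float = 100.0
    t_arrival: float = 10.0
    time_to_peak: float = 8.0
    shape: float = 2.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.baseline, self.amplitude, self.t_arrival,
                self.time_to_peak, self.shape, self.noise_sd)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("kinetic parameters must be finite")
        if self.baseline < 0 or self.amplitude < 0 or self.t_arrival < 0 \
                or self.time_to_peak <= 0 or self.shape <= 0 or self.noise_sd < 0:
            raise ValueError("kinetic parameter out of range")


def gamma_variate_curve(params: KineticParams, t) -> np.ndarray | float:
    """Noiseless intensity at time(s) ``t`` (seconds, >= 0)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or not np.all(np.isfinite(t_arr)):
        raise ValueError("t must be finite and >= 0")
    tau = (t_arr - params.t_arrival) / params.time_to_peak
    out = np.full(t_arr.shape, params.baseline, dtype=float)
    rising = tau > 0
    tr = tau[rising]
    out[rising] += params.amplitude * tr ** params.shape * np.exp(params.shape * (1.0 - tr))
    return out if np.ndim(t) else float(out)


def gamma_variate_slope(params: KineticParams, t) -> np.ndarray | float:
    """Analytic derivative dI/dt (i/s) of the noiseless curve."""
    t_arr = np.asarray(t, dtype=float)
    tau = (t_arr - params.t_arrival) / params.time_to_peak
    out = np.zeros(t_arr.shape, dtype=float)
    rising = tau > 0
    tr = tau[rising]
    a = params.shape
    out[rising] = (params.amplitude * a / params.time_to_peak) \
        * tr ** (a - 1.0) * (1.0 - tr) * np.exp(a * (1.0 - tr))
    return out if np.ndim(t) else float(out)


def analytic_curve_features(params: KineticParams,
                            egress_window_s: float = 5.0) -> dict[str, float]:
    """Closed-form perfusion indicators of the noiseless curve.

    * ingress begin: t0 (first instant of positive slope)
    * t_max, i_max: t0 + tp and B + A
    * ingress: secant slope from ingress begin to the peak, A / tp
    * max ingress / max egress: slope extrema, at tau = 1 -/+ 1/sqrt(alpha)
    * egress: 5-s secant after the peak, (I(t_max + 5) - I(t_max)) / 5

    These are properties of the analytic curve, independent of any recording
    length; whether a finite recording can measure them is the analysis
    stage's concern.  A region with zero amplitude has no perfusion signal:
    all indicators are NaN except i_max = B.
    """
    B, A = params.baseline, params.amplitude
    t0, tp, a = params.t_arrival, params.time_to_peak, params.shape
    if A == 0:
        return {"t_ingress_begin": np.nan, "t_max": np.nan, "i_max": B,
                "ingress": np.nan, "max_ingress": np.nan,
                "egress": np.nan, "max_egress": np.nan}
    if a < 1:
        raise ValueError("slope extrema are unbounded at onset for shape < 1")
    t_max = t0 + tp
    tau_in = 1.0 - 1.0 / math.sqrt(a)
    tau_out = 1.0 + 1.0 / math.sqrt(a)
    max_ingress = float(gamma_variate_slope(params, t0 + tp * tau_in)) if tau_in > 0 \
        else float(A * a / tp * math.exp(a))  # shape == 1: onset jump
    return {
        "t_ingress_begin": t0,
        "t_max": t_max,
        "i_max": B + A,
        "ingress": A / tp,
        "max_ingress": max_ingress,
        "egress": (float(gamma_variate_curve(params, t_max + egress_window_s)) - (B + A))
        / egress_window_s,
        "max_egress": float(gamma_variate_slope(params, t0 + tp * tau_out)),
    }


def make_gain_field(frame_shape: tuple[int, int], strength: float = 0.2,
                    scale_px: float = 3.0, seed: int = 0) -> np.ndarray:
    """Static multiplicative heterogeneity field around 1.

    Real fluorescence scenes are spatially textured (vessels, tissue folds,
    uneven illumination); a smoothed Gaussian random field with relative
    strength ``strength`` and correlation length ``scale_px`` emulates this.
    The field is clipped to [0.5, 1.5] so intensities stay positive.  Without
    such texture, frame-to-frame registration of a synthetic scene would be
    ill-posed (a translation of a piecewise-constant strip pattern is almost
    unobservable).
    """
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.normal(size=frame_shape), scale_px)
    sd = field.std()
    if sd > 0:
        field = field / sd
    return np.clip(1.0 + strength * field, 0.5, 1.5)


@dataclass
class RegionLayout:
    """Label map assigning each pixel to one kinetic region.

    ``labels`` is an H x W array of region names; ``params`` maps each name
    to its kinetics.  A ``drape`` region must have zero amplitude (baseline
    autofluorescence plus noise only).  ``gain`` is an optional static
    per-pixel multiplicative field (see :func:`make_gain_field`); the pixel's
    noiseless curve is ``gain * curve(region params)``, so every slope
    indicator of that pixel scales by its gain.
    """

    labels: np.ndarray
    params: dict[str, KineticParams]
    gain: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be H x W")
        present = set(np.unique(self.labels))
        if present != set(self.params):
            raise ValueError(f"label map regions {present} != parameterised regions "
                             f"{set(self.params)} (zero-area or missing region)")
        drape = self.params.get("drape")
        if drape is not None and drape.amplitude != 0:
            raise ValueError("drape region must have zero amplitude")
        if self.gain is not None:
            self.gain = np.asarray(self.gain, dtype=float)
            if self.gain.shape != self.labels.shape or (self.gain <= 0).any():
                raise ValueError("gain must be a positive H x W field")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.labels.shape

    def region_mask(self, name: str) -> np.ndarray:
        return self.labels == name


@dataclass
class GroundTruth:
    """Analytic per-region perfusion indicators (noise- and seed-invariant)."""

    regions: dict[str, dict[str, float]]
    duration: float
    egress_window_s: float = 5.0

    def feature_map(self, layout: RegionLayout, feature: str) -> np.ndarray:
        """Per-pixel expansion of a region-level ground-truth feature.

        Intensity-scale features (slopes, i_max) are multiplied by the
        layout's static gain field; time landmarks are gain-invariant.
        """
        out = np.full(layout.frame_shape, np.nan)
        for name, feats in self.regions.items():
            out[layout.region_mask(name)] = feats[feature]
        if layout.gain is not None and feature not in ("t_ingress_begin", "t_max"):
            out = out * layout.gain
        return out

    def to_frame(self, patient_id: str = "") -> pd.DataFrame:
        rows = [{"patient_id": patient_id, "region": name,
                 "pixel_row": np.nan, "pixel_col": np.nan,
                 "feature": feat, "value": val}
                for name, feats in self.regions.items()
                for feat, val in feats.items()]
        return pd.DataFrame(rows)

    def to_csv(self, path, patient_id: str = "") -> FsPath:
        path = FsPath(path)
        self.to_frame(patient_id).to_csv(path, index=False)
        return path


def default_pouch_layout(body: KineticParams, apex: KineticParams,
                         appendage: KineticParams | None = None,
                         height: int = 36, width: int = 48,
                         drape_width: int = 10,
                         gain: np.ndarray | None = None) -> RegionLayout:
    """Cartoon J-pouch scene: drape strip (left), appendage (top-left of the
    tissue), pouch body (center) and pouch apex (right, adjacent to the
    anastomosis)."""
    if height < 12 or width < drape_width + 20:
        raise ValueError("frame too small for the default pouch layout")
    labels = np.full((height, width), "body", dtype="<U9")
    labels[:, :drape_width] = "drape"
    app_h = max(6, height // 4)
    app_w = max(6, (width - drape_width) // 4)
    labels[:app_h, drape_width: drape_width + app_w] = "appendage"
    apex_w = max(8, (width - drape_width) // 4)
    labels[:, width - apex_w:] = "apex"
    if appendage is None:
        appendage = body
    drape = KineticParams(baseline=body.baseline, amplitude=0.0, t_arrival=0.0,
                          time_to_peak=1.0, shape=1.0, noise_sd=body.noise_sd)
    return RegionLayout(labels=labels, params={"body": body, "apex": apex,
                                               "appendage": appendage, "drape": drape},
                        gain=gain)


def apply_apex_impairment(layout: RegionLayout, f_amplitude: float,
                          f_time_to_peak: float) -> RegionLayout:
    """Scale apex kinetics: amplitude * f_amplitude, time-to-peak * f_time_to_peak.

    ``f_amplitude`` in (0, 1] and ``f_time_to_peak`` >= 1 jointly depress the
    inflow and outflow slope magnitudes of the apex relative to the body.
    """
    if not (0 < f_amplitude <= 1) or f_time_to_peak < 1:
        raise ValueError("need 0 < f_amplitude <= 1 and f_time_to_peak >= 1")
    apex = layout.params["apex"]
    impaired = replace(apex, amplitude=apex.amplitude * f_amplitude,
                       time_to_peak=apex.time_to_peak * f_time_to_peak)
    params = dict(layout.params)
    params["apex"] = impaired
    return RegionLayout(labels=layout.labels.copy(), params=params,
                        gain=None if layout.gain is None else layout.gain.copy())


# ROI color cycle: apex warm, body cool-to-green, control gray (dashed in plots)
_ROI_COLORS = ["#d62728", "#ff7f0e", "#1f77b4", "#aec7e8", "#2ca02c", "#98df8a",
               "#9467bd", "#c5b0d5", "#8c564b", "#17becf"]


def build_roi_set(layout: RegionLayout, roi_size: int = 5,
                  n_body: int = 8, n_apex: int = 2) -> RoiSet:
    """Place square ROIs on the layout: ids 1..n_apex on the apex,
    then body ROIs (one on the appendage when present, labelled body),
    and one control ROI on the drape."""

    def _square_rois(region: str, n: int, first_id: int, location: str) -> list[Roi]:
        mask = layout.region_mask(region)
        # top-left corners where the full square fits inside the region
        H, W = mask.shape
        if H < roi_size or W < roi_size:
            raise ValueError(f"frame smaller than ROI size {roi_size}")
        win = np.lib.stride_tricks.sliding_window_view(mask, (roi_size, roi_size))
        tl = np.argwhere(win.sum(axis=(2, 3)) == roi_size * roi_size)
        if len(tl) < n:
            raise ValueError(f"region {region!r} too small for {n} ROIs of size {roi_size}")
        picks = tl[np.linspace(0, len(tl) - 1, n).round().astype(int)]
        rois = []
        for j, (r0, c0) in enumerate(picks):
            poly = [[float(c0), float(r0)], [float(c0 + roi_size), float(r0)],
                    [float(c0 + roi_size), float(r0 + roi_size)],
                    [float(c0), float(r0 + roi_size)]]
            m = np.zeros(layout.frame_shape, dtype=bool)
            m[r0:r0 + roi_size, c0:c0 + roi_size] = True
            rid = first_id + j
            color = "#888888" if location == "control" else _ROI_COLORS[(rid - 1) % len(_ROI_COLORS)]
            rois.append(Roi(id=rid, location=location, mask=m, color=color, polygon=poly))
        return rois

    rois = _square_rois("apex", n_apex, 1, "apex")
    has_app = "appendage" in layout.params and layout.region_mask("appendage").any()
    n_body_main = n_body - 1 if has_app else n_body
    rois += _square_rois("body", n_body_main, n_apex + 1, "body")
    if has_app:
        rois += _square_rois("appendage", 1, n_apex + n_body_main + 1, "body")
    rois += _square_rois("drape", 1, n_apex + n_body + 1, "control")
    return RoiSet(rois)


def render_video(layout: RegionLayout, duration: float = 120.0,
                 frame_rate: float = 4.0, seed: int | None = 0
                 ) -> tuple[FluorescenceVideo, GroundTruth]:
    """Render the layout to a frame stack with per-pixel Gaussian noise.

    Identical seeds give bit-identical frames; the attached ground truth is
    computed from the analytic curves and is independent of noise and seed.
    Negative noise excursions are clipped at zero (detector floor).
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    n = int(round(duration * frame_rate))
    if n < 2:
        raise ValueError("duration * frame_rate must give at least 2 frames")
    if seed is None:
        raise ValueError("a seed is required for reproducible rendering")
    t = np.arange(n) / frame_rate
    H, W = layout.frame_shape
    frames = np.empty((n, H, W), dtype=float)
    sigma = np.zeros((H, W), dtype=float)
    truth: dict[str, dict[str, float]] = {}
    for name, p in layout.params.items():
        mask = layout.region_mask(name)
        frames[:, mask] = gamma_variate_curve(p, t)[:, None]
        sigma[mask] = p.noise_sd
        truth[name] = analytic_curve_features(p)
    if layout.gain is not None:
        frames *= layout.gain[None, :, :]
    if sigma.any():
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(size=(n, H, W)) * sigma
        np.clip(frames, 0.0, None, out=frames)
    video = FluorescenceVideo(frames, t, float(frame_rate),
                              meta={"seed": seed, "duration": duration,
                                    "frame_rate": frame_rate})
    return video, GroundTruth(regions=truth, duration=float(duration))


@dataclass
class CohortEntry:
    """One synthetic patient: recording, ROI scheme, outcome and ground truth."""

    patient_id: str
    outcome: str  # "AL" or "non_AL"
    video: FluorescenceVideo
    roi_set: RoiSet
    ground_truth: GroundTruth
    layout: RegionLayout
    time_point: str = "T2"


def _draw_region_params(rng: np.random.Generator, t_arrival: float,
                        time_to_peak: float, noise_sd: float) -> KineticParams:
    """One region's kinetics around the patient's systemic bolus timing.

    Arrival time and time-to-peak are systemic (one intravenous bolus reaches
    the whole pouch nearly simultaneously), so regions share the patient's
    timing up to a small jitter; amplitude, baseline and washout shape vary
    region to region.  Ranges emulate intraoperative recordings: arrival
    within the first 15 s of the 120 s video, peak 8-14 s later, washout
    sharp enough that the slope extrema fall inside the recording.
    """
    return KineticParams(
        baseline=rng.uniform(4.0, 10.0),
        amplitude=rng.uniform(60.0, 120.0),
        t_arrival=t_arrival + rng.uniform(-0.2, 0.2),
        time_to_peak=time_to_peak * rng.uniform(0.96, 1.04),
        shape=rng.uniform(1.5, 3.0),
        noise_sd=noise_sd,
    )


def generate_cohort(n_patients: int = 18, n_al: int = 4, seed: int = 0,
                    f_amplitude: float = 0.3, f_time_to_peak: float = 1.5,
                    height: int = 36, width: int = 48,
                    duration: float = 120.0, frame_rate: float = 4.0,
                    noise_sd: float = 0.5) -> list[CohortEntry]:
    """Synthetic cohort with ``n_al`` anastomotic-leak (AL) patients.

    Every patient draws body and apex kinetics independently from one common
    distribution; AL patients additionally apply the apex impairment factors,
    so their apex ground-truth slope indicators are strictly below the body's.
    With ``f_amplitude = 1`` and ``f_time_to_peak = 1`` the impairment is a
    no-op and AL / non-AL entries are exchangeable (null condition).
    """
    if not 0 <= n_al <= n_patients:
        raise ValueError("need 0 <= n_al <= n_patients")
    rng = np.random.default_rng(seed)
    al_idx = set(rng.choice(n_patients, size=n_al, replace=False).tolist())
    entries = []
    for i in range(n_patients):
        t_arrival = rng.uniform(8.0, 15.0)
        time_to_peak = rng.uniform(8.0, 14.0)
        body = _draw_region_params(rng, t_arrival, time_to_peak, noise_sd)
        apex = _draw_region_params(rng, t_arrival, time_to_peak, noise_sd)
        gain_seed = int(rng.integers(0, 2**31 - 1))
        layout = default_pouch_layout(body=body, apex=apex,
                                      height=height, width=width,
                                      gain=make_gain_field((height, width),
                                                           seed=gain_seed))
        outcome = "AL" if i in al_idx else "non_AL"
        if outcome == "AL":
            layout = apply_apex_impairment(layout, f_amplitude, f_time_to_peak)
        render_seed = int(rng.integers(0, 2**31 - 1))
        video, truth = render_video(layout, duration=duration,
                                    frame_rate=frame_rate, seed=render_seed)
        entries.append(CohortEntry(patient_id=f"P{i + 1:02d}", outcome=outcome,
                                   video=video, roi_set=build_roi_set(layout),
                                   ground_truth=truth, layout=layout))
    return entries


def inject_motion(video: FluorescenceVideo, shift: tuple[float, float],
                  start_frame: int, fill: float | None = None) -> FluorescenceVideo:
    """Translate frames from ``start_frame`` on by ``shift`` = (rows, cols).

    Emulates bowel movement mid-recording.  Uncovered edge pixels are filled
    with ``fill`` (default: median of the first frame, i.e. the pre-bolus
    baseline); timestamps are unchanged.  Fractional shifts use bilinear
    interpolation; integer shifts are exact translations.
    """
    dr, dc = float(shift[0]), float(shift[1])
    H, W = video.frame_shape
    if abs(dr) >= H or abs(dc) >= W:
        raise ValueError("shift larger than the frame")
    if not 0 <= start_frame < video.n_frames:
        raise ValueError("start_frame out of range")
    if fill is None:
        fill = float(np.median(video.frames[0]))
    frames = video.frames.copy()
    if dr != 0 or dc != 0:
        for k in range(start_frame, video.n_frames):
            frames[k] = ndimage.shift(video.frames[k], (dr, dc), order=1,
                                      mode="constant", cval=fill)
        np.clip(frames, 0.0, None, out=frames)
    return FluorescenceVideo(frames, video.timestamps.copy(), video.frame_rate,
                             meta={**video.meta, "injected_shift": (dr, dc),
                                   "motion_start_frame": start_frame})
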