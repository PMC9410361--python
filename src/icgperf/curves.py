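"""Perfusion-time-curve indicators.

A perfusion curve (mean ROI fluorescence intensity vs time) is characterized
by recurring landmarks and slope indicators, all in units of intensity change
per second (i/s):

* **ingress begin** — earliest time of sustained positive slope (dye inflow
  starts).
* **maximum intensity** — the curve peak ``I_max`` at ``t_max``; start of the
  egress (outflow) phase.
* **ingress** — mean inflow slope: the secant from ingress begin to the peak.
* **maximum ingress** — largest instantaneous slope during the ingress phase.
* **egress** — 5-second secant after the peak,
  ``(I_tmax+5 - I_tmax) / 5``; negative for outflow.
* **maximum egress** — most negative instantaneous slope after the peak.

Curves are smoothed with a centered moving average before slope extrema and
intensities are read off; ingress-begin detection runs on the raw curve with
a threshold of ``k`` times the control-ROI slope-noise sd, sustained for
``m`` consecutive samples, so that the detected onset converges to the true
arrival time as the frame rate grows.  Degenerate signals (e.g. the control
ROI) yield invalid flags and quality notes, never exceptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import BackgroundStats, PerfusionCurve

__all__ = [
    "SmoothingConfig",
    "AnalysisConfig",
    "CurveFeatures",
    "smooth_curve",
    "slope_series",
    "detect_ingress_begin",
    "locate_maximum_intensity",
    "compute_ingress",
    "compute_max_ingress",
    "compute_egress",
    "compute_max_egress",
    "analyze_curve",
]


@dataclass(frozen=True)
class SmoothingConfig:
    """Centered moving average; the window shrinks at the recording edges."""

    window_s: float = 1.0
    method: str = "moving_average"


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable constants of the curve characterization.

    k, m
        Ingress-begin detection: slope must exceed ``k`` times the control
        slope-noise sd for ``m`` consecutive samples (3-sigma rule).
    egress_window_s
        Length of the post-peak secant window (5 s).
    subtract_background
        Optionally subtract the control-ROI mean from the curve; off by
        default since every slope indicator is offset-invariant.
    """

    smoothing: SmoothingConfig = SmoothingConfig()
    k: float = 3.0
    m: int = 3
    egress_window_s: float = 5.0
    subtract_background: bool = False


@dataclass
class CurveFeatures:
    """Perfusion indicators for one ROI, with per-feature validity flags.

    Invalid features hold NaN; ``valid`` says which entries are meaningful
    and ``notes`` records why the others are not.  ``i_tmax`` equals
    ``i_max`` by definition.
    """

    roi_id: int
    location: str
    t_ingress_begin: float = np.nan
    t_max: float = np.nan
    i_max: float = np.nan
    i_tmax_plus5: float = np.nan
    ingress: float = np.nan
    max_ingress: float = np.nan
    egress: float = np.nan
    max_egress: float = np.nan
    valid: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    SLOPE_FEATURES = ("ingress", "max_ingress", "egress", "max_egress")

    @property
    def i_tmax(self) -> float:
        return self.i_max

    def to_dict(self) -> dict:
        return {
            "roi_id": self.roi_id, "location": self.location,
            "t_ingress_begin_s": self.t_ingress_begin, "t_max_s": self.t_max,
            "i_max": self.i_max, "i_tmax_plus5": self.i_tmax_plus5,
            "ingress_i_per_s": self.ingress, "max_ingress_i_per_s": self.max_ingress,
            "egress_i_per_s": self.egress, "max_egress_i_per_s": self.max_egress,
            **{f"valid_{k}": v for k, v in self.valid.items()},
            "notes": "; ".join(self.notes),
        }


def _moving_average(y: np.ndarray, half: int) -> np.ndarray:
    n = y.size
    idx = np.arange(n)
    csum = np.concatenate(([0.0], np.cumsum(y)))
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def smooth_curve(curve: PerfusionCurve, cfg: SmoothingConfig = SmoothingConfig()
                 ) -> PerfusionCurve:
    """Fill ``smoothed`` with a centered moving average of the raw curve."""
    if cfg.method != "moving_average":
        raise ValueError(f"unknown smoothing method {cfg.method!r}")
    half = max(1, int(round(cfg.window_s * curve.frame_rate / 2.0)))
    if 2 * half + 1 > curve.n:
        raise ValueError("smoothing window longer than the recording")
    return replace(curve, smoothed=_moving_average(curve.intensity, half))


def _finite_difference(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Central differences, one-sided at the ends."""
    if y.size < 3:
        raise ValueError("need at least 3 samples for a slope series")
    s = np.empty_like(y)
    s[1:-1] = (y[2:] - y[:-2]) / (t[2:] - t[:-2])
    s[0] = (y[1] - y[0]) / (t[1] - t[0])
    s[-1] = (y[-1] - y[-2]) / (t[-1] - t[-2])
    return s


def slope_series(curve: PerfusionCurve) -> np.ndarray:
    """Instantaneous slope (i/s) of the smoothed curve."""
    if curve.smoothed is None:
        raise ValueError("smooth the curve before taking its slope series")
    return _finite_difference(curve.t, curve.smoothed)


def detect_ingress_begin(curve: PerfusionCurve, bg: BackgroundStats,
                         k: float = 3.0, m: int = 3) -> tuple[float, bool]:
    """Earliest sustained positive slope of the raw curve.

    Returns ``(t, True)`` for the first sample of the first run of ``m``
    consecutive raw-curve slopes exceeding ``max(k * bg.slope_sd, guard)``,
    or ``(nan, False)`` when no such run exists.  The guard is a relative
    machine-scale floor so a noiseless flat curve never triggers.  Detection
    deliberately uses the raw (not smoothed) slope: a centered smoother
    spreads the onset backwards by half a window, a bias that would not
    shrink with the frame rate.
    """
    s = _finite_difference(curve.t, curve.intensity)
    guard = 1e-9 * float(np.max(np.abs(s))) if s.size else 0.0
    thr = max(k * bg.slope_sd, guard)
    above = s > thr
    if m > above.size:
        return np.nan, False
    runs = np.convolve(above.astype(int), np.ones(m, dtype=int), mode="valid")
    hits = np.flatnonzero(runs == m)
    if hits.size == 0:
        return np.nan, False
    return float(curve.t[hits[0]]), True


def locate_maximum_intensity(curve: PerfusionCurve,
                             t_ingress_begin: float | None = None
                             ) -> tuple[float, float]:
    """Peak of the smoothed curve (earliest sample on ties).

    The search is restricted to ``t >= t_ingress_begin`` when a valid onset
    is given, so a pre-arrival artifact cannot masquerade as the peak.
    """
    if curve.smoothed is None:
        raise ValueError("smooth the curve before locating its peak")
    y, t = curve.smoothed, curve.t
    if t_ingress_begin is not None and np.isfinite(t_ingress_begin):
        sel = t >= t_ingress_begin
        y, t = y[sel], t[sel]
    i = int(np.argmax(y))  # argmax returns the earliest tie
    return float(t[i]), float(y[i])


def _value_at(curve: PerfusionCurve, t: float) -> float:
    """Smoothed intensity at time t, linearly interpolated between samples."""
    return float(np.interp(t, curve.t, curve.smoothed))


def compute_ingress(curve: PerfusionCurve, t_ingress_begin: float,
                    t_max: float) -> tuple[float, bool]:
    """Mean inflow slope: secant of the smoothed curve over the ingress phase."""
    if not (np.isfinite(t_ingress_begin) and np.isfinite(t_max)) or t_max <= t_ingress_begin:
        return np.nan, False
    rise = _value_at(curve, t_max) - _value_at(curve, t_ingress_begin)
    return rise / (t_max - t_ingress_begin), True


def compute_max_ingress(curve: PerfusionCurve, t_ingress_begin: float,
                        t_max: float) -> tuple[float, bool]:
    """Largest instantaneous slope on [ingress begin, t_max]."""
    if not (np.isfinite(t_ingress_begin) and np.isfinite(t_max)):
        return np.nan, False
    s = slope_series(curve)
    sel = (curve.t >= t_ingress_begin) & (curve.t <= t_max)
    if not sel.any():
        return np.nan, False
    return float(np.max(s[sel])), True


def compute_egress(curve: PerfusionCurve, t_max: float,
                   egress_window_s: float = 5.0) -> tuple[float, float, bool]:
    """Post-peak secant slope: ``(I(t_max + w) - I(t_max)) / w``.

    Returns ``(egress, i_tmax_plus5, valid)``.  Invalid when the recording
    ends less than the window length after the peak.  The late intensity is
    linearly interpolated when no sample falls exactly on ``t_max + w``.
    """
    if not np.isfinite(t_max) or t_max + egress_window_s > curve.t[-1] + 1e-9:
        return np.nan, np.nan, False
    i_peak = _value_at(curve, t_max)
    i_late = _value_at(curve, t_max + egress_window_s)
    return (i_late - i_peak) / egress_window_s, i_late, True


def compute_max_egress(curve: PerfusionCurve, t_max: float) -> tuple[float, bool]:
    """Most negative instantaneous slope strictly after the peak."""
    if not np.isfinite(t_max):
        return np.nan, False
    s = slope_series(curve)
    sel = curve.t > t_max
    if not sel.any():
        return np.nan, False
    return float(np.min(s[sel])), True


def analyze_curve(curve: PerfusionCurve, bg: BackgroundStats,
                  cfg: AnalysisConfig = AnalysisConfig()) -> CurveFeatures:
    """Full characterization of one perfusion curve.

    Runs smoothing, ingress-begin detection, peak location and the four
    slope indicators; degenerate inputs (no perfusion signal, peak too close
    to the end) produce invalid flags plus a quality note instead of raising.
    """
    work = curve
    if cfg.subtract_background:
        work = replace(curve, intensity=curve.intensity - bg.mean, smoothed=None)
    work = smooth_curve(work, cfg.smoothing)

    feats = CurveFeatures(roi_id=curve.roi_id, location=curve.location)
    t_begin, begin_ok = detect_ingress_begin(work, bg, k=cfg.k, m=cfg.m)
    feats.t_ingress_begin = t_begin
    feats.valid["t_ingress_begin"] = begin_ok

    t_max, i_max = locate_maximum_intensity(work, t_begin if begin_ok else None)
    feats.t_max, feats.i_max = t_max, i_max
    feats.valid["t_max"] = feats.valid["i_max"] = True

    if not begin_ok:
        for name in CurveFeatures.SLOPE_FEATURES:
            feats.valid[name] = False
        feats.notes.append("no perfusion signal (no sustained positive slope)")
        return feats

    feats.ingress, ok = compute_ingress(work, t_begin, t_max)
    feats.valid["ingress"] = ok
    if not ok:
        feats.notes.append("ingress phase empty (peak at ingress begin)")

    feats.max_ingress, ok = compute_max_ingress(work, t_begin, t_max)
    feats.valid["max_ingress"] = ok

    feats.egress, feats.i_tmax_plus5, ok = compute_egress(work, t_max, cfg.egress_window_s)
    feats.valid["egress"] = ok
    if not ok:
        feats.notes.append(
            f"recording ends within {cfg.egress_window_s:g} s of maximum intensity")

    feats.max_egress, ok = compute_max_egress(work, t_max)
    feats.valid["max_egress"] = ok
    if not ok and "recording ends" not in " ".join(feats.notes):
        feats.notes.append("egress phase empty (peak at final frame)")
    return feats
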