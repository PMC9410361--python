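"""End-to-end helpers tying I/O, curve analysis and cohort aggregation together.

These are the functions the command-line interface wraps; they are equally
usable directly from Python (and are what the test-suite and the
reproduction script drive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cohort import Cohort, PatientRecord, assemble_cohort, summarize_by_group
from .curves import AnalysisConfig, CurveFeatures, analyze_curve, smooth_curve
from .io import (BackgroundStats, FluorescenceVideo, PerfusionCurve, RoiSet,
                 background_stats, extract_curve, scale_background)
from .simulate import CohortEntry

__all__ = ["RecordingResult", "analyze_recording", "record_from_entry",
           "run_cohort_entries"]


@dataclass
class RecordingResult:
    """Per-ROI curves and features for one recording."""

    curves: dict  # roi_id -> PerfusionCurve (smoothed filled)
    features: dict  # roi_id -> CurveFeatures
    bg: BackgroundStats
    notes: list = field(default_factory=list)


def analyze_recording(video: FluorescenceVideo, roi_set: RoiSet,
                      cfg: AnalysisConfig = AnalysisConfig()) -> RecordingResult:
    """Extract and characterize every ROI curve of one recording.

    The ingress-begin threshold for each ROI uses the control-ROI slope noise
    rescaled to that ROI's pixel count (noise of an n-pixel mean scales as
    1/sqrt(n)).
    """
    bg = background_stats(video, roi_set.control)
    curves: dict[int, PerfusionCurve] = {}
    features: dict[int, CurveFeatures] = {}
    for roi in roi_set:
        curve = extract_curve(video, roi)
        bg_roi = scale_background(bg, roi.n_pixels)
        features[roi.id] = analyze_curve(curve, bg_roi, cfg)
        curves[roi.id] = smooth_curve(curve, cfg.smoothing)
    return RecordingResult(curves=curves, features=features, bg=bg,
                           notes=list(bg.notes))


def record_from_entry(entry: CohortEntry,
                      cfg: AnalysisConfig = AnalysisConfig()
                      ) -> tuple[PatientRecord, RecordingResult]:
    """Analyze one synthetic cohort entry into a patient record."""
    result = analyze_recording(entry.video, entry.roi_set, cfg)
    record = PatientRecord(patient_id=entry.patient_id, outcome=entry.outcome,
                           features=list(result.features.values()),
                           time_point=entry.time_point,
                           meta={"seed": entry.video.meta.get("seed")})
    return record, result


def run_cohort_entries(entries: list[CohortEntry],
                       cfg: AnalysisConfig = AnalysisConfig()
                       ) -> tuple[Cohort, pd.DataFrame, list[PatientRecord]]:
    """Analyze a full synthetic cohort and summarize it by outcome x location."""
    records = [record_from_entry(e, cfg)[0] for e in entries]
    cohort = assemble_cohort(records)
    summary = summarize_by_group(cohort)
    return cohort, summary, records
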