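"""Cohort-level aggregation of perfusion indicators.

Per-ROI indicators from many patients are pooled by clinical outcome
(anastomotic leak, AL, vs non-AL) and ROI location (pouch body vs apex) into
descriptive summaries — median, range {max-min} and interquartile range
{P75-P25} per cell — plus a long-format per-ROI table for ingress-vs-egress
scatter plots, and per-patient perfusion-graph figures.  ROI-level values are
pooled directly (no patient-level averaging first), and no hypothesis tests
are computed: with a feasibility-scale cohort the summaries are descriptive.

Analyses are keyed to the T2 recording (pouch formed, before the anal
anastomosis), the time point most informative for pouch perfusion; records
at other time points pass through with their labels but are excluded from
the location summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path as FsPath

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .curves import CurveFeatures
from .io import PerfusionCurve, RoiSet

__all__ = [
    "PatientRecord",
    "Cohort",
    "assemble_cohort",
    "summarize_by_group",
    "ingress_egress_table",
    "export_perfusion_graph",
    "export_summary_csv",
]

FEATURES = list(CurveFeatures.SLOPE_FEATURES)
OUTCOMES = ("AL", "non_AL")
LOCATIONS = ("body", "apex")


@dataclass
class PatientRecord:
    """One patient's per-ROI curve features plus outcome and metadata."""

    patient_id: str
    outcome: str
    features: list  # of CurveFeatures (tissue and control ROIs)
    time_point: str = "T2"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")


@dataclass
class Cohort:
    """Pooled per-ROI feature table with QC accounting."""

    table: pd.DataFrame  # one row per tissue ROI; NaN where a feature is invalid
    qc: pd.DataFrame  # per-patient exclusion counts and notes
    n_patients: int
    outcome_counts: dict


def assemble_cohort(records: list[PatientRecord]) -> Cohort:
    """Pool valid tissue-ROI features across patients.

    Control ROIs are never pooled; individual invalid features become NaN in
    the long table and are counted per patient in the QC report.
    """
    if not records:
        raise ValueError("empty cohort")
    ids = [r.patient_id for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate patient ids")
    rows, qc_rows = [], []
    for rec in records:
        n_invalid = 0
        notes = []
        for f in rec.features:
            if f.location == "control":
                continue
            row = {"patient_id": rec.patient_id, "outcome": rec.outcome,
                   "time_point": rec.time_point, "roi_id": f.roi_id,
                   "location": f.location}
            for name in FEATURES:
                ok = f.valid.get(name, False)
                row[name] = getattr(f, name) if ok else np.nan
                n_invalid += not ok
            row["t_ingress_begin"] = f.t_ingress_begin
            row["t_max"] = f.t_max
            row["i_max"] = f.i_max
            rows.append(row)
            if f.notes:
                notes.append(f"ROI {f.roi_id}: " + "; ".join(f.notes))
        qc_rows.append({"patient_id": rec.patient_id, "outcome": rec.outcome,
                        "n_invalid_features": n_invalid, "notes": " | ".join(notes)})
    counts = {o: sum(r.outcome == o for r in records) for o in OUTCOMES}
    return Cohort(table=pd.DataFrame(rows), qc=pd.DataFrame(qc_rows),
                  n_patients=len(records), outcome_counts=counts)


def summarize_by_group(cohort: Cohort, time_point: str = "T2") -> pd.DataFrame:
    """Median / range / IQR per feature x outcome x location cell.

    Percentiles use linear interpolation between order statistics; empty
    cells are reported with n = 0 and NaN statistics.  Values are kept at
    full precision here and rounded only at CSV export.
    """
    tab = cohort.table
    tab = tab[tab["time_point"] == time_point] if len(tab) else tab
    out = []
    for feature in FEATURES:
        for outcome in OUTCOMES:
            for location in LOCATIONS:
                if len(tab):
                    sel = (tab["outcome"] == outcome) & (tab["location"] == location)
                    vals = tab.loc[sel, feature].dropna().to_numpy()
                else:
                    vals = np.array([])
                cell = {"feature": feature, "outcome": outcome, "location": location,
                        "n": int(vals.size)}
                if vals.size:
                    p25, p75 = np.percentile(vals, [25, 75])
                    cell.update(median=float(np.median(vals)),
                                max=float(vals.max()), min=float(vals.min()),
                                range=float(vals.max() - vals.min()),
                                p75=float(p75), p25=float(p25),
                                iqr=float(p75 - p25))
                else:
                    cell.update(median=np.nan, max=np.nan, min=np.nan,
                                range=np.nan, p75=np.nan, p25=np.nan, iqr=np.nan)
                out.append(cell)
    return pd.DataFrame(out)


def export_summary_csv(summary: pd.DataFrame, path, decimals: int = 1) -> FsPath:
    """Write the cell summary, rounded to one decimal as in clinical reports."""
    path = FsPath(path)
    summary.round(decimals).to_csv(path, index=False)
    return path


def ingress_egress_table(cohort: Cohort, time_point: str = "T2") -> pd.DataFrame:
    """One row per ROI with valid ingress and egress, for scatter plots."""
    cols = ["patient_id", "roi_id", "location", "outcome",
            "ingress", "egress", "max_ingress"]
    tab = cohort.table
    if not len(tab):
        return pd.DataFrame(columns=cols)
    tab = tab[tab["time_point"] == time_point]
    tab = tab.dropna(subset=["ingress", "egress"])
    return tab[cols].reset_index(drop=True)


def export_perfusion_graph(curves: list[PerfusionCurve], roi_set: RoiSet,
                           features: dict | None, path,
                           title: str = "") -> FsPath:
    """Perfusion graph: one colored intensity-vs-time line per ROI.

    The control ROI is drawn dashed gray; when ``features`` (roi_id ->
    CurveFeatures) is given, each valid peak is marked at (t_max, I_max).
    """
    colors = {r.id: r.color for r in roi_set}
    styles = {r.id: ("--" if r.location == "control" else "-") for r in roi_set}
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for c in curves:
        y = c.smoothed if c.smoothed is not None else c.intensity
        ax.plot(c.t, y, styles.get(c.roi_id, "-"),
                color=colors.get(c.roi_id, "#333333"),
                label=f"ROI {c.roi_id} ({c.location})", linewidth=1.2)
        if features is not None:
            f = features.get(c.roi_id)
            if f is not None and f.valid.get("t_max") and f.valid.get("ingress", False):
                ax.plot(f.t_max, f.i_max, "v", color=colors.get(c.roi_id, "#333333"),
                        markersize=5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("fluorescence intensity (i)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=6, ncol=2, loc="upper right")
    path = FsPath(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
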