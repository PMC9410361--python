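# icgperf

Quantitative assessment of bowel perfusion from indocyanine-green (ICG)
near-infrared fluorescence (NIRF) video.

After an intravenous ICG bolus, well-perfused tissue lights up in the
near-infrared: fluorescence intensity rises (inflow), peaks, and washes out
(outflow). Surgeons judge this visually today; `icgperf` turns a recorded
120 s fluorescence video into objective numbers. It is aimed at surgical
imaging researchers who want reproducible perfusion indicators for regions
of interest (ROIs) on an ileal J-pouch — or any bowel segment — and at
method developers who need a fully ground-truthed synthetic test bed.

## Perfusion indicators

For each ROI the mean intensity *I(t)* (arbitrary detector units *i*) defines
a perfusion-time curve, characterized by:

- **ingress begin** — earliest time of sustained positive slope (3-sigma rule
  against the control-ROI slope noise, 3 consecutive samples);
- **maximum intensity** — *I*<sub>max</sub> at *t*<sub>max</sub>, the start of
  the egress phase;
- **ingress** (i/s) — mean inflow slope: secant from ingress begin to the
  peak;
- **maximum ingress** (i/s) — largest instantaneous slope during inflow;
- **egress** (i/s) — 5-second outflow secant,
  (*I*<sub>tmax+5</sub> − *I*<sub>tmax</sub>) / 5, negative for outflow;
- **maximum egress** (i/s) — most negative instantaneous slope after the
  peak.

Beyond manual ROIs, every pixel can be analyzed as its own ROI, producing
**parametric maps** of maximum ingress / maximum egress — gated by a motion
check (sequential sub-pixel registration; recordings moving > 1 px are
refused, since pixel-wise analysis needs pixel-for-pixel correspondence).
Cohorts of recordings are summarized as median / range {max−min} / IQR
{P75−P25} per indicator × outcome (anastomotic leak vs none) × pouch
location (body vs apex).

Clinical recordings are rarely shareable, so the `simulate` module generates
synthetic videos with gamma-variate bolus kinetics
*I(t) = B + A·τ^α·e^{α(1−τ)}*, τ = (t−t₀)/t_p, static tissue texture,
detector noise, a signal-free drape (negative control), an impaired-apex
mode and optional injected motion — with every indicator known analytically.

## Worked example

```python
from icgperf import (KineticParams, default_pouch_layout, render_video,
                     build_roi_set, analyze_recording)

body = KineticParams(baseline=5, amplitude=100, t_arrival=10,
                     time_to_peak=8, shape=2, noise_sd=0.5)
apex = KineticParams(baseline=6, amplitude=30, t_arrival=10,
                     time_to_peak=12, shape=2, noise_sd=0.5)   # impaired apex
layout = default_pouch_layout(body=body, apex=apex)
video, truth = render_video(layout, duration=120, frame_rate=4, seed=42)
result = analyze_recording(video, build_roi_set(layout))

for rid in (3, 1, 11):
    f = result.features[rid]
    print(f"ROI {rid:2d} ({f.location:7s}): "
          f"t_begin {f.t_ingress_begin:5.2f} s  t_max {f.t_max:5.2f} s  "
          f"ingress {f.ingress:5.2f}  max_ingress {f.max_ingress:5.2f}  "
          f"egress {f.egress:5.2f}  max_egress {f.max_egress:5.2f}  i/s")
```

prints

```
ROI  3 (body   ): t_begin 10.00 s  t_max 18.00 s  ingress 12.40  max_ingress 21.04  egress -4.83  max_egress -7.46  i/s
ROI  1 (apex   ): t_begin 10.50 s  t_max 22.25 s  ingress  2.51  max_ingress  4.25  egress -0.83  max_egress -1.59  i/s
ROI 11 (control): t_begin   nan s  t_max 27.00 s  ingress   nan  max_ingress   nan  egress   nan  max_egress   nan  i/s
```

The pouch-body ROI recovers the analytic ground truth of its kinetics
(ingress 12.50, max ingress 21.30, egress −4.87, max egress −7.34 i/s)
within ~2%. The impaired apex shows depressed inflow *and* outflow — the
signature associated with anastomotic leakage — and the drape control ROI is
correctly flagged as having no perfusion signal (NaN indicators).

## Command line

```bash
icgperf simulate --out demo --patients 18 --al 4 --seed 7   # synthetic cohort
icgperf analyze  --video demo/P01.tif --roi demo/P01_rois.json --out run01
icgperf map      --video demo/P01.tif --roi demo/P01_rois.json --out run01
icgperf cohort   --manifest demo/manifest.csv --out cohort_run
```

`analyze` writes per-ROI curves and indicators (CSV), a perfusion graph and
a run log; `map` writes parametric maps (32-bit TIFF + rendered PNG) or
refuses with exit code 3 when the motion gate fails; `cohort` adds the
outcome × location summary table, a per-ROI ingress-vs-egress table and a QC
report of exclusions.

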