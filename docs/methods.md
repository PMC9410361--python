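# Methods

## The measurement model

A fluorescence recording is a stack of T grayscale frames at a known frame
rate; intensities are arbitrary detector units (*i*). An ROI's
perfusion-time curve is the per-frame arithmetic mean over its pixel mask.
No background subtraction is applied by default: every slope indicator is
invariant to constant offsets, and the control (drape) ROI is used only to
estimate autofluorescence level and noise. Subtraction of the control mean
is available behind `AnalysisConfig.subtract_background` for users who want
comparable absolute intensities.

Pixel conventions are fixed once: row-major frames, origin top-left, 0-based
indices; ROI polygons use (x = column, y = row) vertices and a pixel belongs
to a polygon iff its center (col + 0.5, row + 0.5) lies inside it.

## Curve characterization

Curves are smoothed with a centered moving average (default 1.0 s; the
window shrinks one-sidedly at the recording edges, so constants and interior
segments of affine signals pass through unchanged). Instantaneous slopes are
central finite differences of the smoothed curve, one-sided at the ends.

**Ingress begin** is the first sample of the earliest run of m = 3
consecutive raw-curve slopes exceeding k = 3 times the control-ROI
slope-noise sd (plus a relative machine-scale guard so a noiseless flat
curve never triggers). Detection deliberately uses the *raw* slope rather
than the smoothed one: a centered smoother spreads the onset backwards by
half a window, a bias that does not shrink as the frame rate grows; on the
raw series the detected onset converges to the true arrival time. The
matched noise scale — the sd of the raw finite-difference slope of the
control curve — is estimated by `background_stats` and rescaled to the
target ROI's pixel count (sd of an n-pixel mean scales as 1/sqrt(n) under
independent detector noise). The same rescaling, taken to n = 1, calibrates
the threshold for single-pixel curves in parametric maps; without it a
25-pixel control ROI under-states pixel noise about five-fold and signal-free
pixels would pass the detector by chance.

**Maximum intensity** is the earliest argmax of the smoothed curve,
restricted to times at or after ingress begin when an onset was found.
**Ingress** is the secant slope from ingress begin to the peak; **maximum
ingress** the largest instantaneous slope in that window. **Egress** is the
5-second secant after the peak, evaluated on the smoothed curve with linear
interpolation at t_max + 5 (raw-frame noise at two isolated samples would
dominate the secant, and frame grids need not align with 5 s). **Maximum
egress** is the most negative instantaneous slope strictly after the peak.
The ingress/maximum-egress definitions mirror the egress secant and the
"maximum slope" notion on the outflow side; by construction maximum ingress
≥ ingress, and on curves whose egress phase contains the 5 s window the
maximum egress is at least as negative as the egress.

Degenerate inputs never raise: a constant or pure-noise curve (e.g. the
control ROI) yields invalid flags on all slope indicators plus a "no
perfusion signal" note, so cohort runs always complete with per-ROI QC.

## Synthetic recordings

Each tissue region follows a gamma-variate bolus curve
I(t) = B + A·τ^α·e^{α(1−τ)} with τ = (t − t₀)/t_p — baseline B, amplitude A
(peak exactly B + A at t₀ + t_p), arrival t₀, time-to-peak t_p and shape α.
All indicators have closed forms (slope extrema at τ = 1 ∓ 1/√α, finite for
α ≥ 1), which the generator attaches as ground truth; ground truth is always
computed from the analytic curve, never from rendered frames, so it is
invariant to noise level and seed.

The default scene is a 36 × 48 px cartoon pouch: a 10 px drape strip with
zero amplitude (negative control), a pouch body, a small appendage (body
kinetics) and an apex block. A static multiplicative gain field (smoothed
Gaussian random field, relative strength 0.2, correlation length 3 px,
clipped to [0.5, 1.5]) models the spatial texture of real scenes — vessels,
folds, uneven illumination. This texture matters twice: it is what makes
frame-to-frame registration well-posed (a translated piecewise-constant
strip scene is nearly unobservable), and it makes every pixel's indicators
scale by its gain, which the per-pixel ground-truth expansion accounts for.
Detector noise is additive Gaussian per pixel (default sd 0.5 i against
amplitudes of 60–120 i, consistent with a well-exposed NIR camera after
standardized illumination), clipped at the zero detector floor.

Cohorts draw per-patient systemic bolus timing (arrival U(8, 15) s,
time-to-peak U(8, 14) s) shared by body and apex up to small jitter (±0.2 s
arrival, ±4% time-to-peak) — one intravenous bolus reaches the whole pouch
nearly simultaneously, which reproduces the synchronous peak alignment seen
in healthy pouches — while baseline U(4, 10), amplitude U(60, 120) and shape
U(1.5, 3) vary by region. Recordings default to 120 s at 4 Hz; the rate is
chosen so the 5 s egress window spans 20 samples. Anastomotic-leak (AL)
patients apply the apex impairment: amplitude × f_A (default 0.3) and
time-to-peak × f_tp (default 1.5), depressing inflow and outflow slopes
together. With f_A = f_tp = 1 the AL label is independent of the kinetics,
giving an exact null for calibration.

What the generator does **not** emulate: tissue scattering and absorption,
dye pharmacokinetics (recirculation, hepatic clearance), camera distance or
illumination drift, nonrigid peristaltic deformation, or signal-dependent
noise. Passing tests therefore demonstrate correctness of the *analysis*
under controlled kinetics, not robustness to every property of clinical
footage.

## Motion gate

Pixel-wise mapping requires pixel-for-pixel correspondence over time, so
moving recordings are detected and refused, not corrected. Per-frame
translation is estimated *sequentially*: each frame is registered to its
predecessor by sub-pixel phase cross-correlation (upsampling factor 50) of
difference-of-Gaussians band-passed frames (σ = 1 and 4 px), and the
increments are accumulated into a trajectory re-referenced to the reference
frame (first frame at or after the global mean-intensity ingress begin).
Adjacent frames sit at nearly the same bolus phase, so the evolving region
contrast of the dye transit cannot masquerade as motion; only the static
texture drives each increment, and per-frame estimation errors largely
telescope out of the cumulative sum. Two guards handle degenerate scenes:
an increment is accepted only if applying it actually raises the correlation
with the previous frame (otherwise the correlation surface was flat along
some direction and the pair is treated as stationary), and near-constant
frames contribute zero increments with a QC note. Because genuine bulk
motion is persistent while estimation noise is not, the trajectory is
median-filtered over 9 frames before the maximum shift is taken. The gate
refuses recordings whose maximum shift exceeds 1.0 px — "even minimal
movement" operationalized at the pixel scale. A global-translation model is
used deliberately: peristalsis and pulse are nonrigid, but any nonrigid
motion of a textured scene also produces a nonzero global estimate.

Measured on synthetic scenes with injected translations, estimates track the
injection within 0.5 px for 2–3 px shifts across texture draws (one draw in
eight under-estimates a 2 px event at 1.2 px — still refused at the 1 px
threshold), the zero-shift floor stays below ~0.7 px, and sub-threshold
0.4 px shifts pass.

## Cohort summaries

Valid tissue-ROI indicators are pooled across patients (control ROIs never
pool; each invalid feature is counted in the QC report) and summarized per
feature × outcome × location cell as median, range {max − min} and IQR
{P75 − P25}, using linear interpolation between order statistics; values are
rounded (one decimal) only at CSV export. ROI-level values are pooled
directly without per-patient averaging — matching per-ROI ranges — and the
alternative (patient-level medians first) is deliberately not the default.
Summaries are keyed to the T2 time point (pouch formed); other time points
pass through with labels only. No hypothesis tests are attached to the
summaries: at feasibility scale they are descriptive. The test suite's null
calibration checks the *generator + pipeline* for spurious direction using
exact sign tests on AL vs non-AL cell-median differences across 50 seeds,
Holm-corrected across the 8 (correlated) cells at familywise 0.05.

## Numerical choices and limitations

- Smoothing window 1.0 s, k = 3, m = 3, egress window 5 s, motion threshold
  1.0 px, percentile rule "linear" — all in `AnalysisConfig` / `RunConfig`.
- Ties in the peak search break to the earliest sample; slope series are
  one-sided at the recording edges; the moving-average window shrinks at the
  edges, so indicators that touch the first/last ~window/2 of the recording
  carry a small edge bias.
- Recovery accuracy on noiseless 4 Hz renders of the reference kinetics is
  within ~2% for all six indicators and improves monotonically with frame
  rate (2 → 16 Hz); the residual is discretization plus smoothing
  attenuation, both of which shrink with the sampling step.
- Videos round-trip bit-exactly through float TIFF; 16-bit export quantizes
  to integers and is for interoperability, not archival of exact values.
- Problem sizes in the test-bed (36 × 48 px scenes, 16 × 16 pixel-map
  checks, 18-patient cohorts, 50-seed null) were chosen as the smallest
  scales at which every property under test is well-resolved.
- The motion gate estimates global translation only; it flags but cannot
  quantify nonrigid deformation. Parametric maps on noisy single pixels
  mask out low-amplitude tissue (threshold scales to single-pixel noise), so
  severely impaired regions can appear as invalid rather than low — the
  optional 3 × 3 spatial pre-average trades resolution for coverage.
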