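# Methods note

This note documents the models, estimators and numerical choices behind
`tremorvideo`, what the synthetic-data generator does and does not emulate,
and the known limitations. It states no empirical result that the test suite
or `scripts/acceptance.py` do not themselves compute.

## Scope and shape

The package is organised as a pipeline of small functional modules
(generate → track → analyse → test) rather than a single fitted-model class:
the core of the method is a measurement procedure, not a statistical model
estimated from data. The two genuine fits it contains — the Weber–Fechner
log-linear regression and the ICC ANOVA — return results objects
(`WeberFechnerFit`, `ReliabilityResult`) carrying estimates, uncertainties
and a `summary()`, in the style of statistical modelling libraries.

## Synthetic tremor model

The postural generator produces

x(t) = c + s(t)·(cos θ, sin θ) + v_d·t·(1, 0) + ε(t),
s(t) = (A_pp/2) · [1 + m·sin(2π f_am t)] · sin φ(t)

with peak-to-peak amplitude A_pp (mm), oscillation axis θ, amplitude
modulation depth m ∈ [0, 1), linear drift velocity v_d (applied along the
image x-axis — the direction is arbitrary, a fixed choice keeps outputs
reproducible), and isotropic Gaussian observation noise ε. The phase φ(t)
is piecewise linear in cycles: each cycle k gets its own frequency
f_k ~ N(f₀, σ_f) (clipped at 0.2·f₀), so "waves per second" and per-cycle
amplitude have exact ground truth. The drawing generator moves the pen at
constant velocity along a horizontal 150 mm segment with the same tremor
signal applied perpendicular to it (drift on the perpendicular).

Defaults are chosen once to represent the study conditions: 60 s at 25 fps
for the postural task; tremor 3–10 Hz; amplitudes spanning roughly 1–100 mm
(lognormal with log₁₀ mean 1.05, SD 0.45, matching the clinically observed
postural range of about 1.3–105 mm); observation noise 0.05 mm, the scale of
sub-pixel tracking jitter (~0.15 px at ~0.3 mm/px). Cohorts apply a
multiplicative treatment effect of 0.7 log₁₀ units (≈ 80% amplitude
reduction, consistent with reported group means of ~14 mm pre vs ~2.7 mm
post) with patient-level heterogeneity of 0.15 log₁₀ units.

Ratings are generated **from** amplitude, never the reverse: amplitude is the
physical quantity, the rating its quantised perception. A rating is
round((log₁₀A − a)/b + ε_r) clipped to the scale range. The default anchors
place rating 2 at 2 cm and rating 4 at 4 cm (the visual amplitude anchors of
clinical scales), giving a = 1.0 and b = (log₁₀40 − log₁₀20)/2 ≈ 0.1505
log₁₀-mm per point, with rating noise SD 0.5 points; all configurable. For
analyses that need a wide-range composite score (the 0–32 tremor score), a
`WeberFechnerSpec` with range 0–32, slope 0.06 and intercept 0.11 maps the
1.3–105 mm amplitude range onto the full scale. Narrow 0–4 scales saturate
at both ends by construction — that floor/ceiling behaviour is a feature of
the emulation, not a bug, but it means rating *changes* on a 0–4 scale carry
little information when post-treatment tremor falls below the scale floor.

What the generator does **not** emulate: biomechanics (no limb model, no
frequency–amplitude coupling), realistic appearance (markers are
high-contrast discs on smooth static texture), motion blur, camera shake,
out-of-plane motion, or rater-specific biases beyond additive rating noise.
Passing tests therefore demonstrate correctness of the algorithms under the
stated signal model, not robustness to real clinical video.

## Rendering and tracking

Videos are rendered lazily (one frame on demand) as anti-aliased discs over
a per-seed fixed smoothed-noise background, so a 60 s 720p recording never
needs to be held in memory. Tracking is normalized cross-correlation of a
fixed template (cut from frame 0) within a search window around the previous
position, with the peak refined by independent 1-D quadratic fits; an
optional exponential template update (off by default) handles slow
appearance change. Normalization makes the tracker exactly invariant to a
constant intensity offset. Frames whose best score falls below
`score_threshold` (default 0.5) are flagged lost and linearly interpolated;
tracking fails outright beyond `max_lost_fraction` (default 0.2). On the
smooth synthetic texture, spurious correlations of ~0.6 are possible, so
occlusion experiments use a stricter threshold (0.8); with the marker
visible, scores are ≈ 1.0. Sub-pixel accuracy on rendered videos is well
under 0.1 px RMSE; the guaranteed (tested) bound is 1 px.

Calibration is an explicit user-supplied reference length
(mm per px = reference_mm / pixel distance); the 15 cm target line itself is
the natural reference.

## Tremor signal and cycle analysis

**Detrending.** The slow baseline is a centred 1 s moving average applied
twice (a triangular 2 s kernel), implemented as Savitzky–Golay order 1 with
polynomial edge fits so that a purely linear drift is removed exactly over
the whole record. A single-pass 1 s average was rejected: its sinc sidelobes
leak up to ~10% of a 3.5 Hz component into the baseline, which would corrupt
amplitude recovery; the double pass squares the leakage (< ~1% for ≥ 3 Hz).
At the recording edges the local-line fit can over/undershoot an oscillation
by a few percent; the postural window rule (centres in [5, 55] s) keeps the
analysis away from the edges.

**Projection.** The detrended XY residuals are projected onto their first
principal direction (SVD), with a deterministic sign convention. For planar
tremor this recovers the 1-D oscillation exactly; isotropic noise adds its
axis component.

**Window rule.** The window centre is the argmax over [5, 55] s of a sliding
1 s peak-to-peak envelope of the tremor signal. The raw sliding p2p is flat
for about 1 s around the largest peak, so the envelope is smoothed with a
centred 1 s moving average, restoring a unique maximum at the plateau
centre; exact ties (constant-amplitude tremor) are broken by the earliest
admissible centre, with equality judged at 10⁻⁹ relative tolerance to
absorb floating-point jitter between identical cycles. The window is always
[centre − 5, centre + 5] s and contains exactly `10·fps + 1` samples.

**Oversampling.** At 25 fps a 10 Hz tremor has only 2.5 samples per cycle,
so raw per-cycle extrema underestimate peak-to-peak by ~15%. Since tremor is
band-limited below Nyquist (12.5 Hz), the windowed signal is
Fourier-upsampled ×16 (with ~1 s reflection padding to suppress wrap-around
ringing) before crossing detection and extrema measurement; the residual
amplitude bias is a few tenths of a percent.

**Cycle counting.** Cycles are delimited by positive-going zero crossings
guarded by a Schmitt trigger with hysteresis band h = 10% of the robust
half-range (2.5–97.5 percentiles) of the signal. A first-difference noise
estimate was considered and rejected for the band: at 25 fps with tremor up
to 10 Hz, first differences are dominated by the tremor itself, so that
"noise" estimate scales with the signal and can exceed the tremor amplitude
outright, suppressing all cycles; an amplitude-relative band with an
absolute floor (`amplitude_floor_mm`, default 0) is robust across the whole
frequency range and suppresses noise chatter whenever noise < ~10% of
amplitude. A signal whose robust range falls below the floor is reported as
"no tremor" (frequency 0, amplitude undefined).

**Frequency.** Reported frequency is the mean inter-crossing rate
(n_crossings − 1)/(t_last − t_first) over interpolated crossing times — the
average number of waves per second. A naive count of complete cycles divided
by the 10 s window length is biased low by up to one cycle per window
(3.9 Hz for a 4 Hz tremor); the mean-period form is exact on integer-cycle
windows and agrees with the integrated instantaneous frequency on chirps.

**Amplitude.** Per-cycle amplitude is the peak-to-peak excursion of the
detrended signal within each crossing-delimited cycle — peak-to-peak because
clinical amplitude anchors ("< 2 cm", "2–4 cm") describe the visible
excursion; `amplitude_mode="half"` halves it for centre-to-peak conventions.
The summary is the geometric mean over cycles (log-domain mean), with
cycles below the amplitude floor excluded. The tested recovery guarantee at
25 fps over 3–10 Hz and 5–100 mm pk-pk is 2% (noiseless) and 5% (0.05 mm
observation noise); observation noise inflates per-cycle extrema by roughly
2–3 σ, which is why the guarantee loosens with noise.

**Drawing task.** Metrics are computed over the drawing span — detected as
the first-to-last sustained motion above 5 mm/s for ≥ 0.2 s, or supplied by
the user. Amplitude and frequency are measured on the deviation
perpendicular to the best-fit line through the span (then detrended as
above); cumulative length is the summed frame-to-frame displacement.
Windowing is not applied to the drawing task. Mean acceleration everywhere
is the mean of absolute per-step accelerations: signed accelerations average
to ≈ 0 over any oscillation and would be uninformative.

## Statistics

ICC(1,1) = (BMS − WMS)/(BMS + (k−1)·WMS) from the one-way ANOVA;
ICC(2,k) = (BMS − EMS)/(BMS + (JMS − EMS)/n) from the two-way ANOVA.
Confidence intervals follow the Shrout–Fleiss F-interval constructions, the
two-way average-measure interval being the single-measure interval
(Satterthwaite df) stepped up by Spearman–Brown. Both estimators agree with
an independent variance-components oracle to 10⁻¹⁰ and with
`pingouin.intraclass_corr` (including CIs) in the test suite. Negative ICC
estimates are reported as computed ("very poor"), not truncated. Reliability
categories: ≥ 0.90 excellent, 0.70–0.90 good, 0.50–0.70 moderate, 0.30–0.50
poor, < 0.30 very poor.

MDC₉₅ = 1.96·SDd. On a log₁₀ measure, MDC% = 100·(1 − 10^(−1.96·SDd)) — the
percent amplitude reduction just detectable; rating-scale SDd is first
converted through the Weber–Fechner slope b:
MDC% = 100·(1 − 10^(−b·1.96·SDd)). The log-domain form reproduces the
published postural worked values (SDd 0.211 → 61%; TETRAS SDd 0.408 with
b = 1 → 84%); the published CRST Part A value (89% at SDd 0.823) implies a
sub-unit slope b ≈ 0.59, which is why the rating variant exposes b. The
published line-drawing MDC% cells (and a negative SDd) are mutually
inconsistent with any single formula and are not emulated.

Wilcoxon signed-rank: zero differences dropped, mid-ranks for tied
magnitudes; the two-sided p is exact for up to 25 non-zero pairs via the
tie-aware generating-polynomial distribution (doubled ranks keep exponents
integral), p = min(1, 2·min(P(W ≤ w), P(W ≥ w))); beyond 25 a normal
approximation with tie and continuity corrections is used. The exact path
equals full 2ⁿ enumeration for all n ≤ 12 in the tests, and matches scipy's
exact mode on tie-free data.

Spearman correlation is the Pearson correlation of mid-ranks with a
t-approximate p (exact permutation optional for n ≤ 9). The Weber–Fechner
fit is ordinary least squares of log₁₀ amplitude on rating; note that
integer rounding and rating noise attenuate the OLS slope slightly below
the generating slope (errors-in-variables), so CI-coverage checks target the
large-sample OLS estimand. Multiple testing is not adjusted by default
(matching common reporting practice); `holm_adjust` is available.

Pipeline reports record both median (min–max) and mean (SD) for every
pre/post variable — scores are conventionally summarised by the former and
videographic parameters by the latter — flag significance at p < 0.05 (*)
and p < 0.01 (**), keep raw p-values, and log every operation call, so each
cell is reproducible. Report JSON is byte-identical for identical inputs.

## Degenerate inputs and tie-breaks (summary)

- Constant trajectory → zero tremor signal (not an error); zero signal →
  frequency 0 with a no-tremor flag; amplitude undefined without ≥ 1 cycle.
- Envelope ties → earliest window centre (10⁻⁹ relative equality).
- Non-concave correlation peak → integer-pixel position (no refinement).
- ICC on a zero-variance matrix → explicit error; identical raters → ICC 1
  with CI (1, 1).
- All-zero Wilcoxon differences → explicit error (caller decides).
- log T₂/T₁ requires positive inputs; an amplitude floor can be applied
  upstream.

## Problem sizes

Default test and acceptance runs use: 60 s × 25 fps recordings; 10
render→track round trips at 1280×720; 50-spec recovery ensembles; 100
random ICC matrices; 2ⁿ Wilcoxon enumeration to n = 12; cohorts of 40–200
patients with 200 000-sample generator-analytic references. These sizes were
chosen to exercise every guarantee at the study's own scale while keeping a
full run in the minutes range on one CPU.

## Limitations

2-D projection underestimates depth motion by construction. The tracker is
single-hypothesis NCC — no pose estimation, no re-detection after long
occlusion (lost frames are interpolated, which is only sensible for short
gaps). Spectral analysis is deliberately out of scope: all frequency/
amplitude measures are time-domain cycle statistics. The synthetic cohort's
rating noise is additive and unbiased; real raters have idiosyncratic
thresholds. The published patient-level tables are not reproducible without
the (undeposited) cohort data; everything validated here is validated
against synthetic ground truth plus the two printed worked values.
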