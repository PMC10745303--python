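# tremorvideo

Video-based kinematic quantification of essential tremor (ET).

Clinical tremor rating scales (CRST, TETRAS) grade tremor amplitude by eye on
a 0–4 scale. That makes them rater-dependent, coarse, and subject to a ceiling
effect: every postural tremor above 4 cm scores the CRST maximum of 4, even
though surgical candidates routinely exceed 10 cm. `tremorvideo` implements
the alternative: track an anatomical point (fingertip, pen tip) in ordinary
video of a postural ("wing-beat") hold or a 15 cm line-drawing task, and
summarise the motion by continuous kinematic parameters — velocity,
acceleration, frequency, amplitude, and cumulative path length — together
with the reliability and clinical-correlation statistics needed to validate
them. Because no clinical recordings ship with the package, a first-class
synthetic-data module generates tremor trajectories, rendered marker videos
and rated patient cohorts with known ground truth, so the entire pipeline is
testable end to end.

Intended users: movement-disorder researchers quantifying tremor severity or
treatment response (e.g. MR-guided focused ultrasound thalamotomy) from video,
and methodologists studying the reliability of instrumented tremor measures.

## The measurement model

**Tracking.** Each region of interest is tracked frame by frame with
normalized cross-correlation template matching; the correlation peak is
refined to sub-pixel precision by quadratic interpolation. Pixel positions
are calibrated to mm by a reference length visible in the scene (the 15 cm
target line works). Coordinates use the image convention: origin at the
upper-left corner, x rightward, y downward.

**Kinematics.** For consecutive frames (X₁,Y₁) → (X₂,Y₂) at frame interval
t = 1/fps:

    displacement = √(ΔX² + ΔY²)
    velocity     = displacement / t
    acceleration = (V₁ − V₀) / t

The postural task is summarised over the 10 s window of highest tremor
amplitude, with the window centre restricted to the 5th–55th second of the
60 s recording. Within the window, the XY path is projected onto its
principal oscillation axis after removal of a slow moving-average baseline;
frequency is the average number of waves per second (positive-going
zero crossings with a hysteresis guard), and amplitude is the geometric mean
of per-cycle peak-to-peak excursions. The drawing task reports all five
parameters over the drawing span, including the cumulative pen-tip path
length (≥ 150 mm in proportion to tremor). Treatment change is measured as
log T₂/T₁ = log₁₀(post/pre).

**Statistics.** Test–retest reliability uses the one-way random-effects
single-measure ICC(1,1); inter-rater reliability uses the two-way
random-effects average-measure ICC(2,3); both with Shrout–Fleiss 95% CIs.
Measurement noise is summarised by SDd (SD of test–retest differences),
MDC₉₅ = 1.96·SDd, and — because tremor amplitude is perceived on a log scale
(Weber–Fechner) — the percent minimal detectable change

    MDC% = 100 · (1 − 10^(−1.96·SDd))            (log₁₀-scale measures)
    MDC% = 100 · (1 − 10^(−b·1.96·SDd))          (rating scales, slope b)

where b is the Weber–Fechner slope (log₁₀-mm per rating point) fitted by
`fit_weber_fechner`. Clinical associations use Spearman rank correlation and
the Wilcoxon signed-rank test (exact, tie-aware, for up to 25 pairs).

## Worked example

```python
import numpy as np
from tremorvideo import (
    CohortSpec, MeasurementMatrix, TremorSpec,
    fit_weber_fechner, generate_cohort, generate_postural_trajectory,
    generate_reliability_matrix, icc_one_way_single, spearman_rho,
    summarize_task, wilcoxon_signed_rank,
)

# a 60 s postural recording: 5 Hz tremor, 30 mm peak-to-peak, slight drift
spec = TremorSpec(base_frequency=5.0, peak_to_peak_amplitude=30.0,
                  noise_sd=0.05, drift_velocity=1.0, seed=7)
m = summarize_task(generate_postural_trajectory(spec), "postural")
print(m.mean_frequency_hz, m.amplitude_mm, m.window.start, m.window.end)
# 5.000022437433655 29.985336867925522 22.76 32.76

# a 43-patient treated cohort with Weber–Fechner ratings
cohort = generate_cohort(CohortSpec(n_patients=43, seed=7))
print(fit_weber_fechner(cohort.rating_pre, cohort.amplitude_pre_mm).summary())
# Weber–Fechner fit: log10(amplitude_mm) = 0.765 + 0.246·rating
#   slope 95% CI [0.159, 0.333], R² = 0.443, n = 43
print(spearman_rho(cohort.rating_pre, np.log10(cohort.amplitude_pre_mm)))
# (0.7267..., 3.45e-08)
print(wilcoxon_signed_rank(np.log10(cohort.amplitude_pre_mm),
                           np.log10(cohort.amplitude_post_mm)))
# (0.0, 1.16e-08)        # every patient improved

# test–retest reliability of log10 amplitude for 10 subjects
mat = generate_reliability_matrix(10, 2, within_log_sd=0.05, seed=7)
print(icc_one_way_single(MeasurementMatrix(mat, log10_transformed=True)).summary())
# ICC(1,1) reliability
#   subjects: 10, columns: 2
#   ICC = 0.986 (95% CI 0.948–0.996)  [excellent]
#   SDd = 0.04769, MDC95 = 0.09347
#   MDC% = 19%
```

The recovered frequency (5.000 Hz) and amplitude (29.99 mm) match the
generating spec; the window [22.76, 32.76] s is the 10 s stretch where the
simulated tremor happened to be largest. The cohort statistics show the
structure the method is designed to expose: ratings track log amplitude
(ρ = 0.73), the treatment effect is unambiguous (all signed ranks negative),
and a 0.047 log₁₀-unit test–retest SDd means amplitude changes beyond ~19%
of baseline are distinguishable from measurement noise.

A command-line interface mirrors the library
(`tremorvideo simulate | track | analyze | reliability | correlate | prepost | report`);
run `tremorvideo --help` for details.

## Layout

- `src/tremorvideo/synthetic.py` — trajectory/video/cohort generators
- `src/tremorvideo/tracking.py` — NCC template tracking, calibration
- `src/tremorvideo/kinematics.py` — tremor parameters and the window rule
- `src/tremorvideo/stats.py` — ICC, MDC, Spearman, Wilcoxon, Weber–Fechner
- `src/tremorvideo/pipeline.py` — study sections and reports
- `docs/methods.md` — the methods note (assumptions, defaults, limitations)
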