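"""Synthetic tremor data with known ground truth.

Everything downstream — tracking, kinematics, reliability statistics — is
validated against trajectories, rendered marker videos and patient cohorts
produced here.  The generators emulate:

* quasi-sinusoidal postural ("wing-beat") tremor: a sinusoid with per-cycle
  frequency jitter, sinusoidal amplitude modulation, slow linear drift and
  additive isotropic observation noise;
* the 15 cm line-drawing task: constant-velocity traversal of a horizontal
  segment with tremor superimposed perpendicular to it;
* marker videos: high-contrast discs on a fixed textured background, one
  frame per trajectory sample;
* treated cohorts: lognormal tremor amplitudes, a multiplicative
  (log-additive) treatment effect, and integer clinical ratings drawn from a
  noisy Weber–Fechner (log-linear) rating↔amplitude relation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .trajectory import TrajectorySeries

__all__ = [
    "TremorSpec",
    "WeberFechnerSpec",
    "CohortSpec",
    "generate_postural_trajectory",
    "generate_drawing_trajectory",
    "MarkerVideo",
    "render_marker_video",
    "generate_cohort",
    "generate_reliability_matrix",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class TremorSpec:
    """Parameters of one synthetic tremor recording.

    ``peak_to_peak_amplitude`` is the full excursion of the oscillation in mm
    (the quantity a clinical rater sees); ``tremor_axis_angle`` orients the
    dominant oscillation axis in the image plane (degrees, 0 = horizontal).
    Observation noise emulates sub-pixel tracking jitter and is additive,
    isotropic and Gaussian.
    """

    base_frequency: float = 5.0          # Hz
    peak_to_peak_amplitude: float = 20.0  # mm
    frequency_jitter_sd: float = 0.0     # Hz, per-cycle
    amplitude_mod_depth: float = 0.0     # fraction in [0, 1)
    amplitude_mod_frequency: float = 1.0  # Hz
    drift_velocity: float = 0.0          # mm/s
    noise_sd: float = 0.0                # mm
    tremor_axis_angle: float = 0.0       # degrees
    duration: float = 60.0               # s
    fps: float = 25.0                    # frames/s
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.base_frequency > 0:
            raise ValueError("base_frequency must be > 0")
        if self.peak_to_peak_amplitude < 0:
            raise ValueError("peak_to_peak_amplitude must be >= 0")
        if not 0 <= self.amplitude_mod_depth < 1:
            raise ValueError("amplitude_mod_depth must lie in [0, 1)")
        if self.amplitude_mod_depth > 0 and not self.amplitude_mod_frequency > 0:
            raise ValueError("amplitude_mod_frequency must be > 0 when modulating")
        if self.frequency_jitter_sd < 0:
            raise ValueError("frequency_jitter_sd must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.fps > 0:
            raise ValueError("fps must be > 0")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")


@dataclass(frozen=True)
class WeberFechnerSpec:
    """Noisy log-linear rating↔amplitude relation.

    ``log10(amplitude_mm) = intercept_a + slope_b * rating`` on average; a
    rating is drawn by inverting this map, adding Gaussian rating noise,
    rounding to the nearest integer and clipping to the scale range.

    Defaults place rating 2 at 2 cm and rating 4 at 4 cm, matching the visual
    amplitude anchors of clinical tremor rating scales.
    """

    intercept_a: float = 1.0                      # log10-mm at rating 0
    slope_b: float = (math.log10(40) - math.log10(20)) / 2  # log10-mm per point
    rating_noise_sd: float = 0.5                  # rating points
    rating_min: int = 0
    rating_max: int = 4

    def __post_init__(self) -> None:
        if not self.slope_b > 0:
            raise ValueError("slope_b must be > 0")
        if self.rating_noise_sd < 0:
            raise ValueError("rating_noise_sd must be >= 0")
        if not self.rating_min < self.rating_max:
            raise ValueError("rating_min must be < rating_max")

    def rating_from_amplitude(self, amplitude_mm, rng=None):
        """Draw integer ratings for the given amplitudes (mm)."""
        amplitude_mm = np.asarray(amplitude_mm, dtype=float)
        if np.any(amplitude_mm <= 0):
            raise ValueError("amplitudes must be positive")
        latent = (np.log10(amplitude_mm) - self.intercept_a) / self.slope_b
        if self.rating_noise_sd > 0:
            if rng is None:
                raise ValueError("an rng is required when rating_noise_sd > 0")
            latent = latent + rng.normal(0.0, self.rating_noise_sd, latent.shape)
        return np.clip(np.rint(latent), self.rating_min, self.rating_max).astype(int)


@dataclass(frozen=True)
class CohortSpec:
    """A pre/post-treatment patient cohort.

    Pre-treatment tremor amplitudes are lognormal (``10**N(mean, sd)`` in mm);
    the treatment multiplies amplitude by ``10**(-treatment_effect_log + eta)``
    with patient-level noise ``eta ~ N(0, treatment_noise_log_sd)``.  Ratings
    are drawn pre and post from the same Weber–Fechner relation.

    Defaults span the clinically observed postural amplitude range
    (roughly 1–100 mm) with a treatment effect of 0.7 log10 units
    (an ~80% amplitude reduction).
    """

    n_patients: int = 43
    pre_amplitude_log_mean: float = 1.05   # log10-mm
    pre_amplitude_log_sd: float = 0.45     # log10-mm
    treatment_effect_log: float = 0.7      # log10 reduction
    treatment_noise_log_sd: float = 0.15   # log10-mm, patient-level
    weber_fechner: WeberFechnerSpec = field(default_factory=WeberFechnerSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.pre_amplitude_log_sd < 0:
            raise ValueError("pre_amplitude_log_sd must be >= 0")
        if self.treatment_noise_log_sd < 0:
            raise ValueError("treatment_noise_log_sd must be >= 0")


# ---------------------------------------------------------------------------
# trajectory generators
# ---------------------------------------------------------------------------
def _tremor_phase(spec: TremorSpec, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Oscillation phase in radians, with optional per-cycle frequency jitter."""
    if spec.frequency_jitter_sd == 0:
        return 2 * np.pi * spec.base_frequency * t
    # draw one frequency per cycle; cycle k spans phase [2*pi*k, 2*pi*(k+1)]
    n_cycles = int(np.ceil(spec.duration * (spec.base_frequency + 5 * spec.frequency_jitter_sd))) + 2
    freqs = rng.normal(spec.base_frequency, spec.frequency_jitter_sd, n_cycles)
    freqs = np.clip(freqs, 0.2 * spec.base_frequency, None)
    boundaries = np.concatenate([[0.0], np.cumsum(1.0 / freqs)])
    while boundaries[-1] < t[-1]:
        extra = rng.normal(spec.base_frequency, spec.frequency_jitter_sd, n_cycles)
        extra = np.clip(extra, 0.2 * spec.base_frequency, None)
        boundaries = np.concatenate([boundaries, boundaries[-1] + np.cumsum(1.0 / extra)])
    cycles_at_t = np.interp(t, boundaries, np.arange(boundaries.size, dtype=float))
    return 2 * np.pi * cycles_at_t


def _tremor_scalar(spec: TremorSpec, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Noise-free 1-D tremor signal (mm) along the oscillation axis."""
    half_amp = spec.peak_to_peak_amplitude / 2.0
    envelope = 1.0 + spec.amplitude_mod_depth * np.sin(
        2 * np.pi * spec.amplitude_mod_frequency * t
    )
    return half_amp * envelope * np.sin(_tremor_phase(spec, t, rng))


def generate_postural_trajectory(
    spec: TremorSpec, center_mm: tuple[float, float] = (0.0, 0.0)
) -> TrajectorySeries:
    """Simulate the fingertip path of the 60 s wing-beat postural hold.

    The point oscillates along ``tremor_axis_angle`` with the requested
    peak-to-peak amplitude, amplitude-modulated, on top of a slow linear
    drift (along the image x-axis) plus isotropic Gaussian noise.  Output has
    ``duration * fps + 1`` samples and is reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fps)) + 1
    t = np.arange(n) / spec.fps
    s = _tremor_scalar(spec, t, rng)
    theta = np.deg2rad(spec.tremor_axis_angle)
    x = center_mm[0] + s * np.cos(theta) + spec.drift_velocity * t
    y = center_mm[1] + s * np.sin(theta)
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, (n, 2))
        x = x + noise[:, 0]
        y = y + noise[:, 1]
    return TrajectorySeries(x=x, y=y, fps=spec.fps, units="mm", label="postural")


def generate_drawing_trajectory(
    spec: TremorSpec,
    line_length: float = 150.0,
    draw_duration: float = 6.0,
    start_mm: tuple[float, float] = (0.0, 0.0),
) -> TrajectorySeries:
    """Simulate the pen tip during the 15 cm line-drawing task.

    The pen moves at constant velocity along a horizontal segment of
    ``line_length`` mm while tremor oscillates perpendicular to it (plus
    drift on the perpendicular and isotropic noise).  With zero amplitude and
    noise the path is exactly the straight segment.
    """
    if not line_length > 0:
        raise ValueError("line_length must be > 0")
    if not draw_duration > 0:
        raise ValueError("draw_duration must be > 0")
    rng = np.random.default_rng(spec.seed)
    n = int(round(draw_duration * spec.fps)) + 1
    t = np.arange(n) / spec.fps
    s = _tremor_scalar(spec, t, rng)
    x = start_mm[0] + line_length * t / draw_duration
    y = start_mm[1] + s + spec.drift_velocity * t
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, (n, 2))
        x = x + noise[:, 0]
        y = y + noise[:, 1]
    return TrajectorySeries(x=x, y=y, fps=spec.fps, units="mm", label="drawing")


# ---------------------------------------------------------------------------
# video rendering
# ---------------------------------------------------------------------------
class MarkerVideo:
    """Lazily rendered grayscale image stack of disc markers on texture.

    Frames are rendered on demand (``video[i]``) so a 60 s 720p recording
    never has to live in memory at once; ``to_array()`` materialises the
    stack.  The textured background is fixed per seed, so render→track round
    trips are reproducible.
    """

    def __init__(
        self,
        trajectories: list[TrajectorySeries],
        frame_size: tuple[int, int] = (1280, 720),
        marker_radius: float = 8.0,
        mm_per_px: float = 0.5,
        origin_px: tuple[float, float] | None = None,
        marker_intensity: int = 235,
        seed: int = 0,
    ) -> None:
        if not trajectories:
            raise ValueError("at least one trajectory is required")
        n = trajectories[0].n
        fps = trajectories[0].fps
        for traj in trajectories:
            if traj.n != n or traj.fps != fps:
                raise ValueError("all trajectories must share length and fps")
        if not mm_per_px > 0:
            raise ValueError("mm_per_px must be > 0")
        if not marker_radius > 0:
            raise ValueError("marker_radius must be > 0")
        w, h = int(frame_size[0]), int(frame_size[1])
        if origin_px is None:
            origin_px = (w / 2.0, h / 2.0)
        self.frame_size = (w, h)
        self.fps = fps
        self.marker_radius = float(marker_radius)
        self.mm_per_px = float(mm_per_px)
        self.origin_px = (float(origin_px[0]), float(origin_px[1]))
        self.marker_intensity = int(marker_intensity)
        self.seed = int(seed)
        # positions in px, image convention (col = x, row = y)
        self._pos_px = []
        for k, traj in enumerate(trajectories):
            mm = traj.in_mm() if traj.is_calibrated else traj
            if mm.units != "mm":
                raise ValueError("trajectories must be calibrated (mm)")
            cx = self.origin_px[0] + mm.x / self.mm_per_px
            cy = self.origin_px[1] + mm.y / self.mm_per_px
            margin = self.marker_radius + 1.0
            bad = np.nonzero(
                (cx < margin) | (cx > w - 1 - margin) | (cy < margin) | (cy > h - 1 - margin)
            )[0]
            if bad.size:
                raise ValueError(
                    f"marker {k} leaves the frame at frame {int(bad[0])} "
                    f"(position {cx[bad[0]]:.1f}, {cy[bad[0]]:.1f} px)"
                )
            self._pos_px.append(np.column_stack([cx, cy]))
        self._n_frames = n
        rng = np.random.default_rng(self.seed)
        texture = rng.uniform(50.0, 130.0, size=(h, w))
        self._background = gaussian_filter(texture, sigma=2.0).astype(np.uint8)

    def __len__(self) -> int:
        return self._n_frames

    def marker_positions_px(self, marker: int = 0) -> np.ndarray:
        """Ground-truth (n, 2) marker centre positions in pixels."""
        return self._pos_px[marker].copy()

    def __getitem__(self, i: int) -> np.ndarray:
        if not -self._n_frames <= i < self._n_frames:
            raise IndexError(i)
        i = i % self._n_frames
        frame = self._background.astype(np.float32).copy()
        r = self.marker_radius
        for pos in self._pos_px:
            cx, cy = pos[i]
            x0, x1 = int(np.floor(cx - r - 1)), int(np.ceil(cx + r + 1)) + 1
            y0, y1 = int(np.floor(cy - r - 1)), int(np.ceil(cy + r + 1)) + 1
            yy, xx = np.mgrid[y0:y1, x0:x1]
            dist = np.hypot(xx - cx, yy - cy)
            # anti-aliased disc: coverage ramps linearly over one pixel
            coverage = np.clip(r + 0.5 - dist, 0.0, 1.0)
            patch = frame[y0:y1, x0:x1]
            frame[y0:y1, x0:x1] = patch * (1 - coverage) + self.marker_intensity * coverage
        return np.clip(frame, 0, 255).astype(np.uint8)

    def to_array(self) -> np.ndarray:
        """Materialise all frames as a (n, h, w) uint8 array."""
        return np.stack([self[i] for i in range(len(self))])

    def write_png_sequence(self, directory) -> None:
        """Write frames as zero-padded numbered PNGs into ``directory``."""
        import os

        import imageio.v3 as iio

        os.makedirs(directory, exist_ok=True)
        digits = max(5, len(str(len(self) - 1)))
        for i in range(len(self)):
            iio.imwrite(os.path.join(directory, f"frame_{i:0{digits}d}.png"), self[i])


def render_marker_video(
    trajectories: list[TrajectorySeries],
    frame_size: tuple[int, int] = (1280, 720),
    marker_radius: float = 8.0,
    mm_per_px: float = 0.5,
    **kwargs,
) -> MarkerVideo:
    """Render calibrated trajectories as a lazily evaluated marker video.

    One frame per trajectory sample; each point is drawn as a high-contrast
    anti-aliased disc over a per-seed fixed textured background.  Raises if
    any marker would leave the frame, naming the first offending frame.
    """
    return MarkerVideo(
        trajectories,
        frame_size=frame_size,
        marker_radius=marker_radius,
        mm_per_px=mm_per_px,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------
def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a pre/post-treatment cohort with Weber–Fechner ratings.

    Returns a DataFrame with one row per patient::

        patient_id, amplitude_pre_mm, amplitude_post_mm, rating_pre, rating_post

    Amplitudes are the true (noise-free) tremor amplitudes in mm; ratings are
    integer clinical scores drawn from the cohort's Weber–Fechner relation.
    """
    rng = np.random.default_rng(spec.seed)
    log_pre = rng.normal(spec.pre_amplitude_log_mean, spec.pre_amplitude_log_sd, spec.n_patients)
    eta = (
        rng.normal(0.0, spec.treatment_noise_log_sd, spec.n_patients)
        if spec.treatment_noise_log_sd > 0
        else np.zeros(spec.n_patients)
    )
    log_post = log_pre - spec.treatment_effect_log + eta
    amp_pre = 10.0 ** log_pre
    amp_post = 10.0 ** log_post
    wf = spec.weber_fechner
    rating_rng = rng if wf.rating_noise_sd > 0 else None
    rating_pre = wf.rating_from_amplitude(amp_pre, rating_rng)
    rating_post = wf.rating_from_amplitude(amp_post, rating_rng)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(spec.n_patients)],
            "amplitude_pre_mm": amp_pre,
            "amplitude_post_mm": amp_post,
            "rating_pre": rating_pre,
            "rating_post": rating_post,
        }
    )


def generate_reliability_matrix(
    n_subjects: int = 10,
    n_columns: int = 2,
    between_log_sd: float = 0.45,
    within_log_sd: float = 0.02,
    mean_log: float = 1.05,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a subjects × occasions (or raters) matrix of log10 amplitudes.

    Each subject has a true log10 amplitude drawn from
    ``N(mean_log, between_log_sd)``; each column adds independent occasion /
    rater noise ``N(0, within_log_sd)``.  Useful for exercising the ICC and
    MDC machinery with known variance components.
    """
    if n_subjects < 2 or n_columns < 2:
        raise ValueError("need at least 2 subjects and 2 columns")
    rng = np.random.default_rng(seed)
    truth = rng.normal(mean_log, between_log_sd, (n_subjects, 1))
    noise = rng.normal(0.0, within_log_sd, (n_subjects, n_columns))
    return truth + noise
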