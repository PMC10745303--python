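"""Markerless point tracking by normalized cross-correlation template matching.

Replaces the tracking step of commercial 2-D motion-analysis software with a
transparent, deterministic baseline: a template is cut from frame 0 around a
user-selected region of interest and matched frame by frame within a search
window around the previous position.  The correlation peak is refined to
sub-pixel precision by quadratic interpolation; low-score frames are flagged
lost and linearly interpolated from their neighbours.

Coordinates follow the image convention: origin at the upper-left corner,
x rightward, y downward, sub-pixel positions allowed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template

from .config import AnalysisConfig
from .trajectory import TrajectorySeries

__all__ = [
    "RoiSelection",
    "TrackingResult",
    "TrackingFailure",
    "track_point",
    "calibrate_scale",
]

_ROI_LABELS = {"finger", "wrist", "elbow", "pen_tip", "custom"}


class TrackingFailure(RuntimeError):
    """Raised when tracking loses more frames than ``max_lost_fraction`` allows."""


@dataclass(frozen=True)
class RoiSelection:
    """A region of interest selected on frame 0.

    ``center`` is the (x, y) pixel position of the anatomical point;
    ``template_half_size`` gives a (2h+1)×(2h+1) template; ``search_radius``
    must cover the expected per-frame motion of the point.
    """

    label: str
    center: tuple[float, float]
    template_half_size: int = 10
    search_radius: int = 20

    def __post_init__(self) -> None:
        if self.label not in _ROI_LABELS:
            raise ValueError(f"label must be one of {sorted(_ROI_LABELS)}")
        if self.template_half_size < 2:
            raise ValueError("template_half_size must be >= 2")
        if self.search_radius < 1:
            raise ValueError("search_radius must be >= 1")


@dataclass
class TrackingResult:
    """Trajectory plus per-frame match quality.

    ``scores`` holds the best normalized cross-correlation per frame in
    [-1, 1] (frame 0 scores 1 by construction); ``lost_frames`` lists frames
    whose score fell below the threshold and whose position was interpolated.
    """

    trajectory: TrajectorySeries
    scores: np.ndarray
    lost_frames: list[int] = field(default_factory=list)
    roi: RoiSelection | None = None

    @property
    def lost_fraction(self) -> float:
        return len(self.lost_frames) / self.trajectory.n

    def to_json_sidecar(self, path, config: AnalysisConfig | None = None) -> None:
        payload = {
            "format": "tremorvideo-tracking v1",
            "label": self.roi.label if self.roi else "",
            "scores": np.round(self.scores, 6).tolist(),
            "lost_frames": [int(i) for i in self.lost_frames],
            "config": {
                "score_threshold": config.score_threshold if config else None,
                "max_lost_fraction": config.max_lost_fraction if config else None,
                "template_update": config.template_update if config else None,
                "template_half_size": self.roi.template_half_size if self.roi else None,
                "search_radius": self.roi.search_radius if self.roi else None,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _subpixel_peak(corr: np.ndarray, iy: int, ix: int) -> tuple[float, float]:
    """Refine an argmax on a correlation surface by 1-D quadratic fits."""

    def refine(m1: float, c0: float, p1: float) -> float:
        denom = m1 - 2 * c0 + p1
        if denom >= 0:  # flat or non-concave neighbourhood: keep integer peak
            return 0.0
        delta = 0.5 * (m1 - p1) / denom
        return float(np.clip(delta, -0.5, 0.5))

    dy = dx = 0.0
    if 0 < iy < corr.shape[0] - 1:
        dy = refine(corr[iy - 1, ix], corr[iy, ix], corr[iy + 1, ix])
    if 0 < ix < corr.shape[1] - 1:
        dx = refine(corr[iy, ix - 1], corr[iy, ix], corr[iy, ix + 1])
    return dy, dx


def track_point(
    frames,
    roi: RoiSelection,
    config: AnalysisConfig | None = None,
    fps: float | None = None,
    mm_per_px: float | None = None,
) -> TrackingResult:
    """Track one point through an image stack.

    Parameters
    ----------
    frames : sequence of 2-D arrays
        Grayscale frames of identical shape (a ``MarkerVideo``, a list of
        arrays, or an (n, h, w) array).
    roi : RoiSelection
        Point and template geometry on frame 0.
    config : AnalysisConfig, optional
        Supplies ``score_threshold``, ``max_lost_fraction`` and
        ``template_update``.
    fps : float, optional
        Frame rate for the output trajectory.  Taken from ``frames.fps``
        when available, else defaults to 25.
    mm_per_px : float, optional
        Calibration attached to the output trajectory (positions stay in px).

    Returns
    -------
    TrackingResult
        Per-frame sub-pixel positions; frames whose best correlation fell
        below the threshold are flagged lost and linearly interpolated.
    """
    config = config or AnalysisConfig()
    n = len(frames)
    if n < 2:
        raise ValueError("tracking requires at least 2 frames")
    if fps is None:
        fps = float(getattr(frames, "fps", 25.0))
    if mm_per_px is None:
        mm_per_px = getattr(frames, "mm_per_px", None)

    frame0 = np.asarray(frames[0], dtype=np.float64)
    if frame0.ndim != 2:
        raise ValueError("frames must be 2-D grayscale images")
    h, w = frame0.shape
    half = roi.template_half_size
    cx0, cy0 = int(round(roi.center[0])), int(round(roi.center[1]))
    if not (half <= cx0 < w - half and half <= cy0 < h - half):
        raise ValueError("ROI template window extends outside frame 0")

    template = frame0[cy0 - half : cy0 + half + 1, cx0 - half : cx0 + half + 1].copy()
    if template.std() == 0:
        raise ValueError("ROI template has zero variance; pick a textured point")

    xs = np.empty(n)
    ys = np.empty(n)
    scores = np.empty(n)
    xs[0], ys[0] = float(roi.center[0]), float(roi.center[1])
    scores[0] = 1.0
    lost = np.zeros(n, dtype=bool)

    r = roi.search_radius
    prev_x, prev_y = xs[0], ys[0]
    for i in range(1, n):
        frame = np.asarray(frames[i], dtype=np.float64)
        if frame.shape != (h, w):
            raise ValueError(f"frame {i} has shape {frame.shape}, expected {(h, w)}")
        # search window (template must fit: pad by template half-size)
        x0 = max(0, int(round(prev_x)) - r - half)
        x1 = min(w, int(round(prev_x)) + r + half + 1)
        y0 = max(0, int(round(prev_y)) - r - half)
        y1 = min(h, int(round(prev_y)) + r + half + 1)
        window = frame[y0:y1, x0:x1]
        if window.shape[0] < template.shape[0] or window.shape[1] < template.shape[1]:
            scores[i] = -1.0
            lost[i] = True
            xs[i], ys[i] = prev_x, prev_y
            continue
        corr = match_template(window, template, pad_input=False)
        iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
        score = float(corr[iy, ix])
        scores[i] = score
        if score < config.score_threshold:
            lost[i] = True
            xs[i], ys[i] = prev_x, prev_y  # placeholder, interpolated below
            continue
        dy, dx = _subpixel_peak(corr, int(iy), int(ix))
        xs[i] = x0 + ix + dx + half
        ys[i] = y0 + iy + dy + half
        prev_x, prev_y = xs[i], ys[i]
        if config.template_update > 0:
            cxi, cyi = int(round(xs[i])), int(round(ys[i]))
            if half <= cxi < w - half and half <= cyi < h - half:
                patch = frame[cyi - half : cyi + half + 1, cxi - half : cxi + half + 1]
                a = config.template_update
                template = (1 - a) * template + a * patch

    lost_idx = np.nonzero(lost)[0]
    if lost_idx.size / n > config.max_lost_fraction:
        raise TrackingFailure(
            f"{lost_idx.size}/{n} frames lost "
            f"(> max_lost_fraction = {config.max_lost_fraction})"
        )
    if lost_idx.size:
        good = np.nonzero(~lost)[0]
        xs[lost_idx] = np.interp(lost_idx, good, xs[good])
        ys[lost_idx] = np.interp(lost_idx, good, ys[good])

    traj = TrajectorySeries(
        x=xs,
        y=ys,
        fps=fps,
        units="px",
        mm_per_px=mm_per_px,
        interpolated=lost,
        label=roi.label,
    )
    return TrackingResult(
        trajectory=traj, scores=scores, lost_frames=[int(i) for i in lost_idx], roi=roi
    )


def calibrate_scale(
    reference_length_mm: float, endpoints_px: tuple[tuple[float, float], tuple[float, float]]
) -> float:
    """mm-per-pixel scale from a reference length visible in the frame.

    Typically the 15 cm target line itself serves as the reference.
    """
    if not reference_length_mm > 0:
        raise ValueError("reference_length_mm must be > 0")
    (x0, y0), (x1, y1) = endpoints_px
    dist = float(np.hypot(x1 - x0, y1 - y0))
    if dist == 0:
        raise ValueError("calibration endpoints coincide")
    return reference_length_mm / dist
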