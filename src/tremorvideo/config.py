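"""Analysis configuration shared by the tracking, kinematics and pipeline stages."""
from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Tunable parameters of the tremor analysis.

    All durations are in seconds, lengths in millimetres unless noted.

    Attributes
    ----------
    window_s : float
        Length of the postural analysis window (the highest-amplitude
        window rule).
    search_start_s, search_end_s : float
        Range of admissible window *centres* within the recording.
    envelope_s : float
        Length of the sliding peak-to-peak envelope used to locate the
        highest-amplitude window centre.
    detrend_s : float
        Length of the centred moving-average baseline (applied twice) that
        removes slow drift before cycle analysis.
    hysteresis_frac : float
        Zero-crossing hysteresis band as a fraction of the robust half-range
        of the tremor signal; suppresses noise-driven cycle chatter.
    amplitude_floor_mm : float
        Absolute floor below which per-cycle excursions are treated as noise
        and excluded from the geometric-mean amplitude; also the "no tremor"
        threshold on the robust signal range.
    oversample : int
        Fourier upsampling factor applied to the tremor signal before cycle
        extraction (tremor frequencies approach Nyquist at 25 fps).
    amplitude_mode : {"peak_to_peak", "half"}
        Whether per-cycle amplitude is the full excursion or half of it.
    speed_threshold_mm_s, sustain_s : float
        Drawing-span detection: motion counts once speed exceeds the
        threshold for at least ``sustain_s`` seconds.
    score_threshold : float
        Minimum normalized cross-correlation score for a tracked frame;
        below it the frame is flagged lost and interpolated.
    max_lost_fraction : float
        Tracking fails outright when more than this fraction of frames is lost.
    template_update : float
        Exponential blend rate for slow template update (0 = fixed template).
    significance_levels : tuple of float
        Two-level star convention for report tables (p < .05 -> *, p < .01 -> **).
    """

    window_s: float = 10.0
    search_start_s: float = 5.0
    search_end_s: float = 55.0
    envelope_s: float = 1.0
    detrend_s: float = 1.0
    hysteresis_frac: float = 0.10
    amplitude_floor_mm: float = 0.0
    oversample: int = 16
    amplitude_mode: str = "peak_to_peak"
    speed_threshold_mm_s: float = 5.0
    sustain_s: float = 0.2
    score_threshold: float = 0.5
    max_lost_fraction: float = 0.2
    template_update: float = 0.0
    significance_levels: tuple = (0.05, 0.01)

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.amplitude_mode not in ("peak_to_peak", "half"):
            raise ValueError("amplitude_mode must be 'peak_to_peak' or 'half'")
        if not 0 <= self.max_lost_fraction <= 1:
            raise ValueError("max_lost_fraction must lie in [0, 1]")
        if self.oversample < 1:
            raise ValueError("oversample must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "significance_levels" in data:
            data["significance_levels"] = tuple(data["significance_levels"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["significance_levels"] = list(self.significance_levels)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
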