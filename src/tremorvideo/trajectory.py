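"""Time-stamped XY trajectories of tracked anatomical points.

A :class:`TrajectorySeries` is the common currency of the package: the
synthetic generators produce one, the video tracker recovers one, and the
kinematic analysis consumes one.  Positions are either in millimetres
(``units="mm"``) or in pixels with an attached ``mm_per_px`` calibration.

The on-disk format is a plain CSV with columns
``frame,time_s,x,y,units,interpolated`` preceded by comment lines carrying
the format version and, when known, the pixel calibration::

    # tremorvideo-trajectory v1
    # fps: 25.0
    # mm_per_px: 0.5
    frame,time_s,x,y,units,interpolated
    0,0.0,12.1,40.2,px,0
    ...
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["TrajectorySeries", "read_trajectory_csv", "write_trajectory_csv"]

_FORMAT_TAG = "tremorvideo-trajectory v1"


@dataclass
class TrajectorySeries:
    """XY path of one tracked point sampled at a constant frame rate.

    Parameters
    ----------
    x, y : array-like
        Coordinates per frame.  ``y`` follows the image convention (origin at
        the upper-left corner, y increasing downward) when the series comes
        from video.
    fps : float
        Frames per second; the sample times are ``start_time + i / fps``.
    units : {"mm", "px"}
        Units of ``x`` and ``y``.
    mm_per_px : float, optional
        Pixel calibration.  Required to convert a ``px`` series to mm.
    interpolated : array-like of bool, optional
        Flags samples whose position was filled in (e.g. lost tracking
        frames).  Defaults to all-False.
    start_time : float
        Time of the first sample in seconds (non-zero for cropped series).
    """

    x: np.ndarray
    y: np.ndarray
    fps: float
    units: str = "mm"
    mm_per_px: float | None = None
    interpolated: np.ndarray | None = None
    start_time: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.y.ndim != 1 or self.x.size != self.y.size:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.x.size < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("trajectory coordinates must be finite")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if self.units not in ("mm", "px"):
            raise ValueError(f"units must be 'mm' or 'px', got {self.units!r}")
        if self.interpolated is None:
            self.interpolated = np.zeros(self.x.size, dtype=bool)
        else:
            self.interpolated = np.asarray(self.interpolated, dtype=bool)
            if self.interpolated.size != self.x.size:
                raise ValueError("interpolated flags must match trajectory length")

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return int(self.x.size)

    def __len__(self) -> int:
        return self.n

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(self.n) / self.fps

    @property
    def frame_index(self) -> np.ndarray:
        return np.rint(self.start_time * self.fps).astype(int) + np.arange(self.n)

    @property
    def duration(self) -> float:
        """Time spanned between first and last sample, in seconds."""
        return (self.n - 1) / self.fps

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of coordinates."""
        return np.column_stack([self.x, self.y])

    # -- unit handling ---------------------------------------------------
    @property
    def is_calibrated(self) -> bool:
        return self.units == "mm" or self.mm_per_px is not None

    def in_mm(self) -> "TrajectorySeries":
        """Return this series with coordinates in millimetres.

        Raises
        ------
        ValueError
            If the series is in pixels and no ``mm_per_px`` scale is attached.
        """
        if self.units == "mm":
            return self
        if self.mm_per_px is None:
            raise ValueError(
                "trajectory is in pixels and has no mm_per_px calibration; "
                "attach one (see tracking.calibrate_scale)"
            )
        return replace(
            self,
            x=self.x * self.mm_per_px,
            y=self.y * self.mm_per_px,
            units="mm",
            mm_per_px=self.mm_per_px,
        )

    # -- cropping ---------------------------------------------------------
    def crop(self, t0: float, t1: float) -> "TrajectorySeries":
        """Return the sub-series with sample times in ``[t0, t1]`` (inclusive)."""
        t = self.time
        # half-sample tolerance so window edges on the sample grid are kept
        eps = 0.5 / self.fps
        mask = (t >= t0 - eps) & (t <= t1 + eps)
        idx = np.nonzero(mask)[0]
        if idx.size < 2:
            raise ValueError(f"crop window [{t0}, {t1}] contains fewer than 2 samples")
        return replace(
            self,
            x=self.x[idx],
            y=self.y[idx],
            interpolated=self.interpolated[idx],
            start_time=float(t[idx[0]]),
        )

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame_index,
                "time_s": self.time,
                "x": self.x,
                "y": self.y,
                "units": self.units,
                "interpolated": self.interpolated.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        write_trajectory_csv(self, path)

    @classmethod
    def from_csv(cls, path) -> "TrajectorySeries":
        return read_trajectory_csv(path)

    # -- plotting ----------------------------------------------------------
    def plot(self, ax=None, **kwargs):
        """Plot the XY path (image convention: y axis inverted)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.x, self.y, **kwargs)
        ax.set_xlabel(f"x [{self.units}]")
        ax.set_ylabel(f"y [{self.units}]")
        if not ax.yaxis_inverted():
            ax.invert_yaxis()
        ax.set_aspect("equal", adjustable="datalim")
        return ax


def write_trajectory_csv(traj: TrajectorySeries, path) -> None:
    buf = io.StringIO()
    buf.write(f"# {_FORMAT_TAG}\n")
    buf.write(f"# fps: {traj.fps!r}\n")
    if traj.mm_per_px is not None:
        buf.write(f"# mm_per_px: {traj.mm_per_px!r}\n")
    if traj.label:
        buf.write(f"# label: {traj.label}\n")
    traj.to_frame().to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_trajectory_csv(path) -> TrajectorySeries:
    fps = None
    mm_per_px = None
    label = ""
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        key_val = line.lstrip("# ").split(":", 1)
        if len(key_val) != 2:
            continue
        key, val = key_val[0].strip(), key_val[1].strip()
        if key == "fps":
            fps = float(val)
        elif key == "mm_per_px":
            mm_per_px = float(val)
        elif key == "label":
            label = val
    df = pd.read_csv(io.StringIO(text), comment="#")
    required = {"frame", "time_s", "x", "y", "units"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory CSV missing columns {required - set(df.columns)}")
    if fps is None:
        dt = np.diff(df["time_s"].to_numpy())
        if dt.size == 0 or not np.all(dt > 0):
            raise ValueError("cannot infer fps from CSV time column")
        fps = 1.0 / float(np.median(dt))
    interp = (
        df["interpolated"].to_numpy().astype(bool)
        if "interpolated" in df.columns
        else None
    )
    return TrajectorySeries(
        x=df["x"].to_numpy(),
        y=df["y"].to_numpy(),
        fps=fps,
        units=str(df["units"].iloc[0]),
        mm_per_px=mm_per_px,
        interpolated=interp,
        start_time=float(df["time_s"].iloc[0]),
        label=label,
    )
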