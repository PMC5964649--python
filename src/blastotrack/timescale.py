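"""Embryo volume series, blastocoel-collapse detection and time normalization.

Embryos develop at different paces, so clock time (hours post fertilization
or activation) is rescaled to a *normalized age* (n.a.) anchored at two
morphogenetic fixed points: fertilization/activation at 0 and the first
blastocoel collapse at 1.  The collapse is detected as the first drop of
more than ``drop_threshold`` (default 10%, strict) in the convex-hull volume
of the nucleus point cloud from one timestep to the next.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .errors import CollapseNotFoundError, DegenerateGeometryError
from .lineage_io import EmbryoLineage

__all__ = [
    "VolumeSeries",
    "TimeScale",
    "CommonWindow",
    "hull_volume_series",
    "detect_first_collapse",
    "to_normalized_age",
    "common_window",
    "resample_linear",
    "compute_timescale",
]

DEFAULT_DROP_THRESHOLD = 0.10


@dataclass
class VolumeSeries:
    """Per-timestep convex-hull volume (µm³) with clock time per entry."""

    timesteps: np.ndarray
    time_hp: np.ndarray
    volume: np.ndarray

    def __len__(self) -> int:
        return len(self.volume)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "timestep": self.timesteps,
            "time_hp": self.time_hp,
            "volume_um3": self.volume,
        })


@dataclass(frozen=True)
class TimeScale:
    """Linear map between clock time and normalized age: na = t / t_collapse."""

    t_collapse_hp: float
    collapse_timestep: int | None = None

    def __post_init__(self) -> None:
        if self.t_collapse_hp <= 0:
            raise ValueError("collapse time must be positive")

    def to_na(self, time_hp):
        return to_normalized_age(time_hp, self)

    def from_na(self, na):
        return np.asarray(na, dtype=float) * self.t_collapse_hp


@dataclass(frozen=True)
class CommonWindow:
    """Intersection of per-embryo observation windows in normalized age."""

    lo_na: float
    hi_na: float

    def __post_init__(self) -> None:
        if not self.lo_na < self.hi_na:
            raise ValueError("empty window")

    def contains(self, na) -> np.ndarray:
        na = np.asarray(na, dtype=float)
        return (na >= self.lo_na) & (na <= self.hi_na)

    def grid(self, step: float = 0.05) -> np.ndarray:
        n = int(np.floor((self.hi_na - self.lo_na) / step + 1e-9)) + 1
        return self.lo_na + step * np.arange(n)


# ---------------------------------------------------------------------------

def hull_volume_series(lineage: EmbryoLineage) -> VolumeSeries:
    """3D convex-hull volume of all validated nuclei, per timestep.

    Raises :class:`DegenerateGeometryError` naming the first timestep whose
    validated nuclei are fewer than 4 or coplanar.
    """
    steps = lineage.timesteps
    times = np.empty(len(steps))
    vols = np.empty(len(steps))
    for i, step in enumerate(steps):
        frame = lineage.frame_nodes(int(step))
        pts = frame[["x", "y", "z"]].to_numpy(float)
        if len(pts) < 4:
            raise DegenerateGeometryError(
                f"timestep {step}: {len(pts)} validated nuclei (need >=4)")
        try:
            hull = ConvexHull(pts)
        except QhullError as exc:
            raise DegenerateGeometryError(
                f"timestep {step}: degenerate geometry ({exc})") from exc
        vols[i] = hull.volume
        times[i] = float(frame["time_hp"].iloc[0])
    return VolumeSeries(timesteps=steps, time_hp=times, volume=vols)


def detect_first_collapse(
    series: VolumeSeries,
    drop_threshold: float = DEFAULT_DROP_THRESHOLD,
) -> tuple[int, float]:
    """First blastocoel collapse: earliest timestep whose volume is more than
    ``drop_threshold`` below the preceding timestep's (strict inequality).

    Returns ``(timestep, time_hp)`` of the *later* frame of the qualifying
    pair — the first frame exhibiting the reduced volume.  Raises
    :class:`CollapseNotFoundError` when no drop qualifies.
    """
    if len(series) < 2:
        raise CollapseNotFoundError("volume series has fewer than 2 entries")
    v = np.asarray(series.volume, dtype=float)
    qualifying = np.flatnonzero(v[1:] < (1.0 - drop_threshold) * v[:-1])
    if len(qualifying) == 0:
        raise CollapseNotFoundError(
            f"no volume drop exceeding {drop_threshold:.0%} detected")
    i = int(qualifying[0]) + 1
    return int(series.timesteps[i]), float(series.time_hp[i])


def to_normalized_age(time_hp, timescale: TimeScale):
    """Map hours post fertilization/activation to normalized age."""
    t = np.asarray(time_hp, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    out = t / timescale.t_collapse_hp
    return float(out) if np.isscalar(time_hp) else out


def compute_timescale(
    lineage: EmbryoLineage,
    drop_threshold: float = DEFAULT_DROP_THRESHOLD,
) -> tuple[TimeScale, VolumeSeries]:
    """Convenience: volume series + collapse detection in one call."""
    series = hull_volume_series(lineage)
    step, t_collapse = detect_first_collapse(series, drop_threshold)
    return TimeScale(t_collapse_hp=t_collapse, collapse_timestep=step), series


def observation_window_na(lineage: EmbryoLineage, timescale: TimeScale) -> tuple[float, float]:
    """The embryo's validated observation window in normalized age."""
    times = lineage.nodes.loc[lineage.nodes["validated"].astype(bool), "time_hp"]
    return (to_normalized_age(float(times.min()), timescale),
            to_normalized_age(float(times.max()), timescale))


def common_window(windows: list[tuple[float, float]]) -> CommonWindow:
    """Intersection of per-embryo (lo, hi) windows in n.a."""
    if not windows:
        raise ValueError("no windows given")
    lo = max(w[0] for w in windows)
    hi = min(w[1] for w in windows)
    if not lo < hi:
        raise ValueError(f"empty common window: [{lo:.3f}, {hi:.3f}]")
    return CommonWindow(lo_na=lo, hi_na=hi)


def resample_linear(times: np.ndarray, values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Linear interpolation of a series onto a grid; no extrapolation.

    Grid points coinciding with samples return them exactly.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if len(times) == 0:
        raise ValueError("empty series")
    if np.any(grid < times[0] - 1e-12) or np.any(grid > times[-1] + 1e-12):
        raise ValueError(
            f"grid [{grid.min():g}, {grid.max():g}] outside series range "
            f"[{times[0]:g}, {times[-1]:g}]")
    return np.interp(grid, times, values)
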