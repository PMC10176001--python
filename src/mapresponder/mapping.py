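"""Corticomotor map construction and metrics.

A TMS map is estimated by triangular (Delaunay) linear interpolation of
peak-to-peak MEP amplitudes recorded at scattered scalp coordinates, evaluated
on a regular partition of the stimulated grid.  Partitions whose interpolated
amplitude exceeds a fixed fraction (default 25%) of the map's peak response are
"active"; map area, map volume and the amplitude-weighted center of gravity
(CoG) are computed over the active set.  Between-session reorganization is
summarized by the Euclidean displacement of the CoG.

Coordinates are continuous, vertex-referenced centimeters: ``x`` mediolateral
(positive lateral), ``y`` anteroposterior (positive anterior).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError

__all__ = [
    "GridSpec",
    "StimulationEvent",
    "MotorMap",
    "Displacement",
    "build_map",
    "map_area",
    "map_volume",
    "center_of_gravity",
    "cog_displacement",
    "percent_change",
]


@dataclass(frozen=True)
class GridSpec:
    """Stimulation grid geometry and partition resolution.

    The default mirrors a 5 x 7 cm scalp grid (six rows by eight columns of
    stimulation sites) subdivided into 50 x 50 = 2500 partitions for map
    metrics.  ``origin`` is the vertex-referenced coordinate of the
    medial-posterior grid corner.
    """

    width_cm: float = 7.0
    height_cm: float = 5.0
    rows: int = 6
    cols: int = 8
    origin: tuple[float, float] = (0.0, 0.0)
    partitions: int = 50

    def __post_init__(self) -> None:
        if self.width_cm <= 0 or self.height_cm <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.rows < 2 or self.cols < 2 or self.partitions < 2:
            raise ValueError("rows, cols and partitions must each be >= 2")

    @property
    def area_cm2(self) -> float:
        """Stimulated scalp area (35 cm2 for the default grid)."""
        return self.width_cm * self.height_cm

    @property
    def n_partitions(self) -> int:
        return self.partitions * self.partitions

    def site_coordinates(self) -> np.ndarray:
        """Centers of the rows x cols stimulation sites, shape (n_sites, 2).

        Row 0 is posterior (low y), column 0 medial (low x); sites sit at the
        centers of equal cells tiling the grid.
        """
        ox, oy = self.origin
        xs = ox + (np.arange(self.cols) + 0.5) * self.width_cm / self.cols
        ys = oy + (np.arange(self.rows) + 0.5) * self.height_cm / self.rows
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def partition_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Partition-center coordinate axes ``(x, y)`` of length ``partitions``."""
        ox, oy = self.origin
        n = self.partitions
        x = ox + (np.arange(n) + 0.5) * self.width_cm / n
        y = oy + (np.arange(n) + 0.5) * self.height_cm / n
        return x, y

    def contains(self, x: float, y: float, tol_cm: float = 0.0) -> bool:
        ox, oy = self.origin
        return (
            ox - tol_cm <= x <= ox + self.width_cm + tol_cm
            and oy - tol_cm <= y <= oy + self.height_cm + tol_cm
        )


@dataclass(frozen=True)
class StimulationEvent:
    """One TMS pulse: scalp coordinate plus the elicited MEP amplitude."""

    x: float
    y: float
    amplitude: float
    trial: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("event coordinates must be finite")
        if not np.isfinite(self.amplitude) or self.amplitude < 0:
            raise ValueError("MEP amplitude must be finite and >= 0")


@dataclass
class Displacement:
    """Euclidean displacement (cm) between two CoG coordinates."""

    ed: float
    start: tuple[float, float]
    end: tuple[float, float]


@dataclass
class MotorMap:
    """Interpolated map surface with derived metrics.

    ``surface`` is indexed ``[row, col]`` = ``[y, x]`` with row 0 posterior and
    column 0 medial; ``volume`` is the sum of interpolated amplitudes (mV) over
    active partitions; ``area`` scales the active-partition count to the
    stimulated area.
    """

    grid: GridSpec
    surface: np.ndarray
    active_mask: np.ndarray
    peak: float
    n_active: int
    area: float
    volume: float
    cog: tuple[float, float] | None
    threshold_fraction: float = 0.25
    events_used: int = 0
    events_merged: int = 0

    def summary(self) -> dict:
        cx, cy = self.cog if self.cog is not None else (np.nan, np.nan)
        return {
            "peak_mv": self.peak,
            "n_active": self.n_active,
            "area_cm2": self.area,
            "volume_mv": self.volume,
            "cog_x_cm": cx,
            "cog_y_cm": cy,
        }


def _merge_duplicates(
    points: np.ndarray, amplitudes: np.ndarray, merge_tol_cm: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Average amplitudes of events closer than ``merge_tol_cm``.

    Triangulation needs unique vertices; coordinates are snapped to a lattice
    of pitch ``merge_tol_cm`` and events sharing a lattice cell are merged to
    their mean coordinate and mean amplitude.
    """
    if merge_tol_cm <= 0:
        return points, amplitudes, 0
    keys = np.round(points / merge_tol_cm).astype(np.int64)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    n_groups = int(inverse.max()) + 1
    if n_groups == len(points):
        return points, amplitudes, 0
    counts = np.bincount(inverse, minlength=n_groups).astype(float)
    px = np.bincount(inverse, weights=points[:, 0], minlength=n_groups) / counts
    py = np.bincount(inverse, weights=points[:, 1], minlength=n_groups) / counts
    amp = np.bincount(inverse, weights=amplitudes, minlength=n_groups) / counts
    return np.column_stack([px, py]), amp, len(points) - n_groups


def build_map(
    events: list[StimulationEvent],
    grid: GridSpec | None = None,
    threshold_fraction: float = 0.25,
    merge_tol_cm: float = 0.05,
) -> MotorMap:
    """Interpolate stimulation events into a full surface map and derive metrics.

    Near-duplicate coordinates are merged by averaging amplitude, the merged
    points are Delaunay-triangulated and linearly interpolated at the grid's
    partition centers, partitions outside the convex hull are assigned 0 mV,
    and the surface is floored at 0.  Partitions exceeding
    ``threshold_fraction`` of the surface peak are active.

    Raises
    ------
    ValueError
        If fewer than 3 usable (merged) points remain or the points are
        collinear, so that no triangulation exists.
    """
    grid = grid or GridSpec()
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    if len(events) == 0:
        raise ValueError("no stimulation events supplied")

    points = np.array([[e.x, e.y] for e in events], dtype=float)
    amplitudes = np.array([e.amplitude for e in events], dtype=float)
    points, amplitudes, n_merged = _merge_duplicates(points, amplitudes, merge_tol_cm)
    if len(points) < 3:
        raise ValueError("need >= 3 distinct stimulation coordinates to triangulate")

    try:
        interp = LinearNDInterpolator(points, amplitudes, fill_value=0.0)
    except QhullError as exc:  # collinear or otherwise degenerate point set
        raise ValueError(f"stimulation coordinates admit no triangulation: {exc}") from exc

    px, py = grid.partition_centers()
    xx, yy = np.meshgrid(px, py)
    surface = np.asarray(interp(xx, yy), dtype=float)
    np.maximum(surface, 0.0, out=surface)

    peak = float(surface.max())
    active = surface > threshold_fraction * peak if peak > 0 else np.zeros_like(surface, bool)
    n_active = int(active.sum())
    area = n_active / grid.n_partitions * grid.area_cm2
    volume = float(surface[active].sum())

    cog: tuple[float, float] | None = None
    if volume > 0:
        w = surface[active]
        cog = (float((xx[active] * w).sum() / w.sum()), float((yy[active] * w).sum() / w.sum()))

    return MotorMap(
        grid=grid,
        surface=surface,
        active_mask=active,
        peak=peak,
        n_active=n_active,
        area=area,
        volume=volume,
        cog=cog,
        threshold_fraction=threshold_fraction,
        events_used=len(points),
        events_merged=n_merged,
    )


def map_area(motor_map: MotorMap, grid: GridSpec | None = None) -> float:
    """Map area (cm2): active partitions / total partitions x stimulated area."""
    grid = grid or motor_map.grid
    return motor_map.n_active / grid.n_partitions * grid.area_cm2


def map_volume(motor_map: MotorMap) -> float:
    """Map volume (mV): sum of interpolated amplitudes over active partitions."""
    return float(motor_map.surface[motor_map.active_mask].sum())


def center_of_gravity(motor_map: MotorMap) -> tuple[float, float]:
    """Amplitude-weighted centroid: CoG = (sum(x*z)/sum(z), sum(y*z)/sum(z)).

    ``z`` is the interpolated amplitude at each active partition center.
    Raises ``ValueError`` when the total active amplitude is zero.
    """
    if motor_map.cog is None:
        raise ValueError("center of gravity undefined: zero total amplitude")
    return motor_map.cog


def cog_displacement(
    baseline: tuple[float, float], followup: tuple[float, float]
) -> Displacement:
    """Euclidean displacement ED = sqrt((y1-y2)^2 + (x1-x2)^2) in cm."""
    (x1, y1), (x2, y2) = baseline, followup
    ed = float(np.hypot(y1 - y2, x1 - x2))
    return Displacement(ed=ed, start=(float(x1), float(y1)), end=(float(x2), float(y2)))


def percent_change(pre_value: float, post_value: float) -> float:
    """Signed percent change 100 * (post - pre) / pre; requires pre > 0."""
    if not np.isfinite(pre_value) or pre_value <= 0:
        raise ValueError("percent change requires a positive baseline value")
    return 100.0 * (post_value - pre_value) / pre_value
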