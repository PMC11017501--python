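"""Vessel centerline paths.

A :class:`VesselPath` is an ordered 3D polyline in physical (z,y,x) µm
coordinates with an optional per-point radius estimate, as produced by
seed-guided tracing or by the phantom generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VesselPath", "resample_polyline", "polyline_length"]


def polyline_length(points: np.ndarray) -> float:
    """Total arc length of a polyline given as an (N, 3) µm array."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def resample_polyline(
    points: np.ndarray, spacing_um: float, values: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Resample a polyline to (approximately) uniform arclength spacing.

    Endpoints are preserved exactly; the step is shrunk so that it divides
    the total length evenly.  ``values`` (per-point scalars, e.g. radii) are
    linearly interpolated onto the new stations.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (N, 3)")
    if len(pts) < 2:
        return pts.copy(), None if values is None else np.asarray(values, float).copy()
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        raise ValueError("degenerate polyline: zero length")
    n = max(int(np.ceil(total / spacing_um)), 1)
    stations = np.linspace(0.0, total, n + 1)
    out = np.column_stack([np.interp(stations, s, pts[:, k]) for k in range(3)])
    vals = None
    if values is not None:
        vals = np.interp(stations, s, np.asarray(values, dtype=float))
    return out, vals


@dataclass
class VesselPath:
    """An ordered vessel centerline.

    Parameters
    ----------
    vessel_id :
        Integer identity, unique within a scene.
    points_um :
        ``(N, 3)`` array of (z, y, x) µm coordinates, N ≥ 2.
    radius_um :
        Optional per-point radius estimate in µm (positive where set).
    parent_id :
        Identity of the vessel this one branches off, if any.
    """

    vessel_id: int
    points_um: np.ndarray
    radius_um: np.ndarray | None = None
    parent_id: int | None = None

    def __post_init__(self) -> None:
        self.points_um = np.asarray(self.points_um, dtype=float)
        if self.points_um.ndim != 2 or self.points_um.shape[1] != 3:
            raise ValueError("points_um must be an (N, 3) array")
        if len(self.points_um) < 2:
            raise ValueError("a vessel path needs at least 2 points")
        if self.radius_um is not None:
            self.radius_um = np.asarray(self.radius_um, dtype=float)
            if self.radius_um.shape != (len(self.points_um),):
                raise ValueError("radius_um must have one value per point")
            if np.any(self.radius_um[np.isfinite(self.radius_um)] <= 0):
                raise ValueError("radii must be positive where set")

    # -- arclength parametrisation ---------------------------------------
    @property
    def arclengths(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points_um, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length_um(self) -> float:
        return polyline_length(self.points_um)

    def point_at(self, s: float) -> np.ndarray:
        """Centerline point at arclength ``s`` µm (clamped to the extent)."""
        arcs = self.arclengths
        s = float(np.clip(s, 0.0, arcs[-1]))
        return np.array([np.interp(s, arcs, self.points_um[:, k]) for k in range(3)])

    def radius_at(self, s: float) -> float:
        if self.radius_um is None:
            raise ValueError("path has no radii")
        arcs = self.arclengths
        return float(np.interp(np.clip(s, 0, arcs[-1]), arcs, self.radius_um))

    def tangent_at(self, s: float, window_um: float = 2.0) -> np.ndarray:
        """Unit tangent at arclength ``s``, from a central difference over
        ``±window_um`` (robust to voxel-scale jitter in traced paths)."""
        arcs = self.arclengths
        a = self.point_at(max(s - window_um, 0.0))
        b = self.point_at(min(s + window_um, arcs[-1]))
        t = b - a
        n = np.linalg.norm(t)
        if n == 0:
            raise ValueError("cannot compute tangent on a degenerate segment")
        return t / n

    def resampled(self, spacing_um: float = 1.0) -> "VesselPath":
        pts, rad = resample_polyline(self.points_um, spacing_um, self.radius_um)
        return VesselPath(self.vessel_id, pts, rad, self.parent_id)
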