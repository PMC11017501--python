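"""Perpendicular intensity profiles and full-width-at-half-maximum estimates.

Shared by centerline tracing (per-point radius initialisation) and by the
vessel-diameter measurement: both read an intensity profile along the line
perpendicular to the local path tangent, restricted to the imaging plane,
and take the width between the half-maximum crossings as the lumen
diameter.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .stack import ImageStack

__all__ = ["sample_line", "fwhm", "inplane_normal", "refine_center_z", "fwhm_diameter_at_point"]


def sample_line(
    stack: ImageStack,
    center_um: np.ndarray,
    direction: np.ndarray,
    half_extent_um: float,
    step_um: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample intensities along ``center + t * direction`` for
    ``t in [-half_extent, half_extent]`` (µm); trilinear interpolation,
    zero outside the volume.  Returns (offsets µm, values)."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    n = max(int(np.ceil(half_extent_um / step_um)), 1)
    offsets = np.arange(-n, n + 1) * step_um
    pts = np.asarray(center_um, dtype=float)[None, :] + offsets[:, None] * direction[None, :]
    coords = (pts / stack.spacing - 0.5).T
    values = ndimage.map_coordinates(
        stack.data.astype(float), coords, order=1, mode="constant", cval=0.0
    )
    return offsets, values


def fwhm(offsets: np.ndarray, values: np.ndarray, baseline: float = 0.0) -> float:
    """Full width at half maximum of a 1D profile.

    The half level is ``baseline + (peak - baseline) / 2``; crossings are
    located by marching outward from the peak with linear interpolation.
    Returns NaN when the profile never falls below the half level on either
    side (the structure exits the sampled extent).
    """
    values = np.asarray(values, dtype=float)
    k = int(np.argmax(values))
    peak = values[k]
    if peak <= baseline:
        return float("nan")
    half = baseline + (peak - baseline) / 2.0

    right = float("nan")
    for i in range(k + 1, len(values)):
        if values[i] < half:
            f = (values[i - 1] - half) / (values[i - 1] - values[i])
            right = offsets[i - 1] + f * (offsets[i] - offsets[i - 1])
            break
    left = float("nan")
    for i in range(k - 1, -1, -1):
        if values[i] < half:
            f = (values[i + 1] - half) / (values[i + 1] - values[i])
            left = offsets[i + 1] + f * (offsets[i] - offsets[i + 1])
            break
    return float(right - left)


def inplane_normal(tangent: np.ndarray) -> np.ndarray:
    """Unit vector perpendicular to the (z,y,x) tangent and lying in the
    imaging (xy) plane.  For a near-vertical tangent any in-plane direction
    is perpendicular; +y is returned."""
    tz, ty, tx = np.asarray(tangent, dtype=float)
    n = np.hypot(ty, tx)
    if n < 1e-9:
        return np.array([0.0, 1.0, 0.0])
    return np.array([0.0, -tx / n, ty / n])


def refine_center_z(stack: ImageStack, point_um: np.ndarray, step_um: float | None = None) -> np.ndarray:
    """Shift a station point along z to the local intensity maximum
    (parabolic, sub-voxel).  Compensates the coarse axial sampling so the
    in-plane profile cuts the vessel through its equator."""
    step = float(stack.spacing[0]) if step_um is None else step_um
    pts = np.asarray(point_um, dtype=float)[None, :] + np.array(
        [[-step, 0, 0], [0, 0, 0], [step, 0, 0]]
    )
    coords = (pts / stack.spacing - 0.5).T
    v = ndimage.map_coordinates(stack.data.astype(float), coords, order=1, mode="nearest")
    denom = v[0] - 2 * v[1] + v[2]
    if denom >= -1e-12:  # not a local maximum
        return np.asarray(point_um, dtype=float)
    dz = 0.5 * (v[0] - v[2]) / denom
    dz = float(np.clip(dz, -1.0, 1.0))
    out = np.asarray(point_um, dtype=float).copy()
    out[0] += dz * step
    return out


def fwhm_diameter_at_point(
    stack: ImageStack,
    point_um: np.ndarray,
    tangent: np.ndarray,
    max_radius_um: float = 80.0,
    step_frac: float = 0.25,
    baseline: float = 0.0,
    refine_z: bool = True,
) -> float:
    """FWHM of the in-plane perpendicular profile at one station, in µm."""
    center = refine_center_z(stack, point_um) if refine_z else np.asarray(point_um, float)
    normal = inplane_normal(tangent)
    step = step_frac * float(min(stack.spacing[1], stack.spacing[2]))
    offsets, values = sample_line(stack, center, normal, max_radius_um, step)
    return fwhm(offsets, values, baseline)
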