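"""Core image container for 3D two-photon stacks.

Arrays are ordered ``(z, y, x)``; all physical quantities are in µm.
Voxel centers sit at ``(index + 0.5) * voxel_size``, so a stack of shape
``(nz, ny, nx)`` spans ``nz*vz × ny*vy × nx*vx`` µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """A 3D scalar intensity volume with physical voxel sizes.

    Parameters
    ----------
    data :
        Intensity array of shape ``(nz, ny, nx)``, non-negative, arbitrary
        units.
    voxel_size_um :
        Physical voxel edge lengths ``(vz, vy, vx)`` in µm.
    channel_tag, timepoint_tag :
        Free-form labels carried through the pipeline (e.g. ``"tracer"``,
        ``"pre"``).
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 0.58, 0.58)
    channel_tag: str = ""
    timepoint_tag: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D (z,y,x) data, got shape {self.data.shape}")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError(f"voxel sizes must be three positive µm values, got {self.voxel_size_um}")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Voxel sizes as an array ``(vz, vy, vx)``."""
        return np.asarray(self.voxel_size_um, dtype=float)

    @property
    def extent_um(self) -> np.ndarray:
        """Physical size of the volume ``(z, y, x)`` in µm."""
        return self.spacing * np.asarray(self.shape)

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_um3(self) -> float:
        return float(np.prod(self.extent_um))

    def world_to_index(self, points_um: np.ndarray) -> np.ndarray:
        """Convert ``(..., 3)`` (z,y,x) µm coordinates to fractional voxel indices."""
        return np.asarray(points_um, dtype=float) / self.spacing - 0.5

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Convert voxel indices to (z,y,x) µm coordinates of voxel centers."""
        return (np.asarray(indices, dtype=float) + 0.5) * self.spacing

    def contains_point(self, point_um: np.ndarray) -> bool:
        p = np.asarray(point_um, dtype=float)
        return bool(np.all(p >= 0) and np.all(p <= self.extent_um))

    def same_grid(self, other: "ImageStack") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def copy_with(self, data: np.ndarray, **kwargs) -> "ImageStack":
        return replace(self, data=data, **kwargs)
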