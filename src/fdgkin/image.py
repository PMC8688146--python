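"""4-D dynamic image container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetic_model import FrameSchedule

__all__ = ["DynamicImage", "DEFAULT_VOXEL_DIMS"]

#: default voxel size in mm (x, y, z)
DEFAULT_VOXEL_DIMS = (0.4, 0.4, 0.8)


def _default_affine(voxel_dims) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_dims
    return aff


@dataclass
class DynamicImage:
    """Voxel × frame activity volume (kBq·ml⁻¹) with geometry and timing.

    ``data`` has shape (x, y, z, frame); the frame axis length must match the
    schedule.  ``affine`` maps voxel indices to mm world coordinates.
    """

    data: np.ndarray
    schedule: FrameSchedule
    voxel_dims: tuple[float, float, float] = DEFAULT_VOXEL_DIMS
    affine: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"dynamic image must be 4-D, got {self.data.ndim}-D")
        if self.data.shape[3] != len(self.schedule):
            raise ValueError(
                f"frame axis length {self.data.shape[3]} does not match "
                f"schedule with {len(self.schedule)} frames"
            )
        if any(v <= 0 for v in self.voxel_dims):
            raise ValueError("voxel dimensions must be positive")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_dims)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]
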