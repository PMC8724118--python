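"""Core in-memory containers for cubic micro-CT volumes.

Arrays are indexed ``(z, y, x)``, 0-based; ``z`` is the slice index and, for
vertebral specimens, the superior-inferior axis (normal to the endplates).
Voxels are isotropic; physical size is carried in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Allowed anatomic region tags (anterior-center, posterior-center/left/right).
REGIONS = ("ac", "pc", "pl", "pr")
#: Allowed lumbar vertebra level tags.
LEVELS = ("L1", "L2", "L3", "L4", "L5")


def _check_axes(shape: tuple[int, ...]) -> None:
    if len(shape) != 3:
        raise ValueError(f"volume must be 3-D, got shape {shape}")
    for ax, n in enumerate(shape):
        if n < 2:
            raise ValueError(f"axis {ax} has length {n}; every axis needs >= 2 voxels")


@dataclass
class GrayVolume:
    """A 3-D grayscale image stack with isotropic voxel size in micrometres."""

    data: np.ndarray
    voxel_size_um: float
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_axes(self.data.shape)
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class BinaryVolume:
    """A binarized bone/marrow volume: ``True`` = bone, ``False`` = marrow.

    Attributes
    ----------
    grid : ndarray of bool, shape (nz, ny, nx)
    voxel_size_um : float
        Isotropic voxel edge length in micrometres.
    label, region, level : optional sample metadata
        ``region`` tags the anatomic location in the vertebral body
        (``ac``/``pc``/``pl``/``pr``), ``level`` the lumbar vertebra (L1-L5).
    """

    grid: np.ndarray
    voxel_size_um: float
    label: Optional[str] = None
    region: Optional[str] = None
    level: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.dtype != bool:
            grid = grid.astype(bool)
        self.grid = grid
        _check_axes(grid.shape)
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")
        if self.region is not None and self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")
        if self.level is not None and self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size_mm**3

    @property
    def total_volume_mm3(self) -> float:
        """TV: total (bone + marrow) volume of the VOI in mm^3."""
        return self.grid.size * self.voxel_volume_mm3

    @property
    def bone_voxels(self) -> int:
        return int(np.count_nonzero(self.grid))

    def require_both_phases(self, op: str = "this operation") -> None:
        """Raise unless the volume contains bone *and* marrow voxels."""
        n = self.bone_voxels
        if n == 0:
            raise ValueError(f"{op} requires at least one bone (foreground) voxel")
        if n == self.grid.size:
            raise ValueError(f"{op} requires at least one marrow (background) voxel")

    def with_grid(self, grid: np.ndarray, **changes) -> "BinaryVolume":
        return replace(self, grid=grid, **changes)

    def complement(self) -> "BinaryVolume":
        """Swap bone and marrow phases (used for Tb.Sp. via phase duality)."""
        return self.with_grid(~self.grid)
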