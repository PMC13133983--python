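"""Cubic density volumes and MRC2014 I/O.

The pipeline's volume convention: cubic box, voxel values stored as a
``(nz, ny, nx)`` float32 array (``data[z, y, x]``), the helix axis along Z
through the box center.  On disk the volume is an MRC/CCP4 map whose fast
axis is X, so arrays are transposed at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = ["VolumeGrid", "read_mrc", "write_mrc"]


class VolumeFormatError(ValueError):
    """A volume violates the cubic-box contract."""


@dataclass
class VolumeGrid:
    """Cubic voxel grid with a physical voxel size in Å."""

    data: np.ndarray  # (nz, ny, nx), float32
    voxel_size: float  # Å
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise VolumeFormatError(f"expected 3D data, got {self.data.ndim}D")
        nz, ny, nx = self.data.shape
        if not (nz == ny == nx):
            raise VolumeFormatError(
                f"non-cubic volume {self.data.shape}; the pipeline assumes cubic boxes"
            )
        if not self.voxel_size > 0:
            raise VolumeFormatError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def box_size(self) -> int:
        """Edge length in voxels."""
        return self.data.shape[0]

    @property
    def box_size_A(self) -> float:
        """Edge length in Å."""
        return self.box_size * self.voxel_size

    @property
    def center(self) -> np.ndarray:
        """Box center in voxel coordinates (z, y, x order)."""
        return (np.array(self.data.shape, dtype=float) - 1.0) / 2.0

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.data.copy(), self.voxel_size, self.label)


def read_mrc(path) -> VolumeGrid:
    """Read a cubic MRC2014 volume; axis order normalized to (z, y, x)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ccp4 = gemmi.read_ccp4_map(str(path))
    ccp4.setup(float("nan"))  # normalize axis order to X fast, Z slow
    arr = np.array(ccp4.grid.array, dtype=np.float32)  # indexed [x, y, z]
    spacing = ccp4.grid.spacing
    if not np.allclose(spacing, spacing[0], rtol=1e-5):
        raise VolumeFormatError(f"anisotropic voxel size {spacing} in {path}")
    return VolumeGrid(arr.transpose(2, 1, 0), float(spacing[0]), label=str(path))


def write_mrc(volume: VolumeGrid, path) -> None:
    """Write a volume as an MRC/CCP4 map with its voxel size in the header."""
    ccp4 = gemmi.Ccp4Map()
    arr = np.ascontiguousarray(volume.data.transpose(2, 1, 0), dtype=np.float32)
    ccp4.grid = gemmi.FloatGrid(arr)
    n = volume.box_size
    edge = n * volume.voxel_size
    ccp4.grid.unit_cell = gemmi.UnitCell(edge, edge, edge, 90.0, 90.0, 90.0)
    ccp4.grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))
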