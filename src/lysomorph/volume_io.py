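"""Labeled segmentation volume I/O and per-object slice decomposition.

Volumes are handled in ``(z, y, x)`` axis order (tomography convention:
slice-by-slice processing runs along z). Coordinates are 0-based with pixel
centers at integer positions. Label 0 is background; every positive label is
an independent object (one segmented membrane).

Physical units: voxel sizes are stored in nanometres. MRC headers carry the
cell in Angstrom, so the reader divides by 10 and the writer multiplies back.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gemmi
import numpy as np


class VolumeFormatError(ValueError):
    """Raised when a file does not satisfy the labeled-volume contract."""


@dataclass
class LabeledVolume:
    """Integer-labeled 3D voxel grid with physical voxel size.

    Attributes
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Non-negative integer labels, 0 = background.
    voxel_size : ndarray, shape (3,)
        Physical edge length per axis (z, y, x) in nm; all entries > 0.
    """

    voxels: np.ndarray
    voxel_size: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D volume, got {self.voxels.ndim} dimensions"
            )
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise VolumeFormatError("voxel labels must be integers")
        if self.voxels.size and self.voxels.min() < 0:
            raise VolumeFormatError("voxel labels must be non-negative")
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        if not np.all(self.voxel_size > 0):
            raise VolumeFormatError("all voxel_size entries must be > 0")

    @property
    def labels(self) -> set[int]:
        """Positive object identifiers present in the volume."""
        u = np.unique(self.voxels)
        return {int(v) for v in u if v > 0}

    @property
    def in_plane_voxel_nm(self) -> float:
        """In-plane (y/x) pixel size in nm; assumed isotropic in-plane."""
        return float(self.voxel_size[1])


@dataclass
class SliceStack:
    """Per-slice binary masks of one labeled object.

    ``z_extent`` is the inclusive span from first to last occupied z-index,
    so gaps (slices without object voxels) count toward the extent but do not
    appear in ``slices``.
    """

    object_label: int
    slices: list[tuple[int, np.ndarray]]
    z_extent: int

    def __post_init__(self) -> None:
        zs = [z for z, _ in self.slices]
        if zs != sorted(zs) or len(set(zs)) != len(zs):
            raise ValueError("z indices must be strictly increasing")
        if self.z_extent < len(self.slices):
            raise ValueError("z_extent must be >= number of occupied slices")

    @property
    def total_foreground(self) -> int:
        return int(sum(m.sum() for _, m in self.slices))


def read_labeled_volume(path: str | os.PathLike) -> LabeledVolume:
    """Read a labeled segmentation volume from an MRC2014 file.

    Data modes 0/1/2/6 are accepted; values are safe-cast to integers.
    Axis order is normalized to (z, y, x) and voxel size taken from the
    header (Angstrom, converted to nm).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ccp4 = gemmi.read_ccp4_map(path)
    ccp4.setup(0.0)  # reorder axes to x, y, z and fill missing voxels
    arr = np.array(ccp4.grid.array)  # (x, y, z)
    if arr.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3D data, got shape {arr.shape}")
    rounded = np.rint(arr)
    if not np.allclose(arr, rounded, atol=1e-3):
        raise VolumeFormatError(
            f"{path}: voxel values are not integers after safe cast"
        )
    voxels = rounded.astype(np.int32).T  # -> (z, y, x)
    sp = ccp4.grid.spacing  # Angstrom, (x, y, z)
    voxel_size = np.array([sp[2], sp[1], sp[0]], dtype=float) / 10.0
    return LabeledVolume(
        voxels=voxels,
        voxel_size=voxel_size,
        metadata={"source": path, "in_plane_isotropy_assumed": True},
    )


def write_labeled_volume(vol: LabeledVolume, path: str | os.PathLike) -> None:
    """Write a labeled volume as an MRC2014 map (mode 2, float values)."""
    nz, ny, nx = vol.voxels.shape
    grid = gemmi.FloatGrid(np.ascontiguousarray(vol.voxels.T, dtype=np.float32))
    sz, sy, sx = vol.voxel_size * 10.0  # nm -> Angstrom
    grid.unit_cell = gemmi.UnitCell(nx * sx, ny * sy, nz * sz, 90.0, 90.0, 90.0)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(os.fspath(path))


def extract_object_slices(vol: LabeledVolume, label: int) -> SliceStack:
    """Decompose one labeled object into per-z-slice binary masks.

    Raises
    ------
    KeyError
        If ``label`` does not occur in the volume.
    """
    label = int(label)
    occupied = np.flatnonzero((vol.voxels == label).any(axis=(1, 2)))
    if occupied.size == 0:
        raise KeyError(f"label {label} not present in volume")
    slices = [(int(z), vol.voxels[z] == label) for z in occupied]
    z_extent = int(occupied[-1] - occupied[0] + 1)
    return SliceStack(object_label=label, slices=slices, z_extent=z_extent)
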