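"""Volume-of-interest handling: image/mask loading and tumour volume.

The tumour volume of interest (VOI) is a binary mask drawn over a 3-D MR
intensity volume (one per sequence, e.g. T2WI or CE-T1WI).  Masks may be
supplied as one 3-D NIfTI file or as a stack of per-slice 2-D masks, which
emulates slice-by-slice free-hand ROI drawing assembled into a 3-D
segmentation.  All geometry lives in voxel-index space: the image and the
mask must share grid shape and physical spacing; no resampling is done.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelVolume",
    "TumourVOI",
    "AlignmentError",
    "EmptyVOIError",
    "load_pair",
    "stack_slice_masks",
    "make_voi",
    "tumour_volume_cm3",
]

SEQUENCE_ROLES = ("T2WI", "CE-T1WI")


class AlignmentError(ValueError):
    """Image and mask do not share grid shape and/or voxel spacing."""


class EmptyVOIError(ValueError):
    """The binarized mask contains no voxels."""


@dataclass(frozen=True)
class VoxelVolume:
    """A 3-D scalar intensity grid with physical voxel spacing in mm."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    sequence_role: str = "CE-T1WI"

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 3 or grid.size < 1:
            raise ValueError("intensity grid must be a non-empty 3-D array")
        if not np.all(np.isfinite(grid)):
            raise ValueError("intensity grid contains non-finite values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "spacing", spacing)

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass(frozen=True)
class TumourVOI:
    """Binary tumour mask aligned to a :class:`VoxelVolume` grid.

    ``intensities`` is the multiset of image values inside the mask, in a
    fixed (C-order) traversal so downstream statistics are reproducible.
    """

    mask: np.ndarray
    intensities: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        intens = np.asarray(self.intensities, dtype=float)
        if mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        n = int(mask.sum())
        if n < 1:
            raise EmptyVOIError("mask selects no voxels")
        if intens.shape != (n,):
            raise ValueError("intensities length must equal the mask voxel count")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "intensities", intens)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def make_voi(volume: VoxelVolume, mask: np.ndarray) -> TumourVOI:
    """Binarize ``mask`` (any non-zero voxel is inside) against ``volume``."""
    mask = np.asarray(mask)
    if mask.shape != volume.grid.shape:
        raise AlignmentError(
            f"mask shape {mask.shape} does not match image shape {volume.grid.shape}"
        )
    binary = mask != 0
    if not binary.any():
        raise EmptyVOIError("mask is empty after binarization")
    return TumourVOI(mask=binary, intensities=volume.grid[binary])


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.squeeze(data), zooms


def stack_slice_masks(slice_paths: Sequence[str | Path]) -> np.ndarray:
    """Stack per-slice 2-D mask files (in order) along the last axis.

    Mirrors slice-wise ROI drawing: each file holds one axial slice; the
    stacked array is the 3-D segmentation.
    """
    slices = []
    for p in slice_paths:
        data, _ = _load_nifti(p)
        if data.ndim != 2:
            raise AlignmentError(f"per-slice mask {p} is not 2-D (shape {data.shape})")
        slices.append(data != 0)
    if not slices:
        raise ValueError("no slice masks given")
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise AlignmentError(f"slice masks disagree in shape: {sorted(shapes)}")
    return np.stack(slices, axis=-1)


def load_pair(
    image_path: str | Path,
    mask_path: str | Path | Sequence[str | Path],
    sequence_role: str = "CE-T1WI",
    *,
    spacing_atol: float = 1e-3,
) -> tuple[VoxelVolume, TumourVOI]:
    """Load an image + mask NIfTI pair and assemble the tumour VOI.

    Parameters
    ----------
    image_path:
        NIfTI intensity volume.
    mask_path:
        Either one 3-D NIfTI mask, or a sequence of per-slice 2-D NIfTI
        masks to be stacked along the slice axis.
    sequence_role:
        Label for the MR sequence the image represents ("T2WI" or
        "CE-T1WI").

    Raises
    ------
    AlignmentError
        If grid shapes or voxel spacings disagree (spacing compared to
        ``spacing_atol`` mm).
    EmptyVOIError
        If the binarized mask selects no voxels.
    """
    grid, spacing = _load_nifti(image_path)
    if isinstance(mask_path, (str, Path)):
        mask, mask_spacing = _load_nifti(mask_path)
        if not np.allclose(mask_spacing, spacing, atol=spacing_atol):
            raise AlignmentError(
                f"mask spacing {mask_spacing} != image spacing {spacing}"
            )
    else:
        mask = stack_slice_masks(mask_path)
    volume = VoxelVolume(grid=grid, spacing=spacing, sequence_role=sequence_role)
    return volume, make_voi(volume, mask)


def tumour_volume_cm3(voi: TumourVOI, spacing: Sequence[float]) -> float:
    """Tumour volume in cm^3: voxel count x voxel volume (mm^3) / 1000."""
    dx, dy, dz = (float(s) for s in spacing)
    if min(dx, dy, dz) <= 0:
        raise ValueError("spacing components must be positive")
    return voi.voxel_count * dx * dy * dz / 1000.0
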