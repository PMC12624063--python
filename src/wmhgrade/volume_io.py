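"""NIfTI label-volume I/O and per-subject mask bundling.

Every image in the pipeline is a binary 3D label map on a common voxel grid
with anisotropic millimetre spacing (thick axial slices, fine in-plane
resolution).  This module reads and writes those maps, validates that the
three masks of a subject (brain, lateral ventricles, WMH) share one grid,
and exposes the voxel geometry everything downstream depends on.

No reorientation or resampling is performed: all operations run in the
stored voxel space, and only the axial-axis index and the spacing carry the
anatomy-facing geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "LabelVolume",
    "MaskBundle",
    "AlignmentError",
    "MetadataError",
    "DimensionalityError",
    "ValidationError",
    "read_label_volume",
    "write_label_volume",
    "write_combined_labels",
    "assemble_bundle",
    "voxel_volume_ml",
]

#: voxel values in a combined PVH/DWMH label map
PVH_LABEL = 1
DWMH_LABEL = 2


class MetadataError(ValueError):
    """Image header carries unusable geometry (e.g. non-positive spacing)."""


class DimensionalityError(ValueError):
    """Image is not a single 3D volume."""


class AlignmentError(ValueError):
    """Masks of one subject do not share shape/spacing."""


class ValidationError(ValueError):
    """Semantically invalid input (empty brain mask, negative ratio, ...)."""


@dataclass(frozen=True)
class LabelVolume:
    """A binary 3D label map with millimetre voxel spacing.

    Parameters
    ----------
    voxels : ndarray of bool, shape (nx, ny, nz)
        Foreground/background labels.
    spacing : tuple of float
        Voxel edge lengths in mm, ordered like the array axes.
    axial_axis : int
        Index of the slice axis.  Clinical FLAIR in this regime has 5-6 mm
        slices against sub-millimetre in-plane pixels, so by default the
        axis with the largest spacing is taken as axial.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    axial_axis: int = 2

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3 or min(vox.shape) < 1:
            raise DimensionalityError(
                f"label volume must be 3D with positive dimensions, got shape {vox.shape}"
            )
        if vox.dtype != bool:
            uniq = np.unique(vox)
            if not np.isin(uniq, (0, 1)).all():
                raise ValidationError(f"label values must be binary, found {uniq[:10]}")
            vox = vox.astype(bool)
        object.__setattr__(self, "voxels", vox)
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise MetadataError(f"spacing must be three positive mm lengths, got {sp}")
        object.__setattr__(self, "spacing", sp)
        if self.axial_axis not in (0, 1, 2):
            raise ValidationError(f"axial_axis must be 0, 1 or 2, got {self.axial_axis}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.voxels.sum())

    def replace_voxels(self, voxels: np.ndarray) -> "LabelVolume":
        """New volume on the same grid with different labels."""
        return LabelVolume(voxels, self.spacing, self.axial_axis)


@dataclass(frozen=True)
class MaskBundle:
    """The three co-registered masks of one subject."""

    brain: LabelVolume
    ventricles: LabelVolume
    wmh: LabelVolume
    subject_id: str = "subject"


def read_label_volume(
    path: str | Path,
    threshold: float = 0.5,
    axial_axis: int | None = None,
) -> LabelVolume:
    """Read a NIfTI file and binarize it into a :class:`LabelVolume`.

    Voxels strictly greater than ``threshold`` become foreground, so
    probabilistic masks binarize at 0.5 by default and already-binary maps
    pass through unchanged.  Spacing is taken from the header; the axial
    axis defaults to the axis of maximum spacing unless overridden.
    """
    img = nib.load(str(path))
    if img.ndim != 3:
        # tolerate trailing singleton dims some exporters add
        if img.ndim == 4 and img.shape[3] == 1:
            img = nib.funcs.squeeze_image(img)
        else:
            raise DimensionalityError(
                f"{path}: expected a 3D volume, got shape {img.shape}"
            )
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise MetadataError(f"{path}: non-positive voxel spacing in header: {zooms}")
    data = np.asanyarray(img.dataobj)
    axial = int(np.argmax(zooms)) if axial_axis is None else int(axial_axis)
    return LabelVolume(data > threshold, zooms, axial)


def write_label_volume(vol: LabelVolume, path: str | Path) -> None:
    """Write a binary volume as uint8 NIfTI with spacing in the affine."""
    affine = np.diag((*vol.spacing, 1.0))
    img = nib.Nifti1Image(vol.voxels.astype(np.uint8), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_combined_labels(pvh: LabelVolume, dwmh: LabelVolume, path: str | Path) -> None:
    """Write one label map with PVH=1 and DWMH=2 (masks must be disjoint)."""
    if (pvh.voxels & dwmh.voxels).any():
        raise ValidationError("PVH and DWMH masks overlap; cannot write combined labels")
    combined = np.zeros(pvh.shape, dtype=np.uint8)
    combined[pvh.voxels] = PVH_LABEL
    combined[dwmh.voxels] = DWMH_LABEL
    affine = np.diag((*pvh.spacing, 1.0))
    img = nib.Nifti1Image(combined, affine)
    img.header.set_zooms(pvh.spacing)
    nib.save(img, str(path))


def assemble_bundle(
    brain: LabelVolume,
    ventricles: LabelVolume,
    wmh: LabelVolume,
    subject_id: str = "subject",
    spacing_tol_mm: float = 1e-4,
) -> MaskBundle:
    """Validate grid agreement of a subject's masks and bundle them.

    Shapes must match exactly and spacings within ``spacing_tol_mm``.
    Ventricle voxels outside the brain mask only raise a warning: brain
    segmentations are routinely a little tight around the ventricles.
    """
    named = {"ventricles": ventricles, "wmh": wmh}
    for name, vol in named.items():
        if vol.shape != brain.shape:
            raise AlignmentError(
                f"{name} shape {vol.shape} does not match brain shape {brain.shape}"
            )
        if any(
            abs(a - b) > spacing_tol_mm for a, b in zip(vol.spacing, brain.spacing)
        ):
            raise AlignmentError(
                f"{name} spacing {vol.spacing} does not match brain spacing {brain.spacing}"
            )
    if brain.count() == 0:
        raise ValidationError(f"{subject_id}: brain mask is empty")
    if (ventricles.voxels & ~brain.voxels).any():
        warnings.warn(
            f"{subject_id}: ventricle mask extends outside the brain mask",
            stacklevel=2,
        )
    return MaskBundle(brain=brain, ventricles=ventricles, wmh=wmh, subject_id=subject_id)


def voxel_volume_ml(vol: LabelVolume) -> float:
    """Volume of one voxel in millilitres (product of spacings / 1000)."""
    return float(np.prod(vol.spacing)) / 1000.0
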