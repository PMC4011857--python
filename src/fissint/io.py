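"""Volume and mesh I/O.

NIfTI (.nii/.nii.gz) is read through nibabel and reoriented to the
closest canonical (RAS) axes on load; MetaImage (.mha/.mhd) through
SimpleITK with the array transposed to (x, y, z) order.  Only the
voxel spacing and origin of the affine are preserved — oblique
acquisitions are not resampled.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .volume import ImageVolume

logger = logging.getLogger(__name__)

NIFTI_SUFFIXES = (".nii", ".nii.gz")
META_SUFFIXES = (".mha", ".mhd")


class VolumeIOError(IOError):
    """Raised for unreadable/unwritable volume files."""


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def read_volume(path) -> ImageVolume:
    """Read a NIfTI or MetaImage volume as an :class:`ImageVolume`."""
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such volume: {path}")
    suffix = _suffix(path)
    if suffix in NIFTI_SUFFIXES:
        import nibabel as nib

        img = nib.as_closest_canonical(nib.load(str(path)))
        data = np.asarray(img.get_fdata(), dtype=np.float32)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return ImageVolume(data, spacing, origin)
    if suffix in META_SUFFIXES:
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float32)
        return ImageVolume(data, tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    raise VolumeIOError(f"unsupported volume format: {path.name}")


def write_volume(volume_or_array, path, spacing=None, origin=None) -> None:
    """Write an :class:`ImageVolume` (or raw array + spacing) to disk."""
    path = Path(path)
    if isinstance(volume_or_array, ImageVolume):
        data, spacing, origin = (
            volume_or_array.data,
            volume_or_array.spacing,
            volume_or_array.origin,
        )
    else:
        data = np.asarray(volume_or_array)
        if spacing is None:
            raise VolumeIOError("spacing required when writing a bare array")
        origin = origin or (0.0, 0.0, 0.0)
    suffix = _suffix(path)
    if suffix in NIFTI_SUFFIXES:
        import nibabel as nib

        affine = np.diag(list(spacing) + [1.0])
        affine[:3, 3] = origin
        nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
        return
    if suffix in META_SUFFIXES:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(np.asarray(data).transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in spacing))
        img.SetOrigin(tuple(float(o) for o in origin))
        sitk.WriteImage(img, str(path))
        return
    raise VolumeIOError(f"unsupported volume format: {path.name}")


def read_mask(path) -> tuple[np.ndarray, tuple]:
    """Read a label/mask volume; returns (integer array, spacing)."""
    vol = read_volume(path)
    return np.round(vol.data).astype(np.int16), vol.spacing


def write_mesh(boundary, path) -> None:
    """Export a completed boundary as PLY or STL via trimesh."""
    boundary.to_trimesh().export(str(path))
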