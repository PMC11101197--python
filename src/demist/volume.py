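"""Voxel-volume container and file I/O.

The package's in-memory unit is a 3-D grid of real values on a physical
voxel lattice.  Reconstructed short-axis myocardial-perfusion volumes are
48 x 48 x 48 by convention (rows, cols, slices), but any shape is accepted.
Volumes round-trip through NIfTI (voxel size in the affine) and through a
flat HDF5 layout that can also carry a left-ventricle wall mask and a
centroid alongside the values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import nibabel as nib
import numpy as np

__all__ = [
    "VoxelVolume",
    "save_volume_h5",
    "load_volume_h5",
    "save_volume_nifti",
    "load_volume_nifti",
    "save_sinogram_h5",
    "load_sinogram_h5",
]

DEFAULT_VOXEL_MM = 4.42  # typical zoomed MPI pixel, isotropic


@dataclass
class VoxelVolume:
    """A 3-D grid of real values with a physical voxel size.

    Parameters
    ----------
    values : ndarray of shape (rows, cols, slices)
        Finite real values; activity volumes must be nonnegative.
    voxel_size_mm : tuple of 3 floats
        Physical edge length of a voxel along each axis, in mm.
    """

    values: np.ndarray
    voxel_size_mm: tuple = field(default=(DEFAULT_VOXEL_MM,) * 3)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        vs = np.asarray(self.voxel_size_mm, dtype=float).ravel()
        if vs.size == 1:
            vs = np.repeat(vs, 3)
        if vs.size != 3 or np.any(vs <= 0):
            raise ValueError("voxel_size_mm must be 3 positive reals")
        self.voxel_size_mm = tuple(vs)

    @property
    def shape(self):
        return self.values.shape

    @property
    def voxel_size_cm(self):
        return tuple(v / 10.0 for v in self.voxel_size_mm)

    def copy(self):
        return VoxelVolume(self.values.copy(), self.voxel_size_mm)

    def with_values(self, values):
        return VoxelVolume(np.asarray(values), self.voxel_size_mm)


def save_volume_h5(path, vol, *, mask=None, centroid=None):
    """Write a volume (and optionally an LV mask / centroid) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=vol.values)
        f.create_dataset("voxel_size_mm", data=np.asarray(vol.voxel_size_mm))
        if mask is not None:
            f.create_dataset("mask", data=np.asarray(mask, dtype=np.uint8))
        if centroid is not None:
            f.create_dataset("centroid", data=np.asarray(centroid, dtype=float))


def load_volume_h5(path):
    """Read a volume written by :func:`save_volume_h5`.

    Returns (volume, mask or None, centroid or None).
    """
    with h5py.File(path, "r") as f:
        vol = VoxelVolume(f["values"][()], tuple(f["voxel_size_mm"][()]))
        mask = f["mask"][()].astype(bool) if "mask" in f else None
        centroid = tuple(f["centroid"][()]) if "centroid" in f else None
    return vol, mask, centroid


def save_volume_nifti(path, vol):
    affine = np.diag(list(vol.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), affine), str(path))


def load_volume_nifti(path):
    img = nib.load(str(path))
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelVolume(np.asarray(img.dataobj, dtype=np.float64), vs)


def save_case_h5(path, lowdose, centroid, label, normaldose=None):
    """Write one study case: low-dose volume, defect centroid, label and
    (for training pairs) the normal-dose target."""
    with h5py.File(path, "w") as f:
        f.create_dataset("lowdose", data=lowdose.values)
        f.create_dataset("voxel_size_mm", data=np.asarray(lowdose.voxel_size_mm))
        f.create_dataset("centroid", data=np.asarray(centroid, dtype=float))
        f.attrs["label"] = int(label)
        if normaldose is not None:
            f.create_dataset("normaldose", data=normaldose.values)


def load_case_h5(path):
    """Read a case written by :func:`save_case_h5`.

    Returns (lowdose, normaldose or None, centroid, label).
    """
    with h5py.File(path, "r") as f:
        vs = tuple(f["voxel_size_mm"][()])
        low = VoxelVolume(f["lowdose"][()], vs)
        nd = VoxelVolume(f["normaldose"][()], vs) if "normaldose" in f else None
        centroid = tuple(f["centroid"][()])
        label = int(f.attrs["label"])
    return low, nd, centroid, label


def save_sinogram_h5(path, counts, meta=None):
    """Write projection-domain data; `meta` is a flat dict of scalars."""
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=np.asarray(counts))
        if meta:
            for k, v in meta.items():
                f.attrs[k] = v


def load_sinogram_h5(path):
    with h5py.File(path, "r") as f:
        counts = f["counts"][()]
        meta = dict(f.attrs)
    return counts, meta
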