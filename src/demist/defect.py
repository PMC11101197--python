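"""Cone-region perfusion defects and hybrid defect-present data generation.

A perfusion defect is a cold (reduced-uptake) region of the LV wall,
parameterised by wall location (anterior/inferior), angular extent theta,
severity (fraction of the mean LV uptake removed), and axial length.  The
defect mask is the set of wall voxels whose in-plane polar angle about the
LV centroid falls in a wedge: [80 - theta, 80] degrees for anterior defects
and [-80, -80 + theta] degrees for inferior defects, with the x-axis along
the image rows and angles measured counterclockwise (anterior = upper wall).
The same wedge is replicated across the slices spanning the axial length,
centred on the centroid slice.

Defect-present projection data retain the measured noise of the source
defect-absent acquisition: noise-free projections of the defect-absent and
defect-present phantoms give a per-bin scale factor in [0, 1], and the
measured counts are thinned bin-wise by that factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .phantom import SinogramCounts
from .volume import DEFAULT_VOXEL_MM

STUDY_EXTENTS_DEG = (30.0, 60.0)
STUDY_TEST_ONLY_EXTENT_DEG = 45.0
STUDY_SEVERITIES = (0.10, 0.175, 0.25)
STUDY_LOCATIONS = ("anterior", "inferior")

__all__ = [
    "DefectSpec",
    "cone_mask",
    "insert_defect",
    "projection_scale_factor",
    "apply_scale",
    "STUDY_EXTENTS_DEG",
    "STUDY_SEVERITIES",
    "STUDY_LOCATIONS",
    "STUDY_TEST_ONLY_EXTENT_DEG",
]


@dataclass(frozen=True)
class DefectSpec:
    """Angular extent (deg), severity (fraction of mean LV uptake), wall
    location, and axial length (mm) of a perfusion defect."""

    location: str = "anterior"
    extent_deg: float = 60.0
    severity: float = 0.25
    axial_length_mm: float = 42.0

    def __post_init__(self):
        if self.location not in ("anterior", "inferior"):
            raise ValueError("location must be 'anterior' or 'inferior'")
        if not 0 <= self.extent_deg <= 160:
            raise ValueError("extent must lie in [0, 160] degrees")
        if not 0 < self.severity < 1:
            raise ValueError("severity must lie in (0, 1)")


def wedge_bounds_deg(spec):
    """Closed polar-angle interval [lo, hi] of the defect wedge, degrees."""
    if spec.location == "anterior":
        return 80.0 - spec.extent_deg, 80.0
    return -80.0, -80.0 + spec.extent_deg


def cone_mask(lv_mask, lv_centroid, spec, voxel_size_mm=DEFAULT_VOXEL_MM):
    """Binary defect mask: wall voxels inside the wedge, across the axial span.

    Parameters
    ----------
    lv_mask : 3-D bool array (nonempty)
    lv_centroid : (row, col, slice) floats — origin of the polar angle
    spec : DefectSpec
    voxel_size_mm : float, used to convert the axial length to slices

    Returns
    -------
    3-D bool array.  A wedge that intersects no wall voxel yields an empty
    mask with a warning.
    """
    lv_mask = np.asarray(lv_mask, dtype=bool)
    if not lv_mask.any():
        raise ValueError("empty LV mask")
    r0, c0, z0 = (float(x) for x in lv_centroid)
    nr, nc, nz = lv_mask.shape
    if not (0 <= r0 < nr and 0 <= c0 < nc and 0 <= z0 < nz):
        raise ValueError("centroid outside grid")
    if spec.extent_deg == 0:
        return np.zeros_like(lv_mask)

    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    # x along rows, y up (row index increases downward): anterior = upper wall
    angle = np.degrees(np.arctan2(-(rr - r0), cc - c0))
    lo, hi = wedge_bounds_deg(spec)
    wedge = (angle >= lo) & (angle <= hi)

    half_mm = spec.axial_length_mm / 2.0
    z_center = int(round(z0))
    mask = np.zeros_like(lv_mask)
    for z in range(nz):
        if abs(z - z_center) * voxel_size_mm <= half_mm:
            mask[:, :, z] = wedge & lv_mask[:, :, z]
    if not mask.any():
        warnings.warn("defect wedge intersects no LV-wall voxels", stacklevel=2)
    return mask


def insert_defect(activity, mask, severity, lv_mask):
    """Subtract a severity-scaled cold signal inside the defect mask.

    Output equals ``activity - severity * mean(activity over lv_mask)`` on
    mask voxels (clipped at 0), and is unchanged elsewhere.
    """
    if not 0 < severity < 1:
        raise ValueError("severity must lie in (0, 1)")
    mask = np.asarray(mask, dtype=bool)
    lv_mask = np.asarray(lv_mask, dtype=bool)
    if np.any(mask & ~lv_mask):
        raise ValueError("defect mask must be a subset of the LV mask")
    mean_uptake = float(activity.values[lv_mask].mean())
    out = activity.values.copy()
    out[mask] = np.clip(out[mask] - severity * mean_uptake, 0.0, None)
    return activity.with_values(out)


def projection_scale_factor(proj_absent, proj_present, epsilon=None):
    """Bin-wise ratio present/absent of noise-free projections, in [0, 1]."""
    pa = np.asarray(proj_absent, dtype=float)
    pp = np.asarray(proj_present, dtype=float)
    if pa.shape != pp.shape:
        raise ValueError("projection shapes differ")
    if epsilon is None:
        epsilon = 1e-8 * float(pa.max(initial=0.0))
    return np.clip(pp / (pa + epsilon), 0.0, 1.0)


def apply_scale(counts, scale, seed):
    """Thin measured counts bin-wise by a local scale factor in [0, 1].

    Per-bin binomial thinning keeps the counts integer-valued and preserves
    the clinical-like noise of the source acquisition; note that, as with
    any scaling of measured data, exact Poisson statistics are not
    guaranteed in the scaled output.
    """
    scale = np.asarray(scale, dtype=float)
    if scale.min() < 0 or scale.max() > 1:
        raise ValueError("scale factors must lie in [0, 1]")
    wrap = isinstance(counts, SinogramCounts)
    arr = counts.counts if wrap else np.asarray(counts)
    if arr.shape != scale.shape:
        raise ValueError("counts and scale shapes differ")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = rng.binomial(arr, scale).astype(arr.dtype)
    if wrap:
        return SinogramCounts(out, counts.system, counts.voxel_size_mm)
    return out
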