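"""Synthetic left-ventricle phantoms and a desk-scale SPECT simulation chain.

This module stands in for a clinical myocardial-perfusion SPECT data chain:
an annular LV-wall phantom with anatomical jitter, a slice-parallel 2-D
parallel-beam projector (linear, nonnegativity-preserving, no attenuation or
scatter), Poisson count sampling, OSEM reconstruction, 3-D Butterworth
post-filtering, and windowing of the dynamic range to the LV-wall maximum.

The projector is realised as an explicit sparse matrix per view geometry, so
forward and back projection are exact adjoints and the Poisson log-likelihood
of MLEM is provably non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.ndimage import center_of_mass, gaussian_filter1d

from .volume import DEFAULT_VOXEL_MM, VoxelVolume

__all__ = [
    "LVPhantomSpec",
    "SystemModel",
    "SinogramCounts",
    "generate_lv_phantom",
    "forward_project",
    "sample_poisson",
    "osem_reconstruct",
    "poisson_log_likelihood",
    "butterworth_filter_3d",
    "window_to_lv_max",
]


@dataclass
class LVPhantomSpec:
    """Geometry and uptake of a synthetic LV phantom.

    The LV wall is an annulus (hollow cylinder) of elevated tracer uptake on
    a soft-tissue background confined to a cylindrical body.  Per-study
    anatomical variability is emulated by seeded jitter of the wall radii,
    the in-plane centre, and the uptake level.

    Units are mm for lengths and arbitrary activity units for uptake.
    """

    lv_center_voxel: tuple | None = None  # None -> grid centre
    wall_inner_radius_mm: float = 24.0
    wall_outer_radius_mm: float = 34.0
    wall_axial_extent_mm: float = 66.0
    lv_uptake: float = 100.0
    background_uptake: float = 10.0
    body_radius_mm: float = 100.0
    jitter_radius_mm: float = 0.0
    jitter_center_mm: float = 0.0
    jitter_uptake_frac: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.wall_inner_radius_mm < self.wall_outer_radius_mm:
            raise ValueError("inner radius must be smaller than outer radius")
        if not 0 <= self.background_uptake < self.lv_uptake:
            raise ValueError("need 0 <= background_uptake < lv_uptake (contrast > 1)")


def generate_lv_phantom(spec, grid_shape=(48, 48, 48), voxel_size_mm=DEFAULT_VOXEL_MM):
    """Generate a seeded LV phantom.

    Returns
    -------
    activity : VoxelVolume
        ``lv_uptake`` on the wall, ``background_uptake`` inside the body
        cylinder, zero outside; with seeded anatomical jitter.
    lv_mask : ndarray of bool
        The annular wall region.
    centroid : tuple of float
        Centre of mass of the wall mask (row, col, slice), voxel units.
    """
    rng = np.random.default_rng(spec.seed)
    vs = float(voxel_size_mm)
    nr, nc, nz = grid_shape
    if spec.lv_center_voxel is None:
        center = ((nr - 1) / 2.0, (nc - 1) / 2.0, (nz - 1) / 2.0)
    else:
        center = tuple(float(x) for x in spec.lv_center_voxel)

    # jitter shifts the wall midline (heart size), preserving wall thickness
    dr = rng.normal() * spec.jitter_radius_mm
    r_in = spec.wall_inner_radius_mm + dr
    r_out = spec.wall_outer_radius_mm + dr
    if not 0 < r_in < r_out:
        raise ValueError("jittered radii degenerate; reduce jitter_radius_mm")
    uptake = spec.lv_uptake * (1.0 + rng.normal() * spec.jitter_uptake_frac)
    cr = center[0] + rng.normal() * spec.jitter_center_mm / vs
    cc = center[1] + rng.normal() * spec.jitter_center_mm / vs
    cz = center[2]

    half_grid_mm = vs * min(nr, nc) / 2.0
    if r_out + max(abs(cr - (nr - 1) / 2), abs(cc - (nc - 1) / 2)) * vs > half_grid_mm:
        raise ValueError("LV wall does not fit inside the grid")

    rr, cc_idx, zz = np.meshgrid(
        np.arange(nr), np.arange(nc), np.arange(nz), indexing="ij"
    )
    rho = np.hypot((rr - cr) * vs, (cc_idx - cc) * vs)
    axial = np.abs(zz - cz) * vs
    lv_mask = (rho >= r_in) & (rho <= r_out) & (axial <= spec.wall_axial_extent_mm / 2)

    rho_body = np.hypot((rr - (nr - 1) / 2) * vs, (cc_idx - (nc - 1) / 2) * vs)
    body = rho_body <= spec.body_radius_mm

    values = np.where(body, spec.background_uptake, 0.0)
    values[lv_mask] = uptake
    centroid = tuple(center_of_mass(lv_mask))
    return VoxelVolume(values, (vs, vs, vs)), lv_mask, centroid


# ---------------------------------------------------------------------------
# System model: slice-parallel 2-D parallel-beam projector
# ---------------------------------------------------------------------------


@dataclass
class SystemModel:
    """Idealised parallel-beam SPECT system operator.

    ``sensitivity`` is the expected number of detected counts per unit of
    total activity, summed over the whole sinogram; each view contributes
    ``sensitivity / n_angles``.  The default (0.3) makes a wall voxel at the
    default uptake of 100 contribute ~30 expected counts to the sinogram,
    i.e. a few hundred thousand total counts per study — a clinically
    realistic normal-dose level at which 6.25% thinning visibly degrades
    defect detectability.
    """

    n_angles: int = 64
    angular_range_deg: float = 180.0
    n_bins: int = 48
    blur_fwhm_mm: float = 0.0
    sensitivity: float = 0.3

    def __post_init__(self):
        if self.n_angles < 1 or self.n_bins < 1:
            raise ValueError("n_angles and n_bins must be positive")
        self._matrix_cache = {}

    def angles_rad(self):
        return np.deg2rad(
            np.arange(self.n_angles) * self.angular_range_deg / self.n_angles
        )

    def matrix(self, grid_side):
        """Sparse (n_angles*n_bins, grid_side**2) projection matrix.

        Line integrals over in-plane voxels with linear detector-bin
        splitting; scaled by sensitivity / n_angles.
        """
        key = int(grid_side)
        if key in self._matrix_cache:
            return self._matrix_cache[key]
        n = key
        half = (n - 1) / 2.0
        bhalf = (self.n_bins - 1) / 2.0
        cols_v, rows_v = np.meshgrid(np.arange(n) - half, np.arange(n) - half)
        x = cols_v.ravel()
        y = rows_v.ravel()
        rows_idx, cols_idx, weights = [], [], []
        scale = self.sensitivity / self.n_angles
        for k, phi in enumerate(self.angles_rad()):
            t = x * np.cos(phi) + y * np.sin(phi) + bhalf
            b0 = np.floor(t).astype(int)
            w1 = t - b0
            for b, w in ((b0, 1.0 - w1), (b0 + 1, w1)):
                ok = (b >= 0) & (b < self.n_bins) & (w > 0)
                rows_idx.append(k * self.n_bins + b[ok])
                cols_idx.append(np.flatnonzero(ok))
                weights.append(w[ok] * scale)
        A = sparse.csr_matrix(
            (np.concatenate(weights), (np.concatenate(rows_idx), np.concatenate(cols_idx))),
            shape=(self.n_angles * self.n_bins, n * n),
        )
        self._matrix_cache[key] = A
        return A

    def blur_sigma_bins(self, voxel_size_mm):
        if self.blur_fwhm_mm <= 0:
            return 0.0
        return self.blur_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm


@dataclass
class SinogramCounts:
    """Integer projection-domain count data, (angle, bin, slice)."""

    counts: np.ndarray
    system: SystemModel | None = None
    voxel_size_mm: float = DEFAULT_VOXEL_MM

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise TypeError("counts must be integer-valued")
        if self.counts.min(initial=0) < 0:
            raise ValueError("counts must be nonnegative")


def _apply_blur(sino, sigma_bins):
    if sigma_bins <= 0:
        return sino
    return gaussian_filter1d(sino, sigma_bins, axis=1, mode="constant")


def forward_project(activity, sys):
    """Expected (noise-free) sinogram of an activity volume.

    Parameters
    ----------
    activity : VoxelVolume, nonnegative
    sys : SystemModel

    Returns
    -------
    ndarray of shape (n_angles, n_bins, n_slices)
    """
    vals = activity.values
    if vals.min() < 0:
        raise ValueError("activity must be nonnegative")
    nr, nc, nz = vals.shape
    if nr != nc:
        raise ValueError("projector requires square in-plane grids")
    A = sys.matrix(nr)
    sino = (A @ vals.reshape(nr * nc, nz)).reshape(sys.n_angles, sys.n_bins, nz)
    return _apply_blur(sino, sys.blur_sigma_bins(activity.voxel_size_mm[0]))


def sample_poisson(expected, seed, system=None, voxel_size_mm=DEFAULT_VOXEL_MM):
    """Independent Poisson draws per projection bin (seeded)."""
    expected = np.asarray(expected, dtype=float)
    if expected.min() < 0:
        raise ValueError("expected counts must be nonnegative")
    rng = np.random.default_rng(seed)
    return SinogramCounts(rng.poisson(expected).astype(np.int64), system, voxel_size_mm)


def poisson_log_likelihood(counts, expected):
    """Poisson log-likelihood sum(g*log(lam) - lam), dropping the g! term."""
    g = np.asarray(counts, dtype=float)
    lam = np.asarray(expected, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(g > 0, g * np.log(np.maximum(lam, 1e-300)), 0.0)
    return float(np.sum(term - lam))


def osem_reconstruct(counts, sys=None, n_subsets=8, n_iterations=4, init=None,
                     voxel_size_mm=None):
    """Ordered-subsets EM reconstruction (MLEM for ``n_subsets=1``).

    Standard multiplicative update over angle subsets (angles strided across
    subsets for even angular coverage).  The result is nonnegative; with one
    subset the Poisson log-likelihood is non-decreasing across iterations.
    """
    if isinstance(counts, SinogramCounts):
        sys = sys if sys is not None else counts.system
        voxel_size_mm = voxel_size_mm if voxel_size_mm is not None else counts.voxel_size_mm
        g = counts.counts
    else:
        g = np.asarray(counts)
    if sys is None:
        raise ValueError("a SystemModel is required")
    if voxel_size_mm is None:
        voxel_size_mm = DEFAULT_VOXEL_MM
    if sys.n_angles % n_subsets != 0:
        raise ValueError(f"n_subsets={n_subsets} does not divide n_angles={sys.n_angles}")
    n_ang, n_bins, nz = g.shape
    # square in-plane grid with side equal to the detector row count
    side = n_bins
    A = sys.matrix(side)
    sigma = sys.blur_sigma_bins(voxel_size_mm)

    if init is None:
        f = np.ones((side * side, nz))
    else:
        f = np.asarray(init, dtype=float).reshape(side * side, nz).copy()
        if f.min() <= 0:
            raise ValueError("init must be strictly positive")

    g_flat = g.reshape(n_ang * n_bins, nz).astype(float)
    subsets = []
    for s in range(n_subsets):
        ang = np.arange(s, n_ang, n_subsets)
        rows = (ang[:, None] * n_bins + np.arange(n_bins)[None, :]).ravel()
        A_s = A[rows]
        ones = np.ones((len(rows), 1))
        if sigma > 0:
            ones = _apply_blur(ones.reshape(len(ang), n_bins, 1), sigma).reshape(-1, 1)
        sens = np.asarray(A_s.T @ ones)  # (N2D, 1)
        subsets.append((ang, rows, A_s, sens))

    tiny = 1e-12
    for _ in range(n_iterations):
        for ang, rows, A_s, sens in subsets:
            fp = np.asarray(A_s @ f)
            if sigma > 0:
                fp = _apply_blur(fp.reshape(len(ang), n_bins, nz), sigma).reshape(-1, nz)
            ratio = g_flat[rows] / np.maximum(fp, tiny)
            if sigma > 0:
                ratio = _apply_blur(ratio.reshape(len(ang), n_bins, nz), sigma).reshape(-1, nz)
            back = np.asarray(A_s.T @ ratio)
            with np.errstate(invalid="ignore", divide="ignore"):
                f = np.where(sens > tiny, f * back / np.maximum(sens, tiny), f)
    vs = float(voxel_size_mm)
    return VoxelVolume(f.reshape(side, side, nz), (vs, vs, vs))


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------


def butterworth_filter_3d(vol, order=5, cutoff_cycles_per_cm=0.44):
    """3-D frequency-domain Butterworth low-pass filter.

    Magnitude response 1/sqrt(1 + (f/fc)^(2*order)) on the radial spatial
    frequency in cycles/cm; DC gain is exactly 1.
    """
    if not isinstance(vol, VoxelVolume):
        raise TypeError("butterworth_filter_3d requires a VoxelVolume (voxel size needed)")
    vs_cm = vol.voxel_size_cm
    freqs = [np.fft.fftfreq(n, d=d) for n, d in zip(vol.shape, vs_cm)]
    fr, fc, fz = np.meshgrid(*freqs, indexing="ij")
    f_rad = np.sqrt(fr**2 + fc**2 + fz**2)
    H = 1.0 / np.sqrt(1.0 + (f_rad / cutoff_cycles_per_cm) ** (2 * order))
    out = np.fft.ifftn(np.fft.fftn(vol.values) * H).real
    return vol.with_values(out)


def butterworth_gain(f_cycles_per_cm, order=5, cutoff_cycles_per_cm=0.44):
    """Scalar transfer-function magnitude at a given radial frequency."""
    return 1.0 / np.sqrt(1.0 + (f_cycles_per_cm / cutoff_cycles_per_cm) ** (2 * order))


def window_to_lv_max(vol, lv_mask):
    """Clip the dynamic range to [0, x_LV], x_LV = max value inside the LV wall."""
    lv_mask = np.asarray(lv_mask, dtype=bool)
    if not lv_mask.any():
        raise ValueError("empty LV mask")
    x_lv = float(vol.values[lv_mask].max())
    return vol.with_values(np.clip(vol.values, 0.0, x_lv))
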