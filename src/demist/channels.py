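"""Rotationally symmetric frequency channels and channel-vector extraction.

Anthropomorphic model observers process images through a small bank of
octave-spaced, rotationally symmetric frequency-band filters emulating the
frequency-selective channels of the human visual system.  Channel ``c``
(1-based) has frequency-domain indicator support on radial spatial
frequencies [f_start * 2^(c-1), f_start * 2^c) cycles/cm, with
f_start = 0.1838 cycles/cm: each successive channel doubles both its start
frequency and its bandwidth, and adjacent passbands do not overlap.  The
spatial profiles (columns of the channel matrix U) are the real inverse
DFTs of those indicators, centred on the grid and normalised to unit L2
norm; DC is excluded from every channel.

Applying the channel matrix, shifted so its centre coincides with the
defect centroid, to a 2-D image slice gives the channel vector
v = (S U)^T f_2D, shared by the task-specific training loss and the
channelized Hotelling observer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_F_START = 0.1838  # cycles/cm, start frequency and bandwidth of channel 1

__all__ = ["ChannelSet", "build_rotational_channels", "shift_channels", "channel_vector"]


@dataclass
class ChannelSet:
    """Spatial-domain channel matrix with its frequency-band metadata.

    matrix : (grid_size**2, C) array, one column per channel profile
    passbands : list of (f_start, f_end) half-open intervals in cycles/cm
    """

    matrix: np.ndarray
    grid_size: int
    pixel_size_cm: float
    passbands: list

    @property
    def n_channels(self):
        return self.matrix.shape[1]

    @property
    def center(self):
        return (self.grid_size // 2, self.grid_size // 2)

    def profile(self, c):
        """Channel c as a 2-D (grid_size, grid_size) image."""
        return self.matrix[:, c].reshape(self.grid_size, self.grid_size)


def build_rotational_channels(C=4, grid_size=32, pixel_size_cm=0.442,
                              f_start=DEFAULT_F_START):
    """Construct C octave-spaced rotationally symmetric frequency channels.

    Raises a ValueError if the grid is odd, if ``f_start`` is not below the
    axis Nyquist frequency, or if the highest passband captures no DFT bin
    on this grid (reduce C or the pixel size).
    """
    if grid_size % 2 != 0:
        raise ValueError("grid_size must be even")
    nyquist = 1.0 / (2.0 * pixel_size_cm)
    if not 0 < f_start < nyquist:
        raise ValueError(f"f_start must lie in (0, Nyquist={nyquist:.3f}) cycles/cm")
    freqs = np.fft.fftfreq(grid_size, d=pixel_size_cm)
    fr, fc = np.meshgrid(freqs, freqs, indexing="ij")
    f_rad = np.hypot(fr, fc)

    cols, passbands = [], []
    for c in range(C):
        lo = f_start * 2.0**c
        hi = f_start * 2.0 ** (c + 1)
        indicator = (f_rad >= lo) & (f_rad < hi)
        if not indicator.any():
            raise ValueError(
                f"channel {c + 1} passband [{lo:.4f}, {hi:.4f}) cycles/cm has no "
                "DFT support on this grid; reduce C or the pixel size"
            )
        profile = np.fft.fftshift(np.fft.ifft2(indicator.astype(float)).real)
        cols.append(profile.ravel() / np.linalg.norm(profile))
        passbands.append((lo, hi))
    return ChannelSet(np.column_stack(cols), grid_size, pixel_size_cm, passbands)


def shift_channels(channels, centroid):
    """Translate every channel profile so its centre lands on ``centroid``.

    The shift is acyclic: content moved off the grid is discarded and the
    vacated area is zero-filled.  ``centroid`` is an in-plane (row, col)
    index inside the grid.
    """
    g = channels.grid_size
    r, c = (int(round(float(x))) for x in centroid)
    if not (0 <= r < g and 0 <= c < g):
        raise ValueError("centroid outside grid")
    dr, dc = r - g // 2, c - g // 2
    profiles = channels.matrix.reshape(g, g, -1)
    out = np.zeros_like(profiles)

    def _rng(d, n):
        if d >= 0:
            return slice(d, n), slice(0, n - d)
        return slice(0, n + d), slice(-d, n)

    rd, rs = _rng(dr, g)
    cd, cs = _rng(dc, g)
    if rd.start < rd.stop and cd.start < cd.stop:
        out[rd, cd, :] = profiles[rs, cs, :]
    return out.reshape(g * g, -1)


def channel_vector(slice_2d, shifted_matrix):
    """Channel vector v = (S U)^T f_2D of a 2-D slice.

    ``slice_2d`` may be a 2-D image or an already-flattened vector in the
    same (row-major) order as the channel-matrix rows.
    """
    f = np.asarray(slice_2d, dtype=float).ravel()
    if f.size != shifted_matrix.shape[0]:
        raise ValueError("slice size does not match channel matrix rows")
    return shifted_matrix.T @ f
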