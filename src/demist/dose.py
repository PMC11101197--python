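"""Low-dose acquisition by binomial thinning of projection counts.

Reducing injected activity (or acquisition time) by a fraction ``p`` is
simulated by accepting each detected normal-dose count independently with
probability ``p`` — i.e., replacing each bin count ``n`` with a draw from
Binomial(n, p).  Thinning a Poisson(mu) bin this way yields Poisson(p*mu),
so the low-dose projections retain Poisson statistics.

Thinning acts strictly in the projection (count) domain; reconstruction of
the thinned data then proceeds identically to the normal-dose chain.
"""

from __future__ import annotations

import numpy as np

from .phantom import SinogramCounts

STUDY_DOSE_FRACTIONS = (0.0625, 0.125, 0.25)

__all__ = ["binomial_thin", "STUDY_DOSE_FRACTIONS"]


def binomial_thin(counts, p, seed):
    """Thin integer counts bin-wise with acceptance probability ``p``.

    Parameters
    ----------
    counts : SinogramCounts or integer ndarray
    p : float in (0, 1]
        Dose fraction (the study design uses 0.25, 0.125, 0.0625).
    seed : int or numpy Generator

    Returns
    -------
    Same type as ``counts``; bin-wise output <= input.
    """
    if not 0 < p <= 1:
        raise ValueError(f"dose fraction must lie in (0, 1], got {p}")
    wrap = isinstance(counts, SinogramCounts)
    arr = counts.counts if wrap else np.asarray(counts)
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError("counts must be integer-valued")
    if arr.min(initial=0) < 0:
        raise ValueError("counts must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if p == 1.0:
        thinned = arr.copy()
    else:
        thinned = rng.binomial(arr, p).astype(arr.dtype)
    if wrap:
        return SinogramCounts(thinned, counts.system, counts.voxel_size_mm)
    return thinned
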