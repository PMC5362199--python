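"""Local spatial clustering of trend values with the Getis–Ord G_i* statistic.

For each valid pixel i, with binary weights w_ij = 1 over the 3×3 Queen's
case neighborhood (diagonals and the focal pixel itself included, truncated
to valid in-bounds neighbors):

    G_i* z = [Σ_j w_ij x_j − X̄ W_i] / [ S √( (n Σ_j w_ij² − W_i²)/(n−1) ) ]

where W_i = Σ_j w_ij and X̄, S are the mean and standard deviation (divisor
n) over *all* n valid pixels of the raster — the statistic compares each
pixel's neighborhood against the whole image. With binary weights
Σ w_ij² = W_i. Pixels with |z| beyond a two-sided critical value are
classified as centers of positive or negative clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve

from .errors import DegenerateInputError
from .raster import GridSpec, ScalarRaster

CLUSTER_POSITIVE = 1
CLUSTER_NEGATIVE = -1
CLUSTER_NONE = 0

_QUEEN = np.ones((3, 3))


@dataclass
class HotspotRaster:
    grid: GridSpec
    gi_z: np.ndarray
    cluster_class: np.ndarray  # int8 codes; meaningful only where valid
    valid: np.ndarray


def gi_star(slopes: ScalarRaster, z_crit: float = 1.96) -> HotspotRaster:
    """G_i* z-scores and cluster classes for a slope raster.

    Raises DegenerateInputError when fewer than two valid pixels exist or
    the global variance is zero.
    """
    valid = slopes.valid
    n = int(valid.sum())
    if n < 2:
        raise DegenerateInputError("G_i* needs at least two valid pixels")
    x = np.where(valid, slopes.values, 0.0)
    vals = slopes.values[valid]
    xbar = float(vals.mean())
    s = float(vals.std())  # divisor n
    if s == 0:
        raise DegenerateInputError("G_i* undefined: zero variance across valid pixels")

    local_sum = convolve(x, _QUEEN, mode="constant", cval=0.0)
    w = convolve(valid.astype(float), _QUEEN, mode="constant", cval=0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        denom = s * np.sqrt((n * w - w * w) / (n - 1.0))
        z = (local_sum - xbar * w) / denom
    # a pixel whose neighborhood is the whole set of valid pixels has zero
    # denominator; its numerator is zero too, so define z = 0 there
    z = np.where(valid & ~np.isfinite(z), 0.0, z)
    z[~valid] = np.nan

    out = HotspotRaster(
        grid=slopes.grid,
        gi_z=z,
        cluster_class=np.zeros(slopes.grid.shape, dtype=np.int8),
        valid=valid.copy(),
    )
    return classify_clusters(out, z_crit)


def classify_clusters(h: HotspotRaster, z_crit: float) -> HotspotRaster:
    """(Re)classify a hotspot raster at a two-sided critical z value."""
    cls = np.full(h.grid.shape, CLUSTER_NONE, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        cls[h.valid & (h.gi_z > z_crit)] = CLUSTER_POSITIVE
        cls[h.valid & (h.gi_z < -z_crit)] = CLUSTER_NEGATIVE
    return HotspotRaster(grid=h.grid, gi_z=h.gi_z, cluster_class=cls, valid=h.valid)
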