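"""Spectral indices and the lichen volume estimator (LVE).

The LVE scores each pixel by how close its (NDLI, NDMI) pair sits to a
reference point under a correlated two-dimensional Gaussian:

    LVE = A · exp( −[u² − 2ρuv + v²] / (2(1−ρ²)) )

with u = (NDLI − c₁)/σ₁ and v = (NDMI − c₂)/σ₂. The center c is either a
fixed (μ₁, μ₂) pair or the scene-wide mean of the two indices over the
lichen mask ("scene_mean", the default). The score is a *relative* index of
lichen mat volume, not a calibrated physical volume.

The Gaussian coefficients published for the original Scandinavian
calibration are not reproduced here; the defaults below are placeholders and
any scientific use must supply calibrated parameters explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyDomainError
from .raster import LichenMask, ReflectanceStack, ScalarRaster, require_aligned


@dataclass(frozen=True)
class LveParams:
    """2-D Gaussian LVE parameters.

    amplitude : peak LVE score (placeholder default 100)
    mu_ndli, mu_ndmi : fixed center in index units
    sigma_ndli, sigma_ndmi : Gaussian widths in index units, > 0
    rho : index correlation in (−1, 1)
    center_mode : "scene_mean" centers on the yearly masked index means,
        "fixed" centers on (mu_ndli, mu_ndmi)
    """

    amplitude: float = 100.0
    mu_ndli: float = 0.0
    mu_ndmi: float = 0.0
    sigma_ndli: float = 0.25
    sigma_ndmi: float = 0.25
    rho: float = 0.0
    center_mode: str = "scene_mean"

    def __post_init__(self) -> None:
        if not (self.sigma_ndli > 0 and self.sigma_ndmi > 0):
            raise ValueError("sigmas must be positive")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")
        if self.center_mode not in ("fixed", "scene_mean"):
            raise ValueError("center_mode must be 'fixed' or 'scene_mean'")


@dataclass(frozen=True)
class IndexPair:
    ndli: float
    ndmi: float


def _normalized_difference(a, b):
    """(a − b)/(a + b) with NaN where the denominator is zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (a - b) / np.where(denom == 0, 1.0, denom), np.nan)
    return out


def ndli(swir1, green):
    """Normalized Difference Lichen Index: (SWIR1 − green)/(SWIR1 + green)."""
    return _normalized_difference(swir1, green)


def ndmi(nir, swir1):
    """Normalized Difference Moisture Index: (NIR − SWIR1)/(NIR + SWIR1)."""
    return _normalized_difference(nir, swir1)


def scene_index_means(stack: ReflectanceStack, mask: LichenMask, year: int) -> IndexPair:
    """Masked scene-wide mean NDLI and NDMI for one year.

    Averages over cells that are valid in the stack, lichen in the mask, and
    have defined indices. Raises EmptyDomainError if no such cell exists.
    """
    require_aligned(stack.grid, mask.grid, "stack and mask")
    yi = stack.year_index(year)
    g = stack.band("green", yi)
    n = stack.band("nir", yi)
    s = stack.band("swir1", yi)
    li = _normalized_difference(s, g)
    mi = _normalized_difference(n, s)
    sel = stack.valid[yi] & mask.is_lichen & np.isfinite(li) & np.isfinite(mi)
    if not sel.any():
        raise EmptyDomainError(f"no valid lichen pixels with defined indices in year {year}")
    return IndexPair(ndli=float(li[sel].mean()), ndmi=float(mi[sel].mean()))


def lve_score(idx_ndli, idx_ndmi, params: LveParams, center: IndexPair):
    """Evaluate the 2-D Gaussian LVE at given index values (scalar or array)."""
    u = (np.asarray(idx_ndli, dtype=float) - center.ndli) / params.sigma_ndli
    v = (np.asarray(idx_ndmi, dtype=float) - center.ndmi) / params.sigma_ndmi
    q = (u * u - 2.0 * params.rho * u * v + v * v) / (2.0 * (1.0 - params.rho**2))
    return params.amplitude * np.exp(-q)


def lve_stack(
    stack: ReflectanceStack,
    mask: LichenMask,
    params: LveParams,
    per_year_center: bool = True,
) -> dict[int, ScalarRaster]:
    """Yearly LVE rasters over the lichen mask.

    For each year, indices are computed per pixel; with
    ``center_mode == "scene_mean"`` the Gaussian is centered on that year's
    masked index means (or, with ``per_year_center=False``, on a single mean
    over all years). Non-lichen, invalid, or undefined-index pixels come out
    invalid.
    """
    require_aligned(stack.grid, mask.grid, "stack and mask")

    if params.center_mode == "fixed":
        centers = {int(y): IndexPair(params.mu_ndli, params.mu_ndmi) for y in stack.years}
    elif per_year_center:
        centers = {int(y): scene_index_means(stack, mask, int(y)) for y in stack.years}
    else:
        pairs = [scene_index_means(stack, mask, int(y)) for y in stack.years]
        pooled = IndexPair(
            ndli=float(np.mean([p.ndli for p in pairs])),
            ndmi=float(np.mean([p.ndmi for p in pairs])),
        )
        centers = {int(y): pooled for y in stack.years}

    out: dict[int, ScalarRaster] = {}
    for yi, year in enumerate(stack.years):
        year = int(year)
        g = stack.band("green", yi)
        n = stack.band("nir", yi)
        s = stack.band("swir1", yi)
        li = _normalized_difference(s, g)
        mi = _normalized_difference(n, s)
        valid = stack.valid[yi] & mask.is_lichen & np.isfinite(li) & np.isfinite(mi)
        scores = lve_score(np.where(valid, li, 0.0), np.where(valid, mi, 0.0), params, centers[year])
        out[year] = ScalarRaster(
            grid=stack.grid, values=np.where(valid, scores, 0.0), valid=valid
        )
    return out
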