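"""Per-pixel robust trend detection on yearly LVE rasters.

The yearly change at each pixel is estimated by the Theil–Sen slope (median
of all pairwise slopes) and its significance by the Mann–Kendall test with
tie-corrected variance and continuity correction:

    S = Σ_{i<j} sign(x_j − x_i)
    Var(S) = [n(n−1)(2n+5) − Σ_k t_k(t_k−1)(2t_k+5)] / 18
    z = (S∓1)/√Var(S)  (0 when S = 0)

where t_k are the tie-group sizes. Pixels are classified at a two-sided
alpha into increasing / decreasing / no-change; pixels with fewer valid
years than ``min_years`` are invalid. No multiple-testing correction is
applied across pixels by default (a BH-FDR hook is provided).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError
from .raster import GridSpec, ScalarRaster, require_aligned

CLASS_INCREASING = 1
CLASS_DECREASING = -1
CLASS_NO_CHANGE = 0


@dataclass
class TrendRaster:
    """Per-pixel Theil–Sen slope, Mann–Kendall statistics and change class."""

    grid: GridSpec
    slope: np.ndarray
    mk_s: np.ndarray
    mk_z: np.ndarray
    p_value: np.ndarray
    change_class: np.ndarray  # int8 codes; meaningful only where valid
    valid: np.ndarray

    def slope_raster(self) -> ScalarRaster:
        return ScalarRaster(
            grid=self.grid, values=np.where(self.valid, self.slope, 0.0), valid=self.valid
        )


def theil_sen_slope(t, x) -> float:
    """Median of all pairwise slopes (x_j − x_i)/(t_j − t_i), i < j."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(t)
    if n < 2:
        raise InsufficientDataError("Theil-Sen needs at least two observations")
    if not np.all(np.diff(t) > 0):
        raise ValueError("t must be strictly increasing")
    i, j = np.triu_indices(n, k=1)
    return float(np.median((x[j] - x[i]) / (t[j] - t[i])))


def _tie_term(x: np.ndarray) -> float:
    _, counts = np.unique(x, return_counts=True)
    c = counts.astype(float)
    return float(np.sum(c * (c - 1) * (2 * c + 5)))


def mann_kendall(x, min_n: int = 4) -> tuple[int, float, float]:
    """Mann–Kendall S, continuity-corrected z and two-sided p for a series.

    The series must be ordered in time. An all-tied series (zero variance)
    returns (0, 0.0, 1.0) rather than raising.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < min_n:
        raise InsufficientDataError(f"Mann-Kendall needs at least {min_n} observations")
    i, j = np.triu_indices(n, k=1)
    s = int(np.sign(x[j] - x[i]).sum())
    var = (n * (n - 1) * (2 * n + 5) - _tie_term(x)) / 18.0
    if var <= 0:
        return 0, 0.0, 1.0
    if s > 0:
        z = (s - 1) / np.sqrt(var)
    elif s < 0:
        z = (s + 1) / np.sqrt(var)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return s, float(z), float(min(p, 1.0))


def _stack_array(lve_by_year: dict[int, ScalarRaster]) -> tuple[np.ndarray, np.ndarray, GridSpec]:
    years = np.array(sorted(lve_by_year), dtype=int)
    grid = lve_by_year[int(years[0])].grid
    X = np.empty((len(years), *grid.shape))
    for yi, y in enumerate(years):
        r = lve_by_year[int(y)]
        require_aligned(grid, r.grid, "yearly LVE rasters")
        X[yi] = np.where(r.valid, r.values, np.nan)
    return X, years.astype(float), grid


def trend_raster(
    lve_by_year: dict[int, ScalarRaster],
    alpha: float = 0.05,
    min_years: int = 10,
    fdr: bool = False,
) -> TrendRaster:
    """Theil–Sen + Mann–Kendall per pixel over each pixel's valid years.

    ``fdr=True`` applies a Benjamini–Hochberg correction across valid pixels
    before classification (off by default).
    """
    X, years, grid = _stack_array(lve_by_year)
    ny = X.shape[0]
    X2 = X.reshape(ny, -1)
    npix = X2.shape[1]

    i, j = np.triu_indices(ny, k=1)
    dt = (years[j] - years[i])[:, None]
    with np.errstate(invalid="ignore"):
        diffs = X2[j] - X2[i]
        slopes = diffs / dt
        signs = np.sign(diffs)

    n_valid = np.isfinite(X2).sum(axis=0)
    ok = n_valid >= max(min_years, 2)

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels masked below
        slope = np.nanmedian(np.where(np.isfinite(slopes), slopes, np.nan), axis=0)
    s_stat = np.nansum(signs, axis=0)

    # per-element equal-value counts give the tie correction:
    # a tie group of size t contributes t·(t−1)(2t+5)
    eq = X2[:, None, :] == X2[None, :, :]
    c = eq.sum(axis=1).astype(float)
    tie = np.nansum(
        np.where(np.isfinite(X2), (c - 1.0) * (2.0 * c + 5.0), 0.0), axis=0
    )
    nv = n_valid.astype(float)
    var = (nv * (nv - 1) * (2 * nv + 5) - tie) / 18.0

    z = np.zeros(npix)
    pos = (s_stat > 0) & (var > 0)
    neg = (s_stat < 0) & (var > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z[pos] = (s_stat[pos] - 1) / np.sqrt(var[pos])
        z[neg] = (s_stat[neg] + 1) / np.sqrt(var[neg])
    p = np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0)
    p[var <= 0] = 1.0

    if fdr and ok.any():
        p_ok = p[ok]
        order = np.argsort(p_ok)
        m = len(p_ok)
        adj = np.empty(m)
        adj[order] = np.minimum.accumulate((p_ok[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        p[ok] = np.minimum(adj, 1.0)

    cls = np.full(npix, CLASS_NO_CHANGE, dtype=np.int8)
    cls[(p < alpha) & (slope > 0)] = CLASS_INCREASING
    cls[(p < alpha) & (slope < 0)] = CLASS_DECREASING

    shape = grid.shape
    return TrendRaster(
        grid=grid,
        slope=np.where(ok, slope, np.nan).reshape(shape),
        mk_s=np.where(ok, s_stat, np.nan).reshape(shape),
        mk_z=np.where(ok, z, np.nan).reshape(shape),
        p_value=np.where(ok, p, np.nan).reshape(shape),
        change_class=cls.reshape(shape),
        valid=ok.reshape(shape),
    )
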