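"""Herd-range zonal summaries and spatially-correlated herd comparisons.

Change-class rasters are summarised per herd polygon as percentages of
classified lichen pixels (cell-center-in-polygon membership). Herd mean
slopes are compared with a single-factor generalized least squares model
fitted by maximum likelihood, optionally with a Gaussian spatial correlation
of the errors,

    corr(d) = (1 − n₀) · exp(−(d/r)²)   for d > 0,

with range r (metres) and optional nugget n₀ estimated by ML. The spatial
and independent fits are compared with a likelihood ratio; group differences
are tested with a single-factor F test and, pairwise, a Tukey HSD based on
the studentized range and the model's covariance of the group means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry
from shapely import contains_xy

from .errors import EmptyDomainError, FitError, InsufficientDataError
from .raster import LichenMask, ScalarRaster, require_aligned
from .trend import CLASS_DECREASING, CLASS_INCREASING


@dataclass
class HerdRange:
    herd_id: str
    polygon: BaseGeometry

    def __post_init__(self) -> None:
        if self.polygon.is_empty or not self.polygon.is_valid:
            raise ValueError(f"herd {self.herd_id}: empty or invalid geometry")


def read_herd_ranges(path) -> list[HerdRange]:
    """Read herd-range polygons from a GeoJSON FeatureCollection.

    Each feature must carry a ``herd_id`` property (``herd`` accepted as a
    fallback). Geometries are taken as already being in the raster CRS.
    """
    with open(path) as fh:
        gj = json.load(fh)
    ranges = []
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        herd_id = props.get("herd_id", props.get("herd"))
        if herd_id is None:
            raise ValueError(f"{path}: feature without herd_id property")
        ranges.append(HerdRange(herd_id=str(herd_id), polygon=shapely_shape(feat["geometry"])))
    return ranges


def write_herd_ranges(ranges: list[HerdRange], path) -> None:
    from shapely.geometry import mapping

    gj = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"herd_id": r.herd_id},
                "geometry": mapping(r.polygon),
            }
            for r in ranges
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


def _class_info(classes):
    """Pull (class_codes, valid) out of a TrendRaster or HotspotRaster."""
    if hasattr(classes, "change_class"):
        return classes.change_class, classes.valid, classes.grid
    if hasattr(classes, "cluster_class"):
        return classes.cluster_class, classes.valid, classes.grid
    raise TypeError("classes must be a TrendRaster or HotspotRaster")


def assign_pixels_to_ranges(grid, ranges: list[HerdRange]) -> np.ndarray:
    """Herd index per pixel by cell-center-in-polygon; −1 where unassigned.

    Boundary ties go to the first polygon in file order.
    """
    x, y = grid.cell_centers()
    owner = np.full(grid.shape, -1, dtype=int)
    for k, r in enumerate(ranges):
        hit = contains_xy(r.polygon, x, y) & (owner < 0)
        owner[hit] = k
    return owner


def zonal_class_percentages(classes, mask: LichenMask, ranges: list[HerdRange]) -> pd.DataFrame:
    """Percentages of increasing / decreasing / no-change lichen pixels per herd.

    Percentages are over lichen-mask, valid, classified pixels within each
    range and sum to 100. A range with zero eligible pixels raises
    EmptyDomainError.
    """
    codes, valid, grid = _class_info(classes)
    require_aligned(grid, mask.grid, "classes and mask")
    owner = assign_pixels_to_ranges(grid, ranges)
    rows = []
    for k, r in enumerate(ranges):
        sel = (owner == k) & mask.is_lichen & valid
        n = int(sel.sum())
        if n == 0:
            raise EmptyDomainError(f"herd {r.herd_id}: no classified lichen pixels in range")
        c = codes[sel]
        n_inc = int((c == CLASS_INCREASING).sum())
        n_dec = int((c == CLASS_DECREASING).sum())
        rows.append(
            {
                "herd_id": r.herd_id,
                "n_pixels": n,
                "n_increasing": n_inc,
                "n_decreasing": n_dec,
                "n_no_change": n - n_inc - n_dec,
                "pct_increasing": 100.0 * n_inc / n,
                "pct_decreasing": 100.0 * n_dec / n,
                "pct_no_change": 100.0 * (n - n_inc - n_dec) / n,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spatially stratified sampling
# ---------------------------------------------------------------------------

def largest_remainder_allocation(counts: np.ndarray, n: int) -> np.ndarray:
    """Allocate n draws across strata proportional to counts (Hare quota)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise InsufficientDataError("no eligible pixels to allocate")
    quota = n * counts / total
    alloc = np.floor(quota).astype(int)
    short = n - alloc.sum()
    if short > 0:
        frac = quota - np.floor(quota)
        # stable tie-break: larger remainder first, then lower stratum index
        order = np.lexsort((np.arange(len(frac)), -frac))
        alloc[order[:short]] += 1
    return alloc


def stratified_sample(
    slopes: ScalarRaster, herd: HerdRange, n: int, seed: int
) -> pd.DataFrame:
    """Spatially stratified random sample of valid slope pixels in one range.

    The range's bounding box is split into ⌈√n⌉×⌈√n⌉ strata; samples are
    allocated to strata proportional to their valid-pixel counts
    (largest-remainder rounding) and drawn uniformly without replacement.
    Deterministic given the seed.
    """
    grid = slopes.grid
    x, y = grid.cell_centers()
    eligible = slopes.valid & contains_xy(herd.polygon, x, y)
    idx = np.nonzero(eligible.ravel())[0]
    if idx.size < n:
        raise InsufficientDataError(
            f"herd {herd.herd_id}: {idx.size} valid pixels < requested {n}"
        )
    k = int(np.ceil(np.sqrt(n)))
    minx, miny, maxx, maxy = herd.polygon.bounds
    xr = x.ravel()[idx]
    yr = y.ravel()[idx]
    sx = np.clip(((xr - minx) / max(maxx - minx, 1e-12) * k).astype(int), 0, k - 1)
    sy = np.clip(((yr - miny) / max(maxy - miny, 1e-12) * k).astype(int), 0, k - 1)
    stratum = sy * k + sx
    counts = np.bincount(stratum, minlength=k * k)
    alloc = largest_remainder_allocation(counts, n)
    # proportional quotas can exceed a stratum's pixel count only through
    # rounding; push any excess to the fullest strata deterministically
    over = alloc - counts
    while (over > 0).any():
        excess = int(over[over > 0].sum())
        alloc = np.minimum(alloc, counts)
        room = counts - alloc
        order = np.lexsort((np.arange(len(room)), -room))
        for s in order:
            if excess == 0:
                break
            add = int(min(room[s], excess))
            alloc[s] += add
            excess -= add
        over = alloc - counts

    rng = np.random.default_rng(seed)
    chosen = []
    for s in range(k * k):
        if alloc[s] == 0:
            continue
        members = idx[stratum == s]
        chosen.append(rng.choice(members, size=alloc[s], replace=False))
    chosen = np.sort(np.concatenate(chosen))
    rows, cols = np.unravel_index(chosen, grid.shape)
    return pd.DataFrame(
        {
            "herd_id": herd.herd_id,
            "row": rows,
            "col": cols,
            "x": x[rows, cols],
            "y": y[rows, cols],
            "slope": slopes.values[rows, cols],
        }
    )


# ---------------------------------------------------------------------------
# GLS herd comparison
# ---------------------------------------------------------------------------

@dataclass
class GlsFit:
    herds: list[str]
    group_means: np.ndarray
    cov_means: np.ndarray
    sigma2: float
    correlation: str
    method: str
    correlation_range: float | None
    nugget: float | None
    loglik_spatial: float
    loglik_indep: float
    lr_statistic: float
    lr_p: float
    f_statistic: float
    f_p: float
    df_num: int
    df_den: int
    n: int

    def means_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "herd_id": self.herds,
                "mean_slope": self.group_means,
                "se": np.sqrt(np.diag(self.cov_means)),
            }
        )


def _profile_loglik(corr: np.ndarray, X: np.ndarray, y: np.ndarray, reml: bool = False):
    """Profile log-likelihood (ML or REML) of a GLS fit given a correlation."""
    n, k = X.shape
    L = np.linalg.cholesky(corr)
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdet = float(np.sum(np.log(np.diag(L))))
    if reml:
        sigma2 = rss / (n - k)
        _, ld2 = np.linalg.slogdet(Xw.T @ Xw)
        ll = -0.5 * (n - k) * (np.log(2 * np.pi * sigma2) + 1.0) - logdet - 0.5 * ld2
    else:
        sigma2 = rss / n
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) - logdet
    return ll, beta, sigma2, Xw, yw, rss


def _gaussian_corr(D: np.ndarray, r: float, nugget: float) -> np.ndarray:
    C = (1.0 - nugget) * np.exp(-((D / r) ** 2))
    np.fill_diagonal(C, 1.0)
    return C


def gls_herd_model(
    samples: pd.DataFrame,
    correlation: str = "gaussian",
    nugget: bool = True,
    method: str = "REML",
) -> GlsFit:
    """Single-factor GLS of slope on herd with estimated error correlation.

    ``samples`` needs columns herd_id, x, y, slope (e.g. the concatenated
    output of :func:`stratified_sample` for every herd). The independent and
    spatially-correlated fits are both computed so their likelihood ratio is
    always reported; ``correlation`` selects which fit supplies the group
    means, F test and covariance used downstream. ``method`` chooses the
    estimation criterion for the correlation parameters: REML (default; the
    F test on the group factor is then close to nominal size) or ML. Both
    fits nest (nugget → 1 recovers independence) so the LR is nonnegative
    under either criterion.
    """
    if correlation not in ("none", "gaussian"):
        raise ValueError("correlation must be 'none' or 'gaussian'")
    if method not in ("REML", "ML"):
        raise ValueError("method must be 'REML' or 'ML'")
    reml = method == "REML"
    herds = sorted(samples["herd_id"].unique())
    k = len(herds)
    if k < 2:
        raise InsufficientDataError("need at least two herds")
    counts = samples["herd_id"].value_counts()
    if counts.min() < 3:
        raise InsufficientDataError("need at least three samples per herd")
    y = samples["slope"].to_numpy(dtype=float)
    n = len(y)
    X = np.zeros((n, k))
    for ki, h in enumerate(herds):
        X[samples["herd_id"].to_numpy() == h, ki] = 1.0

    ll_ind, beta_ind, s2_ind, Xw_i, yw_i, rss_i = _profile_loglik(np.eye(n), X, y, reml)

    coords = samples[["x", "y"]].to_numpy(dtype=float)
    D = squareform(pdist(coords))
    off = D[np.triu_indices(n, k=1)]
    d_med = float(np.median(off)) if off.size else 1.0

    def nll(psi):
        r = np.exp(np.clip(psi[0], -20.0, 25.0))
        n0 = 1.0 / (1.0 + np.exp(-np.clip(psi[1], -30.0, 30.0))) if len(psi) > 1 else 0.0
        try:
            C = _gaussian_corr(D, r, n0)
            ll, *_ = _profile_loglik(C, X, y, reml)
        except np.linalg.LinAlgError:
            return 1e10
        return -ll

    best = None
    for frac in (0.02, 0.1, 0.4):
        x0 = [np.log(max(frac * d_med, 1e-9))]
        if nugget:
            x0.append(0.0)  # nugget start 0.5
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"maxiter": 400, "xatol": 1e-4, "fatol": 1e-7})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("Gaussian GLS correlation fit did not converge")
    r_hat = float(np.exp(np.clip(best.x[0], -20.0, 25.0)))
    n0_hat = float(1.0 / (1.0 + np.exp(-np.clip(best.x[1], -30.0, 30.0)))) if nugget else 0.0
    C_hat = _gaussian_corr(D, r_hat, n0_hat)
    ll_sp, beta_sp, s2_sp, Xw_s, yw_s, rss_s = _profile_loglik(C_hat, X, y, reml)

    lr = max(0.0, 2.0 * (ll_sp - ll_ind))
    lr_df = 2 if nugget else 1
    lr_p = float(stats.chi2.sf(lr, lr_df))

    if correlation == "gaussian":
        beta, s2, Xw, yw, rss, ll_use = beta_sp, s2_sp, Xw_s, yw_s, rss_s, ll_sp
        corr_range, nug = r_hat, n0_hat
    else:
        beta, s2, Xw, yw, rss, ll_use = beta_ind, s2_ind, Xw_i, yw_i, rss_i, ll_ind
        corr_range, nug = None, None

    # single-factor F test: whitened full model vs whitened grand-mean model
    X0w = Xw.sum(axis=1, keepdims=True)  # whitened intercept column
    b0, *_ = np.linalg.lstsq(X0w, yw, rcond=None)
    rss0 = float(np.sum((yw - X0w @ b0) ** 2))
    df_num, df_den = k - 1, n - k
    f_stat = ((rss0 - rss) / df_num) / (rss / df_den)
    f_p = float(stats.f.sf(f_stat, df_num, df_den))

    s2_unbiased = rss / df_den
    cov_means = s2_unbiased * np.linalg.inv(Xw.T @ Xw)

    return GlsFit(
        herds=herds,
        group_means=np.asarray(beta, dtype=float),
        cov_means=cov_means,
        sigma2=float(s2_unbiased),
        correlation=correlation,
        method=method,
        correlation_range=corr_range,
        nugget=nug,
        loglik_spatial=float(ll_sp),
        loglik_indep=float(ll_ind),
        lr_statistic=float(lr),
        lr_p=lr_p,
        f_statistic=float(f_stat),
        f_p=f_p,
        df_num=df_num,
        df_den=df_den,
        n=n,
    )


def tukey_pairwise(fit: GlsFit, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise herd-mean differences with studentized-range adjusted p.

    Uses the fitted model's covariance of the group means and its residual
    degrees of freedom; with two groups this reduces to the unadjusted
    pairwise test.
    """
    rows = []
    k = len(fit.herds)
    for a in range(k):
        for b in range(a + 1, k):
            diff = fit.group_means[a] - fit.group_means[b]
            var = fit.cov_means[a, a] + fit.cov_means[b, b] - 2 * fit.cov_means[a, b]
            se = float(np.sqrt(max(var, 0.0)))
            if se == 0:
                q = 0.0
            else:
                q = np.sqrt(2.0) * abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, fit.df_den))
            rows.append(
                {
                    "herd_a": fit.herds[a],
                    "herd_b": fit.herds[b],
                    "estimate": float(diff),
                    "se": se,
                    "q": float(q),
                    "p_adj": min(p, 1.0),
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


def empirical_semivariogram(
    coords: np.ndarray, values: np.ndarray, n_bins: int = 12, max_lag: float | None = None
) -> pd.DataFrame:
    """Binned empirical semivariogram of residuals — a diagnostic utility.

    γ(h) = mean over pairs in the lag bin of (z_i − z_j)²/2.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    d = pdist(coords)
    i, j = np.triu_indices(len(values), k=1)
    g = 0.5 * (values[i] - values[j]) ** 2
    if max_lag is None:
        max_lag = float(np.max(d)) / 2.0
    sel = d <= max_lag
    d, g = d[sel], g[sel]
    edges = np.linspace(0, max_lag, n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = which == b
        if m.sum() == 0:
            continue
        rows.append(
            {
                "lag": float(0.5 * (edges[b] + edges[b + 1])),
                "gamma": float(g[m].mean()),
                "n_pairs": int(m.sum()),
            }
        )
    return pd.DataFrame(rows)
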