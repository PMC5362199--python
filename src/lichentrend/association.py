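"""Seasonal smooth models of movement velocity against lichen volume.

For one season, step velocities (rounded to integer m/h so a count family
applies) are modelled as

    velocity_i ~ NegBin(mean μ_i, size θ),
    log μ_i = β₀ + f(LVE_i) + b_animal(i),

where f is a penalized cubic B-spline (default 8 basis functions,
second-difference penalty) and the per-animal intercepts b are a ridge-
penalized (random-effect-like) term absorbing repeated measures per animal.
Fitting is penalized IRLS with the NB size θ re-estimated by profile maximum
likelihood; the smoothing penalty is chosen by GCV over a grid. The smooth
term is tested against the constant model with a Wald statistic on the
penalized coefficients using the Bayesian covariance and the smooth's
effective degrees of freedom.

Spatial correlation of the residuals is *not* modelled here; the
semivariogram utility in :mod:`lichentrend.range_stats` can be applied to
the deviance residuals to examine it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline
from scipy.special import gammaln

from .errors import DegenerateInputError, FitError, InsufficientDataError


def _bspline_design(x: np.ndarray, n_basis: int, lo: float, hi: float, degree: int = 3):
    """Clamped uniform B-spline design matrix with n_basis functions."""
    n_interior = n_basis - degree - 1
    if n_interior < 0:
        raise ValueError("n_basis must be at least degree + 1")
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    t = np.concatenate([np.repeat(lo, degree + 1), interior, np.repeat(hi, degree + 1)])
    B = BSpline.design_matrix(np.clip(x, lo, hi), t, degree).toarray()
    return B, t


def _nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    mu = np.maximum(mu, 1e-10)
    return float(
        np.sum(
            gammaln(y + theta)
            - gammaln(theta)
            - gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def _nb_deviance(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    mu = np.maximum(mu, 1e-10)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y + theta) * np.log((y + theta) / (mu + theta))))


def _estimate_theta(y: np.ndarray, mu: np.ndarray) -> float:
    res = optimize.minimize_scalar(
        lambda lt: -_nb_loglik(y, mu, np.exp(lt)),
        bounds=(np.log(0.05), np.log(1e4)),
        method="bounded",
    )
    return float(np.exp(res.x))


def _pirls(y, X, P, theta, beta0=None, max_iter=60, tol=1e-8):
    """Penalized IRLS for the NB log-link model; returns beta, mu, XtWX."""
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    if beta0 is None:
        beta[0] = np.log(max(np.mean(y), 0.5))
    eta = X @ beta
    dev_prev = np.inf
    for _ in range(max_iter):
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + mu / theta)
        z = eta + (y - mu) / np.maximum(mu, 1e-10)
        XtW = X.T * w
        A = XtW @ X + P
        b = XtW @ z
        try:
            beta_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"penalized IRLS normal equations singular: {exc}") from exc
        eta = X @ beta_new
        mu = np.exp(np.clip(eta, -30, 30))
        dev = _nb_deviance(y, mu, theta)
        beta = beta_new
        if abs(dev_prev - dev) < tol * (abs(dev) + 0.1):
            break
        dev_prev = dev
    mu = np.exp(np.clip(X @ beta, -30, 30))
    w = mu / (1.0 + mu / theta)
    XtWX = (X.T * w) @ X
    return beta, mu, XtWX


@dataclass
class SmoothFit:
    """A fitted seasonal velocity–LVE smooth."""

    season: str
    knots: np.ndarray
    degree: int
    n_basis: int
    col_means: np.ndarray
    constraint: np.ndarray  # sum-to-zero reparameterization, (n_basis, n_basis−1)
    beta: np.ndarray
    Vb: np.ndarray
    animals: list
    lve_lo: float
    lve_hi: float
    theta: float
    lambda_smooth: float
    lambda_animal: float
    edf_total: float
    edf_smooth: float
    smooth_stat: float
    smooth_df: int
    smooth_p: float
    deviance: float
    null_deviance: float
    n: int

    @property
    def _smooth_slice(self) -> slice:
        return slice(1, self.n_basis)

    def linear_predictor(self, lve: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Population-level eta and its SE on the given LVE values."""
        lve = np.asarray(lve, dtype=float)
        B = BSpline.design_matrix(
            np.clip(lve, self.lve_lo, self.lve_hi), self.knots, self.degree
        ).toarray()
        Xg = np.column_stack([np.ones(len(lve)), (B - self.col_means) @ self.constraint])
        sub = np.r_[0, np.arange(1, self.n_basis)]
        eta = Xg @ self.beta[sub]
        V = self.Vb[np.ix_(sub, sub)]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, V, Xg), 0.0))
        return eta, se


def fit_velocity_smooth(
    steps: pd.DataFrame,
    season: str | None = None,
    n_basis: int = 8,
    lambda_smooth: float | None = None,
    lambda_animal: float = 1.0,
    min_steps: int = 50,
    min_animals: int = 3,
) -> SmoothFit:
    """Fit the seasonal NB velocity smooth with per-animal intercepts.

    ``steps`` must carry velocity_mh, lve_at_start and animal_id (already
    restricted to one season, or pass ``season`` to subset). The smoothing
    penalty is chosen by GCV unless ``lambda_smooth`` is given.
    """
    df = steps
    if season is not None:
        df = df[df["season"] == season]
    df = df.dropna(subset=["velocity_mh", "lve_at_start"])
    season_name = season if season is not None else (
        df["season"].iloc[0] if "season" in df and len(df) else "all"
    )
    if len(df) < min_steps:
        raise InsufficientDataError(f"{season_name}: {len(df)} steps < {min_steps}")
    animals = sorted(df["animal_id"].unique())
    if len(animals) < min_animals:
        raise InsufficientDataError(f"{season_name}: {len(animals)} animals < {min_animals}")

    y = np.round(df["velocity_mh"].to_numpy(dtype=float)).clip(min=0)
    L = df["lve_at_start"].to_numpy(dtype=float)
    lo, hi = float(L.min()), float(L.max())
    if hi - lo < 1e-9:
        raise DegenerateInputError(f"{season_name}: single LVE value, smooth unidentifiable")

    B, knots = _bspline_design(L, n_basis, lo, hi)
    col_means = B.mean(axis=0)
    Bc = B - col_means
    # absorb the sum-to-zero constraint: centred columns leave the constant
    # coefficient direction (B rows sum to 1) unidentified, so project onto
    # the orthogonal complement of the ones vector
    Tq = np.linalg.qr(np.ones((n_basis, 1)), mode="complete")[0][:, 1:]
    Bs = Bc @ Tq
    p_s = n_basis - 1
    m = len(animals)
    Z = np.zeros((len(df), m))
    aidx = {a: k for k, a in enumerate(animals)}
    for i, a in enumerate(df["animal_id"].to_numpy()):
        Z[i, aidx[a]] = 1.0
    # centring the dummies (each row sums to zero) identifies the intercept
    # as the population level, so predictions with b = 0 are population-mean
    # predictions; with one animal the random-effect block vanishes entirely
    Z = Z - 1.0 / m
    X = np.column_stack([np.ones(len(df)), Bs, Z])
    p_tot = X.shape[1]

    # second divided-difference penalty at the Greville abscissae: its null
    # space is exactly the linear functions of LVE (B-splines reproduce
    # linears via coefficients at the Greville points); ridge on animals
    k_deg = 3
    greville = np.array(
        [knots[i + 1 : i + 1 + k_deg].mean() for i in range(n_basis)]
    )
    D2 = np.zeros((n_basis - 2, n_basis))
    for i in range(1, n_basis - 1):
        h0 = greville[i] - greville[i - 1]
        h1 = greville[i + 1] - greville[i]
        D2[i - 1, i - 1] = 1.0 / h0
        D2[i - 1, i] = -(1.0 / h0 + 1.0 / h1)
        D2[i - 1, i + 1] = 1.0 / h1
    D2 *= (hi - lo) / n_basis  # scale-free in the covariate units
    S_smooth = Tq.T @ (D2.T @ D2) @ Tq

    def penalty(lam_s, lam_a):
        P = np.zeros((p_tot, p_tot))
        P[1 : 1 + p_s, 1 : 1 + p_s] = lam_s * S_smooth
        P[1 + p_s :, 1 + p_s :] = lam_a * np.eye(m)
        return P

    theta = _estimate_theta(y, np.full_like(y, max(y.mean(), 0.5), dtype=float))

    def fit_once(lam_s, lam_a, th, beta0=None):
        P = penalty(lam_s, lam_a)
        beta, mu, XtWX = _pirls(y, X, P, th, beta0=beta0)
        A = XtWX + P
        Ainv = np.linalg.inv(A)
        F = Ainv @ XtWX
        edf = float(np.trace(F))
        dev = _nb_deviance(y, mu, th)
        return beta, mu, Ainv, F, edf, dev

    n = len(y)
    gamma = 1.4  # heavier edf cost guards against undersmoothing
    if lambda_smooth is None:
        grid = np.logspace(-1, 5, 9)
        best = None
        for lam_s in grid:
            _, _, _, _, edf, dev = fit_once(lam_s, lambda_animal, theta)
            gcv = n * dev / max(n - gamma * edf, 1.0) ** 2
            if best is None or gcv < best[0]:
                best = (gcv, lam_s)
        lambda_smooth = best[1]

    # alternate theta and coefficient estimation
    beta = None
    for _ in range(3):
        beta, mu, Ainv, F, edf, dev = fit_once(lambda_smooth, lambda_animal, theta, beta0=beta)
        theta_new = _estimate_theta(y, mu)
        if abs(np.log(theta_new / theta)) < 1e-3:
            theta = theta_new
            break
        theta = theta_new
    beta, mu, Ainv, F, edf, dev = fit_once(lambda_smooth, lambda_animal, theta, beta0=beta)

    sl = slice(1, 1 + p_s)
    edf_smooth = float(np.trace(F[sl, sl]))
    # Wald test of the smooth block at its effective rank: the top-variance
    # eigendirections are the least-penalized ones carrying the fitted signal
    Vs = Ainv[sl, sl]
    bs = beta[sl]
    evals, evecs = np.linalg.eigh(Vs)
    r = int(np.clip(np.round(edf_smooth), 1, p_s))
    order = np.argsort(evals)[::-1]
    lead_vals = evals[order[:r]]
    lead_vecs = evecs[:, order[:r]]
    proj = lead_vecs.T @ bs
    stat = float(np.sum(proj**2 / np.maximum(lead_vals, 1e-12)))
    p_smooth = float(stats.chi2.sf(stat, r))

    # null model: intercept + (centred) animal intercepts only
    Xn = np.column_stack([np.ones(n), Z])
    Pn = np.zeros((1 + m, 1 + m))
    Pn[1:, 1:] = lambda_animal * np.eye(m)
    _, mu0, _ = _pirls(y, Xn, Pn, theta)
    dev0 = _nb_deviance(y, mu0, theta)

    return SmoothFit(
        season=str(season_name),
        knots=knots,
        degree=3,
        n_basis=n_basis,
        col_means=col_means,
        constraint=Tq,
        beta=beta,
        Vb=Ainv,
        animals=animals,
        lve_lo=lo,
        lve_hi=hi,
        theta=float(theta),
        lambda_smooth=float(lambda_smooth),
        lambda_animal=float(lambda_animal),
        edf_total=edf,
        edf_smooth=edf_smooth,
        smooth_stat=stat,
        smooth_df=r,
        smooth_p=p_smooth,
        deviance=float(dev),
        null_deviance=float(dev0),
        n=n,
    )


def predict_curve(fit: SmoothFit, lve_grid) -> pd.DataFrame:
    """Population-level predicted mean velocity ± delta-method SE on a grid.

    Random intercepts are set to zero. Grid points outside the fitted LVE
    range trigger a warning; predictions clamp the basis at the range edge.
    """
    lve_grid = np.asarray(lve_grid, dtype=float)
    if (lve_grid < fit.lve_lo - 1e-9).any() or (lve_grid > fit.lve_hi + 1e-9).any():
        warnings.warn(
            f"predict_curve: grid extends beyond fitted LVE range "
            f"[{fit.lve_lo:.3g}, {fit.lve_hi:.3g}]; extrapolated values are clamped",
            stacklevel=2,
        )
    eta, se_eta = fit.linear_predictor(lve_grid)
    mean = np.exp(eta)
    return pd.DataFrame(
        {"lve": lve_grid, "mean_velocity": mean, "se": mean * se_eta,
         "eta": eta, "se_eta": se_eta}
    )


def seasonal_velocity_summary(steps: pd.DataFrame) -> pd.DataFrame:
    """Five-number velocity summaries per herd × season (1.5·IQR whiskers)."""
    rows = []
    for (herd, season), g in steps.groupby(["herd", "season"], sort=True):
        v = g["velocity_mh"].dropna().to_numpy()
        if v.size == 0:
            warnings.warn(f"seasonal_velocity_summary: empty cell {herd}/{season}", stacklevel=2)
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo = float(v[v >= q1 - 1.5 * iqr].min())
        hi = float(v[v <= q3 + 1.5 * iqr].max())
        rows.append(
            {"herd": herd, "season": season, "n": v.size, "median": med,
             "q1": q1, "q3": q3, "whisker_low": lo, "whisker_high": hi}
        )
    return pd.DataFrame(rows)


def plot_predicted_curves(fits: list[SmoothFit], path, n_grid: int = 100) -> None:
    """Small-multiple plot of predicted velocity curves ± one SE per season."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(fits), figsize=(4 * len(fits), 3.2), squeeze=False)
    for ax, fit in zip(axes[0], fits):
        grid = np.linspace(fit.lve_lo, fit.lve_hi, n_grid)
        pred = predict_curve(fit, grid)
        ax.plot(pred["lve"], pred["mean_velocity"], color="k")
        ax.plot(pred["lve"], pred["mean_velocity"] + pred["se"], "k--", lw=0.8)
        ax.plot(pred["lve"], np.maximum(pred["mean_velocity"] - pred["se"], 0), "k--", lw=0.8)
        ax.set_title(f"{fit.season} (edf={fit.edf_smooth:.1f}, p={fit.smooth_p:.3g})")
        ax.set_xlabel("LVE")
        ax.set_ylabel("velocity (m/h)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
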