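"""Synthetic scenes and telemetry with known ground truth.

The scene generator works backwards through the analysis model: it first
lays down the *target* LVE field for every year (baseline + planted cluster
trends + Gaussian noise), then inverts the 2-D Gaussian LVE to per-pixel
(NDLI, NDMI) pairs on the matching level set, and finally solves reflectance
band triples reproducing those indices exactly. Recovery tests are therefore
sharp: whatever the pipeline estimates can be compared against the planted
slopes and cluster labels. Inversion targets the *fixed* Gaussian centre, so
recipes carry ``center_mode="fixed"`` parameters.

The track generator emits correlated random walks whose step lengths are
negative-binomial with a mean set by a season-specific response to the local
LVE, mirroring the qualitative seasonal shapes reported for caribou
(near-linear spring decline, threshold declines in summer/winter, a fall
minimum at intermediate LVE).

All randomness derives from a single recipe seed through
``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .errors import RecipeError
from .lve import LveParams
from .movement import LocalEquirect, SeasonCalendar
from .range_stats import HerdRange
from .raster import GridSpec, LichenMask, ReflectanceStack, ScalarRaster


# ---------------------------------------------------------------------------
# Scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterSpec:
    """A disk of pixels sharing one planted LVE trend (LVE units / year)."""

    row: int
    col: int
    radius: float
    trend: float


@dataclass(frozen=True)
class SceneRecipe:
    n_rows: int = 128
    n_cols: int = 128
    cell_size: float = 30.0
    year_start: int = 1984
    year_end: int = 2012
    lichen_fraction: float = 0.9
    clusters: tuple[ClusterSpec, ...] = (
        ClusterSpec(32, 28, 10.0, -0.5),
        ClusterSpec(92, 36, 10.0, -0.5),
        ClusterSpec(36, 96, 10.0, 0.5),
        ClusterSpec(94, 92, 10.0, 0.5),
    )
    noise_sd: float = 1.0
    baseline: float = 40.0
    baseline_variation_sd: float = 3.0
    lve_params: LveParams = field(
        default_factory=lambda: LveParams(
            amplitude=100.0, mu_ndli=0.0, mu_ndmi=0.0,
            sigma_ndli=0.25, sigma_ndmi=0.25, rho=0.3, center_mode="fixed",
        )
    )
    proj_lat0: float = 65.0
    proj_lon0: float = -110.0
    seed: int = 0

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    def grid(self) -> GridSpec:
        proj = LocalEquirect(self.proj_lat0, self.proj_lon0)
        return GridSpec(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            cell_size=self.cell_size,
            origin_x=-self.n_cols / 2.0 * self.cell_size,
            origin_y=self.n_rows / 2.0 * self.cell_size,
            crs_id=proj.crs_id,
        )


@dataclass
class SceneTruth:
    true_slope: np.ndarray
    cluster_label: np.ndarray  # +1 planted positive, −1 planted negative, 0 background
    baseline_field: np.ndarray
    target_lve: dict[int, np.ndarray]


@dataclass
class Scene:
    stack: ReflectanceStack
    mask: LichenMask
    herd_ranges: list[HerdRange]
    truth: SceneTruth
    recipe: SceneRecipe


def invert_indices_to_bands(nd_li: np.ndarray, nd_mi: np.ndarray, s_max: float = 0.25):
    """Solve (green, nir, swir1) in (0, 1] reproducing given index pairs.

    With swir1 = s, green = s(1−NDLI)/(1+NDLI) and nir = s(1+NDMI)/(1−NDMI);
    s is scaled per pixel so all three bands stay at or below ``s_max``.
    """
    nd_li = np.clip(np.asarray(nd_li, dtype=float), -0.97, 0.97)
    nd_mi = np.clip(np.asarray(nd_mi, dtype=float), -0.97, 0.97)
    g_ratio = (1.0 - nd_li) / (1.0 + nd_li)
    n_ratio = (1.0 + nd_mi) / (1.0 - nd_mi)
    s = s_max / np.maximum(np.maximum(g_ratio, n_ratio), 1.0)
    return s * g_ratio, s * n_ratio, s


def lve_to_indices(target: np.ndarray, params: LveParams, phase: np.ndarray):
    """Invert the LVE Gaussian: pick the level-set point at angle ``phase``.

    For u = t cosφ, v = t sinφ the quadratic form gives
    t² (1 − ρ sin 2φ) = 2(1−ρ²) ln(A / L).
    """
    a = params.amplitude
    m = 2.0 * (1.0 - params.rho**2) * np.log(a / np.minimum(target, a * (1 - 1e-12)))
    denom = 1.0 - params.rho * np.sin(2.0 * phase)
    t = np.sqrt(np.maximum(m, 0.0) / denom)
    nd_li = params.mu_ndli + params.sigma_ndli * t * np.cos(phase)
    nd_mi = params.mu_ndmi + params.sigma_ndmi * t * np.sin(phase)
    return nd_li, nd_mi


def make_scene(recipe: SceneRecipe) -> Scene:
    """Build reflectance stack + mask + herd ranges with planted trends."""
    params = recipe.lve_params
    if params.center_mode != "fixed":
        params = replace(params, center_mode="fixed")
    grid = recipe.grid()
    years = recipe.years
    shape = grid.shape
    n_years = len(years)

    ss = np.random.SeedSequence(recipe.seed)
    rng_mask, rng_base, rng_phase, rng_noise, rng_bg = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    is_lichen = rng_mask.random(shape) < recipe.lichen_fraction

    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    true_slope = np.zeros(shape)
    cluster_label = np.zeros(shape, dtype=np.int8)
    for cl in recipe.clusters:
        if not (0 <= cl.row < shape[0] and 0 <= cl.col < shape[1]):
            raise RecipeError(f"cluster centre {cl.row, cl.col} outside grid")
        disk = (rr - cl.row) ** 2 + (cc - cl.col) ** 2 <= cl.radius**2
        true_slope[disk] = cl.trend
        cluster_label[disk] = np.sign(cl.trend)

    base_var = gaussian_filter(rng_base.normal(0.0, 1.0, shape), sigma=10.0)
    sd = base_var.std()
    if sd > 0:
        base_var = base_var / sd * recipe.baseline_variation_sd
    floor_lve = 0.5
    # keep the smoothed baseline inside the representable LVE range; planted
    # slopes are untouched, only the per-pixel intercept saturates
    baseline_field = np.clip(
        recipe.baseline + base_var, floor_lve + 2.0, recipe.lve_params.amplitude * 0.9
    )

    span = n_years - 1
    extreme = np.maximum(baseline_field + true_slope * span, baseline_field)
    if extreme.max() >= params.amplitude:
        raise RecipeError(
            f"planted trends drive target LVE to {extreme.max():.1f} >= "
            f"amplitude {params.amplitude}"
        )
    if np.minimum(baseline_field + true_slope * span, baseline_field).min() <= floor_lve:
        raise RecipeError("planted trends drive target LVE to or below the floor")

    phase = rng_phase.uniform(0.0, 2.0 * np.pi, shape)

    values = np.zeros((n_years, 3, *shape))
    valid = np.ones((n_years, *shape), dtype=bool)
    target_lve: dict[int, np.ndarray] = {}
    bg_li = -0.3 + 0.02 * rng_bg.standard_normal(shape)
    bg_mi = 0.3 + 0.02 * rng_bg.standard_normal(shape)
    for k, year in enumerate(years):
        noise = rng_noise.normal(0.0, recipe.noise_sd, shape) if recipe.noise_sd > 0 else 0.0
        target = np.clip(
            baseline_field + true_slope * k + noise, floor_lve, params.amplitude * 0.999
        )
        target_lve[int(year)] = target
        nd_li, nd_mi = lve_to_indices(target, params, phase)
        nd_li = np.where(is_lichen, nd_li, bg_li)
        nd_mi = np.where(is_lichen, nd_mi, bg_mi)
        green, nir, swir1 = invert_indices_to_bands(nd_li, nd_mi)
        values[k, 0], values[k, 1], values[k, 2] = green, nir, swir1

    stack = ReflectanceStack(
        grid=grid, years=years, bands=("green", "nir", "swir1"), values=values, valid=valid
    )
    mask = LichenMask(grid=grid, is_lichen=is_lichen)

    # two herd ranges with distinct planted trend mixes (west: negative
    # clusters; east: positive clusters under the default cluster layout)
    x0, y1 = grid.origin_x, grid.origin_y
    x1 = x0 + grid.n_cols * grid.cell_size
    y0 = y1 - grid.n_rows * grid.cell_size
    xm = x0 + (grid.n_cols // 2) * grid.cell_size
    herds = [
        HerdRange("herd_west", box(x0, y0, xm, y1)),
        HerdRange("herd_east", box(xm, y0, x1, y1)),
    ]

    truth = SceneTruth(
        true_slope=true_slope,
        cluster_label=cluster_label,
        baseline_field=baseline_field,
        target_lve=target_lve,
    )
    return Scene(stack=stack, mask=mask, herd_ranges=herds, truth=truth, recipe=recipe)


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

RESPONSE_SHAPES = ("flat", "linear_decline", "threshold_decline", "u_shape")


@dataclass(frozen=True)
class SeasonResponse:
    """Mean-velocity response to local LVE for one season.

    shape: flat | linear_decline | threshold_decline | u_shape
    params: shape-specific constants (see :func:`response_mean`)
    """

    shape: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.shape not in RESPONSE_SHAPES:
            raise ValueError(f"unknown response shape {self.shape!r}")


def response_mean(resp: SeasonResponse, lve, base_speed: float):
    """Mean velocity (m/h) for LVE values under a season response."""
    L = np.asarray(lve, dtype=float)
    p = resp.params
    if resp.shape == "flat":
        v = np.full_like(L, base_speed)
    elif resp.shape == "linear_decline":
        hi = p.get("v0_factor", 1.4)
        lo = p.get("v1_factor", 0.5)
        v = base_speed * (hi + (lo - hi) * L / 100.0)
    elif resp.shape == "threshold_decline":
        L0 = p.get("threshold", 25.0)
        drop = p.get("drop", 0.7)
        v = base_speed * np.where(
            L <= L0, 1.0, 1.0 - drop * (L - L0) / max(100.0 - L0, 1e-9)
        )
    else:  # u_shape
        Lmid = p.get("minimum_at", 25.0)
        depth = p.get("depth", 0.5)
        w = p.get("width", 60.0)
        v = base_speed * ((1.0 - depth) + depth * ((L - Lmid) / w) ** 2)
    return np.maximum(v, 0.05 * base_speed)


def default_season_responses() -> dict[str, SeasonResponse]:
    return {
        "spring": SeasonResponse("linear_decline"),
        "summer": SeasonResponse("threshold_decline", {"threshold": 45.0, "drop": 0.7}),
        "fall": SeasonResponse("u_shape", {"minimum_at": 25.0, "depth": 0.5, "width": 60.0}),
        "winter": SeasonResponse("threshold_decline", {"threshold": 25.0, "drop": 0.7}),
    }


@dataclass(frozen=True)
class TrackRecipe:
    n_animals: int = 6
    fix_intervals_hours: tuple[float, ...] = (5.0, 8.0)  # cycled over animals
    start: str = "2008-01-01T00:00:00Z"
    n_days: int = 400
    season_responses: dict = field(default_factory=default_season_responses)
    base_speed: float = 300.0
    overdispersion: float = 5.0  # negative-binomial size of step lengths
    turn_sd_deg: float = 40.0
    cow_fraction: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("need at least one animal")
        if self.base_speed <= 0:
            raise ValueError("base_speed must be positive")


@dataclass
class TrackTruth:
    responses: dict[str, SeasonResponse]
    base_speed: float
    per_fix_mean: pd.DataFrame  # animal_id, timestamp, true_mean_velocity, lve


def make_tracks(
    recipe: TrackRecipe,
    lve_by_year: dict[int, ScalarRaster],
    herd_of=None,
    calendar: SeasonCalendar | None = None,
) -> tuple[pd.DataFrame, TrackTruth]:
    """Correlated random walks with LVE-dependent NB step lengths.

    Each animal starts at a random cell, keeps a persistent heading with
    wrapped-normal turning, and draws each step length (metres) from a
    negative binomial with mean = season_response(local LVE) × Δt and the
    recipe's size parameter. Positions reflect at the raster boundary.
    ``herd_of`` optionally maps a projected (x, y) start position to a herd
    id; by default animals west of the grid midline are "herd_west", the
    rest "herd_east". Deterministic given the recipe seed.
    """
    if not lve_by_year:
        raise ValueError("need at least one yearly LVE raster")
    cal = calendar or SeasonCalendar()
    grid = next(iter(lve_by_year.values())).grid
    proj = LocalEquirect.from_crs_id(grid.crs_id)
    x_min, y_max = grid.origin_x, grid.origin_y
    x_max = x_min + grid.n_cols * grid.cell_size
    y_min = y_max - grid.n_rows * grid.cell_size
    x_mid = 0.5 * (x_min + x_max)
    if herd_of is None:
        herd_of = lambda x, y: "herd_west" if x < x_mid else "herd_east"  # noqa: E731

    ss = np.random.SeedSequence(recipe.seed)
    animal_seeds = ss.spawn(recipe.n_animals)
    start_ts = pd.Timestamp(recipe.start)

    frames = []
    truth_rows = []
    for a in range(recipe.n_animals):
        rng = np.random.default_rng(animal_seeds[a])
        interval = recipe.fix_intervals_hours[a % len(recipe.fix_intervals_hours)]
        n_fixes = int(recipe.n_days * 24 / interval) + 1
        x = rng.uniform(x_min + grid.cell_size, x_max - grid.cell_size)
        y = rng.uniform(y_min + grid.cell_size, y_max - grid.cell_size)
        heading = rng.uniform(0, 2 * np.pi)
        herd = herd_of(x, y)
        sex = "cow" if rng.random() < recipe.cow_fraction else "bull"
        animal_id = f"animal_{a:03d}"
        xs = np.empty(n_fixes)
        ys = np.empty(n_fixes)
        ts = start_ts + pd.to_timedelta(np.arange(n_fixes) * interval, unit="h")
        for i in range(n_fixes):
            xs[i], ys[i] = x, y
            if i == n_fixes - 1:
                break
            year = int(ts[i].year)
            r = lve_by_year.get(year)
            lve_here = np.nan
            if r is not None:
                row, col = r.grid.index_of(x, y)
                if r.grid.contains_index(row, col) and r.valid[row, col]:
                    lve_here = float(r.values[row, col])
            season = cal.assign(ts[i])
            resp = recipe.season_responses.get(season, SeasonResponse("flat"))
            mean_v = (
                float(response_mean(resp, lve_here, recipe.base_speed))
                if np.isfinite(lve_here)
                else recipe.base_speed
            )
            mean_len = mean_v * interval
            p_nb = recipe.overdispersion / (recipe.overdispersion + mean_len)
            step = float(rng.negative_binomial(recipe.overdispersion, p_nb))
            heading = heading + rng.normal(0.0, np.radians(recipe.turn_sd_deg))
            # keep the drawn step length: if the step would exit the raster,
            # redraw the heading (uniform) so velocities stay faithful to the
            # planted mean; clamp only if no direction fits (huge step draw)
            x_new = x + step * np.cos(heading)
            y_new = y + step * np.sin(heading)
            for _ in range(20):
                if x_min <= x_new <= x_max and y_min <= y_new <= y_max:
                    break
                heading = rng.uniform(0.0, 2.0 * np.pi)
                x_new = x + step * np.cos(heading)
                y_new = y + step * np.sin(heading)
            x_new = float(np.clip(x_new, x_min, x_max))
            y_new = float(np.clip(y_new, y_min, y_max))
            truth_rows.append(
                {
                    "animal_id": animal_id,
                    "timestamp": ts[i],
                    "season": season,
                    "lve": lve_here,
                    "true_mean_velocity": mean_v,
                    "step_m": step,
                }
            )
            x, y = x_new, y_new
        lon, lat = proj.inverse(xs, ys)
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": animal_id,
                    "herd": herd,
                    "sex": sex,
                    "timestamp": ts,
                    "lon": lon,
                    "lat": lat,
                }
            )
        )
    telemetry = pd.concat(frames, ignore_index=True)
    truth = TrackTruth(
        responses=dict(recipe.season_responses),
        base_speed=recipe.base_speed,
        per_fix_mean=pd.DataFrame(truth_rows),
    )
    return telemetry, truth


def write_telemetry_csv(telemetry: pd.DataFrame, path) -> None:
    df = telemetry.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    df.to_csv(path, index=False)
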