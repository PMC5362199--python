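"""Telemetry ingestion, QC, step velocities, seasons, and home ranges.

Telemetry is a tidy table with one GPS fix per row: animal_id, herd, sex,
timestamp (UTC), lon, lat. Animals enter the analysis only if they carry at
least one complete year of tracking with a minimum number of fixes every day
(default 3/day, i.e. a maximum time step of eight hours; some animals are
tracked at five-hour steps). Movement is summarised per consecutive-fix step
as velocity (m/h), which puts five- and eight-hour collars on a common
scale. Distances are great-circle (haversine, sphere radius 6,371,000 m).

Seasons are month-day windows partitioning the year. The default calendar
(configurable) brackets the conventional caribou year: spring Apr 16–Jun 7,
summer Jun 8–Sep 7, fall Sep 8–Nov 30, winter Dec 1–Apr 15.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from .errors import InsufficientDataError
from .range_stats import HerdRange
from .raster import ScalarRaster

log = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0

TELEMETRY_COLUMNS = ["animal_id", "herd", "sex", "timestamp", "lon", "lat"]


# ---------------------------------------------------------------------------
# Projection: a minimal local equirectangular CRS for desk-scale scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocalEquirect:
    """Local equirectangular projection centred at (lat0, lon0).

    x = R cos(lat0) Δλ, y = R Δφ (radians). Adequate for desk-scale scenes a
    few tens of kilometres across; the CRS id encodes the centre so rasters
    and telemetry can round-trip through it.
    """

    lat0: float
    lon0: float
    radius: float = EARTH_RADIUS_M

    @property
    def crs_id(self) -> str:
        return f"LOCAL-ER:{self.lat0:.6f}:{self.lon0:.6f}"

    @classmethod
    def from_crs_id(cls, crs_id: str) -> "LocalEquirect":
        parts = crs_id.split(":")
        if len(parts) != 3 or parts[0] != "LOCAL-ER":
            raise ValueError(f"not a LOCAL-ER crs id: {crs_id!r}")
        return cls(lat0=float(parts[1]), lon0=float(parts[2]))

    def forward(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        x = self.radius * np.cos(np.radians(self.lat0)) * np.radians(lon - self.lon0)
        y = self.radius * np.radians(lat - self.lat0)
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lon = self.lon0 + np.degrees(x / (self.radius * np.cos(np.radians(self.lat0))))
        lat = self.lat0 + np.degrees(y / self.radius)
        return lon, lat


def haversine_m(lon1, lat1, lon2, lat2, radius: float = EARTH_RADIUS_M):
    """Great-circle distance in metres between (lon, lat) points in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * radius * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# Seasons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeasonCalendar:
    """Four inclusive month-day windows partitioning the year.

    ``windows`` maps season name -> ((start_month, start_day),
    (end_month, end_day)); a window may wrap past Dec 31 (winter does by
    default). Construction verifies that all 366 possible days are covered
    exactly once.
    """

    windows: dict = field(
        default_factory=lambda: {
            "spring": ((4, 16), (6, 7)),
            "summer": ((6, 8), (9, 7)),
            "fall": ((9, 8), (11, 30)),
            "winter": ((12, 1), (4, 15)),
        }
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "_lookup", self._build_lookup())

    def _build_lookup(self) -> dict:
        # use leap reference year 2000 so Feb 29 is covered
        days = pd.date_range("2000-01-01", "2000-12-31", freq="D")
        lookup: dict[tuple[int, int], str] = {}
        for season, ((sm, sd), (em, ed)) in self.windows.items():
            start = (sm, sd)
            end = (em, ed)
            for d in days:
                md = (d.month, d.day)
                inside = (start <= md <= end) if start <= end else (md >= start or md <= end)
                if inside:
                    if md in lookup:
                        raise ValueError(f"day {md} covered by {lookup[md]} and {season}")
                    lookup[md] = season
        if len(lookup) != 366:
            missing = {(d.month, d.day) for d in days} - set(lookup)
            raise ValueError(f"season calendar leaves days uncovered: {sorted(missing)[:5]}")
        return lookup

    def assign(self, ts) -> str:
        ts = pd.Timestamp(ts)
        return self._lookup[(ts.month, ts.day)]


def assign_season(ts, cal: SeasonCalendar | None = None) -> str:
    """Season of a timestamp under the given (or default) calendar."""
    return (cal or SeasonCalendar()).assign(ts)


# ---------------------------------------------------------------------------
# Telemetry I/O and QC
# ---------------------------------------------------------------------------

def read_telemetry(path) -> pd.DataFrame:
    """Read a telemetry CSV, validate ranges, and sort by animal and time."""
    df = pd.read_csv(path)
    missing = [c for c in TELEMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: telemetry is missing columns {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    if not df["lat"].between(-90, 90).all() or not df["lon"].between(-180, 180).all():
        raise ValueError(f"{path}: coordinates out of range")
    return df.sort_values(["animal_id", "timestamp"], kind="mergesort").reset_index(drop=True)


def qc_filter(
    telemetry: pd.DataFrame,
    min_fixes_per_day: int = 3,
    require_complete_year: bool = True,
) -> pd.DataFrame:
    """Retain animals with ≥365 consecutive days all having ≥min fixes/day.

    With ``require_complete_year=False`` only the daily-minimum rule is
    applied (an animal passes if its best day streak is ≥ 1). Dropped
    animals are logged with the reason.
    """
    keep = []
    for animal, g in telemetry.groupby("animal_id", sort=False):
        days = g["timestamp"].dt.floor("D")
        counts = days.value_counts().sort_index()
        good = counts[counts >= min_fixes_per_day]
        if good.empty:
            log.info("qc_filter: dropping %s (no day with >= %d fixes)", animal, min_fixes_per_day)
            continue
        if require_complete_year:
            ordinals = np.sort(np.array([d.toordinal() for d in good.index.date]))
            # longest run of consecutive calendar days
            breaks = np.nonzero(np.diff(ordinals) != 1)[0]
            run_bounds = np.concatenate([[-1], breaks, [len(ordinals) - 1]])
            longest = int(np.max(np.diff(run_bounds)))
            if longest < 365:
                log.info(
                    "qc_filter: dropping %s (longest qualifying streak %d days < 365)",
                    animal, longest,
                )
                continue
        keep.append(animal)
    return telemetry[telemetry["animal_id"].isin(keep)].reset_index(drop=True)


def step_velocities(
    telemetry: pd.DataFrame,
    max_dt_hours: float = 8.0,
    dt_tolerance_hours: float = 1.0,
    calendar: SeasonCalendar | None = None,
) -> pd.DataFrame:
    """Per-animal consecutive-fix step table with velocities and seasons.

    Steps longer than ``max_dt_hours + dt_tolerance_hours`` (gaps) and
    duplicate-timestamp steps are excluded and logged. Season and year come
    from the step's start fix.
    """
    cal = calendar or SeasonCalendar()
    limit = max_dt_hours + dt_tolerance_hours
    out = []
    for animal, g in telemetry.groupby("animal_id", sort=False):
        g = g.sort_values("timestamp", kind="mergesort")
        if len(g) < 2:
            continue
        ts = pd.to_datetime(g["timestamp"], utc=True)
        t = ts.dt.tz_localize(None).to_numpy(dtype="datetime64[ns]")
        lon = g["lon"].to_numpy(dtype=float)
        lat = g["lat"].to_numpy(dtype=float)
        dt_h = ((t[1:] - t[:-1]) / np.timedelta64(1, "h")).astype(float)
        dup = dt_h <= 0
        if dup.any():
            log.warning("step_velocities: %s has %d non-increasing steps, skipped", animal, int(dup.sum()))
        gap = dt_h > limit
        ok = ~dup & ~gap
        if gap.any():
            log.info("step_velocities: %s: %d steps exceed %.1f h, excluded", animal, int(gap.sum()), limit)
        dist = haversine_m(lon[:-1], lat[:-1], lon[1:], lat[1:])
        starts = g["timestamp"].iloc[:-1]
        df = pd.DataFrame(
            {
                "animal_id": animal,
                "herd": g["herd"].iloc[0],
                "sex": g["sex"].iloc[0],
                "t_start": starts.values,
                "t_end": g["timestamp"].iloc[1:].values,
                "dt_h": dt_h,
                "distance_m": dist,
                "velocity_mh": np.where(dt_h > 0, dist / np.where(dt_h > 0, dt_h, 1.0), np.nan),
                "lon": lon[:-1],
                "lat": lat[:-1],
            }
        )[ok]
        out.append(df)
    if not out:
        return pd.DataFrame(
            columns=["animal_id", "herd", "sex", "t_start", "t_end", "dt_h",
                     "distance_m", "velocity_mh", "lon", "lat", "season", "year"]
        )
    steps = pd.concat(out, ignore_index=True)
    ts = pd.to_datetime(steps["t_start"], utc=True)
    steps["season"] = [cal.assign(x) for x in ts]
    steps["year"] = ts.dt.year
    return steps


def mcp_95(
    telemetry: pd.DataFrame,
    projection: LocalEquirect,
    herd_id: str | None = None,
    retention: float = 0.95,
) -> HerdRange:
    """Minimum convex polygon home range at the given retention fraction.

    Removes the (1 − retention) fraction of fixes farthest from the
    arithmetic mean of the projected coordinates, then takes the convex hull.
    """
    if len(telemetry) < 3:
        raise InsufficientDataError("MCP needs at least three fixes")
    x, y = projection.forward(telemetry["lon"].to_numpy(), telemetry["lat"].to_numpy())
    cx, cy = x.mean(), y.mean()
    d = np.hypot(x - cx, y - cy)
    n_keep = max(3, int(math.ceil(retention * len(d))))
    order = np.argsort(d, kind="stable")[:n_keep]
    hull = MultiPoint(list(zip(x[order], y[order]))).convex_hull
    if hull.area == 0:
        log.warning("mcp_95: degenerate (collinear) fixes produce a zero-area hull")
        hull = hull.buffer(1e-6)
    hid = herd_id if herd_id is not None else str(telemetry["herd"].iloc[0])
    return HerdRange(herd_id=hid, polygon=hull)


def extract_lve_at_fixes(
    steps: pd.DataFrame,
    lve_by_year: dict[int, ScalarRaster],
    projection: LocalEquirect,
    column: str = "lve_at_start",
) -> pd.DataFrame:
    """Attach the LVE of the raster cell containing each step's start fix.

    The matching year's raster is used; missing year, out-of-extent fix, or
    invalid cell all yield a missing value.
    """
    steps = steps.copy()
    vals = np.full(len(steps), np.nan)
    x, y = projection.forward(steps["lon"].to_numpy(), steps["lat"].to_numpy())
    years = steps["year"].to_numpy()
    for year in np.unique(years):
        r = lve_by_year.get(int(year))
        if r is None:
            log.info("extract_lve_at_fixes: no LVE raster for year %d", year)
            continue
        sel = years == year
        row, col = r.grid.index_of(x[sel], y[sel])
        inb = r.grid.contains_index(row, col)
        out = np.full(int(sel.sum()), np.nan)
        rr, cc = row[inb], col[inb]
        ok = r.valid[rr, cc]
        tmp = np.full(len(rr), np.nan)
        tmp[ok] = r.values[rr, cc][ok]
        out[inb] = tmp
        vals[sel] = out
    steps[column] = vals
    return steps
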