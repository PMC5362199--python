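"""End-to-end orchestration: scene → LVE → trend → hotspot → herd tables,
and telemetry → steps → seasonal association, with a run manifest.

The manifest records the configuration hash, seeds and SHA-256 checksums of
every artifact, making each stage auditable as a pure function of (inputs,
config, seed). Stage timings go to a separate ``timings.txt`` so the
manifest itself is byte-identical across reruns with the same config and
seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import lve as lve_mod
from . import movement as mov
from . import range_stats as rs
from . import synthetic as synth
from . import trend as trend_mod
from .hotspot import gi_star
from .lve import LveParams
from .raster import ScalarRaster, read_mask, read_stack, write_mask, write_raster

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "output_dir": "lichentrend_out",
    "synthetic": {"scene": {}, "tracks": {}},
    "inputs": {},
    "lve": {"params": {}, "per_year_center": True},
    "trend": {"alpha": 0.05, "min_years": 10},
    "hotspot": {"z_crit": 1.96},
    "ranges": {"n_samples": 200},
    "movement": {"max_dt_hours": 8.0, "min_fixes_per_day": 3, "require_complete_year": True},
    "association": {"n_basis": 8, "min_steps": 50, "min_animals": 3},
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _class_raster(codes: np.ndarray, valid: np.ndarray, grid) -> ScalarRaster:
    return ScalarRaster(grid=grid, values=np.where(valid, codes, 0.0), valid=valid)


def run_all(config: dict, progress: bool = False) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    cfg = merge_config(config)
    seed = int(cfg["seed"])
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    counters: dict = {}
    timings: list[tuple[str, float]] = []

    def stage(name):
        timings.append((name, time.perf_counter()))
        if progress:
            log.info("stage: %s", name)

    ss = np.random.SeedSequence(seed)
    seed_scene, seed_tracks, seed_samples = [int(s.generate_state(1)[0] >> 1) for s in ss.spawn(3)]

    # --- inputs: synthetic scene or files -------------------------------
    stage("inputs")
    inputs = cfg.get("inputs") or {}
    if inputs.get("stack_paths"):
        stack = read_stack(inputs["stack_paths"], inputs["band_map"])
        mask = read_mask(inputs["mask_path"])
        herds = rs.read_herd_ranges(inputs["herds_path"])
        truth = None
        params = LveParams(**cfg["lve"].get("params", {}))
    else:
        scene_cfg = dict(cfg["synthetic"].get("scene") or {})
        clusters = scene_cfg.pop("clusters", None)
        lve_params = scene_cfg.pop("lve_params", None)
        kwargs = dict(scene_cfg)
        if clusters is not None:
            kwargs["clusters"] = tuple(synth.ClusterSpec(**c) for c in clusters)
        if lve_params is not None:
            kwargs["lve_params"] = LveParams(**lve_params)
        recipe = synth.SceneRecipe(seed=seed_scene, **kwargs)
        scene = synth.make_scene(recipe)
        stack, mask, herds, truth = scene.stack, scene.mask, scene.herd_ranges, scene.truth
        params = recipe.lve_params
        write_mask(mask, out / "lichen_mask.tif")
        rs.write_herd_ranges(herds, out / "herd_ranges.geojson")
        write_raster(
            ScalarRaster(grid=stack.grid, values=truth.true_slope,
                         valid=np.ones(stack.grid.shape, dtype=bool)),
            out / "true_slope.tif",
        )
        outputs += [out / "lichen_mask.tif", out / "herd_ranges.geojson", out / "true_slope.tif"]
    counters["n_years"] = len(stack.years)
    counters["n_lichen_pixels"] = int(mask.is_lichen.sum())

    # --- LVE -------------------------------------------------------------
    stage("lve")
    lve_by_year = lve_mod.lve_stack(
        stack, mask, params, per_year_center=bool(cfg["lve"].get("per_year_center", True))
    )
    lve_dir = out / "lve"
    lve_dir.mkdir(exist_ok=True)
    for year, r in lve_by_year.items():
        p = lve_dir / f"lve_{year}.tif"
        write_raster(r, p, meta={"year": year})
        outputs.append(p)

    # --- trend -----------------------------------------------------------
    stage("trend")
    tr = trend_mod.trend_raster(
        lve_by_year,
        alpha=float(cfg["trend"]["alpha"]),
        min_years=int(cfg["trend"]["min_years"]),
    )
    slope_r = tr.slope_raster()
    for name, arr in [("slope", tr.slope), ("mk_z", tr.mk_z), ("mk_p", tr.p_value)]:
        p = out / f"{name}.tif"
        write_raster(
            ScalarRaster(grid=tr.grid, values=np.where(tr.valid, arr, 0.0), valid=tr.valid), p
        )
        outputs.append(p)
    p = out / "change_class.tif"
    write_raster(_class_raster(tr.change_class, tr.valid, tr.grid), p)
    outputs.append(p)
    counters["n_trend_valid"] = int(tr.valid.sum())

    # --- hotspot ---------------------------------------------------------
    stage("hotspot")
    hs = gi_star(slope_r, z_crit=float(cfg["hotspot"]["z_crit"]))
    p = out / "gi_z.tif"
    write_raster(
        ScalarRaster(grid=hs.grid, values=np.where(hs.valid, hs.gi_z, 0.0), valid=hs.valid), p
    )
    outputs.append(p)
    p = out / "cluster_class.tif"
    write_raster(_class_raster(hs.cluster_class, hs.valid, hs.grid), p)
    outputs.append(p)

    # --- zonal tables ----------------------------------------------------
    stage("ranges")
    table1 = rs.zonal_class_percentages(tr, mask, herds)
    table2 = rs.zonal_class_percentages(hs, mask, herds)
    _write_csv(table1, out / "trend_class_by_herd.csv")
    _write_csv(table2, out / "cluster_class_by_herd.csv")
    outputs += [out / "trend_class_by_herd.csv", out / "cluster_class_by_herd.csv"]

    n_samples = int(cfg["ranges"]["n_samples"])
    samples = pd.concat(
        [
            rs.stratified_sample(slope_r, h, n_samples, seed_samples + i)
            for i, h in enumerate(herds)
        ],
        ignore_index=True,
    )
    _write_csv(samples, out / "slope_samples.csv")
    outputs.append(out / "slope_samples.csv")
    fit = rs.gls_herd_model(samples, correlation="gaussian")
    gls_df = pd.DataFrame(
        [
            {
                "correlation": fit.correlation,
                "correlation_range_m": fit.correlation_range,
                "nugget": fit.nugget,
                "loglik_spatial": fit.loglik_spatial,
                "loglik_indep": fit.loglik_indep,
                "lr_statistic": fit.lr_statistic,
                "lr_p": fit.lr_p,
                "f_statistic": fit.f_statistic,
                "f_p": fit.f_p,
                "df_num": fit.df_num,
                "df_den": fit.df_den,
            }
        ]
    )
    _write_csv(gls_df, out / "gls_fit.csv")
    _write_csv(fit.means_table(), out / "herd_means.csv")
    _write_csv(rs.tukey_pairwise(fit), out / "tukey_pairs.csv")
    outputs += [out / "gls_fit.csv", out / "herd_means.csv", out / "tukey_pairs.csv"]

    # --- movement --------------------------------------------------------
    stage("movement")
    if inputs.get("telemetry_path"):
        telemetry = mov.read_telemetry(inputs["telemetry_path"])
    else:
        track_cfg = dict(cfg["synthetic"].get("tracks") or {})
        track_recipe = synth.TrackRecipe(seed=seed_tracks, **track_cfg)
        telemetry, _ = synth.make_tracks(track_recipe, lve_by_year)
        synth.write_telemetry_csv(telemetry, out / "telemetry.csv")
        outputs.append(out / "telemetry.csv")
    mv = cfg["movement"]
    retained = mov.qc_filter(
        telemetry,
        min_fixes_per_day=int(mv["min_fixes_per_day"]),
        require_complete_year=bool(mv["require_complete_year"]),
    )
    counters["n_animals_in"] = int(telemetry["animal_id"].nunique())
    counters["n_animals_retained"] = int(retained["animal_id"].nunique())
    steps = mov.step_velocities(retained, max_dt_hours=float(mv["max_dt_hours"]))
    proj = mov.LocalEquirect.from_crs_id(stack.grid.crs_id)
    steps = mov.extract_lve_at_fixes(steps, lve_by_year, proj)
    _write_csv(steps, out / "steps.csv")
    outputs.append(out / "steps.csv")
    counters["n_steps"] = int(len(steps))

    _write_csv(assoc.seasonal_velocity_summary(steps), out / "velocity_summary.csv")
    outputs.append(out / "velocity_summary.csv")

    # --- association -----------------------------------------------------
    stage("association")
    ac = cfg["association"]
    fits = []
    for season in ("spring", "summer", "fall", "winter"):
        sub = steps[steps["season"] == season]
        try:
            f = assoc.fit_velocity_smooth(
                sub,
                n_basis=int(ac["n_basis"]),
                min_steps=int(ac["min_steps"]),
                min_animals=int(ac["min_animals"]),
            )
        except Exception as exc:  # data-dependent: a season may be too thin
            log.info("association: skipping %s (%s)", season, exc)
            continue
        fits.append(f)
        grid = np.linspace(f.lve_lo, f.lve_hi, 100)
        _write_csv(
            assoc.predict_curve(f, grid)[["lve", "mean_velocity", "se"]],
            out / f"curve_{season}.csv",
        )
        outputs.append(out / f"curve_{season}.csv")
    if fits:
        assoc.plot_predicted_curves(fits, out / "velocity_curves.png")
        outputs.append(out / "velocity_curves.png")
    counters["n_seasons_fit"] = len(fits)

    # --- manifest --------------------------------------------------------
    stage("manifest")
    cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()
    manifest = {
        "config_hash": cfg_hash,
        "seed": seed,
        "stage_seeds": {"scene": seed_scene, "tracks": seed_tracks, "samples": seed_samples},
        "counters": counters,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    now = time.perf_counter()
    with open(out / "timings.txt", "w") as fh:
        for (name, t0), (_, t1) in zip(timings, timings[1:] + [("end", now)]):
            fh.write(f"{name}\t{t1 - t0:.3f}s\n")
    return manifest
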