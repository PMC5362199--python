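# lichentrend

Terricolous lichen mats (chiefly *Cladonia* spp.) are the key winter forage
of barren ground caribou (*Rangifer tarandus groenlandicus*). `lichentrend`
is a desk-scale, fully tested pipeline for asking two questions of an annual
multiband reflectance time series over lichen tundra:

1. **Where and how is lichen mat volume changing?** A relative lichen volume
   estimate (LVE) is computed per pixel and year from two spectral indices,
   its temporal trend is estimated robustly, and trends are screened for
   local spatial clustering and summarised per caribou herd range.
2. **Does lichen volume shape caribou movement?** GPS telemetry is reduced to
   step velocities and modelled per season against the LVE at each fix with
   an overdispersed smooth mixed model.

It is aimed at remote-sensing ecologists and movement ecologists who want
the full chain — index → trend → cluster → zonal comparison → behaviour —
as reproducible, seedable library calls rather than a GIS point-and-click
workflow. Because the imagery and collar data such studies use are rarely
redistributable, the package ships a synthetic-data generator that inverts
the analysis model exactly, so every stage can be exercised and validated
against known ground truth.

## The methods in brief

**Spectral scoring.** With surface reflectance bands green, NIR, SWIR1:

    NDLI = (SWIR1 − green)/(SWIR1 + green)
    NDMI = (NIR − SWIR1)/(NIR + SWIR1)
    LVE  = A · exp( −[u² − 2ρuv + v²] / (2(1−ρ²)) ),
           u = (NDLI − c₁)/σ₁,  v = (NDMI − c₂)/σ₂

where the centre c is either fixed or the scene-wide masked index mean. The
Gaussian coefficients must be supplied by the user; the defaults are
placeholders, and outputs are a *relative* index, not litres of lichen.

**Trend.** Per pixel over the yearly LVE stack: the Theil–Sen slope (median
of all pairwise slopes) and the Mann–Kendall test with tie-corrected
variance and continuity correction, classified at α = 0.05 into
increasing / decreasing / no change.

**Clustering.** The Getis–Ord G_i\* statistic on the slope raster with a
3×3 Queen's-case kernel (focal pixel included), standardised against the
whole-image mean and deviation; |z| > 1.96 marks positive/negative cluster
centres.

**Herd comparison.** Classes are tabulated per herd polygon; slopes are
sampled with a spatially stratified design (1000 points per herd at study
scale) and compared with a single-factor GLS whose errors carry a Gaussian
spatial correlation, corr(d) = (1−n₀)·exp(−(d/r)²), against the independent
fit via a likelihood ratio, with Tukey HSD pairwise contrasts.

**Movement.** Animals need a complete tracked year at ≥3 fixes/day; step
velocity (m/h, haversine distance over elapsed time) is modelled per season
as velocity ~ NegBin(exp(β₀ + s(LVE) + b_animal), θ) with a penalized cubic
B-spline s and ridge-shrunk per-animal intercepts.

## Worked example

```python
import numpy as np
import lichentrend as lt

scene = lt.make_scene(lt.SceneRecipe(seed=101))       # 128×128, 1984–2012
lve   = lt.lve_stack(scene.stack, scene.mask, scene.recipe.lve_params)
tr    = lt.trend_raster(lve, alpha=0.05)
hs    = lt.gi_star(tr.slope_raster(), z_crit=1.96)

err = np.abs(tr.slope - scene.truth.true_slope)[tr.valid]
print(f"median |slope error| = {np.median(err):.4f} LVE/yr")
print(lt.zonal_class_percentages(tr, scene.mask, scene.herd_ranges)
        [["herd_id", "pct_increasing", "pct_decreasing", "pct_no_change"]])
```

prints

```
median |slope error| = 0.0159 LVE/yr
     herd_id  pct_increasing  pct_decreasing  pct_no_change
0  herd_west        2.189781       10.097324      87.712895
1  herd_east        9.905982        2.343644      87.750375
```

The planted ±0.5 LVE/yr disks are recovered to ≈0.016 LVE/yr at noise
σ = 1, and the herd planted with positive clusters (east) shows the excess
of significantly increasing pixels, mirroring the west's excess of
decreasing ones.

The same flow is available from the shell:

```bash
lichentrend run-all --seed 5 --out results_dir
lichentrend synth scene --seed 7 --out scene_dir
lichentrend trend --lve-dir scene_lve --alpha 0.05 --min-years 10 --out trend_dir
```

`run-all` executes scene → LVE → trend → hotspot → herd tables and
telemetry → steps → seasonal smooths, writing a manifest with the config
hash, seeds and SHA-256 of every artifact; reruns with the same config and
seed are byte-identical.

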