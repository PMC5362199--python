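"""Shared fixtures: synthetic scenes and derived products, built once."""

import numpy as np
import pytest

import lichentrend as lt
from lichentrend import movement as mov


@pytest.fixture(scope="session")
def trend_scene():
    """Default 128×128 × 29-year scene with planted ±0.5 LVE/yr clusters."""
    return lt.make_scene(lt.SceneRecipe(seed=101))


@pytest.fixture(scope="session")
def trend_scene_lve(trend_scene):
    return lt.lve_stack(trend_scene.stack, trend_scene.mask, trend_scene.recipe.lve_params)


@pytest.fixture(scope="session")
def trend_scene_trend(trend_scene_lve):
    return lt.trend_raster(trend_scene_lve)


@pytest.fixture(scope="session")
def movement_scene():
    """Coarser (250 m) trend-free scene with wide LVE spread for tracks."""
    return lt.make_scene(
        lt.SceneRecipe(
            seed=202, cell_size=250.0, baseline=45.0, baseline_variation_sd=12.0, clusters=()
        )
    )


@pytest.fixture(scope="session")
def movement_scene_lve(movement_scene):
    return lt.lve_stack(
        movement_scene.stack, movement_scene.mask, movement_scene.recipe.lve_params
    )


@pytest.fixture(scope="session")
def movement_projection(movement_scene):
    return mov.LocalEquirect.from_crs_id(movement_scene.stack.grid.crs_id)


def small_grid(n_rows=5, n_cols=5, cell=30.0):
    return lt.GridSpec(
        n_rows=n_rows, n_cols=n_cols, cell_size=cell,
        origin_x=0.0, origin_y=n_rows * cell, crs_id="LOCAL-ER:65.000000:-110.000000",
    )


@pytest.fixture
def grid5():
    return small_grid()
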