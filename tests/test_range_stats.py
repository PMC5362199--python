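"""Zonal summaries, stratified sampling, GLS herd comparison, Tukey HSD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from shapely.geometry import box

import lichentrend as lt
from lichentrend import range_stats as rs
from lichentrend.errors import EmptyDomainError, InsufficientDataError
from lichentrend.trend import CLASS_DECREASING, CLASS_INCREASING, CLASS_NO_CHANGE

from conftest import small_grid


def trend_like(grid, codes, valid=None):
    codes = np.asarray(codes, dtype=np.int8)
    if valid is None:
        valid = np.ones(codes.shape, bool)
    return lt.TrendRaster(
        grid=grid, slope=codes.astype(float), mk_s=codes.astype(float),
        mk_z=codes.astype(float), p_value=np.zeros(codes.shape),
        change_class=codes, valid=valid,
    )


class TestZonal:
    def test_four_pixel_counting(self):
        grid = small_grid(2, 2)
        codes = np.array(
            [[CLASS_INCREASING, CLASS_INCREASING], [CLASS_DECREASING, CLASS_NO_CHANGE]]
        )
        mask = lt.LichenMask(grid=grid, is_lichen=np.ones((2, 2), bool))
        herd = rs.HerdRange("h", box(0.0, 0.0, 60.0, 60.0))
        out = lt.zonal_class_percentages(trend_like(grid, codes), mask, [herd])
        row = out.iloc[0]
        assert row.pct_increasing == pytest.approx(50.0)
        assert row.pct_decreasing == pytest.approx(25.0)
        assert row.pct_no_change == pytest.approx(25.0)

    def test_percentages_sum_to_100_and_counts_partition(self, trend_scene, trend_scene_trend):
        out = lt.zonal_class_percentages(
            trend_scene_trend, trend_scene.mask, trend_scene.herd_ranges
        )
        for _, row in out.iterrows():
            assert row.pct_increasing + row.pct_decreasing + row.pct_no_change == pytest.approx(
                100.0, abs=0.01
            )
            assert row.n_increasing + row.n_decreasing + row.n_no_change == row.n_pixels

    def test_range_disjoint_from_mask_raises(self):
        grid = small_grid(2, 2)
        codes = np.zeros((2, 2), np.int8)
        mask = lt.LichenMask(grid=grid, is_lichen=np.ones((2, 2), bool))
        herd = rs.HerdRange("far", box(1e6, 1e6, 2e6, 2e6))
        with pytest.raises(EmptyDomainError):
            lt.zonal_class_percentages(trend_like(grid, codes), mask, [herd])


class TestStratifiedSample:
    def _slopes(self, n=20):
        grid = lt.GridSpec(n, n, 30.0, 0.0, n * 30.0, "LOCAL-ER:65.000000:-110.000000")
        rng = np.random.default_rng(20)
        return lt.ScalarRaster(
            grid=grid, values=rng.normal(0, 1, (n, n)), valid=np.ones((n, n), bool)
        )

    def test_deterministic_given_seed(self):
        slopes = self._slopes()
        herd = rs.HerdRange("h", box(0, 0, 600, 600))
        a = lt.stratified_sample(slopes, herd, 50, seed=7)
        b = lt.stratified_sample(slopes, herd, 50, seed=7)
        pd.testing.assert_frame_equal(a, b)
        c = lt.stratified_sample(slopes, herd, 50, seed=8)
        assert not a.equals(c)

    def test_n4_uniform_square_one_per_quadrant(self):
        slopes = self._slopes()
        herd = rs.HerdRange("h", box(0, 0, 600, 600))
        s = lt.stratified_sample(slopes, herd, 4, seed=1)
        assert len(s) == 4
        quad = set(zip(s.x > 300, s.y > 300))
        assert len(quad) == 4

    def test_allocation_proportional_largest_remainder(self):
        counts = np.array([10, 10, 10, 70])
        alloc = rs.largest_remainder_allocation(counts, 10)
        assert alloc.sum() == 10
        np.testing.assert_array_equal(alloc, [1, 1, 1, 7])
        alloc = rs.largest_remainder_allocation(np.array([1, 1, 1]), 2)
        assert alloc.sum() == 2 and alloc.max() == 1

    def test_insufficient_pixels_raise(self):
        slopes = self._slopes(4)
        herd = rs.HerdRange("h", box(0, 0, 120, 120))
        with pytest.raises(InsufficientDataError):
            lt.stratified_sample(slopes, herd, 1000, seed=1)

    def test_points_fall_inside_polygon_and_on_valid_pixels(self):
        slopes = self._slopes()
        slopes.valid[:, :5] = False
        herd = rs.HerdRange("h", box(100, 100, 500, 500))
        s = lt.stratified_sample(slopes, herd, 30, seed=2)
        assert (s.x > 100).all() and (s.x < 500).all()
        assert slopes.valid[s.row, s.col].all()


def _herd_samples(rng, means, n=30, spread=1.0):
    frames = []
    for k, (herd, mu) in enumerate(means.items()):
        frames.append(
            pd.DataFrame(
                {
                    "herd_id": herd,
                    "x": rng.uniform(k * 1000, (k + 1) * 1000, n),
                    "y": rng.uniform(0, 1000, n),
                    "slope": rng.normal(mu, spread, n),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestGls:
    def test_independent_fit_reproduces_group_means(self):
        rng = np.random.default_rng(21)
        df = _herd_samples(rng, {"a": 0.1, "b": 0.0, "c": -0.2})
        fit = lt.gls_herd_model(df, correlation="none")
        for herd, mean in zip(fit.herds, fit.group_means):
            assert mean == pytest.approx(df[df.herd_id == herd].slope.mean(), abs=1e-12)
        assert fit.lr_statistic >= 0

    def test_known_unequal_means_recovered(self):
        rng = np.random.default_rng(22)
        df = _herd_samples(rng, {"a": 0.5, "b": 0.0}, n=80, spread=0.3)
        fit = lt.gls_herd_model(df, correlation="gaussian")
        se = np.sqrt(np.diag(fit.cov_means))
        assert abs(fit.group_means[fit.herds.index("a")] - 0.5) < 2 * se[fit.herds.index("a")]
        assert abs(fit.group_means[fit.herds.index("b")] - 0.0) < 2 * se[fit.herds.index("b")]
        assert fit.f_p < 0.001

    def test_spatially_correlated_errors_detected(self):
        """LR favours the Gaussian structure when noise really is correlated."""
        rng = np.random.default_rng(23)
        from scipy.spatial.distance import pdist, squareform

        xs, ys, herds = [], [], []
        for k, h in enumerate(["a", "b"]):
            xs.append(rng.uniform(k * 1000, (k + 1) * 1000, 60))
            ys.append(rng.uniform(0, 1000, 60))
            herds += [h] * 60
        x, y = np.concatenate(xs), np.concatenate(ys)
        D = squareform(pdist(np.c_[x, y]))
        C = 0.8 * np.exp(-((D / 300) ** 2)) + 0.2 * np.eye(len(x))
        np.fill_diagonal(C, 1.0)
        z = np.linalg.cholesky(C) @ rng.standard_normal(len(x))
        df = pd.DataFrame({"herd_id": herds, "x": x, "y": y, "slope": z})
        fit = lt.gls_herd_model(df, correlation="gaussian")
        assert fit.lr_statistic > 10
        assert fit.lr_p < 0.01


class TestTukey:
    def test_two_groups_equal_unadjusted_t(self):
        rng = np.random.default_rng(24)
        df = _herd_samples(rng, {"a": 0.2, "b": 0.0}, n=25)
        fit = lt.gls_herd_model(df, correlation="none")
        pairs = lt.tukey_pairwise(fit)
        diff = pairs.estimate.iloc[0]
        se = pairs.se.iloc[0]
        t = abs(diff) / se
        p_t = 2 * stats.t.sf(t, fit.df_den)
        assert pairs.p_adj.iloc[0] == pytest.approx(p_t, abs=1e-6)

    def test_identical_groups_give_p_near_one(self):
        rng = np.random.default_rng(25)
        base = rng.normal(0, 1, 30)
        frames = []
        for k, herd in enumerate(["a", "b", "c"]):
            frames.append(
                pd.DataFrame(
                    {
                        "herd_id": herd,
                        "x": rng.uniform(k * 1000, (k + 1) * 1000, 30),
                        "y": rng.uniform(0, 1000, 30),
                        "slope": base,
                    }
                )
            )
        fit = lt.gls_herd_model(pd.concat(frames, ignore_index=True), correlation="none")
        pairs = lt.tukey_pairwise(fit)
        assert (pairs.p_adj >= 0.999).all()

    def test_three_group_p_matches_studentized_range_simulation(self):
        """Adjusted p agrees with a Monte-Carlo studentized-range evaluation."""
        rng = np.random.default_rng(26)
        df = _herd_samples(rng, {"a": 0.6, "b": 0.0, "c": 0.05}, n=30, spread=0.8)
        fit = lt.gls_herd_model(df, correlation="none")
        pairs = lt.tukey_pairwise(fit)
        k, dfree = 3, fit.df_den
        sim = np.random.default_rng(27)
        # null distribution of the max studentized pairwise |t|·sqrt(2)
        draws = sim.standard_normal((4000, k))
        chi = np.sqrt(sim.chisquare(dfree, 4000) / dfree)
        q_null = (draws.max(axis=1) - draws.min(axis=1)) / chi
        for _, row in pairs.iterrows():
            p_mc = (q_null >= row.q).mean()
            assert row.p_adj == pytest.approx(p_mc, abs=0.02)


def test_semivariogram_increases_for_correlated_field():
    rng = np.random.default_rng(28)
    from scipy.spatial.distance import pdist, squareform

    pts = rng.uniform(0, 1000, (150, 2))
    D = squareform(pdist(pts))
    C = np.exp(-((D / 300) ** 2))
    np.fill_diagonal(C, 1.0)
    z = np.linalg.cholesky(C + 1e-8 * np.eye(150)) @ rng.standard_normal(150)
    sv = lt.empirical_semivariogram(pts, z, n_bins=6)
    assert sv.gamma.iloc[0] < sv.gamma.iloc[-1]


def test_herd_ranges_geojson_round_trip(tmp_path):
    herds = [
        rs.HerdRange("west", box(0, 0, 100, 100)),
        rs.HerdRange("east", box(100, 0, 200, 100)),
    ]
    path = tmp_path / "herds.geojson"
    rs.write_herd_ranges(herds, path)
    back = rs.read_herd_ranges(path)
    assert [h.herd_id for h in back] == ["west", "east"]
    assert back[0].polygon.equals(herds[0].polygon)
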