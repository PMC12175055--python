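"""Sea-ice covariate derivation and PCA."""

import numpy as np
import pandas as pd
import pytest

from sealsync import phenology as ph


class TestDailyAggregates:
    def test_extent_all_zero(self):
        area = np.ones(4)
        assert ph.daily_extent(np.zeros(4), area) == 0.0

    def test_extent_full_cover_is_total_area(self):
        area = np.array([1.0, 2.0, 3.0, 4.0])
        assert ph.daily_extent(np.full(4, 100.0), area) == pytest.approx(10.0)

    def test_extent_threshold_inclusive_at_15(self):
        # cells {20, 10, 15, 0} with equal areas a: 15 counts, total 2a
        field = np.array([20.0, 10.0, 15.0, 0.0])
        assert ph.daily_extent(field, np.ones(4)) == pytest.approx(2.0)

    def test_area_is_concentration_weighted(self):
        field = np.array([20.0, 10.0, 15.0, 0.0])
        # (20+10+15+0)/100 * a = 0.45a
        assert ph.daily_area(field, np.ones(4)) == pytest.approx(0.45)

    def test_area_half_concentration(self):
        area = np.array([3.0, 7.0])
        assert ph.daily_area(np.full(2, 50.0), area) == pytest.approx(5.0)

    def test_all_missing_propagates_nan(self):
        assert np.isnan(ph.daily_extent(np.full(3, np.nan), np.ones(3)))
        assert np.isnan(ph.daily_area(np.full(3, np.nan), np.ones(3)))

    @pytest.mark.parametrize("value,expected", [(15.0, True), (14.9, False)])
    def test_presence_boundary(self, value, expected):
        assert ph.regional_presence(np.full(4, value), np.ones(4)) is expected

    def test_presence_area_weighted_mean(self):
        # half the area at 40%, half at 0% -> mean 20% -> present
        assert ph.regional_presence(np.array([40.0, 0.0]), np.ones(2))

    def test_extent_and_area_bounded_by_polygon(self, rng):
        field = rng.uniform(0, 100, size=16)
        area = rng.uniform(10, 30, size=16)
        total = area.sum()
        assert ph.daily_extent(field, area) <= total
        assert ph.daily_area(field, area) <= total


class TestSeasonMetrics:
    def _run(self, presence, extent=None, area=None, year=2000):
        n = len(presence)
        extent = np.arange(n, dtype=float) if extent is None else extent
        area = np.arange(n, dtype=float) / 2 if area is None else area
        return ph.season_metrics(np.asarray(presence, bool), extent, area, year)

    def test_step_presence(self):
        n = 365
        presence = np.zeros(n, bool)
        presence[99:299] = True  # window days 100..299
        m = self._run(presence)
        assert (m.advance_day, m.retreat_day) == (100, 300)
        assert m.duration_days == 200
        assert m.persistence_pct == pytest.approx(100.0)

    def test_oscillating_presence_persistence(self):
        # ice on days 100-149 and 160-299: advance 100, retreat 300,
        # 190 ice days over a 200-day season -> persistence 95
        n = 365
        presence = np.zeros(n, bool)
        presence[99:149] = True
        presence[159:299] = True
        m = self._run(presence)
        assert (m.advance_day, m.retreat_day) == (100, 300)
        assert m.duration_days == 200
        assert m.persistence_pct == pytest.approx(95.0)

    def test_saturated_season_pins_window_limits(self):
        n = 200
        m = self._run(np.ones(n, bool))
        assert (m.advance_day, m.retreat_day) == (1, n)
        assert m.persistence_pct == pytest.approx(100.0)

    def test_iceless_season(self):
        n = 150
        m = self._run(np.zeros(n, bool))
        assert m.iceless
        assert m.advance_day == m.retreat_day == n
        assert m.duration_days == 0
        assert m.persistence_pct == 0.0

    def test_short_spells_do_not_establish_advance(self):
        # never 5 consecutive days: treated as iceless
        presence = np.zeros(100, bool)
        presence[10:13] = True
        presence[50:54] = True
        assert self._run(presence).iceless

    def test_extrema_first_day_wins(self):
        presence = np.ones(30, bool)
        extent = np.full(30, 5.0)
        extent[[10, 20]] = 9.0
        extent[[3, 7]] = 1.0
        m = self._run(presence, extent=extent, area=extent / 2)
        assert m.day_max_extent == 11
        assert m.day_min_extent == 4
        assert m.min_extent_km2 == 1.0
        assert m.max_extent_km2 == 9.0

    def test_small_gaps_interpolated_large_rejected(self):
        presence = np.ones(60, bool)
        extent = np.linspace(1, 10, 60)
        holed = extent.copy()
        holed[20:22] = np.nan
        m = ph.season_metrics(presence, holed, extent / 2, 2000)
        assert m.max_extent_km2 == pytest.approx(10.0)
        holed[30:34] = np.nan
        with pytest.raises(ValueError, match="gap"):
            ph.season_metrics(presence, holed, extent / 2, 2000)


class TestCovariateTable:
    def test_noiseless_truth_recovered(self, step_seasons):
        params, grid, truth = step_seasons
        table = ph.build_covariate_table(grid)
        assert list(table.columns) == ph.COVARIATE_COLUMNS
        for p in params:
            row = table.loc[p.label_year]
            assert row.advance_day == truth.advance[p.label_year]
            assert row.retreat_day == truth.retreat[p.label_year]
            assert row.duration_days == row.retreat_day - row.advance_day
            assert 0 <= row.persistence_pct <= 100

    def test_uniform_field_extent_equals_polygon_area(self, step_seasons):
        params, grid, _ = step_seasons
        table = ph.build_covariate_table(grid)
        assert table.max_extent_km2.iloc[0] == pytest.approx(grid.total_area_km2)
        assert table.min_extent_km2.iloc[0] == 0.0


class TestPCA:
    def _table(self, rng, n=40, k=10):
        x = rng.standard_normal((n, k))
        return pd.DataFrame(x, columns=[f"v{i}" for i in range(k)])

    def test_matches_correlation_eigendecomposition(self, rng):
        """Independent oracle: eigen-decomposition of the correlation matrix."""
        table = self._table(rng)
        res = ph.pca(table)
        corr = np.corrcoef(table.to_numpy(), rowvar=False)
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(
            res.var_explained, evals / evals.sum(), atol=1e-10)
        for j in range(evecs.shape[1]):
            v = evecs[:, j]
            v = v * np.sign(v[np.abs(v).argmax()])
            np.testing.assert_allclose(res.loadings.iloc[:, j].to_numpy(), v,
                                       atol=1e-8)

    def test_perfectly_correlated_pair(self, rng):
        x = rng.standard_normal(30)
        table = pd.DataFrame({"a": x, "b": 2 * x + 5})
        res = ph.pca(table)
        assert res.var_explained[0] == pytest.approx(1.0, abs=1e-10)

    def test_score_covariance_is_diagonal_eigenvalues(self, rng):
        table = self._table(rng, n=60, k=6)
        res = ph.pca(table)
        scores = res.scores.to_numpy()
        assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-10)
        cov = np.cov(scores, rowvar=False)
        evals = res.var_explained * res.var_explained.size * 0 + cov.diagonal()
        np.testing.assert_allclose(cov, np.diag(evals), atol=1e-8)
        assert np.all(np.diff(res.var_explained) <= 1e-12)

    def test_projection_reproduces_scores(self, rng):
        table = self._table(rng, n=25, k=4)
        res = ph.pca(table)
        np.testing.assert_allclose(res.project(table).to_numpy(),
                                   res.scores.to_numpy(), atol=1e-10)

    def test_constant_column_rejected_by_name(self, rng):
        table = self._table(rng, n=20, k=3)
        table["v1"] = 7.0
        with pytest.raises(ValueError, match="v1"):
            ph.pca(table)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            ph.pca(pd.DataFrame({"a": [1.0], "b": [2.0]}))


def test_padding_invariance_of_season_metrics():
    """Iceless padding days outside the ice season leave metrics unchanged."""
    presence = np.zeros(200, bool)
    presence[49:150] = True
    extent = presence * 100.0
    m1 = ph.season_metrics(presence, extent, extent / 2, 2000)
    padded = np.concatenate([np.zeros(30, bool), presence])
    ext_p = padded * 100.0
    m2 = ph.season_metrics(padded, ext_p, ext_p / 2, 2000)
    assert m2.advance_day == m1.advance_day + 30
    assert m2.retreat_day == m1.retreat_day + 30
    assert m2.duration_days == m1.duration_days
    assert m2.persistence_pct == m1.persistence_pct
    assert m2.max_extent_km2 == m1.max_extent_km2
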