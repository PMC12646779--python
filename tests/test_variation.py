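import numpy as np
import pandas as pd
import pytest

from movestrat.occurrence import GridSpec
from movestrat.simulate import (CovariateStack, LandscapeParams,
                                default_strategy_params, simulate_landscape,
                                simulate_trajectory)
from movestrat.variation import (SpatialVariationPCA, climate_anthro_indices,
                                 pca_spatial_score, spatial_variation,
                                 standardized_domain, variation_table,
                                 year_round_range, yty_variation)


def tiny_stack(layers, years=(2018, 2019), cell=150.0):
    shape = next(iter(layers.values())).shape[-2:]
    grid = GridSpec(x0=0.0, y0=0.0, cell_size=cell,
                    n_cols=shape[1], n_rows=shape[0])
    return CovariateStack(grid=grid, layers=layers, years=list(years))


class TestSpatialVariation:
    def test_constant_layer_gives_zero_sd(self):
        st = tiny_stack({"elevation": np.full((4, 4), 7.0)})
        mask = np.ones((4, 4), bool)
        assert spatial_variation(st, mask)["elevation"] == 0.0

    def test_two_cell_population_sd_hand_oracle(self):
        """Cells {0, 10}: population SD (denominator n) is exactly 5."""
        layer = np.zeros((1, 2)); layer[0, 1] = 10.0
        st = tiny_stack({"elevation": layer})
        assert spatial_variation(st, np.ones((1, 2), bool))["elevation"] == 5.0

    def test_annual_covariates_averaged_across_years_first(self):
        arr = np.stack([np.zeros((2, 2)), np.full((2, 2), 10.0)])
        arr[1, 0, 0] = 30.0  # mean layer: [[15,5],[5,5]]
        st = tiny_stack({"biomass": arr})
        sd = spatial_variation(st, np.ones((2, 2), bool))["biomass"]
        mean_layer = arr.mean(axis=0)
        assert sd == pytest.approx(mean_layer.std(ddof=0))

    def test_single_cell_mask_rejected(self):
        st = tiny_stack({"elevation": np.ones((3, 3))})
        mask = np.zeros((3, 3), bool); mask[1, 1] = True
        with pytest.raises(ValueError, match="2 cells"):
            spatial_variation(st, mask)


class TestSpatialPCA:
    def test_perfectly_correlated_columns_pc1_explains_all(self):
        x = np.linspace(1, 5, 10)
        df = pd.DataFrame({"a": x, "b": 3 * x})
        est = SpatialVariationPCA().fit(df)
        assert est.explained_variance_ratio_ == pytest.approx(1.0)

    def test_scores_centred(self, rng):
        df = pd.DataFrame(rng.random((15, 4)), columns=list("abcd"))
        scores = pca_spatial_score(df)
        assert scores.mean() == pytest.approx(0.0, abs=1e-10)

    def test_recovers_rank_one_factor(self, rng):
        factor = rng.random(40) * 10
        loadings = np.array([1.0, 0.6, 1.4, 0.9])
        X = np.outer(factor, loadings) + rng.normal(0, 0.02, (40, 4))
        scores = pca_spatial_score(pd.DataFrame(X))
        r = np.corrcoef(scores, factor)[0, 1]
        assert abs(r) > 0.99

    def test_zero_variance_column_dropped_with_warning(self, rng, caplog):
        df = pd.DataFrame({"a": rng.random(10), "b": rng.random(10),
                           "c": np.ones(10)})
        with caplog.at_level("WARNING"):
            est = SpatialVariationPCA().fit(df)
        assert est.columns_ == ["a", "b"]
        assert any("zero-variance" in r.message for r in caplog.records)


class TestYtyVariation:
    def test_identical_years_give_zero(self):
        arr = np.stack([np.ones((3, 3))] * 3)
        st = tiny_stack({"spring_length": arr, "biomass": arr},
                        years=(2018, 2019, 2020))
        out = yty_variation(st, np.ones((3, 3), bool))
        assert out["yty_spring_length_sd"] == 0.0

    def test_sample_sd_hand_oracle(self):
        """Annual means 10, 20, 30: sample SD (denominator n-1) is exactly 10."""
        arr = np.stack([np.full((2, 2), v) for v in (10.0, 20.0, 30.0)])
        st = tiny_stack({"spring_length": arr, "biomass": arr},
                        years=(2018, 2019, 2020))
        out = yty_variation(st, np.ones((2, 2), bool))
        assert out["yty_spring_length_sd"] == pytest.approx(10.0)

    def test_fewer_than_two_years_rejected(self):
        st = tiny_stack({"spring_length": np.ones((1, 2, 2)),
                         "biomass": np.ones((1, 2, 2))}, years=(2018,))
        with pytest.raises(ValueError, match=">= 2"):
            yty_variation(st, np.ones((2, 2), bool))

    def test_invariant_to_year_permutation(self, rng):
        arr = rng.random((4, 3, 3))
        st = tiny_stack({"spring_length": arr, "biomass": arr},
                        years=(2018, 2019, 2020, 2021))
        mask = np.ones((3, 3), bool)
        base = yty_variation(st, mask)
        st2 = tiny_stack({"spring_length": arr[[2, 0, 3, 1]],
                          "biomass": arr[[2, 0, 3, 1]]},
                         years=(2018, 2019, 2020, 2021))
        np.testing.assert_allclose(yty_variation(st2, mask), base,
                                   rtol=1e-12)


class TestStandardizedDomain:
    def grid(self, cell=150.0, n=600):
        return GridSpec(x0=-n / 2 * cell, y0=-n / 2 * cell, cell_size=cell,
                        n_cols=n, n_rows=n)

    def winter_fixes(self, cx=0.0, cy=0.0):
        ts = pd.date_range("2020-12-01", periods=50, freq="6h", tz="UTC")
        return pd.DataFrame({"timestamp": ts, "x": cx + np.zeros(50),
                             "y": cy + np.zeros(50)})

    def test_area_equivalent_radius_to_the_metre(self):
        """3765 km^2 circle: radius sqrt(area/pi) = 34,619 m (to the metre)."""
        assert np.sqrt(3765e6 / np.pi) == pytest.approx(34_618.9, abs=1.0)

    def test_rasterized_area_within_one_percent(self):
        grid = self.grid()
        mask = standardized_domain(self.winter_fixes(), 500.0, grid)
        area_km2 = mask.sum() * grid.cell_area / 1e6
        assert area_km2 == pytest.approx(500.0, rel=0.01)

    def test_translation_equivariance(self):
        grid = self.grid()
        m0 = standardized_domain(self.winter_fixes(0, 0), 200.0, grid)
        m1 = standardized_domain(self.winter_fixes(1500.0, -3000.0), 200.0,
                                 grid)
        assert np.array_equal(np.roll(m0, (-20, 10), axis=(0, 1)), m1)

    def test_no_winter_fixes_raises(self):
        ts = pd.date_range("2020-06-01", periods=10, freq="6h", tz="UTC")
        fixes = pd.DataFrame({"timestamp": ts, "x": np.zeros(10),
                              "y": np.zeros(10)})
        with pytest.raises(ValueError, match="winter"):
            standardized_domain(fixes, 100.0, self.grid())


class TestClimateIndices:
    def test_zero_snow_gives_zero_conditions(self):
        st = tiny_stack({"snow_depth": np.zeros((2, 3, 3)),
                         "pct_agriculture": np.full((3, 3), 0.25),
                         "dist_roads": np.full((3, 3), 4000.0)})
        masks = {"A": np.ones((3, 3), bool), "B": np.ones((3, 3), bool)}
        out = climate_anthro_indices(st, masks)
        assert (out["winter_conditions"] == 0.0).all()
        assert (out["pct_agriculture"] == 0.25).all()

    def test_severity_zscores_standardized(self, rng):
        snow = rng.random((2, 4, 4)) * 30
        st = tiny_stack({"snow_depth": snow})
        masks = {}
        for i in range(6):
            m = np.zeros((4, 4), bool)
            m[i % 4, (i + 1) % 4] = True
            m[(i + 2) % 4, i % 4] = True
            masks[f"A{i}"] = m
        out = climate_anthro_indices(st, masks)
        assert out["winter_severity"].mean() == pytest.approx(0.0, abs=1e-10)
        assert out["winter_severity"].std(ddof=0) == pytest.approx(1.0)

    def test_doubling_snow_doubles_conditions_not_severity(self, rng):
        snow = rng.random((3, 4, 4)) * 20
        masks = {f"A{i}": rng.random((4, 4)) > 0.4 for i in range(5)}
        out1 = climate_anthro_indices(tiny_stack({"snow_depth": snow},
                                                 years=(1, 2, 3)), masks)
        out2 = climate_anthro_indices(tiny_stack({"snow_depth": 2 * snow},
                                                 years=(1, 2, 3)), masks)
        np.testing.assert_allclose(out2["winter_conditions"],
                                   2 * out1["winter_conditions"])
        np.testing.assert_allclose(out2["winter_severity"],
                                   out1["winter_severity"], atol=1e-10)

    def test_missing_snow_layer_flagged(self):
        st = tiny_stack({"elevation": np.ones((3, 3))})
        with pytest.raises(ValueError, match="snow"):
            climate_anthro_indices(st, {"A": np.ones((3, 3), bool)})


class TestYearRoundRange:
    def test_resident_range_area_matches_gaussian_oracle(self):
        """95% KUD area within a factor 2 of the pi*(3 sigma)^2 envelope."""
        p = default_strategy_params("resident")
        df = simulate_trajectory(p, seed=21)
        lp = LandscapeParams(grid_extent=20_000)
        stack = simulate_landscape(lp, seed=0)
        shifted = df.assign(x=df["x"] + 10_000, y=df["y"] + 10_000)
        mask = year_round_range(shifted, stack.grid)
        area = mask.sum() * stack.grid.cell_area
        envelope = np.pi * (3 * p.stationary_sd) ** 2
        assert envelope / 2 < area < envelope * 2

    def test_deterministic(self, resident_track):
        lp = LandscapeParams(grid_extent=20_000)
        stack = simulate_landscape(lp, seed=0)
        df = resident_track.assign(x=resident_track["x"] + 10_000,
                                   y=resident_track["y"] + 10_000)
        m1 = year_round_range(df, stack.grid)
        m2 = year_round_range(df, stack.grid)
        assert np.array_equal(m1, m2)


def test_variation_table_shares_code_path_across_domains(resident_track):
    """Empirical vs standardized tables differ only through the mask."""
    lp = LandscapeParams(grid_extent=20_000)
    stack = simulate_landscape(lp, seed=1)
    df = resident_track.assign(x=resident_track["x"] + 10_000,
                               y=resident_track["y"] + 10_000)
    df2 = df.assign(x=df["x"] + 2000)
    masks_a = {"A": year_round_range(df, stack.grid),
               "B": year_round_range(df2, stack.grid)}
    ta = variation_table(stack, masks_a, domain="empirical")
    tb = variation_table(stack, masks_a, domain="standardized")
    # identical masks => identical numbers; only the domain label differs
    pd.testing.assert_frame_equal(ta.drop(columns="domain"),
                                  tb.drop(columns="domain"))
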