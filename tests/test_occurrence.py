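import numpy as np
import pandas as pd
import pytest

from conftest import brownian_track, make_od
from movestrat.occurrence import (BBMMParams, GridSpec, estimate_bbmm,
                                  estimate_kud, fit_bbmm_variance, make_grid,
                                  volume_isopleth)


def fixes(xy, dt_h=1.0, loc_error_sd=20.0):
    xy = np.asarray(xy, float)
    ts = pd.date_range("2020-01-01", periods=len(xy),
                       freq=pd.Timedelta(hours=dt_h), tz="UTC")
    return pd.DataFrame({"timestamp": ts, "x": xy[:, 0], "y": xy[:, 1],
                         "loc_error_sd": loc_error_sd})


class TestFitVariance:
    def test_recovers_brownian_motion_variance(self):
        """Leave-one-out estimator recovers sigma2_m=1000 m^2/h within 20%."""
        ests = [fit_bbmm_variance(brownian_track(1000.0, 500, seed=s,
                                                 loc_error_sd=20.0),
                                  loc_error_sd=20.0)
                for s in range(3)]
        assert np.mean(ests) == pytest.approx(1000.0, rel=0.20)

    def test_stationary_fixes_give_zero(self):
        df = fixes(np.zeros((50, 2)), loc_error_sd=30.0)
        assert fit_bbmm_variance(df, loc_error_sd=30.0) == 0.0

    def test_two_fixes_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_bbmm_variance(fixes([[0, 0], [1, 1]]))

    def test_all_gaps_exceed_max_lag_error(self):
        df = fixes(np.zeros((5, 2)), dt_h=10.0)
        with pytest.raises(ValueError, match="no usable bridges"):
            fit_bbmm_variance(df, max_lag=8.0)


class TestEstimateBBMM:
    def test_mass_sums_to_one(self):
        df = brownian_track(500.0, 50, seed=1)
        grid = make_grid(df["x"], df["y"], cell_size=150.0)
        od = estimate_bbmm(df, grid, BBMMParams(sigma2_m=500.0))
        assert od.mass.sum() == pytest.approx(1.0, abs=1e-12)
        assert (od.mass >= 0).all()

    def test_noiseless_limit_concentrates_on_segment(self):
        df = fixes([[0.0, 0.0], [1000.0, 0.0]])
        grid = make_grid(df["x"], df["y"], cell_size=150.0, margin=600.0)
        od = estimate_bbmm(df, grid,
                           BBMMParams(sigma2_m=1e-6, loc_error_sd=1e-3))
        ys = grid.y_centres()[:, None] + 0 * grid.x_centres()[None, :]
        near = np.abs(ys) <= 1.5 * grid.cell_size  # within 1 cell of segment
        assert od.mass[near].sum() > 0.99

    def test_coincident_endpoints_match_quadrature_oracle(self):
        """Single bridge with equal endpoints vs dense closed-form quadrature.

        The OD is the alpha-mixture of centred Gaussians with variance
        a(1-a)T*sigma2 + ((1-a)^2 + a^2)*delta^2; the oracle integrates the
        closed-form density at cell centres with Simpson's rule.
        """
        sigma2, delta, T = 2000.0, 50.0, 2.0
        df = fixes([[0.0, 0.0], [0.0, 0.0]], dt_h=T, loc_error_sd=delta)
        grid = GridSpec(x0=-525.0, y0=-525.0, cell_size=150.0,
                        n_cols=7, n_rows=7)
        od = estimate_bbmm(df, grid, BBMMParams(sigma2_m=sigma2,
                                                loc_error_sd=delta,
                                                n_alpha=200))
        alphas = np.linspace(0.0, 1.0, 4001)
        var = alphas * (1 - alphas) * T * sigma2 \
            + ((1 - alphas) ** 2 + alphas ** 2) * delta ** 2
        xc = grid.x_centres()
        r2 = xc[None, :] ** 2 + xc[:, None] ** 2
        dens = np.trapezoid(
            np.exp(-r2[..., None] / (2 * var)) / (2 * np.pi * var),
            alphas, axis=-1)
        oracle = dens * grid.cell_area
        oracle /= oracle.sum()
        tv = 0.5 * np.abs(od.mass - oracle).sum()
        assert tv < 1e-6

    def test_doubling_n_alpha_changes_od_little(self):
        df = brownian_track(800.0, 80, seed=2)
        grid = make_grid(df["x"], df["y"], cell_size=150.0)
        p10 = BBMMParams(sigma2_m=800.0, n_alpha=10)
        p20 = BBMMParams(sigma2_m=800.0, n_alpha=20)
        tv = 0.5 * np.abs(estimate_bbmm(df, grid, p10).mass
                          - estimate_bbmm(df, grid, p20).mass).sum()
        assert tv < 0.02

    def test_grid_not_covering_fixes_raises(self):
        df = fixes([[0, 0], [10_000, 0]])
        grid = GridSpec(x0=-100, y0=-100, cell_size=150, n_cols=5, n_rows=5)
        with pytest.raises(ValueError, match="cover"):
            estimate_bbmm(df, grid)


class TestEstimateKUD:
    def test_tight_cluster_mass_within_three_bandwidths(self, rng):
        pts = fixes(rng.normal(0, 20.0, size=(300, 2)))
        grid = make_grid(pts["x"], pts["y"], cell_size=5.0, margin=300.0)
        od = estimate_kud(pts, grid)
        # Gaussian-mass oracle: P(r <= 3h) ~ 1 - exp(-4.5) = 0.989 around each point
        cx = pts["x"].mean()
        cy = pts["y"].mean()
        h3 = 3.0 * (np.sqrt((pts["x"].var() + pts["y"].var()) / 2)
                    * len(pts) ** (-1 / 6)) + 3 * 20.0
        xs = grid.x_centres()[None, :]
        ys = grid.y_centres()[:, None]
        inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= h3 ** 2
        assert od.mass[inside].sum() > 0.95

    def test_two_far_clusters_split_mass_evenly(self, rng):
        a = rng.normal([-5000, 0], 100.0, size=(200, 2))
        b = rng.normal([5000, 0], 100.0, size=(200, 2))
        pts = fixes(np.vstack([a, b]))
        grid = make_grid(pts["x"], pts["y"], cell_size=50.0)
        od = estimate_kud(pts, grid)
        left = od.mass[:, grid.x_centres() < 0].sum()
        assert left == pytest.approx(0.5, abs=0.02)

    def test_binned_path_matches_exact_at_moderate_bandwidth(self, rng):
        """The FFT-style binned evaluation agrees with direct kernel sums."""
        pts = fixes(rng.normal(0, 800.0, size=(400, 2)))
        grid = make_grid(pts["x"], pts["y"], cell_size=150.0, margin=4000.0)
        od_binned = estimate_kud(pts, grid, bandwidth=1300.0)  # hw > 8 cells
        from movestrat.occurrence import _stamp_gaussians
        sd = np.full(len(pts), 1300.0)
        exact = _stamp_gaussians(grid, pts["x"].to_numpy(),
                                 pts["y"].to_numpy(), sd, np.ones(len(pts)))
        exact /= exact.sum()
        tv = 0.5 * np.abs(od_binned.mass - exact).sum()
        assert tv < 0.01

    def test_zero_variance_without_bandwidth_raises(self):
        pts = fixes(np.zeros((40, 2)))
        grid = GridSpec(x0=-500, y0=-500, cell_size=50, n_cols=20, n_rows=20)
        with pytest.raises(ValueError, match="bandwidth"):
            estimate_kud(pts, grid)
        od = estimate_kud(pts, grid, bandwidth=40.0)
        assert od.mass.sum() == pytest.approx(1.0, abs=1e-9)


class TestIsopleth:
    def test_uniform_od_level_095_takes_95_cells(self):
        od = make_od(np.ones((10, 10)))
        assert volume_isopleth(od, 0.95).sum() == 95

    def test_level_one_takes_all_positive_cells(self):
        m = np.zeros((5, 5))
        m[1:3, 1:4] = 1.0
        od = make_od(m)
        assert volume_isopleth(od, 1.0).sum() == 6

    def test_point_mass_takes_one_cell(self):
        m = np.zeros((6, 6))
        m[2, 3] = 1.0
        od = make_od(m)
        for level in (0.1, 0.5, 0.95, 1.0):
            mask = volume_isopleth(od, level)
            assert mask.sum() == 1 and mask[2, 3]

    def test_mask_monotone_in_level(self, rng):
        od = make_od(rng.random((12, 12)))
        m50 = volume_isopleth(od, 0.5)
        m95 = volume_isopleth(od, 0.95)
        assert (m95 | m50).sum() == m95.sum()  # m50 subset of m95

    def test_invalid_level_rejected(self):
        od = make_od(np.ones((3, 3)))
        with pytest.raises(ValueError):
            volume_isopleth(od, 0.0)
        with pytest.raises(ValueError):
            volume_isopleth(od, 1.2)
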