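"""Synthetic environment, colonies, biased-walk tracks and group labels."""

import numpy as np
import pandas as pd
import pytest

from habtrack.grid import SpatialGrid, project
from habtrack.synthetic import (
    ColonyRegistry,
    EnvironmentConfig,
    PreferenceSpec,
    apply_group_labels,
    default_colonies,
    generate_environment,
    make_grouping_plan,
    make_use_availability,
    simulate_tracks,
)


class TestEnvironment:
    def test_determinism_by_seed(self):
        e1 = generate_environment(seed=1, weeks=3)
        e2 = generate_environment(seed=1, weeks=3)
        for name in e1.dynamic:
            np.testing.assert_array_equal(e1.dynamic[name], e2.dynamic[name])
        np.testing.assert_array_equal(e1.static["depth"], e2.static["depth"])

    def test_zero_noise_sst_equals_trend(self, colonies):
        cfg = EnvironmentConfig(sst_noise_sd=0.0, sst_seasonal_amp=0.0)
        env = generate_environment(seed=3, weeks=2, config=cfg, colonies=colonies)
        lon, lat = env.grid.cell_centers_lonlat()
        trend = cfg.sst_edge + cfg.sst_lapse * (lat - cfg.north_edge_lat)
        ocean = ~env.land_mask
        np.testing.assert_allclose(env.dynamic["sst"][0][ocean], trend[ocean], atol=1e-12)

    def test_poleward_cooling_every_week(self, env_small):
        lon, lat = env_small.grid.cell_centers_lonlat()
        near60 = np.abs(lat + 60.0) < 2.0
        near40 = np.abs(lat + 40.0) < 2.0
        for w in range(env_small.weeks):
            sst = env_small.dynamic["sst"][w]
            assert np.nanmean(sst[near60]) < np.nanmean(sst[near40])

    def test_chlorophyll_strictly_positive(self, env_small):
        chl = env_small.dynamic["chl"]
        assert np.all(chl[np.isfinite(chl)] > 0)

    def test_land_cells_carry_no_ocean_data(self, env_small):
        for name in ("sst", "chl", "sla", "eke", "wind"):
            assert np.all(np.isnan(env_small.dynamic[name][:, env_small.land_mask]))

    def test_focal_std_layers_nonnegative(self, env_small):
        for arr in (env_small.dynamic["sst_std"], env_small.static["depth_std"][None]):
            finite = arr[np.isfinite(arr)]
            assert np.all(finite >= 0)

    def test_rejects_non_polar_grid(self):
        narrow = SpatialGrid(cell_km=100.0, half_extent_km=2000.0)  # only reaches ~-72
        with pytest.raises(ValueError, match="polar"):
            generate_environment(seed=0, weeks=2, grid=narrow)

    def test_rejects_zero_weeks(self):
        with pytest.raises(ValueError):
            generate_environment(seed=0, weeks=0)

    def test_netcdf_roundtrip(self, env_small, tmp_path):
        import xarray as xr

        path = tmp_path / "env.nc"
        env_small.to_netcdf(path)
        ds = xr.open_dataset(path, engine="scipy")
        np.testing.assert_allclose(
            ds["sst"].values, env_small.dynamic["sst"], rtol=1e-6, equal_nan=True
        )


class TestColonies:
    def test_registry_invariants(self, colonies):
        assert len(set(colonies.names)) == 7
        with pytest.raises(ValueError):
            ColonyRegistry(pd.DataFrame({"name": ["a", "a"], "lon": [0, 1], "lat": [-50, -51]}))

    def test_dist_closest_matches_exhaustive_minimum(self, colonies, rng):
        """Brute-force minimum over the six non-own colonies."""
        pts = np.column_stack([rng.uniform(-180, 180, 20), rng.uniform(-75, -35, 20)])
        d_own, d_closest = colonies.dist_own_closest(pts, "marion")
        from habtrack.tracks import great_circle_km

        i_own = colonies.names.index("marion")
        for j, p in enumerate(pts):
            dists = [
                great_circle_km(p, colonies.lonlat[i])
                for i in range(7)
                if i != i_own
            ]
            assert d_closest[j] == pytest.approx(min(dists), rel=1e-12)
            assert d_own[j] == pytest.approx(great_circle_km(p, colonies.lonlat[i_own]))

    def test_fix_at_colony_has_zero_dist_own(self, colonies):
        lon, lat = colonies.position("south_georgia")
        d_own, _ = colonies.dist_own_closest(np.array([[lon, lat]]), "south_georgia")
        assert d_own[0] == 0.0


class TestSimulateTracks:
    def test_determinism_and_start_at_colony(self, env_small, colonies):
        pref = PreferenceSpec(noise_sd_km=0.0)
        t1 = simulate_tracks(env_small, colonies, pref, 2, 15, seed=5, own_colony="marion")
        t2 = simulate_tracks(env_small, colonies, pref, 2, 15, seed=5, own_colony="marion")
        for a, b in zip(t1, t2):
            pd.testing.assert_frame_equal(a.data, b.data)
        lon0, lat0 = colonies.position("marion")
        x0, y0 = project(lon0, lat0)
        for t in t1:
            x, y = project(t.data["lon_true"].iloc[0], t.data["lat_true"].iloc[0])
            # first fix is one step from the colony (walk starts there)
            assert np.hypot(x - x0, y - y0) < 6 * pref.step_mean_km

    def test_zero_noise_identity(self, env_small, colonies):
        pref = PreferenceSpec(noise_sd_km=0.0)
        (t,) = simulate_tracks(env_small, colonies, pref, 1, 15, seed=1)
        np.testing.assert_array_equal(t.data["lon"], t.data["lon_true"])
        np.testing.assert_array_equal(t.data["lat"], t.data["lat_true"])

    def test_noise_sd_recovered(self, env_small, colonies):
        """Empirical sd of (noisy - true) displacement ~ noise_sd at many fixes."""
        pref = PreferenceSpec(noise_sd_km=186.0)
        tracks = simulate_tracks(env_small, colonies, pref, 9, 40, seed=2)
        dx = []
        for t in tracks:
            xn, yn = project(t.data["lon"].to_numpy(), t.data["lat"].to_numpy())
            xt, yt = project(t.data["lon_true"].to_numpy(), t.data["lat_true"].to_numpy())
            dx += [xn - xt, yn - yt]
        sd = np.concatenate(dx).std()
        assert sd == pytest.approx(186.0, rel=0.10)

    def test_fixes_avoid_land(self, env_small, colonies):
        pref = PreferenceSpec(noise_sd_km=0.0)
        tracks = simulate_tracks(env_small, colonies, pref, 3, 20, seed=8)
        for t in tracks:
            x, y = project(t.data["lon_true"].to_numpy(), t.data["lat_true"].to_numpy())
            assert not env_small.is_land(x, y).any()

    def test_neutral_selection_matches_availability(self, env_small, colonies):
        """With zero preference weights the used SST matches the null ensemble."""
        from scipy.stats import ttest_ind

        neutral = PreferenceSpec(noise_sd_km=0.0)

        def per_track_mean_sst(seed):
            tracks = simulate_tracks(env_small, colonies, neutral, 25, 30, seed=seed)
            means = []
            for t in tracks:
                x, y = project(t.data["lon_true"].to_numpy(), t.data["lat_true"].to_numpy())
                iy, ix = env_small.grid.cell_index(x, y)
                w = env_small.week_index(t.data["datetime"]).clip(0, env_small.weeks - 1)
                means.append(np.nanmean(env_small.value_at("sst", w, iy, ix)))
            return np.array(means)

        used = per_track_mean_sst(3)
        null = per_track_mean_sst(103)
        # two independent neutral ensembles: no detectable difference in use
        _, p = ttest_ind(used, null)
        assert p > 0.01

    def test_positive_sst_preference_shifts_usage(self, env_small, colonies):
        warm = PreferenceSpec(weights={"sst": 2.0}, noise_sd_km=0.0)
        neutral = PreferenceSpec(noise_sd_km=0.0)

        def mean_sst(tracks):
            vals = []
            for t in tracks:
                x, y = project(t.data["lon_true"].to_numpy(), t.data["lat_true"].to_numpy())
                iy, ix = env_small.grid.cell_index(x, y)
                w = env_small.week_index(t.data["datetime"]).clip(0, env_small.weeks - 1)
                vals.append(env_small.value_at("sst", w, iy, ix))
            return np.nanmean(np.concatenate(vals))

        sst_warm = mean_sst(simulate_tracks(env_small, colonies, warm, 10, 30, seed=4))
        sst_neutral = mean_sst(simulate_tracks(env_small, colonies, neutral, 10, 30, seed=4))
        assert sst_warm > sst_neutral + 0.5

    def test_duration_validation(self, env_small, colonies):
        with pytest.raises(ValueError):
            simulate_tracks(env_small, colonies, PreferenceSpec(), 1, 10, seed=0)

    def test_preference_spec_validation(self):
        with pytest.raises(ValueError):
            PreferenceSpec(noise_sd_km=-1.0)
        with pytest.raises(KeyError):
            PreferenceSpec(weights={"not_a_covariate": 1.0})


class TestGroupLabels:
    def _tracks(self, env, colonies, n=6, days=400):
        pref = PreferenceSpec(noise_sd_km=0.0)
        return simulate_tracks(env, colonies, pref, n, days, seed=9)

    def test_sex_split_bookkeeping(self, env_small, colonies):
        tracks = self._tracks(env_small, colonies, n=20, days=15)
        plan = make_grouping_plan([t.individual_id for t in tracks], sex_split=0.5)
        out = apply_group_labels(tracks, plan)
        sexes = pd.Series([t.sex for t in out])
        assert (sexes == "female").sum() == 10 and (sexes == "male").sum() == 10

    def test_failed_outcome_truncates_to_277_days(self, env_small, colonies):
        tracks = self._tracks(env_small, colonies, n=2, days=480)
        plan = make_grouping_plan(
            [t.individual_id for t in tracks], failed_fraction=1.0, failed_duration_days=277
        )
        out = apply_group_labels(tracks, plan)
        for t in out:
            span = (t.data["datetime"].iloc[-1] - t.data["datetime"].iloc[0]).days
            assert span == 276  # 277 days of fixes: last fix < start + 277 d

    def test_unknown_level_rejected(self, env_small, colonies):
        tracks = self._tracks(env_small, colonies, n=2, days=15)
        plan = make_grouping_plan([t.individual_id for t in tracks])
        plan.loc[0, "sex"] = "unknown"
        with pytest.raises(ValueError, match="unknown levels"):
            apply_group_labels(tracks, plan)

    def test_uncovered_individual_rejected(self, env_small, colonies):
        tracks = self._tracks(env_small, colonies, n=2, days=15)
        plan = make_grouping_plan([tracks[0].individual_id])
        with pytest.raises(ValueError, match="does not cover"):
            apply_group_labels(tracks, plan)


class TestRecordLevelTruth:
    def test_reproducible_and_shaped(self):
        df1 = make_use_availability(n_individuals=4, records_per_individual=50, seed=3)
        df2 = make_use_availability(n_individuals=4, records_per_individual=50, seed=3)
        pd.testing.assert_frame_equal(df1, df2)
        assert len(df1) == 200
        assert set(df1["response"].unique()) <= {0, 1}

    def test_weight_sign_controls_marginal_association(self):
        df = make_use_availability(
            n_individuals=10, records_per_individual=400, weights={"sst": 1.5}, seed=4
        )
        used = df.loc[df.response == 1, "sst"].mean()
        avail = df.loc[df.response == 0, "sst"].mean()
        assert used > avail
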