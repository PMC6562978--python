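"""Synthetic landscape and survey generator: ground truth and calibration."""

import numpy as np
import pandas as pd
import pytest

from roosurvey.grouping import assign_groups
from roosurvey.landscape import LandscapeError, grazing_density, greenness
from roosurvey.synthetic import (
    DisturbanceProfile,
    SimulationConfig,
    default_profiles,
    generate_landscape,
    generate_survey,
    profiles_with,
    simulate_greenness_patch,
    simulate_session,
)


def single_zone_config(label, seed, n_sessions=1, **overrides):
    prof = default_profiles()[label]
    if overrides:
        prof = profiles_with({label: prof}, **overrides)[label]
        return SimulationConfig(seed=seed, n_sessions=n_sessions,
                                profiles={label: prof})
    return SimulationConfig(seed=seed, n_sessions=n_sessions,
                            profiles={label: prof})


class TestLandscape:
    def test_areas_match_request_within_one_percent(self):
        land = generate_landscape(SimulationConfig(seed=0))
        areas = {z.label: z.area_ha for z in land.zones}
        for label, want in [("HB", 17.1), ("LB", 232.4), ("LH", 104.0),
                            ("HH", 139.0)]:
            assert areas[label] == pytest.approx(want, rel=0.01)

    def test_zero_zones_empty_landscape(self):
        cfg = SimulationConfig(seed=0, profiles={})
        land = generate_landscape(cfg)
        assert land.zones == []

    def test_zones_pairwise_disjoint_and_inside_forest(self):
        land = generate_landscape(SimulationConfig(seed=0))
        polys = [z.polygon for z in land.zones]
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                assert polys[i].intersection(polys[j]).area == 0.0
        forest = land.forest
        for p in polys:
            # each cleared polygon is enclosed by forest on all sides
            assert forest.contains(p.exterior.buffer(1.0).difference(p))

    def test_infeasible_packing_rejected(self):
        cfg = SimulationConfig(seed=0, landscape_extent=500.0)
        with pytest.raises(LandscapeError, match="pack"):
            generate_landscape(cfg)


class TestProfiles:
    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="probability"):
            DisturbanceProfile(
                label="HB", cleared_area_ha=10, density_mean=50,
                cover_slope_beta=0.3, size_intercept=0.5,
                groupsize_dispersion=1.5,
                demographic_mix=(0.5, 0.5, 0.5, 0, 0, 0))

    def test_degenerate_mix_all_large_adults(self):
        cfg = single_zone_config(
            "HB", seed=4, demographic_mix={"HB": (1.0, 0, 0, 0, 0, 0)})
        land = generate_landscape(cfg)
        df = simulate_session(land, cfg, 1)
        assert (df["demo_class"] == "LA").all()
        assert (df["in_pouch"] == 0).all()


class TestSurvey:
    def test_six_sessions_by_default(self):
        cfg = single_zone_config("HB", seed=1)
        cfg = SimulationConfig(seed=1, profiles=cfg.profiles)  # default n
        ds = generate_survey(cfg)
        assert ds.observations["session"].nunique() == 6

    def test_same_seed_is_bit_identical(self):
        cfg = dict(seed=21, n_sessions=2)
        a = generate_survey(SimulationConfig(**cfg)).observations
        b = generate_survey(SimulationConfig(**cfg)).observations
        pd.testing.assert_frame_equal(a, b)

    def test_neighbouring_seeds_differ(self):
        a = generate_survey(SimulationConfig(seed=21, n_sessions=2)).observations
        b = generate_survey(SimulationConfig(seed=22, n_sessions=2)).observations
        assert not a.equals(b)

    def test_pouch_young_share_mother_coordinates(self):
        cfg = SimulationConfig(seed=3, n_sessions=2)
        ds = generate_survey(cfg)
        obs = ds.observations
        py = obs[obs["in_pouch"] == 1]
        assert len(py) > 0
        adults = obs[obs["demo_class"].isin(["LA", "MA", "SA"])]
        merged = py.merge(adults, on=["session", "x_m", "y_m"],
                          suffixes=("_py", "_ad"))
        assert len(merged) >= len(py)

    def test_chain_rule_recovers_planted_partition(self):
        cfg = SimulationConfig(seed=17, n_sessions=3)
        land = generate_landscape(cfg)
        for sess in range(1, 4):
            df = simulate_session(land, cfg, sess)
            part = assign_groups(df, 15.0)
            planted = {frozenset(g["id"]) for _, g in df.groupby("true_group")}
            found = {frozenset(g["id"])
                     for _, g in part.membership.groupby("group_id")}
            assert planted == found

    def test_observations_fall_inside_their_zone(self):
        cfg = SimulationConfig(seed=5, n_sessions=1)
        land = generate_landscape(cfg)
        df = simulate_session(land, cfg, 1)
        from shapely.geometry import Point

        for zone_label, sub in df.groupby("zone"):
            poly = land.zone(zone_label).polygon
            for _, row in sub.iterrows():
                assert poly.covers(Point(row["x_m"], row["y_m"]))

    def test_missing_profile_rejected(self):
        cfg = SimulationConfig(seed=0)
        land = generate_landscape(cfg)
        cfg_bad = SimulationConfig(
            seed=0, profiles={"HB": default_profiles()["HB"]})
        with pytest.raises(LandscapeError, match="profile"):
            simulate_session(land, cfg_bad, 1)


class TestDensityCalibration:
    """Mean realized per-zone density stays within 5% of density_mean.

    Each zone is simulated alone over many sessions; the session count per
    zone is chosen so Monte Carlo noise is well inside the 5% band.
    """

    @pytest.mark.parametrize("label,n_sessions",
                             [("HB", 700), ("LB", 150), ("LH", 300),
                              ("HH", 400)])
    def test_realized_density_matches_target(self, label, n_sessions):
        cfg = single_zone_config(label, seed=1234, n_sessions=n_sessions)
        ds = generate_survey(cfg)
        den = grazing_density(ds.observations, ds.landscape)
        realized = den["density_per_km2"].mean()
        target = cfg.profiles[label].density_mean
        assert realized == pytest.approx(target, rel=0.05)


class TestSlopePlanting:
    def test_null_slope_yields_no_correlation(self):
        # beta = 0 and near-Poisson sizes: log size uncorrelated with log d
        cfg = single_zone_config(
            "LH", seed=8, n_sessions=40,
            cover_slope_beta={"LH": 0.0}, groupsize_dispersion={"LH": 1e6})
        land = generate_landscape(cfg)
        sizes, dists = [], []
        from shapely.geometry import Point

        poly = land.zone("LH").polygon
        for sess in range(1, 41):
            df = simulate_session(land, cfg, sess)
            for _, g in df[df["in_pouch"] == 0].groupby("true_group"):
                cx, cy = g["x_m"].mean(), g["y_m"].mean()
                sizes.append(len(g))
                dists.append(max(poly.exterior.distance(Point(cx, cy)), 1.0))
            if len(sizes) >= 500:
                break
        from scipy.stats import pearsonr

        r, p = pearsonr(np.log(np.asarray(sizes, float)), np.log(dists))
        assert p > 0.01

    def test_planted_slope_recovered_by_nb_glm(self):
        from roosurvey.stats import groupsize_cover_glmm

        cfg = single_zone_config("HB", seed=31, n_sessions=90,
                                 cover_slope_beta={"HB": 0.5})
        land = generate_landscape(cfg)
        rows = []
        from shapely.geometry import Point

        poly = land.zone("HB").polygon
        for sess in range(1, 91):
            df = simulate_session(land, cfg, sess)
            for _, g in df[df["in_pouch"] == 0].groupby("true_group"):
                cx, cy = g["x_m"].mean(), g["y_m"].mean()
                rows.append({"size": len(g), "zone": "HB", "session": sess,
                             "cover_m": poly.exterior.distance(Point(cx, cy))})
            if len(rows) >= 500:
                break
        fit = groupsize_cover_glmm(pd.DataFrame(rows), sigma=0)
        slope = fit.params.set_index("term").loc["HB:Cover"]
        assert slope["ci_low"] <= 0.5 <= slope["ci_high"]


class TestGreennessPatch:
    def test_stated_mean_with_zero_noise(self):
        patch = simulate_greenness_patch(0.3576, 0.0, 64, seed=0)
        assert greenness(patch) == pytest.approx(0.3576, abs=1 / 255)

    def test_one_third_gives_equal_channels(self):
        patch = simulate_greenness_patch(1 / 3, 0.0, 16, seed=0)
        px = patch.pixels
        assert (px[..., 0] == px[..., 1]).all()
        assert (px[..., 1] == px[..., 2]).all()

    def test_noisy_patch_clt_bound(self):
        patch = simulate_greenness_patch(0.5, 0.02, 10_000, seed=12)
        assert greenness(patch) == pytest.approx(0.5, abs=0.01)

    @pytest.mark.parametrize("bad_mean", [0.0, 1.0, -0.2, 1.3])
    def test_mean_outside_unit_interval_rejected(self, bad_mean):
        with pytest.raises(ValueError):
            simulate_greenness_patch(bad_mean, 0.0, 16, seed=0)

    def test_zero_pixels_rejected(self):
        with pytest.raises(ValueError):
            simulate_greenness_patch(0.4, 0.0, 0, seed=0)
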