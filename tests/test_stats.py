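"""Inferential layer: moment tests, ANOVA, mixed models, NB-Laplace GLMM, GAM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from roosurvey.stats import (
    anscombe_kurtosis,
    clusteredness_lmm,
    dagostino_skewness,
    density_anova,
    greenness_models,
    groupsize_cover_glmm,
    groupsize_lmm,
    positioning_gam,
)

# frozen oracle values computed once with scipy.stats.skewtest /
# kurtosistest (independent implementations of the same transformations)
SKEW_VECTOR = np.array([1, 2, 3, 4, 5, 6, 7, 8, 20], float)
SKEW_ORACLE = dict(g1=1.731213587319087, z=2.8022799888185697,
                   p=0.005074281377375844)
KURT_VECTOR = np.array(
    [5.069, 5.443, 0.657, 4.566, 7.899, 3.955, 0.91, 2.596, 0.67, 0.741,
     4.688, 1.602, 1.478, 1.416, 2.095, 1.754, 2.612, 2.961, 1.422, 1.799,
     5.655, 1.822, 0.854, 8.058, 0.891])
KURT_ORACLE = dict(b2=3.023786806277407, z=0.5830877963475439,
                   p=0.5598341985967601)


class TestMomentTests:
    def test_skewness_matches_reference_oracle(self):
        r = dagostino_skewness(SKEW_VECTOR)
        assert r.statistic == pytest.approx(SKEW_ORACLE["g1"], abs=1e-12)
        assert r.z == pytest.approx(SKEW_ORACLE["z"], abs=1e-10)
        assert r.p == pytest.approx(SKEW_ORACLE["p"], abs=1e-10)

    def test_kurtosis_matches_reference_oracle(self):
        r = anscombe_kurtosis(KURT_VECTOR)
        assert r.statistic == pytest.approx(KURT_ORACLE["b2"], abs=1e-12)
        assert r.z == pytest.approx(KURT_ORACLE["z"], abs=1e-10)
        assert r.p == pytest.approx(KURT_ORACLE["p"], abs=1e-10)

    def test_symmetric_sample_has_zero_skew(self):
        x = np.array([0.3, 1.1, 2.7, 5.0])
        sym = np.concatenate([x, -x])
        r = dagostino_skewness(sym)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_uniform_sample_is_platykurtic(self):
        rng = np.random.default_rng(99)
        r = anscombe_kurtosis(rng.uniform(size=20_000))
        assert r.statistic == pytest.approx(1.8, abs=0.1)
        assert r.z < 0

    def test_statistics_match_central_moment_formulas(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = rng.gamma(2.0, size=rng.integers(25, 200))
            m = x - x.mean()
            g1 = np.mean(m**3) / np.mean(m**2) ** 1.5
            b2 = np.mean(m**4) / np.mean(m**2) ** 2
            assert dagostino_skewness(x).statistic == pytest.approx(g1, abs=1e-12)
            assert anscombe_kurtosis(x).statistic == pytest.approx(b2, abs=1e-12)

    def test_minimum_n_enforced(self):
        with pytest.raises(ValueError):
            dagostino_skewness(np.arange(7.0))
        with pytest.raises(ValueError):
            anscombe_kurtosis(np.arange(19.0))

    def test_zero_variance_signalled(self):
        with pytest.raises(ValueError):
            dagostino_skewness(np.full(30, 2.0))


class TestDensityAnova:
    @staticmethod
    def _table(zone_values: dict):
        rows = []
        for zone, vals in zone_values.items():
            for s, v in enumerate(vals, 1):
                rows.append({"zone": zone, "session": s,
                             "density_per_km2": v})
        return pd.DataFrame(rows)

    def test_identical_densities_give_null_result(self):
        fr = density_anova(self._table({"HB": [5, 5, 5], "LB": [5, 5, 5],
                                        "LH": [5, 5, 5], "HH": [5, 5, 5]}))
        assert fr.stats["F"] == 0.0
        assert fr.stats["p"] == 1.0
        assert (fr.contrasts["p_adj"] == 1.0).all()

    def test_two_group_hand_computed_f(self):
        # log densities {1,2,3} vs {4,5,6}: SSB/MSW = 13.5 by hand
        fr = density_anova(self._table({"A": np.exp([1, 2, 3]),
                                        "B": np.exp([4, 5, 6])}))
        assert fr.stats["F"] == pytest.approx(13.5, rel=1e-9)
        assert fr.stats["df1"] == 1
        assert fr.stats["df2"] == 4

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError, match="log"):
            density_anova(self._table({"A": [0.0, 1.0], "B": [2.0, 3.0]}))

    def test_tukey_not_less_than_unadjusted(self):
        rng = np.random.default_rng(6)
        fr = density_anova(self._table(
            {z: rng.lognormal(3, 0.3, 6) for z in ["HB", "LB", "LH", "HH"]}))
        assert fr.contrasts["p_adj"].between(0, 1).all()


class TestGroupsizeLMM:
    @staticmethod
    def _balanced(zone_means, sd=0.0, seed=0, n_per=4):
        rng = np.random.default_rng(seed)
        rows = []
        for chain in (15, 30):
            for zone, mu in zone_means.items():
                for sess in range(1, 7):
                    sizes = np.exp(rng.normal(mu, sd, n_per) if sd > 0
                                   else np.full(n_per, mu))
                    rows.append(pd.DataFrame(
                        {"size": np.maximum(sizes, 1.0), "zone": zone,
                         "chain_m": chain, "session": sess}))
        return pd.concat(rows, ignore_index=True)

    def test_degenerate_random_effect_reduces_to_cell_means(self):
        df = self._balanced({"HB": 1.2, "HH": 0.8}, sd=0.0)
        fr = groupsize_lmm(df)
        lsm = {r["level"]: r["lsmean"] for r in fr.stats["lsmeans"]}
        cell = df.assign(ls=np.log(df["size"])).groupby(
            ["zone", "chain_m"])["ls"].mean()
        for (zone, chain), want in cell.items():
            assert lsm[f"{zone}@{chain}m"] == pytest.approx(want, abs=1e-6)

    def test_separated_zones_detected(self):
        df = self._balanced({"HB": 1.8, "HH": 0.6}, sd=0.3, seed=1)
        fr = groupsize_lmm(df)
        within = fr.contrasts[fr.contrasts["pair"] == "HB@15m-HH@15m"]
        assert within["p_adj"].iloc[0] < 0.01
        assert fr.random_sd["session"] >= 0.0

    def test_needs_two_zones(self):
        df = self._balanced({"HB": 1.0})
        with pytest.raises(ValueError):
            groupsize_lmm(df)

    def test_ci_orders_and_tukey_bounds(self):
        df = self._balanced({"HB": 1.4, "LB": 1.2, "HH": 0.9}, sd=0.4, seed=2)
        fr = groupsize_lmm(df)
        p = fr.params
        assert (p["ci_low"] <= p["estimate"] + 1e-12).all()
        assert (p["estimate"] <= p["ci_high"] + 1e-12).all()
        # studentized-range adjustment never reports less than the t-test
        df_resid = fr.n_obs - len(p)
        for _, row in fr.contrasts.iterrows():
            p_t = 2 * sps.t.sf(abs(row["stat"]), df_resid)
            assert row["p_adj"] >= p_t - 1e-9


class TestClusterednessAndDemographyLMM:
    def test_single_zone_lrt_is_identity(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"mean_nn_m": rng.lognormal(1.5, 0.3, 60),
                           "zone": "HB",
                           "session": rng.integers(1, 7, 60),
                           "size": rng.integers(2, 10, 60)})
        fr = clusteredness_lmm(df)
        assert fr.stats["lrt_p"] == 1.0

    def test_planted_zone_difference_detected(self):
        rng = np.random.default_rng(1)
        frames = []
        for zone, mu in [("HB", 2.2), ("LB", 1.5), ("LH", 1.5), ("HH", 1.5)]:
            frames.append(pd.DataFrame(
                {"mean_nn_m": rng.lognormal(mu, 0.25, 60), "zone": zone,
                 "session": rng.integers(1, 7, 60),
                 "size": rng.integers(2, 10, 60)}))
        fr = clusteredness_lmm(pd.concat(frames, ignore_index=True))
        assert fr.stats["lrt_p"] < 0.001
        hb_lb = fr.contrasts[fr.contrasts["pair"] == "HB-LB"]
        assert hb_lb["p_adj"].iloc[0] < 0.01


class TestCoverGLMM:
    @staticmethod
    def _simulate(betas, icepts, n_per=300, k=1.5, sess_sd=0.0, seed=0,
                  n_sess=6):
        rng = np.random.default_rng(seed)
        eff = rng.normal(0, sess_sd, n_sess) if sess_sd > 0 else np.zeros(n_sess)
        rows = []
        for (z, b), a in zip(betas.items(), icepts):
            d = rng.uniform(5, 250, n_per)
            sess = rng.integers(0, n_sess, n_per)
            mu = np.exp(a + b * np.log(d) + eff[sess])
            y = np.maximum(1, rng.negative_binomial(k, k / (k + mu)))
            rows.append(pd.DataFrame({"size": y, "cover_m": d, "zone": z,
                                      "session": sess + 1}))
        return pd.concat(rows, ignore_index=True)

    def test_reduces_to_plain_nb_glm_when_sigma_zero(self):
        import warnings

        import statsmodels.api as sm

        df = self._simulate({"HB": 0.5, "LB": 0.25, "LH": 0.0, "HH": 0.2},
                            [0.4, 0.7, 1.6, 0.8], seed=3)
        fr = groupsize_cover_glmm(df, sigma=0)
        zones = ["HB", "LB", "LH", "HH"]
        zc = df["zone"].map({z: i for i, z in enumerate(zones)}).to_numpy()
        X = np.zeros((len(df), 8))
        X[:, 0] = 1
        for i in range(1, 4):
            X[:, i] = zc == i
        for i in range(4):
            X[:, 4 + i] = (zc == i) * np.log(df["cover_m"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.NegativeBinomial(df["size"].to_numpy(), X).fit(
                disp=0, maxiter=500, method="newton")
        assert np.max(np.abs(fr.params["estimate"].to_numpy()
                             - ref.params[:8])) < 1e-6

    def test_sigma_estimate_collapses_when_planted_zero(self):
        df = self._simulate({"HB": 0.4, "LH": 0.0}, [0.5, 1.4], seed=5)
        fr = groupsize_cover_glmm(df)
        assert fr.random_sd["session"] <= 1e-3

    def test_session_variance_recovered_when_present(self):
        df = self._simulate({"HB": 0.4, "LH": 0.0}, [0.5, 1.4], sess_sd=0.4,
                            n_per=600, n_sess=14, seed=6)
        fr = groupsize_cover_glmm(df)
        assert 0.1 < fr.random_sd["session"] < 0.9

    def test_planted_slopes_inside_wald_cis(self):
        df = self._simulate({"HB": 0.5, "LB": 0.25, "LH": 0.0, "HH": 0.2},
                            [0.4, 0.7, 1.6, 0.8], seed=7)
        fr = groupsize_cover_glmm(df)
        tab = fr.params.set_index("term")
        assert tab.loc["HB:Cover", "detected"]
        assert not tab.loc["LH:Cover", "detected"]
        assert (tab.loc["HB:Cover", "ci_low"] - 0.1 <= 0.5
                <= tab.loc["HB:Cover", "ci_high"] + 0.1)

    def test_sizes_below_one_rejected(self):
        df = pd.DataFrame({"size": [0, 2], "cover_m": [5, 10],
                           "zone": "HB", "session": 1})
        with pytest.raises(ValueError):
            groupsize_cover_glmm(df)


class TestPositioningGAM:
    @staticmethod
    def _records(rng, n_per=200, hb_offset=0.0, decay=0.012, flat=False):
        rows = []
        for z in ["HB", "LB", "LH", "HH"]:
            d = rng.uniform(2, 300, n_per)
            eta = (0.3 * np.ones_like(d) if flat
                   else 2.2 * np.exp(-decay * d) - 0.8)
            eta = eta + (hb_offset if z == "HB" else 0.0)
            front = rng.random(n_per) < 1 / (1 + np.exp(-eta))
            rows.append(pd.DataFrame(
                {"zone": z, "GDC": d,
                 "side": np.where(front, "front", "behind")}))
        return pd.concat(rows, ignore_index=True)

    def test_planted_zone_offset_detected(self):
        rng = np.random.default_rng(10)
        fr = positioning_gam(self._records(rng, hb_offset=-1.2))
        hb = fr.contrasts[fr.contrasts["pair"].str.startswith("HB-")]
        assert (hb["p_adj"] < 0.05).all()

    def test_flat_truth_selects_smooth_of_one_df(self):
        rng = np.random.default_rng(11)
        edfs = [positioning_gam(self._records(rng, flat=True)).stats[
            "edf_smooth"] for _ in range(3)]
        assert np.median(edfs) <= 1.5

    def test_monotone_truth_gives_declining_proportions(self):
        from roosurvey.stats import predicted_front_proportion

        rng = np.random.default_rng(12)
        rec = self._records(rng, n_per=600, decay=0.02)
        props = predicted_front_proportion(rec)
        for z, sub in props.groupby("zone"):
            r = sps.spearmanr(sub["gdc"], sub["prop_front"]).statistic
            assert r < 0


class TestGreennessModels:
    @staticmethod
    def _data(rng, hb_mean=0.3576, other_mean=0.345, noise=0.005, n_per=80,
              slope=0.0):
        rows = []
        for z in ["HB", "LB", "LH", "HH"]:
            g = rng.normal(hb_mean if z == "HB" else other_mean, noise, n_per)
            size = np.maximum(1, rng.poisson(
                np.exp(1.0 + slope * (100 * g - 34.5)), n_per))
            rows.append(pd.DataFrame(
                {"greenness": g, "zone": z, "size": size,
                 "session": rng.integers(1, 7, n_per)}))
        return pd.concat(rows, ignore_index=True)

    def test_planted_hb_greenness_detected(self):
        rng = np.random.default_rng(13)
        a, _ = greenness_models(self._data(rng))
        assert a.stats["lrt_p"] < 0.001
        hb = a.contrasts[a.contrasts["pair"].str.startswith("HB-")]
        assert (hb["p_adj"] < 0.05).all()

    def test_no_greenness_size_link_when_none_planted(self):
        rng = np.random.default_rng(14)
        _, b = greenness_models(self._data(rng, slope=0.0))
        green = b.params[b.params["term"].str.endswith(":Green")]
        assert len(green) == 4
        assert (~green["detected"]).sum() >= 3

    def test_equal_greenness_is_null(self):
        rng = np.random.default_rng(15)
        a, _ = greenness_models(
            self._data(rng, hb_mean=0.345, other_mean=0.345, noise=0.02))
        assert a.stats["lrt_p"] > 0.01
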