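"""ANOVA layer: degenerate cases, algebraic identities, calibration oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.integrate import quad

import hpmrsi as hp
from hpmrsi.cohort import simulate_ratio_table


def balanced_table(rng, n_per_cell=5, effects=None):
    effects = effects or {}
    rows = []
    for hemi in ("injured", "contralateral"):
        for tp in ("baseline", "7d"):
            mu = effects.get((hemi, tp), 0.0)
            for i in range(n_per_cell):
                rows.append({"animal_id": f"{hemi}-{tp}-{i}", "hemisphere": hemi,
                             "timepoint": tp, "value": mu + rng.normal()})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_identical_responses_give_f_zero_p_one(self):
        df = balanced_table(np.random.default_rng(0))
        df["value"] = 0.7
        res = hp.two_way_anova(df)
        assert np.all(res.effects["F"] == 0.0)
        assert np.all(res.effects["p"] == 1.0)

    def test_matches_hand_computed_sums_of_squares(self):
        """2x2 balanced design against a by-hand partition of the variance."""
        rng = np.random.default_rng(3)
        df = balanced_table(rng, n_per_cell=6,
                            effects={("injured", "7d"): 1.0})
        res = hp.two_way_anova(df)

        y = df["value"].to_numpy()
        grand = y.mean()
        ss = {}
        for factor in ("hemisphere", "timepoint"):
            ss[factor] = sum(
                len(g) * (g["value"].mean() - grand) ** 2
                for _, g in df.groupby(factor)
            )
        ss_cells = sum(
            len(g) * (g["value"].mean() - grand) ** 2
            for _, g in df.groupby(["hemisphere", "timepoint"])
        )
        ss_inter = ss_cells - ss["hemisphere"] - ss["timepoint"]
        ss_resid = sum(
            ((g["value"] - g["value"].mean()) ** 2).sum()
            for _, g in df.groupby(["hemisphere", "timepoint"])
        )
        ms_resid = ss_resid / (len(y) - 4)
        for effect, ss_eff, df_eff in (
            ("hemisphere", ss["hemisphere"], 1),
            ("timepoint", ss["timepoint"], 1),
            ("hemisphere:timepoint", ss_inter, 1),
        ):
            f_hand = (ss_eff / df_eff) / ms_resid
            assert res.p_value(effect) == pytest.approx(
                sps.f.sf(f_hand, df_eff, len(y) - 4), rel=1e-8)
            row = res.effects.loc[res.effects.effect == effect].iloc[0]
            assert row["F"] == pytest.approx(f_hand, rel=1e-8)

    def test_empty_cells_named(self):
        df = balanced_table(np.random.default_rng(0))
        df = df[~((df.hemisphere == "injured") & (df.timepoint == "7d"))]
        with pytest.raises(ValueError, match="injured"):
            hp.two_way_anova(df)

    def test_invariant_to_row_order_and_affine_rescaling(self):
        rng = np.random.default_rng(5)
        df = balanced_table(rng, effects={("injured", "7d"): 0.8})
        a = hp.two_way_anova(df).effects
        shuffled = df.sample(frac=1.0, random_state=1)
        b = hp.two_way_anova(shuffled).effects
        rescaled = df.assign(value=3.0 * df["value"] + 11.0)
        c = hp.two_way_anova(rescaled).effects
        for other in (b, c):
            assert np.allclose(a["F"], other["F"], rtol=1e-9)
            assert np.allclose(a["p"], other["p"], rtol=1e-9)


class TestOneWayAnova:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"timepoint": ["a"] * 8 + ["b"] * 8,
                           "value": rng.normal(size=16)})
        res = hp.one_way_anova(df)
        t, p = sps.ttest_ind(df.value[:8], df.value[8:])
        assert res.effects["F"].iloc[0] == pytest.approx(t**2, rel=1e-10)
        assert res.effects["p"].iloc[0] == pytest.approx(p, rel=1e-10)

    def test_identical_groups_p_one(self):
        df = pd.DataFrame({"timepoint": list("aabb"), "value": [2.0] * 4})
        assert hp.one_way_anova(df).effects["p"].iloc[0] == 1.0

    def test_large_effect_detected_in_power_simulation(self):
        """Delta = 3 sd with n=10/group detected at p < 0.001 at the rate the
        closed-form noncentral-t power predicts (0.991)."""
        n_reps = 200
        hits = 0
        for rep in range(n_reps):
            rng = np.random.default_rng(10_000 + rep)
            df = pd.DataFrame({
                "timepoint": ["a"] * 10 + ["b"] * 10,
                "value": np.concatenate([rng.normal(0, 1, 10), rng.normal(3, 1, 10)]),
            })
            hits += hp.one_way_anova(df, posthoc=False).effects["p"].iloc[0] < 1e-3
        ncp = 3.0 / np.sqrt(2.0 / 10.0)
        crit = sps.t.ppf(1 - 0.0005, 18)
        power = 1 - sps.nct.cdf(crit, 18, ncp) + sps.nct.cdf(-crit, 18, ncp)
        tol = 3.0 * np.sqrt(power * (1 - power) / n_reps)
        assert hits / n_reps >= power - tol
        assert hits / n_reps >= 0.95


class TestRepeatedMeasures:
    def test_constant_within_animal_gives_zero_time_effect(self):
        df = pd.DataFrame({
            "animal_id": np.repeat(list("abcd"), 3),
            "timepoint": np.tile(["t1", "t2", "t3"], 4),
            "value": np.repeat([1.0, 2.0, 3.0, 4.0], 3),
        })
        res = hp.repeated_measures_anova(df)
        assert res.p_value("timepoint") == 1.0
        row = res.effects.loc[res.effects.effect == "timepoint"].iloc[0]
        assert row["F"] == 0.0

    def test_additive_subject_offsets_do_not_change_time_f(self):
        rng = np.random.default_rng(11)
        base = pd.DataFrame({
            "animal_id": np.repeat([f"m{i}" for i in range(6)], 3),
            "timepoint": np.tile(["t1", "t2", "t3"], 6),
            "value": rng.normal(size=18),
        })
        shifted = base.copy()
        offsets = dict(zip([f"m{i}" for i in range(6)], rng.normal(0, 10, 6)))
        shifted["value"] = base["value"] + base["animal_id"].map(offsets)
        f0 = hp.repeated_measures_anova(base)
        f1 = hp.repeated_measures_anova(shifted)
        r0 = f0.effects.loc[f0.effects.effect == "timepoint", "F"].iloc[0]
        r1 = f1.effects.loc[f1.effects.effect == "timepoint", "F"].iloc[0]
        assert r1 == pytest.approx(r0, rel=1e-8)

    def test_unbalanced_panel_rejected(self):
        df = pd.DataFrame({
            "animal_id": ["a", "a", "b"],
            "timepoint": ["t1", "t2", "t1"],
            "value": [1.0, 2.0, 3.0],
        })
        with pytest.raises(ValueError, match="unbalanced"):
            hp.repeated_measures_anova(df)

    def test_null_calibration(self):
        """No time effect: rejection rate at alpha=0.05 within 0.05 +/- 0.02."""
        rejections = 0
        n_reps = 1000
        for rep in range(n_reps):
            rng = np.random.default_rng(40_000 + rep)
            df = pd.DataFrame({
                "animal_id": np.repeat([f"m{i}" for i in range(8)], 3),
                "timepoint": np.tile(["t1", "t2", "t3"], 8),
                "value": rng.normal(size=24),
            })
            rejections += hp.repeated_measures_anova(df).p_value("timepoint") < 0.05
        assert abs(rejections / n_reps - 0.05) <= 0.02


class TestTukey:
    def test_identical_groups_adjusted_p_near_one(self):
        df = pd.DataFrame({"timepoint": list("aaabbbccc"), "value": [1.0] * 9})
        table = hp.tukey_hsd(df, factor="timepoint")
        assert np.all(table["p_adjusted"] == 1.0)

    def test_adjusted_p_never_below_unadjusted(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame({
            "timepoint": np.repeat(list("abcd"), 6),
            "value": rng.normal(size=24) + np.repeat([0, 0.5, 1.0, 2.0], 6),
        })
        table = hp.tukey_hsd(df, factor="timepoint")
        assert np.all(table["p_adjusted"] >= table["p_unadjusted"])

    def test_matches_statsmodels_tukeyhsd(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(17)
        df = pd.DataFrame({
            "timepoint": np.repeat(list("abc"), 7),
            "value": rng.normal(size=21) + np.repeat([0.0, 0.0, 1.5], 7),
        })
        ours = hp.tukey_hsd(df, factor="timepoint")
        theirs = pairwise_tukeyhsd(df["value"], df["timepoint"])
        assert np.allclose(ours["p_adjusted"], theirs.pvalues, atol=1e-6)

    def test_adjusted_p_matches_independent_range_integration(self):
        """Cross-check one pair against quad-integrated studentized range."""
        rng = np.random.default_rng(19)
        df = pd.DataFrame({
            "timepoint": np.repeat(list("abc"), 5),
            "value": rng.normal(size=15) + np.repeat([0.0, 0.8, 1.6], 5),
        })
        table = hp.tukey_hsd(df, factor="timepoint")
        k, df_resid = 3, 12
        row = table.iloc[0]
        q_obs = abs(row["t"]) * np.sqrt(2.0)

        def range_cdf_given_scale(q, s):
            inner, _ = quad(
                lambda z: k * sps.norm.pdf(z)
                * (sps.norm.cdf(z) - sps.norm.cdf(z - q * s)) ** (k - 1),
                -8, 8, limit=200)
            return inner

        # integrate over the distribution of s = sqrt(chi2_df / df)
        def p_adjusted_oracle(q):
            val, _ = quad(
                lambda s: range_cdf_given_scale(q, s)
                * 2 * df_resid * s * sps.chi2.pdf(df_resid * s**2, df_resid),
                1e-6, 8, limit=200)
            return 1.0 - val

        assert row["p_adjusted"] == pytest.approx(p_adjusted_oracle(q_obs), abs=1e-4)

    def test_two_levels_degenerate_to_pooled_t(self):
        rng = np.random.default_rng(23)
        df = pd.DataFrame({"timepoint": list("aaaabbbb"),
                           "value": rng.normal(size=8)})
        table = hp.tukey_hsd(df, factor="timepoint")
        assert len(table) == 1
        assert table["p_adjusted"].iloc[0] == pytest.approx(
            table["p_unadjusted"].iloc[0], abs=1e-9)


class TestTwoGroupTTest:
    def test_mirrored_samples_symmetric(self):
        vals = np.array([0.5, 1.0, 1.5, 2.0])
        df = pd.DataFrame({"group": ["a"] * 4 + ["b"] * 4,
                           "value": np.concatenate([-vals, vals])})
        t1, p1 = hp.two_group_ttest(df)
        flipped = df.assign(value=-df["value"])
        t2, p2 = hp.two_group_ttest(flipped)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_identical_groups_t_zero_p_one(self):
        df = pd.DataFrame({"group": list("aabb"), "value": [1.0, 2.0, 1.0, 2.0]})
        t, p = hp.two_group_ttest(df)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_degenerate_variance_conventions(self):
        same = pd.DataFrame({"group": list("aabb"), "value": [2.0] * 4})
        assert hp.two_group_ttest(same) == (0.0, 1.0)
        apart = pd.DataFrame({"group": list("aabb"), "value": [1.0, 1.0, 2.0, 2.0]})
        t, p = hp.two_group_ttest(apart)
        assert p == 0.0

    def test_wrong_group_count_rejected(self):
        df = pd.DataFrame({"group": list("abc") * 2, "value": np.arange(6.0)})
        with pytest.raises(ValueError, match="two groups"):
            hp.two_group_ttest(df)


class TestGroupTableValidation:
    def test_duplicates_and_nonfinite_rejected(self):
        df = pd.DataFrame({"animal_id": ["a", "a"], "timepoint": ["t1", "t1"],
                           "hemisphere": ["injured", "injured"], "value": [1.0, 2.0]})
        with pytest.raises(ValueError, match="duplicate"):
            hp.validate_group_table(df, ("animal_id", "timepoint", "hemisphere"))
        df2 = pd.DataFrame({"animal_id": ["a", "b"], "timepoint": ["t1", "t1"],
                            "hemisphere": ["injured", "injured"],
                            "value": [1.0, np.inf]})
        with pytest.raises(ValueError, match="finite"):
            hp.validate_group_table(df2, ("animal_id", "timepoint", "hemisphere"))

    def test_simulated_ratio_table_is_valid_and_programmed(self):
        table = simulate_ratio_table(10, {"baseline": 0.0, "7d": 37.0}, seed=1)
        hp.validate_group_table(table, ("animal_id", "timepoint", "hemisphere"))
        by = table.groupby(["timepoint", "hemisphere"])["value"].mean()
        elev = (by["7d", "injured"] - by["7d", "contralateral"]) / by["7d", "contralateral"]
        assert elev * 100 == pytest.approx(37.0, abs=10.0)
        base_elev = (by["baseline", "injured"] - by["baseline", "contralateral"])
        assert abs(base_elev) < 0.05


def test_stars_convention():
    assert hp.p_to_stars(0.03) == "*"
    assert hp.p_to_stars(0.004) == "**"
    assert hp.p_to_stars(5e-4) == "***"
    assert hp.p_to_stars(5e-5) == "****"
    assert hp.p_to_stars(0.2) == "ns"
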