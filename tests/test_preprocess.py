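"""Adjusted-weight formulas, contemporary groups, filters, fixed-effect screening."""

import numpy as np
import pandas as pd
import pytest

from willham.preprocess import (
    TRAITS,
    adjusted_weights,
    contemporary_groups,
    filter_outliers,
    filter_structure,
    preprocess_records,
    screen_fixed_effects,
)


def raw(**kw):
    base = dict(
        animal="X1", sire="S1", dam="D1", herd="3", birth_date="1990-02-15",
        sex="M", dam_age=5.0, bw=np.nan, ww=np.nan, weaning_age=np.nan,
        aw=np.nan, last_age=np.nan,
    )
    base.update(kw)
    return base


class TestAdjustedWeights:
    def test_pre_weaning_formulas(self):
        df, _ = adjusted_weights(pd.DataFrame([raw(bw=30, ww=186, weaning_age=240)]))
        assert df["w120"].iloc[0] == pytest.approx(108.0)
        assert df["w240"].iloc[0] == pytest.approx(186.0)
        assert np.isnan(df["w365"].iloc[0])

    def test_post_weaning_formulas(self):
        df, _ = adjusted_weights(
            pd.DataFrame([raw(bw=30, ww=186, weaning_age=240, aw=258, last_age=490)])
        )
        assert df["w365"].iloc[0] == pytest.approx(222.0)
        assert df["w450"].iloc[0] == pytest.approx(246.48)

    def test_missing_inputs_propagate(self):
        df, excl = adjusted_weights(pd.DataFrame([raw(bw=30)]))
        assert len(excl) == 0
        assert df[TRAITS].isna().all().all()

    @pytest.mark.parametrize(
        "bad", [dict(bw=30, ww=20, weaning_age=200), dict(weaning_age=-1.0),
                dict(bw=30, ww=90, weaning_age=180, aw=100, last_age=200)]
    )
    def test_impossible_rows_excluded(self, bad):
        df, excl = adjusted_weights(pd.DataFrame([raw(**bad)]))
        assert len(df) == 0 and len(excl) == 1
        assert excl["reason"].iloc[0] != ""

    def test_linear_in_age(self):
        # adjustment evaluated at the weaning age returns WW; at age 0, BW
        rec = raw(bw=32, ww=170, weaning_age=200)
        pre = (170 - 32) / 200
        df, _ = adjusted_weights(pd.DataFrame([rec]))
        assert 32 + 200 * pre == pytest.approx(170)
        assert df["w120"].iloc[0] == pytest.approx(32 + 120 * pre)


class TestContemporaryGroups:
    @pytest.mark.parametrize(
        "herd,date,cg",
        [("3", "1990-02-15", "3-1990-1"), ("3", "1990-10-01", "3-1990-4"),
         ("7", "2010-06-30", "7-2010-2")],
    )
    def test_quarter_coding(self, herd, date, cg):
        df, _ = contemporary_groups(pd.DataFrame([raw(herd=herd, birth_date=date)]))
        assert df["cg"].iloc[0] == cg

    def test_missing_date_excluded(self):
        df, excl = contemporary_groups(pd.DataFrame([raw(birth_date="")]))
        assert len(df) == 0 and len(excl) == 1


class TestOutlierFilter:
    def test_matches_brute_force(self, rng):
        # a lone extreme among n values cannot exceed (n-1)/sqrt(n) SDs, so a
        # 3-SD removable outlier needs n >= 11; use 19 clustered + 1 extreme
        vals = np.r_[rng.normal(100, 5, 19), 200.0]
        df = pd.DataFrame([raw() for _ in vals]).assign(w120=vals)
        out = filter_outliers(df, "w120", k=3)
        mu, sd = vals.mean(), vals.std(ddof=1)
        keep_bf = np.abs(vals - mu) <= 3 * sd
        assert keep_bf.sum() == 19  # the 200 is the one outlier
        np.testing.assert_array_equal(out["w120"].notna().to_numpy(), keep_bf)

    def test_zero_sd_guard(self):
        df = pd.DataFrame([raw() for _ in range(5)]).assign(w120=50.0)
        assert filter_outliers(df, "w120")["w120"].notna().all()

    def test_random_tables_against_brute_force(self, rng):
        for _ in range(20):
            vals = rng.normal(150, 30, size=40)
            vals[rng.random(40) < 0.2] = np.nan
            df = pd.DataFrame([raw() for _ in vals]).assign(w240=vals)
            out = filter_outliers(df, "w240", k=2.5)
            ok = ~np.isnan(vals)
            mu = np.nanmean(vals)
            sd = np.nanstd(vals, ddof=1)
            expect = np.where(ok & (np.abs(vals - mu) > 2.5 * sd), np.nan, vals)
            np.testing.assert_array_equal(out["w240"].to_numpy(), expect)


class TestStructureFilter:
    def make(self, cgs, sires, vals):
        return pd.DataFrame(
            [raw(animal=f"A{i}", sire=s) for i, s in enumerate(sires)]
        ).assign(cg=cgs, w120=vals)

    def test_small_cg_blanked(self):
        df = self.make(["g1"] * 2 + ["g2"] * 3, ["S1"] * 5, [100.0] * 5)
        out = filter_structure(df, traits=["w120"])
        assert out["w120"].isna().tolist() == [True, True, False, False, False]

    def test_sire_boundary_kept(self):
        df = self.make(["g1"] * 3, ["S1"] * 3, [100.0] * 3)
        out = filter_structure(df, traits=["w120"])
        assert out["w120"].notna().all()

    def test_one_pass_no_iteration(self):
        # CG of 3 where the sire rule removes one: survivors are kept
        cgs = ["g1"] * 3 + ["g2"] * 3
        sires = ["S1", "S2", "S2", "S2", "S2", "S1"]
        df = self.make(cgs, sires, [100.0] * 6)
        out = filter_structure(df, traits=["w120"])
        # S1 has 2 offspring -> blanked; g1 keeps its remaining 2 (no re-check)
        assert out["w120"].isna().tolist() == [True, False, False, False, False, True]


class TestFixedEffectScreen:
    def test_one_way_anova_hand_sums(self):
        y = [1, 2, 3, 7, 8, 9]
        df = pd.DataFrame([raw(animal=f"A{i}", sex=g) for i, g in enumerate("AAABBB")])
        df["w120"] = y
        tab = screen_fixed_effects(df, "w120", effects=("sex",))
        row = tab.set_index("effect").loc["sex"]
        assert row["df"] == 1
        assert row["F"] == pytest.approx(54.0)

    def test_zero_slope_covariate(self):
        # covariate balanced within sex so it is orthogonal to the signal
        df = pd.DataFrame(
            [raw(animal=f"A{i}", sex="M" if i % 2 else "F", dam_age=3 + (i // 2) % 2) for i in range(16)]
        )
        df["w120"] = 100.0 + (df["sex"] == "M") * 10
        tab = screen_fixed_effects(df, "w120", effects=("sex", "dam_age"))
        assert tab.set_index("effect").loc["dam_age", "F"] == pytest.approx(0.0, abs=1e-18)

    def test_single_level_factor_excluded(self):
        df = pd.DataFrame([raw(animal=f"A{i}", dam_age=float(i)) for i in range(8)])
        df["w120"] = np.arange(8.0)
        tab = screen_fixed_effects(df, "w120", effects=("sex", "dam_age"))
        assert "sex" not in tab["effect"].tolist()

    def test_cross_check_against_statsmodels(self, rng):
        import statsmodels.formula.api as smf

        n = 60
        df = pd.DataFrame(
            [raw(animal=f"A{i}", sex=rng.choice(["M", "F"]), herd=str(rng.integers(1, 4)),
                 dam_age=float(rng.integers(3, 10))) for i in range(n)]
        )
        df["w120"] = (
            100 + 8 * (df["sex"] == "M") + 3 * df["herd"].astype(int)
            + 1.5 * df["dam_age"] + rng.normal(0, 5, n)
        )
        tab = screen_fixed_effects(df, "w120", effects=("sex", "herd", "dam_age")).set_index("effect")
        fit_full = smf.ols("w120 ~ C(sex) + C(herd) + dam_age", df).fit()
        for eff, red in [("sex", "w120 ~ C(herd) + dam_age"),
                         ("herd", "w120 ~ C(sex) + dam_age"),
                         ("dam_age", "w120 ~ C(sex) + C(herd)")]:
            fit_red = smf.ols(red, df).fit()
            F_sm = (fit_red.ssr - fit_full.ssr) / (fit_red.df_resid - fit_full.df_resid) / fit_full.mse_resid
            assert tab.loc[eff, "F"] == pytest.approx(F_sm, rel=1e-8)


def test_pipeline_counts_monotone(rng):
    n = 60
    rows = []
    for i in range(n):
        rows.append(
            raw(animal=f"A{i}", sire=f"S{i % 6}", herd=str(1 + i % 2),
                birth_date=f"199{i % 3}-0{1 + i % 9}-15",
                bw=float(rng.normal(30, 3)), ww=float(rng.normal(180, 15)),
                weaning_age=float(rng.integers(200, 280)),
                aw=float(rng.normal(260, 20)), last_age=float(rng.integers(420, 540)))
        )
    df, report = preprocess_records(pd.DataFrame(rows))
    counts = [s["n_records"] for s in report.stages]
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    assert df["cg"].notna().all()
    assert df[TRAITS].notna().any(axis=1).all()
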