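import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from thalnet.stats import (
    bonferroni,
    control_profile,
    edgewise_map,
    independent_t,
    mixed_anova,
    one_sample_t,
    paired_t,
    partial_eta_from_F,
    pearson_corr,
)


class TestOneSampleT:
    def test_from_summary_statistics(self):
        res = one_sample_t(mean=-0.56, sd=1.01, n=136)
        assert round(res.t, 2) == -6.47
        assert round(res.cohen_d, 2) == 0.55

    def test_summary_equals_raw_sample(self):
        """Any raw sample with the same moments gives the same t."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        x = (x - x.mean()) / x.std(ddof=1)  # exact mean 0, sd 1
        x = 0.3 + 0.8 * x
        res_raw = one_sample_t(x)
        res_sum = one_sample_t(mean=0.3, sd=0.8, n=50)
        assert np.isclose(res_raw.t, res_sum.t, atol=1e-12)
        assert np.isclose(res_raw.p_uncorrected, res_sum.p_uncorrected, atol=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.2, 1.0, 40)
        res = one_sample_t(x)
        t, p = sps.ttest_1samp(x, 0.0)
        assert np.isclose(res.t, t) and np.isclose(res.p_uncorrected, p)

    def test_all_zero_sample_is_null(self):
        res = one_sample_t(np.zeros(10))
        assert (res.t, res.p_uncorrected, res.cohen_d) == (0.0, 1.0, 0.0)

    def test_zero_spread_off_target_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t(np.full(10, 2.0))


class TestPairedT:
    def test_equals_one_sample_on_differences(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=30), rng.normal(size=30)
        res = paired_t(a, b)
        ref = one_sample_t(a - b)
        assert np.isclose(res.t, ref.t, atol=1e-14)
        assert res.mean_diff == pytest.approx((a - b).mean())

    def test_identical_samples_give_zero(self):
        a = np.arange(10.0)
        res = paired_t(a, a)
        assert res.t == 0.0 and res.mean_diff == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_t(np.ones(4), np.ones(5))


class TestIndependentT:
    def test_identical_distributions(self):
        a = np.array([1.0, 2.0, 3.0])
        res = independent_t(a, a.copy())
        assert res.t == 0.0 and res.p_uncorrected == 1.0

    def test_pooled_matches_hand_computation(self):
        a = np.array([5.0, 6.0, 7.0, 8.0])
        b = np.array([1.0, 2.0, 3.0])
        na, nb = 4, 3
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        res = independent_t(a, b)
        assert np.isclose(res.t, t_hand, atol=1e-12)
        assert res.df == 5


class TestEtaAndBonferroni:
    @pytest.mark.parametrize(
        "F,df1,df2,expected",
        [(6.30, 1, 204, 0.03), (5.30, 3, 77, 0.17), (2.75, 3, 125, 0.06),
         (0.0, 3, 100, 0.0)],
    )
    def test_partial_eta_conversion(self, F, df1, df2, expected):
        assert round(partial_eta_from_F(F, df1, df2), 2) == expected

    def test_bonferroni(self):
        assert bonferroni(0.2, 8) == 1.0
        assert bonferroni(0.05, 1) == 0.05
        assert bonferroni(0.004, 8) == pytest.approx(0.032)
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)

    @given(p=st.floats(0, 1), m=st.integers(1, 50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bonferroni_bounds(self, p, m):
        out = bonferroni(p, m)
        assert 0 <= out <= 1 and out >= p


def _long(Y, grp, within_names=None):
    n, k = Y.shape
    rows = []
    for i in range(n):
        for j in range(k):
            rows.append(dict(subject=f"s{i}", group=grp[i],
                             cond=(within_names or [f"c{j}" for j in range(k)])[j],
                             value=Y[i, j]))
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_df_structure_two_group_eight_levels(self):
        """N=206, 2 groups, 8 within levels -> within df (7, 198), between (1, 204)."""
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(206, 8))
        grp = np.array(["a"] * 136 + ["b"] * 70)
        res = {(r.effect, r.statistic): r
               for r in mixed_anova(_long(Y, grp), "value", "subject", ["cond"], "group")}
        r = res[("cond", "pillai")]
        assert (r.df1, r.df2) == (7, 198)
        r = res[("group", "F")]
        assert (r.df1, r.df2) == (1, 204)

    def test_df_structure_three_way(self):
        """N=136, 3 groups, 4x2 within -> (3,131), (6,264), (1,133)."""
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(136, 8))
        grp = np.array(["TLE"] * 81 + ["FLE"] * 36 + ["PQE"] * 19)
        rows = []
        nuclei = ["ant", "lat", "med", "pul"]
        for i in range(136):
            c = 0
            for nu in nuclei:
                for la in ("ipsi", "contra"):
                    rows.append(dict(subject=f"s{i}", group=grp[i],
                                     nucleus=nu, lat=la, value=Y[i, c]))
                    c += 1
        res = {(r.effect, r.statistic): r
               for r in mixed_anova(pd.DataFrame(rows), "value", "subject",
                                    ["nucleus", "lat"], "group")}
        assert (res[("nucleus", "pillai")].df1, res[("nucleus", "pillai")].df2) == (3, 131)
        assert (res[("nucleus x group", "pillai")].df1,
                res[("nucleus x group", "pillai")].df2) == (6, 264)
        assert (res[("lat", "pillai")].df1, res[("lat", "pillai")].df2) == (1, 133)
        assert (res[("lat x group", "pillai")].df1,
                res[("lat x group", "pillai")].df2) == (2, 133)
        assert (res[("nucleus x lat", "pillai")].df1,
                res[("nucleus x lat", "pillai")].df2) == (3, 131)
        assert (res[("nucleus x lat x group", "pillai")].df1,
                res[("nucleus x lat x group", "pillai")].df2) == (6, 264)
        assert (res[("group", "F")].df1, res[("group", "F")].df2) == (2, 133)

    def test_matches_pingouin_balanced(self):
        """Exact F agreement with an independent implementation."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(30, 2)) + np.array([0.0, 0.5])
        grp = np.repeat(["A", "B"], 15)
        mine = {(r.effect, r.statistic): r
                for r in mixed_anova(_long(Y, grp), "value", "subject", ["cond"], "group")}
        ref = pg.mixed_anova(
            data=_long(Y, grp), dv="value", within="cond",
            subject="subject", between="group",
        ).set_index("Source")
        assert mine[("cond", "pillai")].F == pytest.approx(ref.loc["cond", "F"])
        assert mine[("group", "F")].F == pytest.approx(ref.loc["group", "F"])
        assert mine[("cond x group", "pillai")].F == pytest.approx(
            ref.loc["Interaction", "F"]
        )

    def test_matches_statsmodels_manova(self):
        """Pillai and Wilks agree with statsmodels on contrast scores."""
        MANOVA = pytest.importorskip("statsmodels.multivariate.manova").MANOVA
        rng = np.random.default_rng(7)
        k = 4
        grp = np.repeat(["A", "B", "C"], [14, 15, 16])
        Y = rng.normal(size=(45, k))
        mine = {(r.effect, r.statistic): r
                for r in mixed_anova(_long(Y, grp), "value", "subject", ["cond"], "group")}
        Cm = np.zeros((k, k - 1))
        Cm[0, :] = 1
        for j in range(k - 1):
            Cm[j + 1, j] = -1
        dat = pd.DataFrame(Y @ Cm, columns=["d1", "d2", "d3"])
        dat["group"] = grp
        mv = MANOVA.from_formula(
            "d1 + d2 + d3 ~ C(group, Sum)", data=dat
        ).mv_test()
        for term, effect in (("Intercept", "cond"),
                             ("C(group, Sum)", "cond x group")):
            stat = mv.results[term]["stat"]
            assert mine[(effect, "pillai")].value == pytest.approx(
                stat.loc["Pillai's trace", "Value"]
            )
            assert mine[(effect, "wilks")].value == pytest.approx(
                stat.loc["Wilks' lambda", "Value"]
            )
            assert mine[(effect, "wilks")].F == pytest.approx(
                stat.loc["Wilks' lambda", "F Value"]
            )

    def test_incomplete_design_rejected(self):
        df = _long(np.random.default_rng(0).normal(size=(6, 2)),
                   ["A", "A", "A", "B", "B", "B"])
        df = df.drop(index=3)
        with pytest.raises(ValueError, match="incomplete"):
            mixed_anova(df, "value", "subject", ["cond"], "group")

    def test_eta_conversion_invariant(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(40, 4))
        grp = np.repeat(["A", "B"], 20)
        for r in mixed_anova(_long(Y, grp), "value", "subject", ["cond"], "group"):
            assert r.partial_eta_sq == pytest.approx(
                r.F * r.df1 / (r.F * r.df1 + r.df2), abs=1e-12
            )


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = pearson_corr(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_recovers_planted_correlation(self):
        rng = np.random.default_rng(4)
        rs = []
        for _ in range(30):
            x = rng.normal(size=89)
            y = -0.3 / np.sqrt(1 - 0.09) * x + rng.normal(size=89)
            rs.append(pearson_corr(x, y).r)
        assert np.mean(rs) == pytest.approx(-0.3, abs=0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr(np.ones(10), np.arange(10.0))


class TestEdgewise:
    def _mats(self, atlas, n, seed, bump=None):
        rng = np.random.default_rng(seed)
        out = {}
        for k in range(n):
            a = rng.normal(0, 0.1, (122, 122))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0)
            if bump is not None:
                i, j, v = bump
                a[i, j] = a[j, i] = a[i, j] + v
            out[f"x{seed}_{k}"] = a
        return out

    def test_identical_sets_give_zero_t(self, atlas):
        mats = self._mats(atlas, 4, 0)
        emap = edgewise_map(mats, dict(mats), atlas, "pulvinar", "L")
        assert len(emap) == 121
        assert np.allclose(emap["t"], 0.0)

    def test_planted_edge_carries_extreme_t(self, atlas):
        i = atlas.thalamic_index("anterior", "L")
        j = atlas.index("L_hippocampus")
        a = self._mats(atlas, 10, 1, bump=(i, j, -0.9))
        b = self._mats(atlas, 10, 2)
        emap = edgewise_map(a, b, atlas, "anterior", "L")
        worst = emap.loc[emap["t"].idxmin(), "target"]
        assert worst == "L_hippocampus"

    def test_control_profile_rank_and_topk(self, atlas):
        from thalnet.cohort import mean_connectivity_z

        z = mean_connectivity_z(atlas)
        rng = np.random.default_rng(5)
        mats = {}
        for k in range(6):
            nz = rng.normal(0, 0.02, (122, 122))
            nz = (nz + nz.T) / 2
            np.fill_diagonal(nz, 0)
            mats[f"c{k}"] = np.tanh(z + nz)
        prof = control_profile(mats, atlas, "anterior", top_k=10)
        assert len(prof) == 10
        # the designated strongest partner of the anterior nucleus
        assert prof.loc[0, "target"] == "amygdala"
        prof_pul = control_profile(mats, atlas, "pulvinar", top_k=10)
        assert prof_pul.loc[0, "target"] == "hippocampus"
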