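import numpy as np
import pandas as pd
import pytest

from thalnet.normalize import (
    StagedTable,
    adjust_for_etiv,
    fit_normative_model,
    relabel_laterality,
    zscore_to_controls,
)


def _cohort_frame(n=80, seed=0, slope=0.0, sex_gap=0.0, noise=1.0):
    rng = np.random.default_rng(seed)
    idx = [f"s{i}" for i in range(n)]
    age = pd.Series(rng.uniform(5, 18, n), index=idx)
    sex = pd.Series(np.where(rng.random(n) < 0.5, "F", "M"), index=idx)
    table = pd.DataFrame(
        {
            "L_anterior": 10 + slope * age + sex_gap * (sex == "M")
            + rng.normal(0, noise, n),
            "R_anterior": 10 + slope * age + rng.normal(0, noise, n),
        },
        index=idx,
    )
    return table, age, sex


class TestEtivAdjust:
    def test_exact_proportionality_removed(self):
        idx = [f"s{i}" for i in range(30)]
        etiv = pd.Series(np.linspace(1.2e6, 1.6e6, 30), index=idx)
        vols = pd.DataFrame({"v": 0.001 * etiv})
        ctrl = pd.Series(True, index=idx)
        adj = adjust_for_etiv(vols, etiv, ctrl)
        assert adj["v"].std() == pytest.approx(0.0, abs=1e-9)

    def test_constant_etiv_is_identity_up_to_constant(self):
        idx = [f"s{i}" for i in range(20)]
        rng = np.random.default_rng(1)
        etiv = pd.Series(1.4e6, index=idx)
        vols = pd.DataFrame({"v": rng.normal(100, 5, 20)}, index=idx)
        ctrl = pd.Series(True, index=idx)
        adj = adjust_for_etiv(vols, etiv, ctrl)
        assert np.allclose(adj["v"] - adj["v"].mean(),
                           vols["v"] - vols["v"].mean())

    def test_group_effect_invariant_to_adjustment(self):
        """An eTIV-independent deficit survives the residual adjustment."""
        rng = np.random.default_rng(2)
        n = 400
        idx = [f"s{i}" for i in range(n)]
        ctrl = pd.Series(np.arange(n) < n // 2, index=idx)
        etiv = pd.Series(rng.normal(1.4e6, 1.2e5, n), index=idx)
        # eTIV contributes little variance relative to noise, so removing it
        # leaves the group separation essentially unchanged
        base = 0.00001 * etiv + rng.normal(0, 12, n)
        vols = pd.DataFrame({"v": base - 10 * (~ctrl)})
        adj = adjust_for_etiv(vols, etiv, ctrl)

        def cohen_d(tab):
            a, b = tab[ctrl.values], tab[~ctrl.values]
            sp = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            return (a.mean() - b.mean()) / sp

        assert cohen_d(adj["v"]) == pytest.approx(cohen_d(vols["v"]), rel=0.1)

    def test_missing_etiv_rejected(self):
        table, age, sex = _cohort_frame(10)
        etiv = pd.Series(np.nan, index=table.index)
        with pytest.raises(ValueError, match="missing eTIV"):
            adjust_for_etiv(table, etiv, pd.Series(True, index=table.index))


class TestNormativeModel:
    def test_recovers_planted_age_slope(self):
        slopes = []
        for seed in range(10):
            table, age, sex = _cohort_frame(70, seed=seed, slope=0.1)
            model = fit_normative_model(table, age, sex)
            slopes.append(model.age_slope[0])
        assert np.mean(slopes) == pytest.approx(0.1, abs=0.02)

    def test_null_slopes_near_zero(self):
        table, age, sex = _cohort_frame(200, seed=3)
        model = fit_normative_model(table, age, sex)
        assert np.allclose(model.age_slope, 0.0, atol=0.05)

    def test_residual_mean_zero(self):
        table, age, sex = _cohort_frame(50, seed=4, slope=0.2, sex_gap=1.0)
        model = fit_normative_model(table, age, sex)
        pred = model.predict(age, sex)
        assert np.allclose((table - pred).mean(), 0.0, atol=1e-10)

    def test_single_sex_rejected(self):
        table, age, sex = _cohort_frame(30, seed=5)
        sex[:] = "F"
        with pytest.raises(ValueError, match="both sexes"):
            fit_normative_model(table, age, sex)

    def test_too_few_controls_rejected(self):
        table, age, sex = _cohort_frame(8)
        with pytest.raises(ValueError, match="at least 10"):
            fit_normative_model(table, age, sex)


class TestZScore:
    def test_controls_score_near_standard(self):
        table, age, sex = _cohort_frame(120, seed=6, slope=0.1, sex_gap=0.5)
        model = fit_normative_model(table, age, sex)
        z = zscore_to_controls(table, model, age, sex)
        n = len(table)
        assert np.allclose(z.mean(), 0.0, atol=1e-10)
        assert np.allclose(z.std(ddof=1), 1.0, atol=1 / np.sqrt(2 * n) + 0.05)

    def test_value_at_prediction_is_zero(self):
        table, age, sex = _cohort_frame(40, seed=7, slope=0.3)
        model = fit_normative_model(table, age, sex)
        probe_age = pd.Series([10.0], index=["p"])
        probe_sex = pd.Series(["M"], index=["p"])
        pred = model.predict(probe_age, probe_sex)
        z = zscore_to_controls(pred, model, probe_age, probe_sex)
        assert np.allclose(z, 0.0, atol=1e-12)

    def test_hemisphere_separation(self):
        """Shifting only right-hemisphere controls recalibrates only R."""
        table, age, sex = _cohort_frame(100, seed=8)
        shifted = table.copy()
        shifted["R_anterior"] += 5.0
        m0 = fit_normative_model(table, age, sex)
        m1 = fit_normative_model(shifted, age, sex)
        probe = table.iloc[[0]]
        z0 = zscore_to_controls(probe, m0, age, sex)
        z1 = zscore_to_controls(probe, m1, age, sex)
        assert np.isclose(z0["L_anterior"].iloc[0], z1["L_anterior"].iloc[0])
        assert not np.isclose(z0["R_anterior"].iloc[0], z1["R_anterior"].iloc[0])

    def test_unknown_feature_rejected(self):
        table, age, sex = _cohort_frame(40, seed=9)
        model = fit_normative_model(table, age, sex)
        with pytest.raises(KeyError):
            zscore_to_controls(table.rename(columns={"L_anterior": "X"}),
                               model, age, sex)


class TestRelabel:
    def _z(self):
        return pd.DataFrame(
            {"L_pulvinar": [-0.7, -0.7], "R_pulvinar": [0.2, 0.2]},
            index=["left_focus", "right_focus"],
        )

    def test_left_and_right_focus_mapping(self):
        focus = pd.Series(["L", "R"], index=["left_focus", "right_focus"])
        out = relabel_laterality(self._z(), focus)
        assert out.loc["left_focus", "ipsi_pulvinar"] == -0.7
        assert out.loc["left_focus", "contra_pulvinar"] == 0.2
        assert out.loc["right_focus", "ipsi_pulvinar"] == 0.2
        assert out.loc["right_focus", "contra_pulvinar"] == -0.7

    def test_idempotent(self):
        focus = pd.Series(["L", "R"], index=["left_focus", "right_focus"])
        once = relabel_laterality(self._z(), focus)
        twice = relabel_laterality(once, focus)
        pd.testing.assert_frame_equal(once, twice)

    def test_controls_rejected(self):
        focus = pd.Series(["L", "none"], index=["left_focus", "right_focus"])
        with pytest.raises(ValueError, match="focus side"):
            relabel_laterality(self._z(), focus)

    def test_mirror_symmetry(self):
        """Flipping focus sides and hemispheres leaves ipsi/contra intact."""
        rng = np.random.default_rng(10)
        idx = [f"p{i}" for i in range(40)]
        z = pd.DataFrame(
            {"L_medial": rng.normal(size=40), "R_medial": rng.normal(size=40)},
            index=idx,
        )
        focus = pd.Series(np.where(rng.random(40) < 0.6, "L", "R"), index=idx)
        mirrored = z.rename(columns={"L_medial": "R_medial",
                                     "R_medial": "L_medial"})
        flipped = focus.map({"L": "R", "R": "L"})
        out = relabel_laterality(z, focus)
        out_m = relabel_laterality(mirrored, flipped)
        pd.testing.assert_frame_equal(out, out_m)


class TestStageOrdering:
    def test_out_of_order_rejected(self):
        table, _, _ = _cohort_frame(12)
        staged = StagedTable(table, "raw").advance(table, "harmonized")
        staged = staged.advance(table, "etiv_adjusted")
        with pytest.raises(ValueError, match="cannot follow"):
            staged.advance(table, "harmonized")

    def test_skipping_forward_allowed(self):
        table, _, _ = _cohort_frame(12)
        staged = StagedTable(table, "harmonized")
        assert staged.advance(table, "z").stage == "z"
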