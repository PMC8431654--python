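"""Clock representation, prediction, fitting and delta-age."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from epiage import clocks, synthetic
from epiage.clocks import (
    ClockDefinition,
    CollinearityError,
    MissingCpGError,
    age_transform,
    age_transform_inverse,
    ba3_clock,
)


def _betas(values: dict[str, list[float]], cpgs) -> pd.DataFrame:
    return pd.DataFrame(values, index=cpgs)


class TestBa3Clock:
    CPGS = ["CCDC102B", "FHL2", "PDE4C"]

    def test_intercept_at_zero_methylation(self):
        pred = clocks.predict_age(_betas({"s": [0, 0, 0]}, self.CPGS), ba3_clock())
        assert pred["predicted_age"][0] == pytest.approx(3.86, abs=1e-12)

    def test_full_hypomethylating_cpg(self):
        pred = clocks.predict_age(_betas({"s": [100, 0, 0]}, self.CPGS), ba3_clock())
        assert pred["predicted_age"][0] == pytest.approx(3.86 - 34.0, abs=1e-9)

    def test_hand_computed_mixed_profile(self):
        # -0.34*30 + 0.83*40 + 1.18*25 + 3.86 = 56.36
        pred = clocks.predict_age(_betas({"s": [30, 40, 25]}, self.CPGS), ba3_clock())
        assert pred["predicted_age"][0] == pytest.approx(56.36, abs=1e-9)


class TestPredictAge:
    def test_identity_single_cpg_clock(self):
        c = ClockDefinition("id", (("c1", 1.0),), 0.0)
        pred = clocks.predict_age(_betas({"a": [33.0], "b": [61.5]}, ["c1"]), c)
        assert list(pred["predicted_age"]) == [33.0, 61.5]

    def test_matches_explicit_dot_product(self, rng):
        cpgs = [f"c{i}" for i in range(5)]
        w = rng.normal(size=5)
        c = ClockDefinition("r", tuple(zip(cpgs, w)), intercept=2.5)
        mat = pd.DataFrame(rng.uniform(0, 100, (5, 7)), index=cpgs,
                           columns=[f"s{j}" for j in range(7)])
        pred = clocks.predict_age(mat, c)
        for j, s in enumerate(mat.columns):
            expect = sum(w[i] * mat.iloc[i, j] for i in range(5)) + 2.5
            assert pred.loc[pred.sample_id == s, "predicted_age"].item() == pytest.approx(expect)

    def test_missing_cpg_error_lists_them(self):
        with pytest.raises(MissingCpGError, match="PDE4C"):
            clocks.predict_age(_betas({"s": [1, 2]}, ["CCDC102B", "FHL2"]), ba3_clock())

    def test_drop_sample_policy(self):
        mat = _betas({"a": [10, 20, 30], "b": [10, np.nan, 30]},
                     ["CCDC102B", "FHL2", "PDE4C"])
        pred = clocks.predict_age(mat, ba3_clock(), missing_policy="drop_sample")
        assert list(pred["sample_id"]) == ["a"]

    def test_mean_impute_policy(self):
        mat = _betas({"a": [10.0, 20.0, 30.0], "b": [10.0, np.nan, 30.0]},
                     ["CCDC102B", "FHL2", "PDE4C"])
        pred = clocks.predict_age(mat, ba3_clock(), missing_policy="mean_impute")
        # NaN filled with the row mean (= a's value), so b predicts like a
        assert pred["predicted_age"][1] == pytest.approx(pred["predicted_age"][0])

    def test_zero_weight_term_never_changes_predictions(self, rng):
        cpgs = ["x", "y"]
        mat = pd.DataFrame(rng.uniform(0, 100, (3, 4)), index=cpgs + ["z"])
        base = ClockDefinition("b", (("x", 0.7), ("y", -0.2)), 1.0)
        extended = ClockDefinition("b", (("x", 0.7), ("y", -0.2), ("z", 0.0)), 1.0)
        np.testing.assert_allclose(
            clocks.predict_age(mat, base)["predicted_age"],
            clocks.predict_age(mat, extended)["predicted_age"],
        )

    @given(alpha=st.floats(0.1, 3.0))
    def test_linearity_of_zero_intercept_identity_clock(self, alpha):
        c = ClockDefinition("lin", (("c1", 0.5), ("c2", -0.1)), 0.0)
        mat = _betas({"s": [30.0, 10.0]}, ["c1", "c2"])
        p1 = clocks.predict_age(mat, c)["predicted_age"][0]
        p2 = clocks.predict_age(mat * alpha, c)["predicted_age"][0]
        assert p2 == pytest.approx(alpha * p1, rel=1e-9)

    def test_log_linear_transform_applied(self):
        c = ClockDefinition("h", (("c1", 1.0),), 0.0, transform="log_linear", adult_age=20)
        mat = _betas({"young": [-0.5], "old": [2.0]}, ["c1"])
        pred = clocks.predict_age(mat, c)
        assert pred["predicted_age"][0] == pytest.approx(21 * np.exp(-0.5) - 1)
        assert pred["predicted_age"][1] == pytest.approx(21 * 2.0 + 20)


class TestAgeTransform:
    @given(age=st.floats(0.0, 120.0))
    def test_round_trip_identity(self, age):
        back = age_transform_inverse(age_transform(age))
        assert float(back) == pytest.approx(age, abs=1e-9)

    def test_continuous_at_adult_age(self):
        lo = age_transform(20.0 - 1e-9)
        hi = age_transform(20.0 + 1e-9)
        assert abs(lo - hi) < 1e-8


class TestFitClock:
    def test_exact_interpolation_of_linear_model(self, rng):
        cpgs = ["a", "b", "c"]
        mat = pd.DataFrame(rng.uniform(0, 100, (3, 30)), index=cpgs)
        truth = ClockDefinition("t", (("a", 0.4), ("b", -0.3), ("c", 1.1)), 5.0)
        ages = clocks.predict_age(mat, truth)["predicted_age"].to_numpy()
        fit = clocks.fit_clock(mat, ages, cpgs)
        np.testing.assert_allclose(
            [dict(fit.clock.terms)[c] for c in cpgs], [0.4, -0.3, 1.1], atol=1e-8
        )
        assert fit.clock.intercept == pytest.approx(5.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.mae == pytest.approx(0.0, abs=1e-8)

    def test_duplicated_rows_leave_coefficients_unchanged(self, rng):
        cpgs = ["a", "b"]
        mat = pd.DataFrame(rng.uniform(0, 100, (2, 25)), index=cpgs)
        ages = rng.uniform(18, 74, 25)
        f1 = clocks.fit_clock(mat, ages, cpgs)
        doubled = pd.concat([mat, mat.add_suffix("_dup", axis=1)], axis=1)
        f2 = clocks.fit_clock(doubled, np.concatenate([ages, ages]), cpgs)
        np.testing.assert_allclose(
            [w for _, w in f1.clock.terms], [w for _, w in f2.clock.terms], atol=1e-9
        )

    def test_collinear_design_names_offender(self, rng):
        mat = pd.DataFrame(rng.uniform(0, 100, (1, 20)), index=["a"])
        mat.loc["b"] = 2.0 * mat.loc["a"]
        with pytest.raises(CollinearityError, match="b"):
            clocks.fit_clock(mat, rng.uniform(18, 74, 20), ["a", "b"])

    def test_noise_free_cohort_inverts_generating_model(self, noisefree_cohort):
        """Regressing age on a single noise-free CpG recovers the inverse of
        its generating line (weight 1/b, intercept -a/b) and reproduces the
        true ages.  (All three CpGs at once are exactly collinear with the
        intercept on noise-free data — covered by the collinearity test.)"""
        _, models, betas, ages = noisefree_cohort
        m = next(mod for mod in models if mod.cpg_id == "FHL2")
        fit = clocks.fit_clock(betas, ages, ["FHL2"])
        assert dict(fit.clock.terms)["FHL2"] == pytest.approx(1 / m.slope_b, abs=1e-8)
        assert fit.clock.intercept == pytest.approx(-m.baseline_a / m.slope_b, abs=1e-6)
        pred = clocks.predict_age(betas, fit.clock)["predicted_age"].to_numpy()
        np.testing.assert_allclose(pred, ages, atol=1e-7)

    def test_noise_free_collinear_cpgs_detected(self, noisefree_cohort):
        """Three noise-free age-driven CpGs are affinely dependent; the fit
        must refuse rather than return an arbitrary coefficient split."""
        _, _, betas, ages = noisefree_cohort
        with pytest.raises(CollinearityError):
            clocks.fit_clock(betas, ages)

    def test_needs_more_samples_than_cpgs(self, rng):
        mat = pd.DataFrame(rng.uniform(0, 100, (3, 4)), index=["a", "b", "c"])
        with pytest.raises(ValueError, match="samples"):
            clocks.fit_clock(mat, [30, 40, 50, 60], ["a", "b", "c"])


class TestDeltaAge:
    def _sheet(self):
        return pd.DataFrame(
            {"sample_id": ["a", "b"], "age": [50.0, 56.36], "group": ["healthy"] * 2}
        )

    def test_sign_convention_positive_is_acceleration(self):
        preds = pd.DataFrame(
            {"sample_id": ["a", "b"], "clock": "x", "predicted_age": [56.36, 56.36]}
        )
        out = clocks.delta_age(preds, self._sheet())
        assert out["delta_age"][0] == pytest.approx(6.36)
        assert out["delta_age"][1] == pytest.approx(0.0)

    def test_order_invariance(self):
        preds = pd.DataFrame(
            {"sample_id": ["b", "a"], "clock": "x", "predicted_age": [60.0, 40.0]}
        )
        out = clocks.delta_age(preds, self._sheet()).set_index("sample_id")
        assert out.loc["a", "delta_age"] == pytest.approx(40.0 - 50.0)
        assert out.loc["b", "delta_age"] == pytest.approx(60.0 - 56.36)

    def test_unmatched_sample_raises(self):
        preds = pd.DataFrame({"sample_id": ["zz"], "clock": "x", "predicted_age": [40.0]})
        with pytest.raises(KeyError, match="zz"):
            clocks.delta_age(preds, self._sheet())
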