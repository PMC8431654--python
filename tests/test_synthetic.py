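"""Generator behaviour: determinism, distributional calibration, ground truth."""
import numpy as np
import pandas as pd
import pytest
import scipy.stats

from epiage import clocks, synthetic
from epiage.synthetic import CpGAgeModel, SampleRecord


class TestGenerateCohort:
    def test_sizes_and_age_bounds(self):
        cohort = synthetic.generate_cohort(95, (18, 74), seed=1)
        assert len(cohort) == 95
        ages = np.array([s.age for s in cohort])
        assert ages.min() >= 18 and ages.max() <= 74
        assert all(s.group == "healthy" for s in cohort)
        assert len({s.sample_id for s in cohort}) == 95

    def test_degenerate_range_gives_exact_age(self):
        (rec,) = synthetic.generate_cohort(1, (30, 30), seed=0)
        assert rec.age == 30.0

    def test_group_counts_match_multinomial_sampling(self):
        """Counts sit within 3 sigma of Binomial(n, p) for a 50/50 split."""
        n, p = 1000, 0.5
        cohort = synthetic.generate_cohort(
            n, (18, 74), {"healthy": p, "covid_ards": p}, seed=42
        )
        k = sum(s.group == "healthy" for s in cohort)
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(k - n * p) <= 3 * sigma

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n": 0, "age_range": (18, 74)},
            {"n": 10, "age_range": (74, 18)},
            {"n": 10, "age_range": (-5, 20)},
            {"n": 10, "age_range": (18, 74), "group_proportions": {"healthy": 0.7}},
        ],
    )
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            synthetic.generate_cohort(**kwargs, seed=0)

    def test_determinism(self):
        a = synthetic.generate_cohort(50, (18, 74), {"healthy": 0.6, "covid_ards": 0.4}, seed=9)
        b = synthetic.generate_cohort(50, (18, 74), {"healthy": 0.6, "covid_ards": 0.4}, seed=9)
        assert a == b


class TestSimulateBetas:
    def test_noise_free_line(self):
        s = [SampleRecord("x", 40.0, "healthy")]
        betas = synthetic.simulate_betas(s, [CpGAgeModel("c", 10.0, 0.5, 0.0)], seed=0)
        assert betas.loc["c", "x"] == pytest.approx(30.0)

    def test_clipping_at_scale_boundary(self):
        s = [SampleRecord("x", 50.0, "healthy")]
        betas = synthetic.simulate_betas(s, [CpGAgeModel("c", 99.0, 1.0, 0.0)], seed=0)
        assert betas.loc["c", "x"] == 100.0

    def test_empirical_noise_sd_in_sampling_band(self):
        """At one age with sd=3, 500 draws land in the Monte-Carlo band [2.6, 3.4]."""
        s = [SampleRecord(f"s{i}", 40.0, "healthy") for i in range(500)]
        betas = synthetic.simulate_betas(s, [CpGAgeModel("c", 50.0, 0.1, 3.0)], seed=7)
        assert 2.6 <= betas.loc["c"].std(ddof=1) <= 3.4

    def test_requires_a_model(self):
        with pytest.raises(ValueError):
            synthetic.simulate_betas([SampleRecord("x", 40.0, "healthy")], [], seed=0)

    def test_determinism(self):
        s = synthetic.generate_cohort(20, (18, 74), seed=3)
        m = list(synthetic.DEFAULT_CPG_MODELS)
        pd.testing.assert_frame_equal(
            synthetic.simulate_betas(s, m, seed=5), synthetic.simulate_betas(s, m, seed=5)
        )


class TestConsistentClock:
    def test_single_cpg_identity(self):
        c = synthetic.consistent_clock([CpGAgeModel("c", 0.0, 1.0, 0.0)])
        assert dict(c.terms)["c"] == pytest.approx(1.0)
        assert c.intercept == pytest.approx(0.0)

    def test_single_cpg_algebra(self):
        c = synthetic.consistent_clock([CpGAgeModel("c", 10.0, 0.5, 0.0)])
        assert dict(c.terms)["c"] == pytest.approx(2.0)
        assert c.intercept == pytest.approx(-20.0)
        betas = pd.DataFrame({"x": [10.0 + 0.5 * 40.0]}, index=["c"])
        assert clocks.predict_age(betas, c)["predicted_age"][0] == pytest.approx(40.0)

    def test_recovers_true_ages_on_noise_free_betas(self):
        """Mixed-sign 3-CpG models: noise-free predictions equal true age to 1e-9."""
        models = [
            CpGAgeModel("a", 60.0, -0.5, 0.0),
            CpGAgeModel("b", 20.0, 0.6, 0.0),
            CpGAgeModel("c", 10.0, 0.55, 0.0),
        ]
        rng = np.random.default_rng(0)
        ages = rng.uniform(18, 74, 100)
        samples = [SampleRecord(f"s{i}", float(a), "healthy") for i, a in enumerate(ages)]
        betas = synthetic.simulate_betas(samples, models, seed=1)
        pred = clocks.predict_age(betas, synthetic.consistent_clock(models))
        np.testing.assert_allclose(pred["predicted_age"].to_numpy(), ages, atol=1e-9)

    def test_default_models_calibrated_to_published_clock(self):
        """The default generator emulates the assay the published 3-CpG
        clock was trained on: noise-free default betas fed through that
        clock return the generating age exactly."""
        from epiage.clocks import ba3_clock

        models = [
            synthetic.CpGAgeModel(m.cpg_id, m.baseline_a, m.slope_b, 0.0)
            for m in synthetic.DEFAULT_CPG_MODELS
        ]
        cohort = synthetic.generate_cohort(50, (18, 74), seed=17)
        betas = synthetic.simulate_betas(cohort, models, seed=18)
        pred = clocks.predict_age(betas, ba3_clock())
        ages = np.array([s.age for s in cohort])
        np.testing.assert_allclose(pred["predicted_age"].to_numpy(), ages, atol=1e-9)

    def test_all_zero_slopes_rejected(self):
        with pytest.raises(ValueError, match="invertible"):
            synthetic.consistent_clock([CpGAgeModel("c", 10.0, 0.0, 1.0)])


class TestSimulateCellMixtures:
    def test_pure_sample_equals_reference_column(self, cell_reference):
        f = pd.Series(0.0, index=cell_reference.columns)
        f["CD4T"] = 1.0
        b = synthetic.simulate_cell_mixture_betas(f, cell_reference, noise_sd=0.0)
        pd.testing.assert_series_equal(b, cell_reference["CD4T"], check_names=False)

    def test_fifty_fifty_mixture_is_column_mean(self, cell_reference):
        f = pd.Series(0.0, index=cell_reference.columns)
        f[["CD4T", "CD8T"]] = 0.5
        b = synthetic.simulate_cell_mixture_betas(f, cell_reference, noise_sd=0.0)
        expected = cell_reference[["CD4T", "CD8T"]].mean(axis=1)
        pd.testing.assert_series_equal(b, expected, check_names=False)

    def test_covid_preset_shifts_toward_granulocyte_profile(self, cell_reference):
        """Granulocyte-discriminating CpGs move toward the Gran column under
        the disease preset, matching direct mixture arithmetic."""
        bh = synthetic.simulate_cell_mixture_betas(
            synthetic.HEALTHY_FRACTIONS, cell_reference, noise_sd=0.0
        )
        bc = synthetic.simulate_cell_mixture_betas(
            synthetic.COVID_FRACTIONS, cell_reference, noise_sd=0.0
        )
        expected = cell_reference.to_numpy() @ (
            synthetic.COVID_FRACTIONS - synthetic.HEALTHY_FRACTIONS
        ).to_numpy()
        np.testing.assert_allclose((bc - bh).to_numpy(), expected, atol=1e-9)
        gran_cpgs = [i for i in cell_reference.index if "Gran" in i]
        toward_gran = np.sign(cell_reference.loc[gran_cpgs, "Gran"] - bh[gran_cpgs])
        assert ((bc - bh)[gran_cpgs] * toward_gran > 0).all()

    def test_dimension_mismatch_rejected(self, cell_reference):
        with pytest.raises(ValueError):
            synthetic.simulate_cell_mixture_betas(
                pd.Series([0.5, 0.5], index=["CD4T", "CD8T"]), cell_reference
            )

    def test_fractions_must_sum_to_one(self, cell_reference):
        f = pd.Series(1.0 / 7, index=cell_reference.columns)
        with pytest.raises(ValueError, match="sum"):
            synthetic.simulate_cell_mixture_betas(f, cell_reference)


class TestSimulateTelomeres:
    def test_noise_free_attrition_line(self):
        s = [SampleRecord("x", 40.0, "healthy")]
        (m,) = synthetic.simulate_telomeres(s, 10.0, -0.05, 0.0, seed=0)
        assert m.mean_kb == pytest.approx(8.0)
        assert len(m.replicate_values) == 3
        assert m.replicate_values == (8.0, 8.0, 8.0)

    def test_intercept_at_age_zero_limit(self):
        s = [SampleRecord("x", 1e-9, "healthy")]
        (m,) = synthetic.simulate_telomeres(s, 9.5, -0.05, 0.0, seed=0)
        assert m.mean_kb == pytest.approx(9.5)

    def test_ols_slope_recovery_on_reference_cohort(self):
        """356 simulated controls: fitted OLS slope within 3 SE of truth."""
        cohort = synthetic.generate_cohort(356, (18, 80), seed=21)
        meas = synthetic.simulate_telomeres(cohort, 9.5, -0.05, 0.7, seed=22)
        res = scipy.stats.linregress([m.age for m in meas], [m.mean_kb for m in meas])
        assert abs(res.slope - (-0.05)) <= 3 * res.stderr


class TestGroundTruth:
    def test_json_round_trip(self):
        cohort = synthetic.generate_cohort(5, (18, 74), seed=2)
        gt = synthetic.GroundTruth(
            seed=2,
            samples=cohort,
            cpg_models=list(synthetic.DEFAULT_CPG_MODELS),
            telomere_params={"intercept_kb": 9.5, "slope": -0.05},
        )
        back = synthetic.GroundTruth.from_json(gt.to_json())
        assert back == gt
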