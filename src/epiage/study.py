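"""End-to-end synthetic study replica.

Wires the generators and analysis modules into the full workflow of the
underlying cohort design: a healthy control arm plus hospitalised patients
with and without ARDS, methylation-age prediction and delta-age group
comparison, leukocyte deconvolution with a disease-associated composition
shift, and age-adjusted telomere comparison against a healthy reference.

By construction the replica is a *null* for epigenetic age: clock CpGs
follow the same age-methylation models in every group (disease shifts only
the leukocyte composition), so delta-age comparisons should come out
non-significant — the study's qualitative headline reproduced under its
own null.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import clocks, deconvolution, stats, synthetic, telomere

__all__ = ["StudyReplicaResult", "run_study_replica"]

# cohort arm sizes mirroring the underlying study design
N_HEALTHY = 95
N_COVID_NO_ARDS = 20
N_COVID_ARDS = 27
N_TELOMERE_CONTROLS = 356
N_TELOMERE_PATIENTS = 19


@dataclass
class StudyReplicaResult:
    sheet: pd.DataFrame
    deltas: pd.DataFrame                 # per-sample delta-age annotations
    delta_age_tests: dict[str, stats.WelchResult]
    clock_metrics: stats.RegressionMetrics
    composition: pd.DataFrame            # per-cell-type healthy-vs-covid table
    telomere_comparison: dict

    @property
    def delta_age_p_values(self) -> dict[str, float]:
        return {k: v.p_value for k, v in self.delta_age_tests.items()}


def _fixed_size_cohort(rng: np.random.Generator, age_range=(18.0, 74.0)):
    """Fixed per-arm sample counts (study design, not multinomial draws)."""
    sizes = {
        "healthy": N_HEALTHY,
        "covid_no_ards": N_COVID_NO_ARDS,
        "covid_ards": N_COVID_ARDS,
    }
    samples, i = [], 0
    for group, n in sizes.items():
        ages = rng.uniform(age_range[0], age_range[1], size=n)
        for a in ages:
            samples.append(
                synthetic.SampleRecord(sample_id=f"S{i:04d}", age=float(a), group=group)
            )
            i += 1
    return samples


def run_study_replica(seed: int = 0, noise_sd: float | None = None) -> StudyReplicaResult:
    """Run the full pipeline on one synthetic cohort with known truth.

    ``noise_sd`` overrides the per-CpG beta noise of the default clock-CpG
    models (percent).  Methylation-age generation is identical across
    groups — the disease arms differ only in leukocyte composition — and
    telomere attrition follows the same model in patients and controls,
    so both the delta-age and the telomere comparisons are true nulls.
    """
    ss = np.random.SeedSequence(seed)
    s_cohort, s_beta, s_mix, s_tel_ref, s_tel_pat = [
        np.random.default_rng(c) for c in ss.spawn(5)
    ]

    samples = _fixed_size_cohort(s_cohort)
    sheet = synthetic.cohort_to_sheet(samples)

    models = list(synthetic.DEFAULT_CPG_MODELS)
    if noise_sd is not None:
        models = [
            synthetic.CpGAgeModel(m.cpg_id, m.baseline_a, m.slope_b, noise_sd)
            for m in models
        ]
    betas = synthetic.simulate_betas(
        samples, models, seed=int(s_beta.integers(2**31))
    )
    # the default generator is calibrated to the published clock, so the
    # replica applies exactly the clock the real analysis used
    clock = clocks.ba3_clock()
    preds = clocks.predict_age(betas, clock)
    deltas = clocks.delta_age(preds, sheet)

    def _delta(group_mask):
        return deltas.loc[group_mask, "delta_age"].to_numpy()

    g = deltas["group"]
    tests = {
        "healthy_vs_covid": stats.welch_t(_delta(g == "healthy"), _delta(g != "healthy")),
        "healthy_vs_covid_no_ards": stats.welch_t(
            _delta(g == "healthy"), _delta(g == "covid_no_ards")
        ),
        "healthy_vs_covid_ards": stats.welch_t(
            _delta(g == "healthy"), _delta(g == "covid_ards")
        ),
    }
    healthy = deltas["group"] == "healthy"
    metrics = stats.regression_metrics(
        deltas.loc[healthy, "predicted_age"], deltas.loc[healthy, "chronological_age"]
    )

    # leukocyte composition: per-sample fractions jittered around the group
    # preset (Dirichlet, concentration 150), mixture betas, deconvolution
    reference = synthetic.synthetic_cell_reference()
    mix_cols, truth_fracs = {}, {}
    for s in samples:
        preset = (
            synthetic.HEALTHY_FRACTIONS
            if s.group == "healthy"
            else synthetic.COVID_FRACTIONS
        )
        frac = pd.Series(
            s_mix.dirichlet(preset.to_numpy() * 150.0), index=preset.index
        )
        truth_fracs[s.sample_id] = frac
        mix_cols[s.sample_id] = synthetic.simulate_cell_mixture_betas(
            frac, reference, noise_sd=1.0, seed=int(s_mix.integers(2**31))
        )
    mix_betas = pd.DataFrame(mix_cols)
    estimates = deconvolution.deconvolve_matrix(mix_betas, reference)
    comp_groups = pd.Series(
        np.where(sheet.set_index("sample_id").loc[estimates.index, "group"] == "healthy",
                 "healthy", "covid"),
        index=estimates.index,
    )
    composition = deconvolution.compare_composition(estimates, comp_groups)

    # telomeres under the null: same attrition model for controls & patients
    controls = synthetic.generate_cohort(
        N_TELOMERE_CONTROLS, (18.0, 80.0), seed=int(s_tel_ref.integers(2**31))
    )
    control_meas = synthetic.simulate_telomeres(
        controls, seed=int(s_tel_ref.integers(2**31))
    )
    ref = telomere.fit_percentile_curves(
        [m.age for m in control_meas], [m.mean_kb for m in control_meas]
    )
    pat_groups = ["covid_no_ards"] * 9 + ["covid_ards"] * (N_TELOMERE_PATIENTS - 9)
    pat_ages = s_tel_pat.uniform(30.0, 80.0, size=N_TELOMERE_PATIENTS)
    patients = [
        synthetic.SampleRecord(sample_id=f"P{i:03d}", age=float(a), group=grp)
        for i, (a, grp) in enumerate(zip(pat_ages, pat_groups))
    ]
    pat_meas = synthetic.simulate_telomeres(
        patients, seed=int(s_tel_pat.integers(2**31)), replicate_sd_kb=0.15
    )
    pat_deltas = [telomere.age_adjusted_delta(m, ref) for m in pat_meas]
    tel_cmp = telomere.compare_telomere_groups(
        pat_deltas, "covid_no_ards", "covid_ards"
    )

    return StudyReplicaResult(
        sheet=sheet,
        deltas=deltas,
        delta_age_tests=tests,
        clock_metrics=metrics,
        composition=composition,
        telomere_comparison=tel_cmp,
    )
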