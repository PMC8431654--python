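# epiage

Epigenetic-age analysis for targeted bisulfite-amplicon methylation data,
built around the question of whether a patient cohort (here: hospitalised
COVID-19 patients with and without ARDS) shows accelerated epigenetic aging
or telomere attrition relative to healthy controls.

The package is aimed at researchers analysing blood methylation data who
need the complete chain from raw amplicon reads to cohort-level statistics:

* **Bisulfite amplicon pipeline** — bisulfite-aware alignment of FASTQ
  reads against a small amplicon panel (both template strands, collapsed
  C→T / G→A comparison space) and per-CpG methylation calling with
  coverage reporting.
* **Clock engine** — linear epigenetic clocks as coefficient tables.
  A methylation clock predicts age as

  `age = Σⱼ wⱼ·βⱼ + c`

  with β the methylation level (percent) at CpG *j*.  The bundled
  three-CpG bisulfite-amplicon blood clock is

  `age [yr] = −0.34·β(CCDC102B) + 0.83·β(FHL2) + 1.18·β(PDE4C) + 3.86`

  combining one hypomethylating and two hypermethylating CpGs.  Any
  published clock loads from a two-column TSV (optionally with the
  piecewise log/linear age transform used by several array clocks).
  Delta-age = predicted − chronological age; positive values mean age
  acceleration.
* **Leukocyte deconvolution** — cell-type fractions (CD4 T, CD8 T, NK,
  B, monocytes, granulocytes) by constrained projection
  `min ‖R·f − β‖²  s.t.  f ≥ 0, Σf ≤ 1` onto a reference profile matrix.
* **Telomere analysis** — linear quantile-regression percentile curves
  (1/10/50/90/99) over a healthy reference cohort; patient Flow-FISH
  measurements expressed as age-adjusted deltas from the median curve and
  flagged when below the 10th percentile.
* **Cohort statistics** — Welch's t-test (Satterthwaite df), clock
  validation metrics (R², MAE, regression p), PCA.
* **Synthetic cohorts** — generators for every data type above with
  serialisable ground truth, used throughout the test suite.

## Worked example

Simulate a healthy validation cohort of 95 donors (ages 18–74), generate
amplicon methylation levels from the default age models, and apply the
three-CpG clock:

```sh
epiage simulate cohort --n 95 --seed 7 --out demo
epiage simulate betas --sheet demo/samples.tsv --seed 8 --out demo
epiage predict --betas demo/betas.tsv --clock ba3 \
    --sheet demo/samples.tsv --out demo/pred.tsv
head -4 demo/pred.tsv
```

```
sample_id  clock  predicted_age       chronological_age   delta_age          group
S0000      BA3    59.58048138314713   53.00534612986135   6.575135253285779  healthy
S0001      BA3    76.64576749364143   68.24397285429623   8.401794639345198  healthy
S0002      BA3    68.80890429656138   61.43839865373084   7.370505642830537  healthy
```

Summarising the fit of predicted on chronological age:

```python
import pandas as pd
from epiage import stats

df = pd.read_csv("demo/pred.tsv", sep="\t")
m = stats.regression_metrics(df.predicted_age, df.chronological_age)
print(f"R2={m.r_squared:.3f}  MAE={m.mae:.2f} yr  slope={m.slope:.3f}")
print(f"mean delta-age: {df.delta_age.mean():.2f} yr")
```

```
R2=0.930  MAE=3.53 yr  slope=1.003
mean delta-age: -0.03 yr
```

With the default per-CpG noise of 3 percentage points the clock recovers
chronological age with a mean absolute error of ~3.5 years and no
systematic delta-age — the regime in which real amplicon clocks of this
size operate.  `epiage.study.run_study_replica` runs the full design
(95 healthy + 47 patients, composition-shifted leukocyte mixtures, a
356-control telomere reference) in one call and returns the group tests.

Other entry points: `epiage call-meth` (FASTQ → methylation calls),
`epiage deconvolve`, `epiage telomere`, `epiage compare`,
`epiage simulate reads|mixtures|telomeres`.

## Layout

```
src/epiage/
  synthetic.py       cohort / beta / read / mixture / telomere generators
  amplicon.py        bisulfite alignment + methylation calling
  clocks.py          clock definitions, prediction, fitting, delta-age
  deconvolution.py   constrained-projection cell-fraction estimation
  telomere.py        percentile curves + age-adjusted deltas
  stats.py           Welch t, regression metrics, PCA
  study.py           end-to-end synthetic study replica
  io.py              TSV/FASTA/FASTQ/JSON readers and writers
  cli.py             `epiage` command-line interface
docs/methods.md      modelling and design notes
```
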