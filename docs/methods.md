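# Methods and design notes

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical choices a maintainer should know about.

## Linear methylation clocks

A clock is a weighted sum of CpG methylation levels plus an intercept,
optionally followed by the piecewise log/linear age transform (logarithmic
below an "adult age" knot, default 20 years, linear above) that several
large published array clocks train against.  The transform is implemented
generically, off by default, and is external to the bundled amplicon
clock, which is a plain linear model.

**Scale.** Methylation is percent (0–100) everywhere.  The bundled
three-CpG clock's coefficients only produce plausible adult ages on the
percent scale (on the 0–1 fraction scale its predictions would be capped
near 6 years); the beta-matrix reader therefore rejects matrices whose
maximum is ≤ 1 unless a `--fraction`/`fraction=True` conversion is
requested explicitly.

**Missing CpGs.** Default policy is to raise, listing the missing CpGs:
silently imputing a clock input distorts predictions.  `mean_impute` fills
per-sample NaNs with the CpG's cross-sample mean; a CpG absent from the
matrix entirely is dropped from the clock with a warning, which introduces
a systematic offset of `weight × typical level` — acceptable for
exploratory use, not for reporting.

**Fitting.** `fit_clock` is unregularised OLS of age on the selected
betas — appropriate at the scale of a handful of amplicon CpGs fitted on
tens of samples, where elastic-net machinery is unnecessary.  Design-rank
failures name the offending CpGs (greedy scan for columns dependent on
earlier ones, tolerance 1e-8).  Note an inherent property of this inverse
regression: when noise lives on the betas rather than on age, OLS targets
the population best linear predictor, whose coefficients are slightly
attenuated relative to the algebraic inverse of the generating lines.

## Bisulfite amplicon pipeline

Reads are aligned directly against the amplicon panel, not a reference
genome.  A genome-wide bisulfite aligner is the right tool for shotgun
data; for a three-amplicon assay the panel comparison is equivalent
(the amplicons are unique loci) and self-contained.  Comparison happens in
bisulfite-collapsed space so methylation state never counts as a mismatch:
for original-top candidates both read and reference are collapsed C→T; for
original-bottom candidates the reverse-complemented read and the G→A
collapsed reference are compared (directional-protocol logic).  Every
reference × strand × offset placement is scored; ties break by fewer
mismatches, then alphabetical reference name, then top before bottom
strand, then smaller offset.

Defaults: `max_mismatch_frac` 0.1 (tolerates sequencing error and stray
non-converted cytosines while rejecting foreign sequence), minimum read
length 30 nt, `min_coverage` 100 (at 100 reads the binomial standard error
of a level estimate is ≤ 5 percentage points; lower-coverage CpGs are
flagged and excluded from clock input).  Quality strings are read but not
used for trimming or filtering.  Read pairs are treated as independent
single-end reads; where mates overlap, CpGs in the overlap are counted
twice.  Indels are not modelled: a read whose indel pushes it past the
mismatch budget is reported unaligned.

Coordinates are 0-based, half-open; a CpG is identified by the position of
its C on the top strand.  On bottom-strand reads the informative base is
the complementary cytosine, observed at position +1 (G methylated / A
unmethylated after re-orientation).

The repository ships deterministic **synthetic placeholder amplicons**
(three ~160 nt sequences named after the real loci, with realistic CpG
density) because the real assay's primer sequences and coordinates are
external supplementary data; user-supplied references load from
FASTA + CpG-table files.

## Synthetic data generators

All randomness descends from one integer seed through a
`numpy.random.SeedSequence` hierarchy; identical seeds give byte-identical
output.

* **Cohorts** — ages uniform over a configurable range (default 18–74,
  the validation cohort's span); uniform is the simplest distribution
  covering that range and avoids imposing a census structure the analyses
  do not need.  Group labels are multinomial, or fixed per-arm counts in
  the study replica (95 / 20 / 27, plus 356 telomere controls and 19
  telomere patients), mirroring the study design.
* **Methylation** — per CpG, `beta = a + b·age + N(0, sd²)` clipped to
  [0, 100].  Clipping biases levels generated near the scale boundaries
  toward the interior; the default models stay > 5 points away from the
  boundaries over the default age range, so the bias is negligible there.
  The default three-CpG model set is calibrated to the bundled clock
  (slopes scaled so the clock weights satisfy Σwⱼbⱼ = 1, baselines so the
  intercept cancels): a generator that emulates the assay a clock was
  trained on must return the true age on noise-free betas under that
  clock.  The per-CpG noise sd of 3 percentage points is not taken from
  any measurement; it is chosen so that the resulting prediction noise
  (sd 3·√Σwⱼ² ≈ 4.45 yr, mean absolute error ≈ 3.55 yr) matches the error
  regime reported for amplicon clocks of this size.
* **Reads** — per read: strand drawn with probability 0.5 top/bottom;
  each CpG cytosine kept as C with probability level/100; each non-CpG
  cytosine (on the read's template strand) converted with probability
  0.995; independent substitution errors at 0.001/base (typical bisulfite
  chemistry and Illumina error rates; both configurable).  Bottom-strand
  reads are emitted in physical 5'→3' orientation.  Qualities are constant
  'I' — the pipeline does not use them.  Not emulated: PCR amplification
  bias, indels, quality decay along the read, adapter read-through, and
  paired-end mate structure.  Passing read-level tests therefore shows the
  calling logic is correct, not that the pipeline is robust to every real
  sequencing artefact.
* **Cell mixtures** — `beta = R·f + noise`, with presets for a healthy
  leukocyte composition and a disease composition (lymphocyte subsets
  reduced, monocytes and granulocytes increased).  Per-sample fractions in
  the study replica are Dirichlet-jittered around the preset
  (concentration preset × 150, giving a few percentage points of
  inter-individual spread).  The bundled reference matrix is a clearly
  labelled **synthetic fixture** (block structure: four CpGs per cell type,
  high ~90% in that type, low ~10% elsewhere) — real sorted-cell reference
  profiles are external data and load through the same TSV path.  Because
  the synthetic reference is much better conditioned than real sorted-cell
  profiles, recovery accuracy on it is an upper bound.
* **Telomeres** — `TL = intercept + slope·age + N(0, sd²)` kb, floored at
  0, with exact-by-default triplicates (replicate spread configurable).
  Defaults 9.5 kb at age 0, −0.05 kb/yr, sd 0.7 kb — typical lymphocyte
  Flow-FISH values for an adult reference cohort.  Real telomere data are
  right-skewed and heteroscedastic with age; the Gaussian generator does
  not emulate that, which is precisely why the analysis module uses
  quantile regression rather than assuming normality.

## Deconvolution

`min ‖R·f − β‖²  s.t.  f ≥ 0, Σf ≤ 1`, solved by non-negative least
squares; if the plain NNLS solution violates the sum constraint the
constraint must be active at the optimum, so the problem is re-solved with
Σf = 1 enforced through an augmented penalty row whose weight escalates
until |Σf − 1| ≤ 1e-10.  The sum constraint is an inequality (not an
equality) so that profile noise and unmodelled cell types can leave an
unexplained remainder; `normalize=True` rescales post hoc.  The reference
must have full column rank and at least as many CpG rows as cell types.

## Telomere percentile analysis

Linear quantile regression (pinball loss, via iteratively reweighted least
squares) per requested percentile.  Linear rather than spline curves: a
~350-point reference cannot support stable nonlinear quantile fits at the
1st and 99th percentiles, and adult lymphocyte telomere attrition is
approximately linear.  Degenerate input (all points on one line, zero OLS
residual) short-circuits to that line for every percentile.  Non-crossing
is enforced within the observed age range by sorting the fitted curve
values across percentiles at the two range endpoints and re-deriving each
line through its adjusted endpoints — two lines ordered at both endpoints
are ordered on the whole interval.

A patient's delta is `mean of replicates − median curve at the patient's
age`.  The percentile **band** uses "below" phrasing under the median and
"at least" phrasing above it: a value under the median reports the lowest
percentile curve it falls below (`<10th` is the clinically used attrition
flag), a value at or above the median reports the highest curve it
reaches (`>=50th`, `>=90th`, …).  Ages more than 5 years outside the
fitted range are evaluated but flagged as extrapolations.  Group
comparison: Welch's t on the deltas plus Fisher's exact test on the 2×2
below-10th table (chosen for the small counts typical of patient cohorts).

## Cohort statistics

Welch's t-test is two-sided throughout (conservative when no direction is
pre-registered), with the convention p = 1 for two identical constant
groups.  No multiple-testing correction is applied by default across the
per-clock / per-cell-type panels — the comparisons are reported raw, as is
usual for descriptive cohort panels — and a Bonferroni helper is provided.
Regression metrics report R² and the F-test p of predicted on
chronological age, while MAE is deliberately computed on the raw pairs: a
clock with a constant offset keeps R² = 1 but pays in MAE, which is why
delta-age is reported separately.  PCA runs on centered, unscaled betas
(all features share the percent unit) via SVD.

## Study replica

`run_study_replica` wires the full chain on one synthetic cohort:
fixed-size arms (95 healthy / 20 no-ARDS / 27 ARDS), identical
age-methylation models in every arm (the null: disease does not shift
methylation age), disease-shifted leukocyte mixtures, and telomeres drawn
from the same attrition model for patients and controls.  It returns the
delta-age Welch tests (expected non-significant), the clock validation
metrics on the healthy arm, the per-cell-type composition comparison
(expected to detect the generating shift), and the telomere group
comparison.  The replica works at the beta-matrix level; read-level
simulation is exercised separately because it tests calling, not cohort
statistics.  Problem sizes throughout the test suite (e.g. 3000 reads per
amplicon per level, 200 random mixtures, 10,000 null t-tests, 50 replica
runs) are chosen as the smallest scales at which the binomial and
Monte-Carlo error bands in the assertions are meaningful.

## Known limitations

* The aligner is substitution-only; indel-containing reads beyond the
  mismatch budget are dropped, biasing coverage at real indel-prone loci.
* Overlapping read pairs are double-counted (see above).
* `fit_clock` assumes noise on age, not on betas; see the attenuation note.
* The constrained projection assumes the reference spans the sample's cell
  types; an unmodelled cell type leaks into the residual and, partially,
  into the most similar reference column.
* Percentile curves are linear in age; outside roughly ages 18–80 (or any
  strongly nonlinear attrition regime, e.g. childhood) they are wrong by
  construction.
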