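"""Synthetic cohorts with known ground truth.

Generates every data type the analysis modules consume — sample sheets,
age-dependent beta matrices, bisulfite amplicon reads, leukocyte-mixture
profiles and telomere measurements — from explicit generative models, so
that each downstream estimate can be checked against the generating truth.

What is emulated: per-CpG linear age-methylation relations with Gaussian
noise (clipped to the 0-100% scale); disease-associated leukocyte shifts
(lymphocyte subsets down, monocytes/granulocytes up); bisulfite reads at
set methylation levels with incomplete conversion and sequencing error on
both template strands; linear age-dependent telomere attrition with
percentile spread and triplicate measurement.

All randomness flows from a single integer seed through a
``numpy.random.SeedSequence`` hierarchy: the same seed and arguments always
reproduce byte-identical output.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amplicon import AmpliconReference, revcomp
from .clocks import ClockDefinition
from .deconvolution import CELL_TYPES
from .telomere import TelomereMeasurement

__all__ = [
    "GROUPS",
    "SampleRecord",
    "CpGAgeModel",
    "FastqRead",
    "ReadTruth",
    "GroundTruth",
    "DEFAULT_CPG_MODELS",
    "HEALTHY_FRACTIONS",
    "COVID_FRACTIONS",
    "generate_cohort",
    "simulate_betas",
    "consistent_clock",
    "simulate_reads",
    "aggregate_read_truth",
    "simulate_cell_mixture_betas",
    "synthetic_cell_reference",
    "simulate_telomeres",
    "placeholder_references",
    "cohort_to_sheet",
]

GROUPS = ("healthy", "covid_no_ards", "covid_ards")


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    age: float  # years, > 0
    group: str  # one of GROUPS

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


@dataclass(frozen=True)
class CpGAgeModel:
    """Linear age-methylation model for one CpG: beta = a + b*age + noise.

    ``baseline_a`` is the percent methylation at age 0, ``slope_b`` percent
    per year (negative for hypomethylating CpGs), ``noise_sd`` the Gaussian
    noise sd in percent.  Generated betas are clipped to [0, 100].
    """

    cpg_id: str
    baseline_a: float
    slope_b: float
    noise_sd: float = 3.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _ba3_compatible_models(noise_sd: float = 3.0) -> tuple[CpGAgeModel, ...]:
    """Default clock-CpG models, calibrated to the published 3-CpG clock.

    One hypomethylating (CCDC102B, high baseline) and two hypermethylating
    sites, with slopes scaled so that the published weights w satisfy
    sum(w_j * b_j) = 1 and baselines chosen so that the clock intercept
    cancels sum(w_j * a_j): applying the published clock to noise-free
    default betas returns the generating age identically, as it must for a
    generator emulating the assay the clock was trained on.  With per-CpG
    sd 3% the induced prediction noise of the published clock is
    3*sqrt(sum w_j^2) = 4.45 years (analytic MAE ~ 3.55 years).
    """
    w = {"CCDC102B": -0.34, "FHL2": 0.83, "PDE4C": 1.18}
    intercept = 3.86
    shape = {"CCDC102B": -0.5, "FHL2": 0.5, "PDE4C": 0.45}  # slope proportions
    scale = 1.0 / sum(w[k] * shape[k] for k in w)
    b = {k: shape[k] * scale for k in w}
    a = {"FHL2": 20.0, "PDE4C": 10.0}
    a["CCDC102B"] = (intercept + w["FHL2"] * a["FHL2"] + w["PDE4C"] * a["PDE4C"]) / (
        -w["CCDC102B"]
    )
    return tuple(CpGAgeModel(k, a[k], b[k], noise_sd) for k in ("CCDC102B", "FHL2", "PDE4C"))


DEFAULT_CPG_MODELS = _ba3_compatible_models()

# Leukocyte composition presets.  "covid" shifts lymphocyte subsets down
# and monocytes/granulocytes up relative to "healthy".
HEALTHY_FRACTIONS = pd.Series(
    {"CD4T": 0.15, "CD8T": 0.10, "NK": 0.05, "Bcell": 0.05, "Mono": 0.08, "Gran": 0.57}
)
COVID_FRACTIONS = pd.Series(
    {"CD4T": 0.08, "CD8T": 0.05, "NK": 0.02, "Bcell": 0.03, "Mono": 0.12, "Gran": 0.70}
)


def generate_cohort(
    n: int,
    age_range: tuple[float, float],
    group_proportions: dict[str, float] | None = None,
    seed: int = 0,
) -> list[SampleRecord]:
    """Draw a cohort of ``n`` samples.

    Ages are uniform on ``age_range`` (inclusive bounds); group labels are
    multinomial with ``group_proportions`` (default: all healthy), which
    must sum to 1 within 1e-9.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = float(age_range[0]), float(age_range[1])
    if lo <= 0 or hi < lo:
        raise ValueError(f"invalid age range ({lo}, {hi})")
    if group_proportions is None:
        group_proportions = {"healthy": 1.0}
    for g in group_proportions:
        if g not in GROUPS:
            raise ValueError(f"unknown group {g!r}")
    props = np.array(list(group_proportions.values()), dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("group proportions must sum to 1")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, lo)
    labels = rng.choice(list(group_proportions.keys()), size=n, p=props)
    width = max(4, len(str(n)))
    return [
        SampleRecord(sample_id=f"S{i:0{width}d}", age=float(a), group=str(g))
        for i, (a, g) in enumerate(zip(ages, labels))
    ]


def cohort_to_sheet(samples) -> pd.DataFrame:
    """Sample sheet DataFrame (sample_id, age, group) from SampleRecords."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "age": [s.age for s in samples],
            "group": [s.group for s in samples],
        }
    )


def simulate_betas(samples, cpg_models, seed: int = 0) -> pd.DataFrame:
    """Beta matrix (CpG rows x sample columns, percent) from age models.

    beta(cpg, sample) = clip(a + b*age + N(0, sd^2), 0, 100).  Clipping is
    a small bias source for CpGs generated near the scale boundaries.
    """
    cpg_models = list(cpg_models)
    if not cpg_models:
        raise ValueError("at least one CpG model required")
    rng = np.random.default_rng(seed)
    ages = np.array([s.age for s in samples], dtype=float)
    rows = []
    for m in cpg_models:
        mean = m.baseline_a + m.slope_b * ages
        noise = rng.normal(0.0, m.noise_sd, size=len(ages)) if m.noise_sd > 0 else 0.0
        rows.append(np.clip(mean + noise, 0.0, 100.0))
    return pd.DataFrame(
        np.vstack(rows),
        index=[m.cpg_id for m in cpg_models],
        columns=[s.sample_id for s in samples],
    )


def consistent_clock(cpg_models, name: str = "consistent") -> ClockDefinition:
    """A clock that inverts the generating age-methylation models exactly.

    Allocation rule: all weight goes to the CpG with the largest |slope|
    (first such on ties) — weight 1/b there, zero elsewhere, intercept
    -a/b — so that on noise-free betas the prediction equals the
    generating age identically (sum w_j b_j = 1, intercept = -sum w_j a_j).
    """
    cpg_models = list(cpg_models)
    slopes = np.array([m.slope_b for m in cpg_models])
    if not np.any(slopes != 0):
        raise ValueError("no invertible signal: every slope_b is zero")
    j = int(np.argmax(np.abs(slopes)))
    m = cpg_models[j]
    terms = tuple(
        (mm.cpg_id, 1.0 / m.slope_b if i == j else 0.0) for i, mm in enumerate(cpg_models)
    )
    return ClockDefinition(
        name=name, terms=terms, intercept=-m.baseline_a / m.slope_b, transform="identity"
    )


# ---------------------------------------------------------------------------
# bisulfite read simulation


@dataclass(frozen=True)
class FastqRead:
    read_id: str
    sequence: str
    quality: str


@dataclass(frozen=True)
class ReadTruth:
    """Per-read ground truth: origin and true methylation states."""

    read_id: str
    amplicon: str
    strand: str  # original_top | original_bottom
    offset: int  # window start in top-strand coordinates
    meth: dict[int, bool]  # cpg top-strand position -> methylated


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_reads(
    amplicon: AmpliconReference,
    cpg_levels: dict[int, float],
    coverage: int,
    conversion_rate: float = 0.995,
    error_rate: float = 0.001,
    seed: int = 0,
    strand_fraction: float = 0.5,
    read_length: int | None = None,
) -> tuple[list[FastqRead], list[ReadTruth]]:
    """Simulate bisulfite-converted amplicon reads at set methylation levels.

    Per read: each CpG cytosine is retained as C with probability
    level/100 (methylated) else read as T; every non-CpG cytosine converts
    C->T with probability ``conversion_rate``; independent substitution
    errors hit each base at ``error_rate``.  Strand is original-top with
    probability ``strand_fraction``; original-bottom reads are emitted in
    their physical 5'->3' orientation (reverse complement of top-strand
    coordinates, with the complementary-strand conversion pattern).
    Qualities are fixed at 'I' (Phred 40).  Ground truth per read
    (origin, strand, window, methylation states) is returned alongside.
    """
    for p, lv in cpg_levels.items():
        if not 0 <= lv <= 100:
            raise ValueError(f"level at {p} outside [0, 100]")
    if not 0 <= conversion_rate <= 1 or not 0 <= error_rate <= 1:
        raise ValueError("rates must be in [0, 1]")
    missing = set(amplicon.cpg_positions) - set(cpg_levels)
    if missing:
        raise ValueError(f"no level given for CpG positions {sorted(missing)}")
    if coverage == 0:
        return [], []

    rng = np.random.default_rng(seed)
    ref = np.frombuffer(amplicon.sequence.encode("ascii"), dtype=np.uint8)
    L = len(ref)
    rl = L if read_length is None else min(int(read_length), L)
    n = int(coverage)

    cpg_pos = np.array(amplicon.cpg_positions, dtype=int)
    cpg_g_pos = cpg_pos + 1
    is_c = ref == ord("C")
    is_g = ref == ord("G")
    nonCpG_c = np.where(is_c & ~np.isin(np.arange(L), cpg_pos))[0]
    nonCpG_g = np.where(is_g & ~np.isin(np.arange(L), cpg_g_pos))[0]
    levels = np.array([cpg_levels[p] / 100.0 for p in cpg_pos])

    is_top = rng.random(n) < strand_fraction
    meth = rng.random((n, len(cpg_pos))) < levels  # true per-read states
    offsets = (
        np.zeros(n, dtype=int) if rl == L else rng.integers(0, L - rl + 1, size=n)
    )

    # build all reads in top-strand coordinates, then orient
    mat = np.tile(ref, (n, 1))
    # top-strand conversion: CpG C per methylation state, other Cs per rate
    top_rows = np.where(is_top)[0]
    if top_rows.size:
        mat[np.ix_(top_rows, cpg_pos)] = np.where(
            meth[top_rows], ord("C"), ord("T")
        ).astype(np.uint8)
        conv = rng.random((top_rows.size, nonCpG_c.size)) < conversion_rate
        sub = mat[np.ix_(top_rows, nonCpG_c)]
        sub[conv] = ord("T")
        mat[np.ix_(top_rows, nonCpG_c)] = sub
    # bottom-strand conversion acts on bottom-strand Cs = top-strand Gs
    bot_rows = np.where(~is_top)[0]
    if bot_rows.size:
        mat[np.ix_(bot_rows, cpg_g_pos)] = np.where(
            meth[bot_rows], ord("G"), ord("A")
        ).astype(np.uint8)
        conv = rng.random((bot_rows.size, nonCpG_g.size)) < conversion_rate
        sub = mat[np.ix_(bot_rows, nonCpG_g)]
        sub[conv] = ord("A")
        mat[np.ix_(bot_rows, nonCpG_g)] = sub
    # sequencing errors: substitute to a uniformly random *different* base
    if error_rate > 0:
        err = rng.random((n, L)) < error_rate
        shift = rng.integers(1, 4, size=err.sum())
        idx_in_bases = np.searchsorted(_BASES, mat[err])
        # non-ACGT bases (none in practice) would map via modulo harmlessly
        mat[err] = _BASES[(idx_in_bases + shift) % 4]

    reads, truths = [], []
    qual = "I" * rl
    for i in range(n):
        window = mat[i, offsets[i] : offsets[i] + rl]
        seq = window.tobytes().decode("ascii")
        strand = "original_top" if is_top[i] else "original_bottom"
        if strand == "original_bottom":
            seq = revcomp(seq)
        rid = f"{amplicon.name}_read{i:06d}"
        reads.append(FastqRead(read_id=rid, sequence=seq, quality=qual))
        covered = {}
        for j, p in enumerate(cpg_pos):
            informative = p if strand == "original_top" else p + 1
            if offsets[i] <= informative < offsets[i] + rl:
                covered[int(p)] = bool(meth[i, j])
        truths.append(
            ReadTruth(
                read_id=rid,
                amplicon=amplicon.name,
                strand=strand,
                offset=int(offsets[i]),
                meth=covered,
            )
        )
    return reads, truths


def aggregate_read_truth(truths) -> dict[int, tuple[int, int]]:
    """True (methylated, unmethylated) read counts per CpG position."""
    counts: dict[int, list[int]] = {}
    for t in truths:
        for p, m in t.meth.items():
            c = counts.setdefault(p, [0, 0])
            c[0 if m else 1] += 1
    return {p: (c[0], c[1]) for p, c in sorted(counts.items())}


# ---------------------------------------------------------------------------
# cell mixtures


def synthetic_cell_reference(n_cpgs_per_type: int = 4, seed: int = 2024) -> pd.DataFrame:
    """A synthetic leukocyte methylation reference (non-biological fixture).

    For each of the six cell types, ``n_cpgs_per_type`` discriminating CpGs
    are generated that are highly methylated (85-95%) in that type and
    lowly methylated (5-15%) in the others — the block structure guarantees
    full column rank.  CpG ids are prefixed ``syn_``; the values carry no
    biological meaning.
    """
    rng = np.random.default_rng(seed)
    rows, index = [], []
    for k, ct in enumerate(CELL_TYPES):
        for j in range(n_cpgs_per_type):
            row = rng.uniform(5.0, 15.0, size=len(CELL_TYPES))
            row[k] = rng.uniform(85.0, 95.0)
            rows.append(row)
            index.append(f"syn_{ct}_{j}")
    return pd.DataFrame(rows, index=index, columns=list(CELL_TYPES))


def simulate_cell_mixture_betas(
    fractions: pd.Series,
    reference: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """One sample's beta column as a weighted mixture of reference profiles.

    beta = sum_k fraction_k * reference_k + N(0, noise_sd^2), clipped to
    [0, 100].  Fractions must be non-negative and sum to 1 within 1e-6.
    """
    f = fractions.reindex(reference.columns) if hasattr(fractions, "reindex") else pd.Series(fractions)
    if len(f) != reference.shape[1] or f.isna().any():
        raise ValueError(
            f"fraction vector must match the {reference.shape[1]} reference cell types"
        )
    v = f.to_numpy(dtype=float)
    if (v < 0).any():
        raise ValueError("fractions must be non-negative")
    if abs(v.sum() - 1.0) > 1e-6:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    beta = reference.to_numpy(dtype=float) @ v
    if noise_sd > 0:
        beta = beta + rng.normal(0.0, noise_sd, size=len(beta))
    return pd.Series(np.clip(beta, 0.0, 100.0), index=reference.index)


# ---------------------------------------------------------------------------
# telomeres


def simulate_telomeres(
    samples,
    intercept_kb: float = 9.5,
    slope_kb_per_year: float = -0.05,
    sd_kb: float = 0.7,
    seed: int = 0,
    n_replicates: int = 3,
    replicate_sd_kb: float = 0.0,
) -> list[TelomereMeasurement]:
    """Telomere measurements with linear age attrition and Gaussian spread.

    Per sample: latent TL = intercept + slope*age + N(0, sd_kb^2);
    ``n_replicates`` replicate values are drawn around the latent TL with
    sd ``replicate_sd_kb`` (default 0: exact triplicates).  Values are
    floored at 0 kb.
    """
    if sd_kb < 0 or replicate_sd_kb < 0:
        raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for s in samples:
        latent = intercept_kb + slope_kb_per_year * s.age
        if sd_kb > 0:
            latent += rng.normal(0.0, sd_kb)
        reps = np.full(n_replicates, latent)
        if replicate_sd_kb > 0:
            reps = reps + rng.normal(0.0, replicate_sd_kb, size=n_replicates)
        reps = np.maximum(reps, 0.0)
        out.append(
            TelomereMeasurement(
                sample_id=s.sample_id,
                replicate_values=tuple(float(r) for r in reps),
                age=s.age,
                group=s.group,
            )
        )
    return out


# ---------------------------------------------------------------------------
# placeholder amplicon references


def _make_amplicon(name: str, seed: int, length: int = 160) -> AmpliconReference:
    rng = np.random.default_rng(seed)
    while True:
        seq = "".join(rng.choice(list("ACGT"), p=[0.28, 0.24, 0.24, 0.24], size=length))
        cpgs = tuple(
            i for i in range(length - 1) if seq[i] == "C" and seq[i + 1] == "G"
        )
        if 3 <= len(cpgs) <= 10:
            return AmpliconReference(
                name=name,
                sequence=seq,
                cpg_positions=cpgs,
                signature_cpg_index=len(cpgs) // 2,
            )


def placeholder_references() -> list[AmpliconReference]:
    """Synthetic stand-ins for the three clock amplicons.

    The real assay's primer sequences and genomic coordinates are external
    supplementary data; these deterministic synthetic sequences (labelled
    by the gene names of the loci they stand in for) carry realistic CpG
    density and serve testing and simulation.  Real references can be
    loaded from FASTA + CpG-table files instead.
    """
    return [
        _make_amplicon("CCDC102B", seed=101),
        _make_amplicon("FHL2", seed=202),
        _make_amplicon("PDE4C", seed=303),
    ]


# ---------------------------------------------------------------------------
# ground truth container


@dataclass
class GroundTruth:
    """Everything needed to score estimates against the generating process."""

    seed: int
    samples: list[SampleRecord] = field(default_factory=list)
    cpg_models: list[CpGAgeModel] = field(default_factory=list)
    cell_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    telomere_params: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "samples": [dataclasses.asdict(s) for s in self.samples],
                "cpg_models": [dataclasses.asdict(m) for m in self.cpg_models],
                "cell_fractions": self.cell_fractions,
                "telomere_params": self.telomere_params,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            seed=d["seed"],
            samples=[SampleRecord(**s) for s in d["samples"]],
            cpg_models=[CpGAgeModel(**m) for m in d["cpg_models"]],
            cell_fractions=d.get("cell_fractions", {}),
            telomere_params=d.get("telomere_params", {}),
        )
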