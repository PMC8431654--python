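"""Readers and writers for the pipeline's on-disk formats.

Beta matrices are TSV with CpG ids as the row index and sample ids as
columns, on the percent scale; matrices that look fraction-scaled
(maximum <= 1) are rejected unless conversion is explicitly requested.
Clock coefficient tables are two-column TSV (``cpg_id<TAB>weight``) with a
reserved ``(Intercept)`` row and an optional ``#transform=`` header line,
so published clock supplements load with minimal editing.  Sequence
formats go through Biopython.
"""
from __future__ import annotations

import gzip
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .amplicon import AmpliconReference, MethylationCall
from .clocks import ClockDefinition
from .synthetic import FastqRead
from .telomere import TelomereMeasurement

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_clock",
    "write_clock",
    "read_fastq",
    "write_fastq",
    "write_fasta",
    "read_references",
    "write_cpg_table",
    "write_calls",
    "read_calls",
    "read_telomere_reference",
    "read_telomere_measurements",
]


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# beta matrices & sample sheets


def read_beta_matrix(path, fraction: bool = False) -> pd.DataFrame:
    """Read a CpG x sample TSV beta matrix (percent scale).

    ``fraction=True`` accepts a 0-1 scaled matrix and multiplies by 100;
    without it, a matrix whose maximum is <= 1 is rejected as likely
    fraction-scaled (a fraction-scale clock input would predict infant
    ages for every adult).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty beta matrix")
    mx = df.to_numpy(dtype=float).max()
    if fraction:
        return df * 100.0
    if mx <= 1.0:
        raise ValueError(
            f"{path}: matrix maximum {mx:.3g} <= 1 looks fraction-scaled; "
            "pass fraction=True (--fraction) to convert to percent"
        )
    return df


def write_beta_matrix(betas: pd.DataFrame, path) -> None:
    betas.to_csv(path, sep="\t", index_label="cpg_id")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "age"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clock coefficient tables


def read_clock(path, name: str | None = None) -> ClockDefinition:
    """Load a clock from a coefficient TSV.

    Format: optional ``#transform=identity|log_linear[:adult_age]`` comment
    lines, then a header ``cpg_id<TAB>weight``, one row per CpG and a
    reserved ``(Intercept)`` row.
    """
    transform, adult_age = "identity", 20.0
    rows: list[tuple[str, float]] = []
    intercept = 0.0
    with _open_text(path) as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#transform="):
                    spec = line.split("=", 1)[1].strip()
                    if ":" in spec:
                        transform, adult = spec.split(":", 1)
                        adult_age = float(adult)
                    else:
                        transform = spec
                continue
            if not header_seen:
                header_seen = True
                cols = line.split("\t")
                if cols[:2] != ["cpg_id", "weight"]:
                    raise ValueError(f"{path}: expected header 'cpg_id\\tweight'")
                continue
            cpg, w = line.split("\t")[:2]
            if cpg == "(Intercept)":
                intercept = float(w)
            else:
                rows.append((cpg, float(w)))
    if not rows:
        raise ValueError(f"{path}: no CpG terms found")
    return ClockDefinition(
        name=name or Path(path).stem,
        terms=tuple(rows),
        intercept=intercept,
        transform=transform,
        adult_age=adult_age,
    )


def write_clock(clock: ClockDefinition, path) -> None:
    with open(path, "w") as fh:
        spec = clock.transform
        if spec == "log_linear":
            spec += f":{clock.adult_age:g}"
        fh.write(f"#transform={spec}\n")
        fh.write("cpg_id\tweight\n")
        fh.write(f"(Intercept)\t{clock.intercept!r}\n")
        for cpg, w in clock.terms:
            fh.write(f"{cpg}\t{w!r}\n")


# ---------------------------------------------------------------------------
# sequences


def read_fastq(path) -> list[FastqRead]:
    with _open_text(path) as fh:
        return [
            FastqRead(
                read_id=rec.id,
                sequence=str(rec.seq),
                quality="".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                ),
            )
            for rec in SeqIO.parse(fh, "fastq")
        ]


def write_fastq(reads, path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in r.quality]
        records.append(rec)
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fastq")


def write_fasta(references, path) -> None:
    records = [
        SeqRecord(Seq(r.sequence), id=r.name, description="") for r in references
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_references(fasta_path, cpg_table_path) -> list[AmpliconReference]:
    """Load amplicon references from FASTA plus a CpG-position TSV.

    The table has columns ``amplicon``, ``position`` (0-based offset of
    the CpG's C on the top strand) and ``signature`` (0/1 flag marking the
    clock-feeding CpG of each amplicon).
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    table = pd.read_csv(cpg_table_path, sep="\t")
    refs = []
    for name, sub in table.groupby("amplicon"):
        if name not in seqs:
            raise KeyError(f"amplicon {name!r} in CpG table but not in FASTA")
        sub = sub.sort_values("position")
        positions = tuple(int(p) for p in sub["position"])
        sig = sub["signature"].to_numpy().nonzero()[0]
        refs.append(
            AmpliconReference(
                name=str(name),
                sequence=seqs[name],
                cpg_positions=positions,
                signature_cpg_index=int(sig[0]) if len(sig) else 0,
            )
        )
    return refs


def write_cpg_table(references, path) -> None:
    rows = []
    for r in references:
        for i, p in enumerate(r.cpg_positions):
            rows.append(
                {
                    "amplicon": r.name,
                    "position": p,
                    "signature": int(i == r.signature_cpg_index),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# methylation calls


def write_calls(calls, path) -> None:
    pd.DataFrame(
        [
            {
                "amplicon": c.amplicon,
                "cpg_position": c.cpg_position,
                "methylated_count": c.methylated_count,
                "unmethylated_count": c.unmethylated_count,
                "level_percent": c.level,
                "low_coverage": int(c.low_coverage),
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def read_calls(path) -> list[MethylationCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        MethylationCall(
            amplicon=row["amplicon"],
            cpg_position=int(row["cpg_position"]),
            methylated_count=int(row["methylated_count"]),
            unmethylated_count=int(row["unmethylated_count"]),
            low_coverage=bool(row["low_coverage"]),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# telomeres


def read_telomere_reference(path) -> pd.DataFrame:
    """Reference cohort TSV: sample_id, age, kb."""
    df = pd.read_csv(path, sep="\t")
    if missing := {"age", "kb"} - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_telomere_measurements(path) -> list[TelomereMeasurement]:
    """Patient TSV: sample_id, age, group, rep1..repK (kb)."""
    df = pd.read_csv(path, sep="\t")
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    if not rep_cols:
        raise ValueError(f"{path}: no replicate columns (rep1, rep2, ...)")
    return [
        TelomereMeasurement(
            sample_id=str(row["sample_id"]),
            replicate_values=tuple(
                float(row[c]) for c in rep_cols if pd.notna(row[c])
            ),
            age=float(row["age"]),
            group=str(row.get("group", "")),
        )
        for _, row in df.iterrows()
    ]


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=str)
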