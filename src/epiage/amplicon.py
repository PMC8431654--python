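"""Bisulfite-aware alignment of amplicon reads and per-CpG methylation calling.

Reads from a targeted bisulfite-amplicon assay are aligned directly against
the handful of amplicon reference sequences rather than a whole genome: the
amplicons are unique loci, so genome-wide alignment adds nothing but an
external dependency.  Comparison happens in bisulfite-collapsed space so
that methylation state never counts as a mismatch:

* original-top candidate: both read and reference collapsed C->T;
* original-bottom candidate: the reverse-complemented read and the
  reference collapsed G->A.

Coordinates are 0-based half-open throughout; a CpG is identified by the
position of its C on the top strand.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AmpliconReference",
    "ReadAlignment",
    "MethylationCall",
    "bisulfite_align",
    "align_reads",
    "call_methylation",
    "coverage_report",
    "revcomp",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class AmpliconReference:
    """One amplicon: name, top-strand sequence and its CpG positions.

    ``cpg_positions`` are 0-based offsets of the C of each CG dinucleotide;
    ``signature_cpg_index`` marks which of them feeds the age clock.
    """

    name: str
    sequence: str
    cpg_positions: tuple[int, ...]
    signature_cpg_index: int = 0

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        pos = tuple(int(p) for p in self.cpg_positions)
        if list(pos) != sorted(set(pos)):
            raise ValueError("cpg_positions must be strictly increasing")
        for p in pos:
            if not (0 <= p < len(self.sequence) - 1) or self.sequence[p : p + 2] != "CG":
                raise ValueError(f"{self.name}: position {p} is not the C of a CG dinucleotide")
        object.__setattr__(self, "cpg_positions", pos)
        if not 0 <= self.signature_cpg_index < len(pos):
            raise ValueError("signature_cpg_index out of range")

    @property
    def signature_cpg(self) -> int:
        return self.cpg_positions[self.signature_cpg_index]


@dataclass(frozen=True)
class ReadAlignment:
    read_id: str
    amplicon: str
    offset: int  # 0-based start on the reference, top-strand coordinates
    strand: str  # "original_top" | "original_bottom"
    mismatches: int
    length: int


@dataclass
class MethylationCall:
    amplicon: str
    cpg_position: int
    methylated_count: int
    unmethylated_count: int
    low_coverage: bool = False

    @property
    def total(self) -> int:
        return self.methylated_count + self.unmethylated_count

    @property
    def level(self) -> float:
        """Methylation level in percent; NaN when no informative reads."""
        if self.total == 0:
            return float("nan")
        return 100.0 * self.methylated_count / self.total


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _collapse_ct(arr: np.ndarray) -> np.ndarray:
    out = arr.copy()
    out[out == ord("C")] = ord("T")
    return out


def _collapse_ga(arr: np.ndarray) -> np.ndarray:
    out = arr.copy()
    out[out == ord("G")] = ord("A")
    return out


class _RefIndex:
    """Pre-collapsed reference arrays, built once per alignment batch."""

    def __init__(self, references):
        # fixed deterministic reference order for tie-breaking
        self.refs = sorted(references, key=lambda r: r.name)
        self.ct = [_collapse_ct(_encode(r.sequence)) for r in self.refs]
        self.ga = [_collapse_ga(_encode(r.sequence)) for r in self.refs]


def _best_placement(read: str, idx: _RefIndex, max_mismatch_frac: float):
    """Scan every reference/strand/offset; return the best ReadAlignment fields.

    Candidates are ranked by (mismatches, reference name, strand, offset),
    original_top preferred over original_bottom at equal mismatch count.
    """
    fwd_ct = _collapse_ct(_encode(read))
    rev_ga = _collapse_ga(_encode(revcomp(read)))
    L = len(read)
    budget = int(np.floor(max_mismatch_frac * L))
    best = None  # (mm, ref_i, strand_i, offset)
    for ri, ref in enumerate(idx.refs):
        for si, (query, target) in enumerate(((fwd_ct, idx.ct[ri]), (rev_ga, idx.ga[ri]))):
            n_off = len(target) - L + 1
            if n_off <= 0:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(target, L)
            mms = (windows != query).sum(axis=1)
            off = int(np.argmin(mms))
            key = (int(mms[off]), ri, si, off)
            if key[0] <= budget and (best is None or key < best):
                best = key
    return best


def bisulfite_align(
    read_id: str,
    read_seq: str,
    references,
    max_mismatch_frac: float = 0.1,
    min_read_length: int = 30,
) -> ReadAlignment | None:
    """Align one read against the amplicon panel; None if unalignable."""
    if len(read_seq) < min_read_length:
        return None
    idx = references if isinstance(references, _RefIndex) else _RefIndex(references)
    best = _best_placement(read_seq.upper(), idx, max_mismatch_frac)
    if best is None:
        return None
    mm, ri, si, off = best
    return ReadAlignment(
        read_id=read_id,
        amplicon=idx.refs[ri].name,
        offset=off,
        strand="original_top" if si == 0 else "original_bottom",
        mismatches=mm,
        length=len(read_seq),
    )


def align_reads(
    reads,
    references,
    max_mismatch_frac: float = 0.1,
    min_read_length: int = 30,
):
    """Align an iterable of (read_id, sequence) pairs.

    Returns ``(alignments, n_unaligned)``; aligned + unaligned always equals
    the number of input reads.
    """
    idx = _RefIndex(references)
    alignments, unaligned = [], 0
    for read_id, seq in reads:
        aln = bisulfite_align(read_id, seq, idx, max_mismatch_frac, min_read_length)
        if aln is None:
            unaligned += 1
        else:
            alignments.append(aln)
    return alignments, unaligned


def call_methylation(
    alignments,
    reads: dict[str, str],
    reference: AmpliconReference,
    min_coverage: int = 100,
) -> list[MethylationCall]:
    """Count methylated (C) vs unmethylated (T) reads at each CpG.

    On original-top reads the CpG cytosine itself is inspected; on
    original-bottom reads the complementary strand's cytosine maps to the
    G of the CpG (position +1 in top coordinates), observed as G
    (methylated) or A (unmethylated) after reverse-complementing the read
    back into reference orientation.  Any other base is ignored.  CpGs with
    fewer than ``min_coverage`` informative reads are flagged low-coverage
    (callers exclude them from clock input).
    """
    mine = [a for a in alignments if a.amplicon == reference.name]
    if not mine:
        warnings.warn(f"no aligned reads for amplicon {reference.name}", stacklevel=2)
        return []
    calls = []
    for p in reference.cpg_positions:
        meth = unmeth = 0
        for a in mine:
            if a.strand == "original_top":
                i = p - a.offset
                if not 0 <= i < a.length:
                    continue
                base = reads[a.read_id][i]
                if base == "C":
                    meth += 1
                elif base == "T":
                    unmeth += 1
            else:
                i = (p + 1) - a.offset
                if not 0 <= i < a.length:
                    continue
                base = revcomp(reads[a.read_id])[i]
                if base == "G":
                    meth += 1
                elif base == "A":
                    unmeth += 1
        calls.append(
            MethylationCall(
                amplicon=reference.name,
                cpg_position=p,
                methylated_count=meth,
                unmethylated_count=unmeth,
                low_coverage=(meth + unmeth) < min_coverage,
            )
        )
    return calls


def coverage_report(calls, n_total_reads: int | None = None, n_aligned: int | None = None):
    """Per-amplicon mean/median CpG coverage plus overall aligned fraction."""
    per_amplicon = {}
    for c in calls:
        per_amplicon.setdefault(c.amplicon, []).append(c.total)
    summary = {
        name: {
            "mean_coverage": float(np.mean(totals)),
            "median_coverage": float(np.median(totals)),
            "n_cpgs": len(totals),
        }
        for name, totals in sorted(per_amplicon.items())
    }
    report = {"amplicons": summary}
    if not summary:
        report["mean_coverage"] = None
        report["median_coverage"] = None
    else:
        all_totals = [c.total for c in calls]
        report["mean_coverage"] = float(np.mean(all_totals))
        report["median_coverage"] = float(np.median(all_totals))
    if n_total_reads is not None:
        report["n_reads"] = int(n_total_reads)
        report["aligned_fraction"] = (
            0.0 if not n_total_reads else float((n_aligned or 0) / n_total_reads)
        )
    return report
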