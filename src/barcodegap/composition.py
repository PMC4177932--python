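"""Nucleotide-composition statistics for barcode libraries.

COI barcodes in insects are strongly AT biased, with the bias concentrated
at third codon positions where selection on the protein is weakest.  This
module computes per-sequence base composition, GC content by codon
position, and library-level summary tables (min / mean / max / standard
error of the mean per statistic).

All percentages are computed over unambiguous, non-gap positions only.
"""

from __future__ import annotations

import math

import pandas as pd

from .io_formats import (
    INVERTEBRATE_MITO,
    Library,
    SpecimenRecord,
    UNAMBIGUOUS,
    _internal_stop_count,
    stop_codons,
)

#: Row order of the library summary table.
SUMMARY_STATISTICS = [
    "G%", "C%", "A%", "T%", "GC%",
    "GC% pos1", "GC% pos2", "GC% pos3",
    "AT%", "AT% pos3",
]


def base_composition(record: SpecimenRecord) -> dict[str, float]:
    """Per-sequence base percentages over unambiguous bases.

    Returns A%, C%, G%, T%, GC% and AT% (GC% + AT% = 100).  Gaps and IUPAC
    ambiguity codes are excluded from the denominator.
    """
    counts = {b: 0 for b in "ACGT"}
    for c in record.sequence.upper():
        if c in UNAMBIGUOUS:
            counts[c] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError(
            f"specimen {record.specimen_id!r} has no unambiguous bases"
        )
    pct = {f"{b}%": 100.0 * counts[b] / total for b in "ACGT"}
    pct["GC%"] = 100.0 * (counts["G"] + counts["C"]) / total
    pct["AT%"] = 100.0 * (counts["A"] + counts["T"]) / total
    return pct


def gc_by_codon_position(
    record: SpecimenRecord, frame_offset: int = 0
) -> tuple[float, float, float]:
    """GC% at codon positions 1, 2 and 3.

    Alignment columns are assigned to codon positions cyclically starting
    from ``frame_offset`` (counted over non-gap characters, so an indel-free
    alignment and its ungapped sequences agree).  Ambiguous characters are
    excluded from the per-position denominators.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    seq = record.ungapped.upper()
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    gc = [0, 0, 0]
    tot = [0, 0, 0]
    for i, c in enumerate(seq):
        if c not in UNAMBIGUOUS:
            continue
        pos = (i - frame_offset) % 3
        tot[pos] += 1
        if c in "GC":
            gc[pos] += 1
    out = []
    for p in range(3):
        if tot[p] == 0:
            raise ValueError(f"no unambiguous bases at codon position {p + 1}")
        out.append(100.0 * gc[p] / tot[p])
    return tuple(out)  # type: ignore[return-value]


def infer_reading_frame(
    library: Library, genetic_code: str = INVERTEBRATE_MITO
) -> int:
    """Infer the reading frame by stop-codon minimisation.

    Protein-coding barcodes read in frame contain no internal stop codons,
    so the offset in {0, 1, 2} minimising the total stop count across the
    library is taken as the frame; ties break toward the smallest offset.
    """
    if not library.records:
        raise ValueError("cannot infer frame of an empty library")
    stops = stop_codons(genetic_code)
    totals = []
    for offset in (0, 1, 2):
        totals.append(
            sum(_internal_stop_count(r.ungapped, offset, stops) for r in library)
        )
    return min(range(3), key=lambda o: (totals[o], o))


def _per_record_stats(record: SpecimenRecord, frame_offset: int) -> dict[str, float]:
    stats = base_composition(record)
    gc1, gc2, gc3 = gc_by_codon_position(record, frame_offset)
    stats["GC% pos1"] = gc1
    stats["GC% pos2"] = gc2
    stats["GC% pos3"] = gc3
    stats["AT% pos3"] = 100.0 - gc3
    return stats


def summarize_composition(
    library: Library, frame_offset: int | None = None
) -> pd.DataFrame:
    """Library-level composition summary table.

    One row per statistic (G%, C%, A%, T%, GC%, GC% by codon position,
    AT%, AT% pos3) with columns ``min``, ``mean``, ``max`` and ``se``
    (standard error of the mean, sample SD / sqrt(n); NaN when n < 2).
    """
    if not library.records:
        raise ValueError("empty library")
    if frame_offset is None:
        frame_offset = infer_reading_frame(library)
    rows = [_per_record_stats(r, frame_offset) for r in library]
    df = pd.DataFrame(rows)
    n = len(df)
    summary = pd.DataFrame(
        {
            "min": df.min(),
            "mean": df.mean(),
            "max": df.max(),
            "se": (df.std(ddof=1) / math.sqrt(n)) if n >= 2 else float("nan"),
        }
    )
    return summary.loc[SUMMARY_STATISTICS]


def write_composition_table(summary: pd.DataFrame, path) -> None:
    """Write the summary as TSV, percentages rounded to 2 decimals."""
    summary.round(2).to_csv(path, sep="\t", index_label="statistic")
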