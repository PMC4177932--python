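"""Reading, validating and writing COI barcode libraries.

A *library* is a set of aligned (or at least equal-length) COI barcode
sequences, each tied to a specimen identifier and, usually, a binomial
species name.  Sequences arrive as FASTA with headers of the form
``specimen_id`` or ``specimen_id|Genus_species``; a separate tab-separated
metadata table can attach or override species names (and optionally a
country and a pre-assigned BIN label).

The module also houses the barcode-compliance filter: the minimum
data-quality standard a record must meet before it enters any analysis
(minimum length, low ambiguity, no internal stop codons under the
invertebrate mitochondrial genetic code).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger("barcodegap")

GAP_CHARS = frozenset("-")
UNAMBIGUOUS = frozenset("ACGT")
# IUPAC nucleotide codes accepted on input (ambiguities count toward the
# ambiguity fraction; gaps do not).
IUPAC_AMBIGUOUS = frozenset("NRYSWKMBDHV")
VALID_CHARS = UNAMBIGUOUS | IUPAC_AMBIGUOUS | GAP_CHARS

#: NCBI translation table for the invertebrate mitochondrial code.
INVERTEBRATE_MITO = "invertebrate_mitochondrial"
_GENETIC_CODE_IDS = {
    INVERTEBRATE_MITO: 5,
    "standard": 1,
    "vertebrate_mitochondrial": 2,
}


def stop_codons(genetic_code: str = INVERTEBRATE_MITO) -> frozenset[str]:
    """Stop codons of a named genetic code (e.g. TAA/TAG for table 5)."""
    table_id = _GENETIC_CODE_IDS.get(genetic_code)
    if table_id is None:
        raise ValueError(f"unknown genetic code: {genetic_code!r}")
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return frozenset(table.stop_codons)


@dataclass(frozen=True)
class SpecimenRecord:
    """One barcode sequence with its specimen-level metadata."""

    specimen_id: str
    sequence: str
    species: str = ""
    country: str = ""
    bin_label: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for specimen {self.specimen_id!r}")
        bad = set(self.sequence.upper()) - VALID_CHARS
        if bad:
            raise ValueError(
                f"specimen {self.specimen_id!r}: invalid characters {sorted(bad)}"
            )

    @property
    def length_bp(self) -> int:
        """Number of non-gap characters (true sequence length)."""
        return sum(1 for c in self.sequence if c not in GAP_CHARS)

    @property
    def ungapped(self) -> str:
        return "".join(c for c in self.sequence if c not in GAP_CHARS)

    def ambiguity_fraction(self) -> float:
        """Fraction of non-gap characters that are not unambiguous A/C/G/T."""
        n = self.length_bp
        ambig = sum(1 for c in self.ungapped if c.upper() not in UNAMBIGUOUS)
        return ambig / n if n else 0.0


@dataclass
class Library:
    """An ordered collection of specimen records.

    ``aligned`` means all sequences share one string length so columns are
    comparable; equal-length ungapped inputs are also treated as aligned.
    """

    records: list[SpecimenRecord] = field(default_factory=list)
    aligned: bool = False

    def __post_init__(self) -> None:
        ids = [r.specimen_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate specimen id(s): {sorted(dupes)}")
        if self.aligned and self.records:
            lengths = {len(r.sequence) for r in self.records}
            if len(lengths) > 1:
                raise ValueError(
                    f"library flagged aligned but has {len(lengths)} distinct "
                    "sequence lengths"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def alignment_length(self) -> Optional[int]:
        if self.aligned and self.records:
            return len(self.records[0].sequence)
        return None

    @property
    def ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    @property
    def species_names(self) -> list[str]:
        """Sorted distinct non-empty species labels."""
        return sorted({r.species for r in self.records if r.species})

    def by_species(self) -> dict[str, list[SpecimenRecord]]:
        out: dict[str, list[SpecimenRecord]] = {}
        for r in self.records:
            out.setdefault(r.species, []).append(r)
        return out

    def subset(self, specimen_ids: Iterable[str]) -> "Library":
        keep = set(specimen_ids)
        return Library(
            records=[r for r in self.records if r.specimen_id in keep],
            aligned=self.aligned,
        )

    def subset_species(self, species: Iterable[str]) -> "Library":
        keep = set(species)
        return Library(
            records=[r for r in self.records if r.species in keep],
            aligned=self.aligned,
        )


@dataclass
class ComplianceConfig:
    """Barcode-compliance thresholds.

    Defaults follow published barcode-standard practice: at least 500 bp,
    at most 1% ambiguous bases, and no internal stop codon in the reading
    frame that minimises stops library-wide under the invertebrate
    mitochondrial code.  Each check is independently switchable.
    """

    min_length_bp: int = 500
    max_ambiguity_fraction: float = 0.01
    check_stop_codons: bool = True
    genetic_code: str = INVERTEBRATE_MITO

    def __post_init__(self) -> None:
        if self.min_length_bp <= 0:
            raise ValueError("min_length_bp must be positive")
        if not 0.0 <= self.max_ambiguity_fraction <= 1.0:
            raise ValueError("max_ambiguity_fraction must be in [0, 1]")


def _parse_header(header: str) -> tuple[str, str]:
    """Split a FASTA header into (specimen_id, species).

    Dialect: ``id|Genus_species`` with underscores standing for spaces in
    the species name; anything after a second ``|`` is ignored.
    """
    parts = header.split("|")
    specimen_id = parts[0].strip()
    species = parts[1].strip().replace("_", " ") if len(parts) > 1 else ""
    return specimen_id, species


def read_fasta(path: str | Path, aligned: Optional[bool] = None) -> Library:
    """Read a FASTA file into a :class:`Library`.

    The aligned flag defaults to auto-detection: true iff all sequences
    share one string length and at least one gap character is present, or
    all are equal-length and ungapped (pre-trimmed amplicons).  Pass
    ``aligned`` explicitly to override.
    """
    path = Path(path)
    records = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        specimen_id, species = _parse_header(entry.description)
        if specimen_id in seen:
            raise ValueError(f"duplicate specimen id in {path.name}: {specimen_id!r}")
        seen.add(specimen_id)
        records.append(
            SpecimenRecord(
                specimen_id=specimen_id,
                species=species,
                sequence=str(entry.seq).upper(),
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if aligned is None:
        lengths = {len(r.sequence) for r in records}
        aligned = len(lengths) == 1
    return Library(records=records, aligned=aligned)


def write_fasta(library: Library, path: str | Path) -> None:
    """Write a library back to FASTA (``id|Genus_species`` headers)."""
    path = Path(path)
    with path.open("w") as fh:
        for r in library:
            header = r.specimen_id
            if r.species:
                header += "|" + r.species.replace(" ", "_")
            fh.write(f">{header}\n{r.sequence}\n")


def read_specimen_table(path: str | Path, library: Library) -> Library:
    """Attach species (and optional country/bin) from a metadata TSV.

    The table must have ``specimen_id`` and ``species`` columns; species
    from the table override any parsed from FASTA headers.  Table rows
    whose id is absent from the library are reported with a warning and
    returned untouched in the log.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"specimen_id", "species"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing column(s): {sorted(missing)}")

    meta = {row.specimen_id: row for row in df.itertuples(index=False)}
    known = set(library.ids)
    unmatched = [sid for sid in meta if sid not in known]
    if unmatched:
        msg = f"{len(unmatched)} metadata row(s) match no FASTA record: {unmatched[:5]}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)

    new_records = []
    for r in library:
        row = meta.get(r.specimen_id)
        if row is None:
            new_records.append(r)
            continue
        new_records.append(
            replace(
                r,
                species=row.species or r.species,
                country=getattr(row, "country", "") or r.country,
                bin_label=getattr(row, "bin", "") or r.bin_label,
            )
        )
    return Library(records=new_records, aligned=library.aligned)


def _internal_stop_count(seq: str, frame_offset: int, stops: frozenset[str]) -> int:
    """Count stop codons at complete codon positions (frame fixed)."""
    s = seq.upper()
    count = 0
    for i in range(frame_offset, len(s) - 2, 3):
        if s[i : i + 3] in stops:
            count += 1
    return count


def filter_barcode_compliant(
    library: Library,
    config: ComplianceConfig | None = None,
    frame_offset: Optional[int] = None,
) -> tuple[Library, pd.DataFrame]:
    """Split a library into compliant records and a rejection report.

    Checks, in order: minimum ungapped length, ambiguity fraction, and
    (optionally) zero internal stop codons.  The reading frame for the
    stop-codon check is inferred by stop-minimisation across the library
    unless given.  Returns ``(compliant_library, report)`` where the report
    has one row per rejected specimen with the first failing reason.
    """
    if config is None:
        config = ComplianceConfig()
    if not library.records:
        raise ValueError("cannot filter an empty library")

    stops = stop_codons(config.genetic_code)
    if config.check_stop_codons and frame_offset is None:
        # local import: composition depends on io_formats, not vice versa
        from .composition import infer_reading_frame

        frame_offset = infer_reading_frame(library, config.genetic_code)

    kept: list[SpecimenRecord] = []
    rejected: list[dict[str, str]] = []
    for r in library:
        if r.length_bp < config.min_length_bp:
            rejected.append({"specimen_id": r.specimen_id, "reason": "length"})
        elif r.ambiguity_fraction() > config.max_ambiguity_fraction:
            rejected.append({"specimen_id": r.specimen_id, "reason": "ambiguity"})
        elif config.check_stop_codons and _internal_stop_count(
            r.ungapped, frame_offset or 0, stops
        ) > 0:
            rejected.append({"specimen_id": r.specimen_id, "reason": "stop_codon"})
        else:
            kept.append(r)

    report = pd.DataFrame(rejected, columns=["specimen_id", "reason"])
    if rejected:
        logger.info("compliance filter rejected %d of %d records", len(rejected), len(library))
    aligned = library.aligned and len({len(r.sequence) for r in kept} or {0}) <= 1
    return Library(records=kept, aligned=aligned if kept else False), report


def read_config_file(path: str | Path) -> dict[str, str]:
    """Read a flat ``key=value`` config file; '#' starts a comment."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line (expected key=value): {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out
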