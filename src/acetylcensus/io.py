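"""Readers and writers for the plain-text formats used throughout the census.

Every external representation is a FASTA file or a header-less/headered TSV.
All readers *reject* malformed rows rather than repairing them, and TSV error
messages carry 1-based line numbers.  Coordinates are 1-based inclusive at the
file boundary; the single place where they are converted to 0-based half-open
intervals is :func:`zero_based_interval`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

# closed vocabularies ------------------------------------------------------

SPECIES_TYPES = (
    "dicot",
    "monocot",
    "green_algae",
    "red_algae_glaucophyte",
    "heterokont_other",
    "non_photosynthetic",
)

COMPARTMENTS = ("nucleus", "cytosol", "mitochondrion", "chloroplast", "secretory", "other")

MOTIF_CATEGORIES = ("cold_drought", "light_circadian", "other")

DOMAIN_SOURCES = ("pfam_like", "prosite_like")

N_PREDICTORS = 5

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
GAP_CHARS = frozenset("-.")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# domain types -------------------------------------------------------------


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence (protein or nucleotide), stored uppercase."""

    id: str
    description: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneLocus:
    """Gene location with 1-based inclusive coordinates, as in the source file."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class MotifElement:
    """A promoter cis-element: an exact DNA string with a functional category."""

    name: str
    pattern: str
    category: str


@dataclass(frozen=True)
class DomainAnnotation:
    """One domain occurrence on a protein, 1-based inclusive coordinates."""

    protein_id: str
    domain_name: str
    start: int
    end: int
    source: str


def zero_based_interval(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open.

    This is the only place in the package where that conversion happens.
    """
    return start - 1, end


# FASTA --------------------------------------------------------------------


def _validate_sequence(seq_id: str, seq: str, kind: str, allow_gaps: bool) -> None:
    if not seq:
        raise FormatError(f"empty sequence for id {seq_id!r}")
    letters = set(seq)
    gaps = letters & GAP_CHARS
    if gaps and not allow_gaps:
        raise FormatError(f"gap characters {sorted(gaps)} not allowed in {kind} record {seq_id!r}")
    letters -= GAP_CHARS
    allowed = PROTEIN_ALPHABET if kind == "protein" else NUCLEOTIDE_ALPHABET
    bad = letters - allowed
    if bad:
        raise FormatError(f"invalid {kind} characters {sorted(bad)} in record {seq_id!r}")


def read_fasta(path: str | Path, kind: str = "protein", allow_gaps: bool = False) -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord`.

    Parameters
    ----------
    kind:
        ``"protein"`` or ``"nucleotide"``; controls alphabet validation.
    allow_gaps:
        Permit ``-``/``.`` characters (used for aligned seed FASTA input).

    Order is preserved, sequences are uppercased; duplicate ids and empty
    sequences are hard errors.
    """
    if kind not in ("protein", "nucleotide"):
        raise ValueError(f"kind must be 'protein' or 'nucleotide', got {kind!r}")
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        _validate_sequence(rec.id, seq, kind, allow_gaps)
        records.append(SeqRecord(id=rec.id, description=rec.description, sequence=seq))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            header = rec.description if rec.description and rec.description != rec.id else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# TSV helpers --------------------------------------------------------------


def _tsv_rows(path: str | Path, n_cols: int, header: tuple[str, ...] | None = None):
    """Yield (lineno, fields) for a TSV file, validating the column count.

    If ``header`` is given and the first line equals it, the line is skipped;
    a header is otherwise not required.
    """
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and header is not None and tuple(fields) == header:
                continue
            if len(fields) != n_cols:
                raise FormatError(f"{path}:{lineno}: expected {n_cols} tab-separated columns, got {len(fields)}")
            yield lineno, fields


def write_tsv(path: str | Path, header: Iterable[str], rows: Iterable[Iterable]) -> None:
    """Write a TSV with header row, UTF-8, LF line endings."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(map(str, header)) + "\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


# gene locations -----------------------------------------------------------

_LOCI_HEADER = ("gene_id", "scaffold", "start", "end", "strand")


def read_gene_locations(path: str | Path) -> list[GeneLocus]:
    """Read a 5-column gene location TSV (gene_id, scaffold, start, end, strand).

    Coordinates are kept 1-based inclusive, exactly as in the file.
    """
    loci: list[GeneLocus] = []
    seen: set[str] = set()
    for lineno, f in _tsv_rows(path, 5, header=_LOCI_HEADER):
        gene_id, scaffold, start_s, end_s, strand = f
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate") from None
        if strand not in ("+", "-"):
            raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
        if not (1 <= start <= end):
            raise FormatError(f"{path}:{lineno}: invalid interval start={start} end={end}")
        if gene_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene_id {gene_id}")
        seen.add(gene_id)
        loci.append(GeneLocus(gene_id, scaffold, start, end, strand))
    return loci


def read_gene_locations_gff3(path: str | Path) -> list[GeneLocus]:
    """GFF3 import shim: extract ``gene`` features, using the ID attribute as gene_id.

    Only the minimal subset needed for promoter extraction is interpreted.
    """
    loci: list[GeneLocus] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            if fields[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv)
            gene_id = attrs.get("ID")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: gene feature without ID attribute")
            if fields[6] not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand {fields[6]!r}")
            start, end = int(fields[3]), int(fields[4])
            if not (1 <= start <= end):
                raise FormatError(f"{path}:{lineno}: invalid interval start={start} end={end}")
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene ID {gene_id}")
            seen.add(gene_id)
            loci.append(GeneLocus(gene_id, fields[0], start, end, fields[6]))
    return loci


# motif library ------------------------------------------------------------

_MOTIF_HEADER = ("name", "pattern", "category")


def read_motif_library(path: str | Path) -> list[MotifElement]:
    """Read the promoter element library TSV (name, pattern, category)."""
    elements: list[MotifElement] = []
    seen: set[str] = set()
    for lineno, f in _tsv_rows(path, 3, header=_MOTIF_HEADER):
        name, pattern, category = f[0], f[1].upper(), f[2]
        bad = set(pattern) - set("ACGT")
        if bad:
            raise FormatError(f"{path}:{lineno}: non-ACGT characters {sorted(bad)} in pattern for {name}")
        if len(pattern) < 2:
            raise FormatError(f"{path}:{lineno}: pattern for {name} shorter than 2 nt")
        if category not in MOTIF_CATEGORIES:
            raise FormatError(f"{path}:{lineno}: unknown category {category!r}")
        if name in seen:
            raise FormatError(f"{path}:{lineno}: duplicate element name {name}")
        seen.add(name)
        elements.append(MotifElement(name, pattern, category))
    if not elements:
        logger.warning("motif library %s is empty", path)
    return elements


# species table ------------------------------------------------------------

_SPECIES_HEADER = ("species_id", "species_type")


def read_species_table(path: str | Path) -> dict[str, str]:
    """Read the species table TSV into an ordered mapping species_id -> species_type."""
    table: dict[str, str] = {}
    for lineno, f in _tsv_rows(path, 2, header=_SPECIES_HEADER):
        species_id, species_type = f
        if species_type not in SPECIES_TYPES:
            raise FormatError(f"{path}:{lineno}: unknown species_type {species_type!r}")
        if species_id in table:
            raise FormatError(f"{path}:{lineno}: duplicate species_id {species_id}")
        table[species_id] = species_type
    return table


# domain table -------------------------------------------------------------

_DOMAIN_HEADER = ("protein_id", "domain_name", "start", "end", "source")


def read_domain_table(
    path: str | Path, proteome: Mapping[str, SeqRecord] | None = None
) -> list[DomainAnnotation]:
    """Read the domain annotation TSV; optionally cross-check coordinates against a proteome."""
    rows: list[DomainAnnotation] = []
    for lineno, f in _tsv_rows(path, 5, header=_DOMAIN_HEADER):
        protein_id, domain_name, start_s, end_s, source = f
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate") from None
        if source not in DOMAIN_SOURCES:
            raise FormatError(f"{path}:{lineno}: unknown source {source!r}")
        if not (1 <= start <= end):
            raise FormatError(f"{path}:{lineno}: invalid interval start={start} end={end}")
        if proteome is not None:
            if protein_id not in proteome:
                raise FormatError(f"{path}:{lineno}: unknown protein {protein_id}")
            if end > len(proteome[protein_id]):
                raise FormatError(
                    f"{path}:{lineno}: domain end {end} exceeds length of protein {protein_id}"
                )
        rows.append(DomainAnnotation(protein_id, domain_name, start, end, source))
    return rows


# localization prediction table -------------------------------------------

_PREDICTION_HEADER = ("protein_id", "predictor", "call")


def read_prediction_table(
    path: str | Path, aliases: Mapping[str, str] | None = None
) -> dict[str, dict[str, str]]:
    """Read the five-predictor localization table into protein_id -> {predictor: call}.

    Exactly five rows per protein are required.  ``aliases`` maps predictor-
    specific compartment labels onto the six-label vocabulary (plus "none").
    """
    table: dict[str, dict[str, str]] = {}
    valid_calls = set(COMPARTMENTS) | {"none"}
    for lineno, f in _tsv_rows(path, 3, header=_PREDICTION_HEADER):
        protein_id, predictor, call = f
        if aliases is not None:
            call = aliases.get(call, call)
        if call not in valid_calls:
            raise FormatError(f"{path}:{lineno}: unknown compartment label {call!r} (supply an alias table?)")
        calls = table.setdefault(protein_id, {})
        if predictor in calls:
            raise FormatError(f"{path}:{lineno}: duplicate predictor {predictor} for protein {protein_id}")
        calls[predictor] = call
    bad = sorted(p for p, calls in table.items() if len(calls) != N_PREDICTORS)
    if bad:
        raise FormatError(f"{path}: proteins without exactly {N_PREDICTORS} predictor rows: {', '.join(bad)}")
    return table
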