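"""Readers and writers for the pipeline's on-disk formats.

Formats handled: FASTA contigs, PAF read-to-contig alignment summaries, and
the pipeline's TSV tables (tool evidence, sample metadata, gene annotations,
abundance matrices, protein-cluster membership, population membership,
boundary evidence), plus a flat JSON / key=value run configuration.

Conventions
-----------
* All interval coordinates are 0-based half-open; PAF is natively so.
* Missing values in TSV tables are written as ``"."`` and are semantically
  distinct from zero.
* FASTA output wraps sequence lines at 60 columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

VALID_BASES = frozenset("ACGTN")
ZONES = ("oxic", "redoxcline", "euxinic", "unknown")

MISSING = "."


class FormatError(ValueError):
    """A file violates its declared dialect (malformed record, bad header...)."""


class SchemaError(FormatError):
    """A TSV table does not match the named schema."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContigRecord:
    """A nucleotide contig with sample/zone provenance.

    ``zone`` is the water-column layer the source sample came from:
    ``oxic`` (oxygenated), ``redoxcline`` (the O2/sulfide transition) or
    ``euxinic`` (anoxic and sulfidic).
    """

    contig_id: str
    sequence: str
    sample_id: str = ""
    zone: str = "unknown"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"contig {self.contig_id!r}: empty sequence")
        if self.zone not in ZONES:
            raise FormatError(f"contig {self.contig_id!r}: unknown zone {self.zone!r}")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FormatError(
                f"contig {self.contig_id!r}: invalid characters {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadAlignment:
    """One read-to-contig alignment summary (a PAF line).

    ``aligned_read_bases`` is the span of the read that aligned
    (query_end - query_start); ``matches`` is the number of matching
    columns (PAF column 10).  Read identity downstream is
    ``100 * matches / aligned_read_bases`` so gap columns count against
    identity through the denominator.
    """

    read_id: str
    read_length: int
    contig_id: str
    contig_start: int
    contig_end: int
    aligned_read_bases: int
    matches: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise FormatError(f"read {self.read_id!r}: non-positive read length")
        if not (0 <= self.contig_start < self.contig_end):
            raise FormatError(
                f"read {self.read_id!r}: inverted contig interval "
                f"[{self.contig_start}, {self.contig_end})"
            )
        if not (0 < self.aligned_read_bases <= self.read_length):
            raise FormatError(f"read {self.read_id!r}: bad aligned_read_bases")
        if not (0 <= self.matches <= self.aligned_read_bases):
            raise FormatError(f"read {self.read_id!r}: matches out of range")

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.matches / self.aligned_read_bases

    @property
    def read_fraction(self) -> float:
        return self.aligned_read_bases / self.read_length


@dataclass(frozen=True)
class SampleMetadata:
    """A virome sample: depth, zone, and total sequenced bases."""

    sample_id: str
    depth_m: float
    zone: str
    metagenome_size_bp: int

    def __post_init__(self) -> None:
        if self.zone not in ZONES:
            raise FormatError(f"sample {self.sample_id!r}: unknown zone {self.zone!r}")
        if self.metagenome_size_bp <= 0:
            raise FormatError(f"sample {self.sample_id!r}: metagenome_size_bp must be > 0")


@dataclass(frozen=True)
class GeneAnnotationRow:
    """One predicted gene on a contig (see :mod:`viropop.amg_context`)."""

    contig_id: str
    gene_index: int
    start: int
    end: int
    strand: str
    category: str
    amg_name: str | None = None


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[ContigRecord]:
    """Read contigs from FASTA; sequences are uppercased and validated.

    Raises :class:`FormatError` on duplicate headers, empty sequences or
    characters outside ``{A,C,G,T,N}``.  Record order is preserved.
    """
    records: list[ContigRecord] = []
    seen: set[str] = set()
    dupes: list[str] = []
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            contig_id = header.split()[0] if header.split() else header
            if contig_id in seen:
                dupes.append(contig_id)
                continue
            seen.add(contig_id)
            records.append(ContigRecord(contig_id=contig_id, sequence=seq.upper()))
    if dupes:
        raise FormatError(f"duplicate FASTA headers: {sorted(set(dupes))}")
    return records


def write_fasta(records: Iterable[ContigRecord], path: str | Path, width: int = 60) -> None:
    """Write contigs as FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.contig_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------


def read_paf(path: str | Path, sample_id: str = "") -> list[ReadAlignment]:
    """Parse a 12+-column PAF file into :class:`ReadAlignment` records.

    Column 10 (1-based) is the match count and columns 3/4 the query
    start/end; strand is ignored because recruitment counts both strands.
    Raises :class:`FormatError` with the line number on short or
    inconsistent lines.
    """
    alignments: list[ReadAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: PAF line has {len(fields)} columns, expected >= 12"
                )
            try:
                read_id = fields[0]
                read_length = int(fields[1])
                qstart, qend = int(fields[2]), int(fields[3])
                contig_id = fields[5]
                tstart, tend = int(fields[7]), int(fields[8])
                matches = int(fields[9])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable field ({exc})") from exc
            if qend <= qstart or tend <= tstart:
                raise FormatError(f"{path}:{lineno}: inverted coordinates")
            alignments.append(
                ReadAlignment(
                    read_id=read_id,
                    read_length=read_length,
                    contig_id=contig_id,
                    contig_start=tstart,
                    contig_end=tend,
                    aligned_read_bases=qend - qstart,
                    matches=matches,
                    sample_id=sample_id,
                )
            )
    return alignments


def write_paf(alignments: Iterable[ReadAlignment], path: str | Path) -> None:
    """Write alignments as minimal 12-column PAF (strand '+', MAPQ 60).

    Target length (column 7) is written as the alignment end coordinate —
    a lower bound, sufficient for the round-trip of the fields this
    pipeline consumes.
    """
    with open(path, "w") as fh:
        for a in alignments:
            block = max(a.aligned_read_bases, a.contig_end - a.contig_start)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        a.read_id,
                        a.read_length,
                        0,
                        a.aligned_read_bases,
                        "+",
                        a.contig_id,
                        a.contig_end,
                        a.contig_start,
                        a.contig_end,
                        a.matches,
                        block,
                        60,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

#: required columns per named schema
SCHEMAS: dict[str, tuple[str, ...]] = {
    "evidence": (
        "contig_id",
        "virsorter_category",
        "virfinder_score",
        "cat_viral",
        "phaster_prophage",
        "contig_length",
    ),
    "samples": ("sample_id", "depth_m", "zone", "metagenome_size_bp"),
    "genes": ("contig_id", "gene_index", "start", "end", "strand", "category", "amg_name"),
    "abundance": ("population_id",),  # remaining columns are sample ids
    "pc": ("population_id", "pc_id"),
    "populations": ("population_id", "representative_id", "member_id"),
    "boundary": ("contig_id", "attL_coord", "attR_coord", "termini_predicted",
                 "phaster_start", "phaster_end"),
}


def _split_rows(path: str | Path) -> tuple[list[str], list[list[str]]]:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise SchemaError(f"{path}: empty table")
    header = lines[0].split("\t")
    return header, [ln.split("\t") for ln in lines[1:]]


def _opt(value: str, cast, path, rownum, col):
    if value == MISSING or value == "":
        return None
    try:
        if cast is bool:
            if value.lower() in ("true", "1", "yes"):
                return True
            if value.lower() in ("false", "0", "no"):
                return False
            raise ValueError(f"not a boolean: {value!r}")
        return cast(value)
    except ValueError as exc:
        raise SchemaError(f"{path}: row {rownum}, column {col!r}: {exc}") from exc


def read_table(path: str | Path, schema_name: str):
    """Read a TSV table and return typed rows for the named schema.

    Unknown columns are preserved in the raw row dictionaries but ignored
    by the typed constructors.  ``"."`` marks a missing value.  Raises
    :class:`SchemaError` naming the first missing required column or the
    row/column of an unparseable cell.
    """
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}")
    header, raw_rows = _split_rows(path)
    required = SCHEMAS[schema_name]
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing} for schema {schema_name!r}")

    idx = {c: header.index(c) for c in header}
    rows = []
    for rownum, fields in enumerate(raw_rows, start=2):
        if len(fields) < len(header):
            raise SchemaError(f"{path}: row {rownum}: {len(fields)} fields, expected {len(header)}")
        cell = {c: fields[idx[c]] for c in header}
        if schema_name == "evidence":
            from viropop.viral_id import ToolEvidence

            rows.append(
                ToolEvidence(
                    contig_id=cell["contig_id"],
                    virsorter_category=_opt(cell["virsorter_category"], int, path, rownum, "virsorter_category"),
                    virfinder_score=_opt(cell["virfinder_score"], float, path, rownum, "virfinder_score"),
                    cat_viral=_opt(cell["cat_viral"], bool, path, rownum, "cat_viral"),
                    phaster_prophage=_opt(cell["phaster_prophage"], bool, path, rownum, "phaster_prophage"),
                    contig_length=_opt(cell["contig_length"], int, path, rownum, "contig_length"),
                )
            )
        elif schema_name == "samples":
            rows.append(
                SampleMetadata(
                    sample_id=cell["sample_id"],
                    depth_m=_opt(cell["depth_m"], float, path, rownum, "depth_m"),
                    zone=cell["zone"],
                    metagenome_size_bp=_opt(cell["metagenome_size_bp"], int, path, rownum, "metagenome_size_bp"),
                )
            )
        elif schema_name == "genes":
            amg = cell["amg_name"]
            rows.append(
                GeneAnnotationRow(
                    contig_id=cell["contig_id"],
                    gene_index=_opt(cell["gene_index"], int, path, rownum, "gene_index"),
                    start=_opt(cell["start"], int, path, rownum, "start"),
                    end=_opt(cell["end"], int, path, rownum, "end"),
                    strand=cell["strand"],
                    category=cell["category"],
                    amg_name=None if amg in (MISSING, "") else amg,
                )
            )
        else:
            rows.append(cell)
    return rows


def write_table(rows: Sequence[dict], columns: Sequence[str], path: str | Path) -> None:
    """Write dictionaries as a TSV table; ``None`` becomes ``"."``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write(
                "\t".join(MISSING if row.get(c) is None else str(row.get(c)) for c in columns)
                + "\n"
            )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a run configuration: JSON if the file starts with ``{``,
    otherwise flat ``key=value`` lines (values parsed as JSON scalars when
    possible)."""
    text = Path(path).read_text(encoding="utf-8")
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return json.loads(text)
    config: dict = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected key=value")
        key, _, value = line.partition("=")
        value = value.strip()
        try:
            config[key.strip()] = json.loads(value)
        except json.JSONDecodeError:
            config[key.strip()] = value
    return config
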