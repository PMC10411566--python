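"""Reading and writing BUSCO full tables and sequence-length tables.

BUSCO's ``full_table.tsv`` lists every marker of a lineage dataset, one line
per observation, with its completeness status and (for found markers) the
sequence and coordinates of the best hit.  Version 5 writes eight columns
(``Busco id, Status, Sequence, Gene Start, Gene End, Strand, Score, Length``);
versions 3/4 lack the Strand column, and some older outputs embed coordinates
in the sequence field as ``scaffold:start-end``.  All dialects are normalised
here into :class:`MarkerRecord` lists; everything downstream is
dialect-agnostic.

Coordinates are treated as 1-based inclusive.  Only the *relative order* of
markers along a sequence is ever used by the synteny analysis, so base-pair
conventions cannot change any result.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

__all__ = [
    "MarkerRecord",
    "SequenceLengths",
    "BuscoParseError",
    "STATUSES",
    "parse_full_table",
    "write_full_table",
    "load_sequence_lengths",
    "infer_sequence_lengths",
]

STATUSES = frozenset({"Complete", "Duplicated", "Fragmented", "Missing"})

V5_HEADER = (
    "# Busco id\tStatus\tSequence\tGene Start\tGene End\tStrand\tScore\tLength"
)


class BuscoParseError(ValueError):
    """Malformed full-table input; message carries the 1-based line number."""


@dataclass(frozen=True)
class MarkerRecord:
    """One observation of a single-copy ortholog marker in one genome.

    A *Duplicated* marker produces several records (one per hit line), a
    *Missing* marker exactly one record with no positional fields.
    """

    marker_id: str
    status: str
    sequence_id: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str = "unknown"  # '+', '-', or 'unknown'
    score: float | None = None
    length: int | None = None

    def __post_init__(self) -> None:
        if not self.marker_id:
            raise ValueError("marker_id must be non-empty")
        if self.status not in STATUSES:
            raise ValueError(f"unrecognized status {self.status!r}")
        if self.status == "Missing" and (
            self.sequence_id is not None
            or self.start is not None
            or self.end is not None
        ):
            raise ValueError(
                f"Missing marker {self.marker_id} must not carry coordinates"
            )
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValueError(
                f"marker {self.marker_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def has_position(self) -> bool:
        return (
            self.sequence_id is not None
            and self.start is not None
            and self.end is not None
        )


@dataclass
class SequenceLengths:
    """Mapping sequence name -> length in bp.

    ``inferred`` marks lengths reconstructed from marker coordinates (a lower
    bound on the true assembly lengths); per-Mbp rates computed from inferred
    lengths are annotated as such in reports.
    """

    lengths: dict[str, int] = field(default_factory=dict)
    inferred: bool = False

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"sequence {name}: non-positive length {length}")

    def __getitem__(self, name: str) -> int:
        return self.lengths[name]

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def total_bp(self, sequences: Iterable[str] | None = None) -> int:
        if sequences is None:
            return sum(self.lengths.values())
        return sum(self.lengths[s] for s in sequences if s in self.lengths)


Source = Union[str, "os.PathLike[str]", IO[str]]


def _as_lines(source: Source) -> list[str]:
    """Accept a path, an open text handle, or literal table text."""
    if hasattr(source, "read"):
        return source.read().splitlines()  # type: ignore[union-attr]
    if isinstance(source, os.PathLike):
        return Path(source).read_text().splitlines()
    assert isinstance(source, str)
    # A string containing a newline or tab is table content, not a filename.
    if "\n" in source or "\t" in source:
        return source.splitlines()
    return Path(source).read_text().splitlines()


_COLUMN_ALIASES = {
    "busco id": "marker_id",
    "busco_id": "marker_id",
    "status": "status",
    "sequence": "sequence_id",
    "contig": "sequence_id",
    "scaffold": "sequence_id",
    "gene start": "start",
    "start": "start",
    "gene end": "end",
    "end": "end",
    "strand": "strand",
    "score": "score",
    "length": "length",
    # informational columns of some BUSCO 5 outputs; ignored
    "orthodb url": None,
    "url": None,
    "description": None,
}

_EMBEDDED_COORDS = re.compile(r"^(?P<seq>.+):(?P<start>\d+)-(?P<end>\d+)$")


def _detect_columns(lines: list[str]) -> list[str | None] | None:
    """Map header columns to field names; None when no header is present."""
    for line in lines:
        if not line.startswith("#"):
            break
        lowered = line.lstrip("#").strip().lower()
        if "busco" in lowered and "\t" in line:
            cols = [c.strip().lower() for c in line.lstrip("#").strip().split("\t")]
            mapped: list[str | None] = []
            for c in cols:
                if c in _COLUMN_ALIASES:
                    mapped.append(_COLUMN_ALIASES[c])
                else:
                    mapped.append(None)  # tolerate unknown extra columns
            if "marker_id" in mapped and "status" in mapped:
                return mapped
    return None


_POSITIONAL = {
    8: ["marker_id", "status", "sequence_id", "start", "end", "strand", "score", "length"],
    7: ["marker_id", "status", "sequence_id", "start", "end", "score", "length"],
    5: ["marker_id", "status", "sequence_id", "start", "end"],
    3: ["marker_id", "status", "sequence_id"],
    2: ["marker_id", "status"],
}


def _int_field(value: str, what: str, lineno: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise BuscoParseError(
            f"line {lineno}: non-integer {what} {value!r}"
        ) from None


def parse_full_table(source: Source) -> list[MarkerRecord]:
    """Parse a BUSCO full table into records, preserving input order.

    Dialect is detected from the header when present, otherwise from the
    column count of data lines.  Inputs without a Strand column yield
    ``strand='unknown'`` on every record; a ``scaffold:start-end`` sequence
    field is split into its parts when no explicit coordinate columns exist.
    """
    lines = _as_lines(source)
    columns = _detect_columns(lines)
    records: list[MarkerRecord] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if columns is not None:
            cols = columns
            if len(fields) > len(cols):
                raise BuscoParseError(
                    f"line {lineno}: {len(fields)} columns, header declares {len(cols)}"
                )
        else:
            n = len(fields)
            if n not in _POSITIONAL:
                # Missing lines are always 2 columns; found lines must match
                # one of the known layouts.
                raise BuscoParseError(f"line {lineno}: unexpected column count {n}")
            cols = _POSITIONAL[n]
        values: dict[str, str] = {}
        for name, value in zip(cols, fields):
            if name is not None and value != "":
                values[name] = value

        marker_id = values.get("marker_id", "")
        if not marker_id:
            raise BuscoParseError(f"line {lineno}: empty marker id")
        status = values.get("status", "")
        if status not in STATUSES:
            raise BuscoParseError(f"line {lineno}: unrecognized status {status!r}")

        sequence_id = values.get("sequence_id")
        start = end = None
        if "start" in values:
            start = _int_field(values["start"], "start coordinate", lineno)
        if "end" in values:
            end = _int_field(values["end"], "end coordinate", lineno)
        if sequence_id is not None and start is None and end is None:
            m = _EMBEDDED_COORDS.match(sequence_id)
            if m:
                sequence_id = m.group("seq")
                start = int(m.group("start"))
                end = int(m.group("end"))

        strand = values.get("strand", "unknown")
        if strand in ("−", "-"):  # tolerate U+2212 minus
            strand = "-"
        elif strand not in ("+", "unknown"):
            strand = "unknown"

        score = float(values["score"]) if "score" in values else None
        length = (
            _int_field(values["length"], "length", lineno)
            if "length" in values
            else None
        )
        if status == "Missing":
            sequence_id = start = end = None
            strand = "unknown"
        try:
            records.append(
                MarkerRecord(
                    marker_id=marker_id,
                    status=status,
                    sequence_id=sequence_id,
                    start=start,
                    end=end,
                    strand=strand,
                    score=score,
                    length=length,
                )
            )
        except ValueError as exc:
            raise BuscoParseError(f"line {lineno}: {exc}") from None
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)  # shortest representation that parses back exactly
    return str(value)


def write_full_table(records: Iterable[MarkerRecord]) -> str:
    """Serialize records as v5-dialect full-table text.

    ``parse_full_table(write_full_table(r))`` reproduces ``r`` field for
    field; unknown strands are written as empty cells.
    """
    out = io.StringIO()
    out.write(V5_HEADER + "\n")
    for r in records:
        if r.status == "Missing":
            out.write(f"{r.marker_id}\t{r.status}\n")
            continue
        strand = r.strand if r.strand in ("+", "-") else ""
        out.write(
            "\t".join(
                [
                    r.marker_id,
                    r.status,
                    _fmt(r.sequence_id),
                    _fmt(r.start),
                    _fmt(r.end),
                    strand,
                    _fmt(r.score),
                    _fmt(r.length),
                ]
            )
            + "\n"
        )
    return out.getvalue()


def load_sequence_lengths(source: Source) -> SequenceLengths:
    """Read a FASTA-index-style table (name and length in the first columns)."""
    lengths: dict[str, int] = {}
    for lineno, line in enumerate(_as_lines(source), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"line {lineno}: expected >=2 tab-separated columns")
        name = fields[0]
        try:
            length = int(fields[1])
        except ValueError:
            raise ValueError(f"line {lineno}: non-integer length {fields[1]!r}") from None
        if name in lengths:
            raise ValueError(f"line {lineno}: duplicate sequence name {name!r}")
        if length <= 0:
            raise ValueError(f"line {lineno}: non-positive length for {name!r}")
        lengths[name] = length
    return SequenceLengths(lengths=lengths, inferred=False)


def infer_sequence_lengths(records: Iterable[MarkerRecord]) -> SequenceLengths:
    """Lower-bound sequence lengths from the markers themselves.

    Per sequence, the maximum marker end coordinate.  The result is flagged
    ``inferred`` so per-Mbp rates derived from it are reported as
    lower-resolution.
    """
    lengths: dict[str, int] = {}
    for r in records:
        if not r.has_position:
            continue
        assert r.sequence_id is not None and r.end is not None
        lengths[r.sequence_id] = max(lengths.get(r.sequence_id, 0), r.end)
    if not lengths:
        raise ValueError("no positioned records: cannot infer sequence lengths")
    return SequenceLengths(lengths=lengths, inferred=True)
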