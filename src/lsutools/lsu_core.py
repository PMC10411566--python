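"""Synteny-unit definition, target assignment, and composition analysis.

A synteny unit (LSU) is the subset of single-copy ortholog markers residing
on one chromosome of the anchor genome.  Because the markers are
near-universal single-copy orthologs, marker identity alone carries homology
across species: a target genome's markers are joined to the anchor units by
id, never by coordinate, and the resulting per-chromosome unit composition
exposes fusions (one target chromosome holding several units) and fissions
(one unit spread over several target chromosomes).
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .busco_io import MarkerRecord, SequenceLengths, _as_lines

__all__ = [
    "LsuEntry",
    "LsuTable",
    "AssignmentRow",
    "Assignment",
    "ChromosomeCall",
    "LsuCall",
    "CompositionReport",
    "CoverageRow",
    "CoverageSummary",
    "filter_usable",
    "define_lsus",
    "coverage_summary",
    "assign_markers",
    "composition_matrix",
    "classify_composition",
]

logger = logging.getLogger(__name__)

UNASSIGNED = None  # sentinel for markers absent from the unit table

_TRAILING_INT = re.compile(r"(\d+)\s*$")
_Z_TOKEN = re.compile(r"(?:^|[^0-9a-z])z$", re.IGNORECASE)


def filter_usable(
    records: Sequence[MarkerRecord], drop_fragmented: bool = False
) -> list[MarkerRecord]:
    """Remove markers unusable as single-copy homology anchors.

    Drops every Missing line and *every* line of any marker that appears with
    status Duplicated — BUSCO cannot say which duplicate is the orthologous
    copy, so the marker is discarded entirely.  Fragmented markers are kept
    unless ``drop_fragmented``; relative order is preserved.
    """
    duplicated_ids = {r.marker_id for r in records if r.status == "Duplicated"}
    kept: list[MarkerRecord] = []
    n_missing = n_dup = n_frag = 0
    for r in records:
        if r.marker_id in duplicated_ids:
            n_dup += 1
            continue
        if r.status == "Missing":
            n_missing += 1
            continue
        if drop_fragmented and r.status == "Fragmented":
            n_frag += 1
            continue
        kept.append(r)
    logger.info(
        "filter_usable: kept %d lines (removed %d Missing, %d Duplicated, %d Fragmented)",
        len(kept),
        n_missing,
        n_dup,
        n_frag,
    )
    if not kept:
        raise ValueError("no usable markers after filtering")
    return kept


@dataclass(frozen=True)
class LsuEntry:
    marker_id: str
    lsu_id: str
    anchor_sequence_id: str
    anchor_start: int
    anchor_rank: int  # 1-based, contiguous within each unit


@dataclass
class LsuTable:
    """Anchor-derived mapping marker -> (unit, rank along the anchor chromosome)."""

    entries: list[LsuEntry]
    anchor_name: str = "anchor"
    lsu_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_marker = {}
        for e in self.entries:
            if e.marker_id in self._by_marker:
                raise ValueError(f"marker {e.marker_id} appears more than once")
            self._by_marker[e.marker_id] = e
        if not self.lsu_names:
            seen: dict[str, None] = {}
            for e in self.entries:
                seen.setdefault(e.lsu_id, None)
            self.lsu_names = list(seen)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, marker_id: str) -> LsuEntry | None:
        return self._by_marker.get(marker_id)

    def lsu_of_sequence(self, sequence_id: str) -> str | None:
        for e in self.entries:
            if e.anchor_sequence_id == sequence_id:
                return e.lsu_id
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.lsu_id, e.marker_id, e.anchor_sequence_id, e.anchor_start, e.anchor_rank)
                for e in self.entries
            ],
            columns=["lsu_id", "marker_id", "anchor_sequence", "anchor_start", "anchor_rank"],
        )

    def to_tsv(self) -> str:
        out = io.StringIO()
        out.write(f"# lsutools unit table\tanchor={self.anchor_name}\n")
        out.write("lsu_id\tmarker_id\tanchor_sequence\tanchor_start\tanchor_rank\n")
        for e in self.entries:
            out.write(
                f"{e.lsu_id}\t{e.marker_id}\t{e.anchor_sequence_id}\t"
                f"{e.anchor_start}\t{e.anchor_rank}\n"
            )
        return out.getvalue()

    @classmethod
    def from_tsv(cls, source) -> "LsuTable":
        anchor_name = "anchor"
        entries: list[LsuEntry] = []
        lines = _as_lines(source)
        for line in lines:
            if line.startswith("#"):
                m = re.search(r"anchor=(\S+)", line)
                if m:
                    anchor_name = m.group(1)
                continue
            if not line.strip() or line.startswith("lsu_id\t"):
                continue
            lsu_id, marker_id, seq, start, rank = line.split("\t")
            entries.append(LsuEntry(marker_id, lsu_id, seq, int(start), int(rank)))
        return cls(entries=entries, anchor_name=anchor_name)


def _sequence_sort_key(name: str):
    """Natural order for chromosome names: trailing integer, Z-named last.

    'Chr1' < 'Chr2' < ... < 'Chr30' < 'ChrZ'; names with neither a trailing
    integer nor a Z token sort alphabetically between the two groups.
    """
    is_z = bool(_Z_TOKEN.search(name)) or name.upper() == "Z"
    m = _TRAILING_INT.search(name)
    if is_z:
        return (2, 0, name)
    if m:
        return (0, int(m.group(1)), name)
    return (1, 0, name)


def _order_sequences(
    groups: dict[str, list[MarkerRecord]],
    naming_policy: str,
    lengths: SequenceLengths | None,
) -> list[str]:
    names = list(groups)
    if naming_policy == "by_sequence_suffix":
        return sorted(names, key=_sequence_sort_key)
    if naming_policy == "by_length_desc":
        if lengths is None:
            raise ValueError("naming_policy=by_length_desc requires sequence lengths")
        missing = [n for n in names if n not in lengths]
        if missing:
            raise ValueError(f"no length for sequences: {missing}")
        return sorted(names, key=lambda n: (-lengths[n], n))
    if naming_policy == "as_encountered":
        return names  # dict preserves first-appearance order
    raise ValueError(f"unknown naming_policy {naming_policy!r}")


def define_lsus(
    anchor_records: Sequence[MarkerRecord],
    naming_policy: str = "by_sequence_suffix",
    lengths: SequenceLengths | None = None,
    anchor_name: str = "anchor",
) -> LsuTable:
    """Define synteny units from a filtered anchor marker table.

    Markers are grouped by anchor sequence, sorted within each group by
    (start, end, marker_id), and ranked 1..m.  Units are named
    ``LSU_1..LSU_n`` in policy order; under ``by_sequence_suffix`` the unit
    index follows the chromosome's trailing integer and any Z-named sequence
    is placed last, so the Z unit always gets the highest index.
    """
    groups: dict[str, list[MarkerRecord]] = {}
    for r in anchor_records:
        if not r.has_position:
            raise ValueError(f"marker {r.marker_id} lacks coordinates; filter first")
        groups.setdefault(r.sequence_id, []).append(r)  # type: ignore[arg-type]
    ordered = _order_sequences(groups, naming_policy, lengths)
    if len(ordered) < 2:
        logger.warning("anchor has %d marker-bearing sequence(s)", len(ordered))
    entries: list[LsuEntry] = []
    lsu_names: list[str] = []
    for i, seq in enumerate(ordered, start=1):
        lsu_id = f"LSU_{i}"
        lsu_names.append(lsu_id)
        members = sorted(groups[seq], key=lambda r: (r.start, r.end, r.marker_id))
        for rank, r in enumerate(members, start=1):
            entries.append(
                LsuEntry(
                    marker_id=r.marker_id,
                    lsu_id=lsu_id,
                    anchor_sequence_id=seq,
                    anchor_start=r.start,  # type: ignore[arg-type]
                    anchor_rank=rank,
                )
            )
    return LsuTable(entries=entries, anchor_name=anchor_name, lsu_names=lsu_names)


@dataclass(frozen=True)
class CoverageRow:
    sequence_id: str
    size_bp: int | None
    from_pos: int
    to_pos: int
    n_markers: int


@dataclass
class CoverageSummary:
    """Per anchor chromosome: marker count and the span they cover."""

    rows: list[CoverageRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.sequence_id, r.size_bp, r.from_pos, r.to_pos, r.n_markers) for r in self.rows],
            columns=["sequence", "size_bp", "from_pos", "to_pos", "n_markers"],
        )

    def to_tsv(self) -> str:
        out = io.StringIO()
        out.write("# lsutools coverage summary\n")
        out.write("sequence\tsize_bp\tfrom_pos\tto_pos\tn_markers\n")
        for r in self.rows:
            size = "" if r.size_bp is None else str(r.size_bp)
            out.write(f"{r.sequence_id}\t{size}\t{r.from_pos}\t{r.to_pos}\t{r.n_markers}\n")
        return out.getvalue()


def coverage_summary(
    records: Sequence[MarkerRecord], lengths: SequenceLengths | None = None
) -> CoverageSummary:
    """Marker count and covered span (min start .. max end) per sequence."""
    stats: dict[str, list[int]] = {}
    for r in records:
        if not r.has_position:
            raise ValueError(f"marker {r.marker_id} lacks coordinates")
        s = stats.setdefault(r.sequence_id, [r.start, r.end, 0])  # type: ignore[list-item]
        s[0] = min(s[0], r.start)
        s[1] = max(s[1], r.end)
        s[2] += 1
    rows = [
        CoverageRow(
            sequence_id=seq,
            size_bp=lengths[seq] if lengths is not None and seq in lengths else None,
            from_pos=s[0],
            to_pos=s[1],
            n_markers=s[2],
        )
        for seq, s in sorted(stats.items(), key=lambda kv: _sequence_sort_key(kv[0]))
    ]
    return CoverageSummary(rows=rows)


@dataclass(frozen=True)
class AssignmentRow:
    marker_id: str
    lsu_id: str | None  # None = marker not in the unit table
    target_sequence_id: str
    target_start: int
    target_rank: int  # 1-based within the target sequence
    anchor_rank: int | None


@dataclass
class Assignment:
    """A target genome's markers joined to units, ordered along its chromosomes."""

    rows: list[AssignmentRow]
    target_name: str = "target"

    def assigned(self) -> list[AssignmentRow]:
        return [r for r in self.rows if r.lsu_id is not None]

    def sequences(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.target_sequence_id, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    r.target_sequence_id,
                    r.target_rank,
                    r.marker_id,
                    r.lsu_id if r.lsu_id is not None else "unassigned",
                    r.target_start,
                    r.anchor_rank,
                )
                for r in self.rows
            ],
            columns=[
                "target_sequence",
                "target_rank",
                "marker_id",
                "lsu_id",
                "target_start",
                "anchor_rank",
            ],
        )

    def to_tsv(self) -> str:
        out = io.StringIO()
        out.write(f"# lsutools assignment\ttarget={self.target_name}\n")
        out.write(
            "target_sequence\ttarget_rank\tmarker_id\tlsu_id\ttarget_start\tanchor_rank\n"
        )
        for r in self.rows:
            lsu = r.lsu_id if r.lsu_id is not None else "unassigned"
            anchor_rank = "" if r.anchor_rank is None else str(r.anchor_rank)
            out.write(
                f"{r.target_sequence_id}\t{r.target_rank}\t{r.marker_id}\t{lsu}\t"
                f"{r.target_start}\t{anchor_rank}\n"
            )
        return out.getvalue()


def assign_markers(
    target_records: Sequence[MarkerRecord],
    lsu_table: LsuTable,
    target_name: str = "target",
) -> Assignment:
    """Join target markers to anchor units by marker identity.

    Positions are never compared across genomes: the join key is the marker
    id alone.  Rows are sorted along each target sequence and given a
    contiguous 1-based target rank; markers absent from the unit table are
    kept with ``lsu_id=None`` (reported as "unassigned").
    """
    positioned = []
    for r in target_records:
        if not r.has_position:
            raise ValueError(f"marker {r.marker_id} lacks coordinates; filter first")
        positioned.append(r)
    positioned.sort(key=lambda r: (r.sequence_id, r.start, r.end, r.marker_id))
    rows: list[AssignmentRow] = []
    rank = 0
    prev_seq: str | None = None
    n_assigned = 0
    for r in positioned:
        if r.sequence_id != prev_seq:
            rank = 0
            prev_seq = r.sequence_id
        rank += 1
        entry = lsu_table.get(r.marker_id)
        if entry is not None:
            n_assigned += 1
        rows.append(
            AssignmentRow(
                marker_id=r.marker_id,
                lsu_id=entry.lsu_id if entry else None,
                target_sequence_id=r.sequence_id,  # type: ignore[arg-type]
                target_start=r.start,  # type: ignore[arg-type]
                target_rank=rank,
                anchor_rank=entry.anchor_rank if entry else None,
            )
        )
    if n_assigned == 0:
        raise ValueError(
            "no overlap between the target marker set and the unit table"
        )
    n_unassigned = len(rows) - n_assigned
    if n_unassigned:
        logger.info("assign_markers: %d marker(s) not in the unit table", n_unassigned)
    return Assignment(rows=rows, target_name=target_name)


@dataclass(frozen=True)
class ChromosomeCall:
    """Unit composition of one target chromosome."""

    sequence_id: str
    components: tuple  # ((lsu_id, count, fraction), ...) sorted by count desc
    call: str  # 'single' | 'fusion_of_k' | 'unclassified'


@dataclass(frozen=True)
class LsuCall:
    """How one unit is distributed over the target chromosomes."""

    lsu_id: str
    contributions: tuple  # ((sequence_id, count, fraction_of_recovered), ...)
    call: str  # 'intact' | 'split' | 'dispersed'


@dataclass
class CompositionReport:
    """Hit-count matrix (target sequences x units) plus composition calls."""

    matrix: pd.DataFrame
    chromosome_calls: dict[str, ChromosomeCall] = field(default_factory=dict)
    lsu_calls: dict[str, LsuCall] = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    def components_of(self, sequence_id: str) -> set[str]:
        call = self.chromosome_calls.get(sequence_id)
        if call is None:
            return set()
        return {lsu for lsu, _, _ in call.components}

    def matrix_tsv(self) -> str:
        out = io.StringIO()
        out.write("# lsutools hit-count matrix\n")
        out.write(self.matrix.to_csv(sep="\t", index_label="target_sequence"))
        return out.getvalue()

    def calls_tsv(self) -> str:
        out = io.StringIO()
        out.write("# lsutools composition calls\n")
        for key, value in sorted(self.thresholds.items()):
            out.write(f"# {key}={value}\n")
        out.write("record\tname\tcall\tcomponents\n")
        for seq, call in self.chromosome_calls.items():
            comp = ",".join(f"{l}:{c}({f:.3f})" for l, c, f in call.components)
            out.write(f"chromosome\t{seq}\t{call.call}\t{comp}\n")
        for lsu, lcall in self.lsu_calls.items():
            comp = ",".join(f"{s}:{c}({f:.3f})" for s, c, f in lcall.contributions)
            out.write(f"lsu\t{lsu}\t{lcall.call}\t{comp}\n")
        return out.getvalue()


def _lsu_sort_key(name: str):
    m = _TRAILING_INT.search(name)
    return (0, int(m.group(1)), name) if m else (1, 0, name)


def composition_matrix(assignment: Assignment) -> CompositionReport:
    """Tally assigned markers per (target sequence x unit)."""
    assigned = assignment.assigned()
    if not assigned:
        raise ValueError("assignment holds no assigned markers")
    counts: dict[str, dict[str, int]] = {}
    for r in assigned:
        row = counts.setdefault(r.target_sequence_id, {})
        row[r.lsu_id] = row.get(r.lsu_id, 0) + 1  # type: ignore[index]
    lsus = sorted({l for row in counts.values() for l in row}, key=_lsu_sort_key)
    seqs = sorted(counts, key=_sequence_sort_key)
    matrix = pd.DataFrame(0, index=seqs, columns=lsus, dtype=int)
    for seq, row in counts.items():
        for lsu, n in row.items():
            matrix.at[seq, lsu] = n
    return CompositionReport(matrix=matrix)


def classify_composition(
    report: CompositionReport,
    min_component_markers: int = 5,
    min_component_fraction: float = 0.05,
    intact_fraction: float = 0.95,
) -> CompositionReport:
    """Classify target chromosomes and units from the hit-count matrix.

    A unit is a *component* of a chromosome iff it contributes at least
    ``min_component_markers`` markers AND at least ``min_component_fraction``
    of the chromosome's assigned markers — this separates genuine fusion
    partners from small transposed fragments.  Chromosomes are then
    ``single`` (one component), ``fusion_of_k`` (k >= 2) or ``unclassified``
    (none); a unit is ``intact`` when one chromosome holds at least
    ``intact_fraction`` of its recovered markers, ``split`` when it is a
    component of two or more chromosomes, else ``dispersed``.
    """
    if min_component_markers < 1:
        raise ValueError("min_component_markers must be >= 1")
    for name, value in (
        ("min_component_fraction", min_component_fraction),
        ("intact_fraction", intact_fraction),
    ):
        if not 0 < value <= 1:
            raise ValueError(f"{name} must be in (0, 1]")

    matrix = report.matrix
    chromosome_calls: dict[str, ChromosomeCall] = {}
    component_chromosomes: dict[str, list[str]] = {l: [] for l in matrix.columns}
    for seq in matrix.index:
        row = matrix.loc[seq]
        total = int(row.sum())
        components = []
        for lsu in matrix.columns:
            n = int(row[lsu])
            if n == 0:
                continue
            frac = n / total
            if n >= min_component_markers and frac >= min_component_fraction:
                components.append((lsu, n, frac))
                component_chromosomes[lsu].append(seq)
        components.sort(key=lambda t: (-t[1], t[0]))
        k = len(components)
        call = "single" if k == 1 else (f"fusion_of_{k}" if k >= 2 else "unclassified")
        chromosome_calls[seq] = ChromosomeCall(seq, tuple(components), call)

    lsu_calls: dict[str, LsuCall] = {}
    for lsu in matrix.columns:
        col = matrix[lsu]
        recovered = int(col.sum())
        contributions = [
            (seq, int(col[seq]), int(col[seq]) / recovered)
            for seq in matrix.index
            if int(col[seq]) > 0
        ]
        contributions.sort(key=lambda t: (-t[1], t[0]))
        top_fraction = contributions[0][2] if contributions else 0.0
        if top_fraction >= intact_fraction:
            call = "intact"
        elif len(component_chromosomes[lsu]) >= 2:
            call = "split"
        else:
            call = "dispersed"
        lsu_calls[lsu] = LsuCall(lsu, tuple(contributions), call)

    return CompositionReport(
        matrix=matrix,
        chromosome_calls=chromosome_calls,
        lsu_calls=lsu_calls,
        thresholds={
            "min_component_markers": min_component_markers,
            "min_component_fraction": min_component_fraction,
            "intact_fraction": intact_fraction,
        },
    )
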