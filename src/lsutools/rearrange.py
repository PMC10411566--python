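"""Order-breakpoint counting and small-transposition detection.

Intrachromosomal rearrangements leave footprints in marker order: an
inversion leaves 2 breakpoints, a translocation 3.  Within each
(target chromosome x unit) group the shared markers are taken in target
order, re-ranked 1..m by their anchor rank restricted to that shared set,
and a breakpoint is counted at every adjacent pair whose re-ranked values
differ by more than 1 in absolute value.  The re-ranking makes the count
robust to markers missing from the target; the unsigned rule makes a whole
reversed group score zero (orientation-free counting).  Chromosome ends and
junctions between different units on a fused chromosome are never counted.

Small nonreciprocal transpositions — runs of one to a few adjacent markers
relocated onto a chromosome dominated by another unit — are detected first
and their markers removed before counting, so each such event is reported
once (as a transposition), not as extra breakpoints.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .busco_io import SequenceLengths
from .lsu_core import Assignment, AssignmentRow, CompositionReport

__all__ = [
    "TranspositionEvent",
    "TranslocatedSegment",
    "BreakpointGroup",
    "BreakpointReport",
    "detect_transpositions",
    "detect_foreign_runs",
    "count_breakpoints",
    "breakpoints_oracle",
    "per_mbp",
]


@dataclass(frozen=True)
class TranspositionEvent:
    """A run of <= max_run adjacent markers from a unit foreign to its chromosome."""

    lsu_id: str
    target_sequence_id: str
    marker_ids: tuple[str, ...]

    @property
    def run_size(self) -> int:
        return len(self.marker_ids)


@dataclass(frozen=True)
class TranslocatedSegment:
    """A foreign run longer than max_run; reported, never counted as a transposition."""

    lsu_id: str
    target_sequence_id: str
    marker_ids: tuple[str, ...]

    @property
    def run_size(self) -> int:
        return len(self.marker_ids)


def detect_foreign_runs(
    assignment: Assignment, report: CompositionReport, max_run: int = 3
) -> tuple[list[TranspositionEvent], list[TranslocatedSegment]]:
    """Scan each target chromosome for maximal runs of foreign-unit markers.

    A run is foreign when its unit is not a component of the chromosome it
    sits on (components per the composition calls).  Runs of length
    <= ``max_run`` are transposition events; longer runs are flagged as
    translocated segments.  Together the runs partition the foreign markers.
    """
    if max_run < 1:
        raise ValueError("max_run must be >= 1")
    if not report.chromosome_calls:
        raise ValueError("composition calls not computed; run classify_composition")
    events: list[TranspositionEvent] = []
    segments: list[TranslocatedSegment] = []

    by_seq: dict[str, list[AssignmentRow]] = {}
    for row in assignment.assigned():
        by_seq.setdefault(row.target_sequence_id, []).append(row)

    for seq, rows in by_seq.items():
        rows.sort(key=lambda r: r.target_rank)
        components = report.components_of(seq)
        run: list[AssignmentRow] = []

        def flush() -> None:
            if not run:
                return
            ids = tuple(r.marker_id for r in run)
            if len(run) <= max_run:
                events.append(TranspositionEvent(run[0].lsu_id, seq, ids))
            else:
                segments.append(TranslocatedSegment(run[0].lsu_id, seq, ids))
            run.clear()

        for row in rows:
            foreign = row.lsu_id not in components
            if foreign and run and run[-1].lsu_id == row.lsu_id:
                run.append(row)
            else:
                flush()
                if foreign:
                    run.append(row)
        flush()
    return events, segments


def detect_transpositions(
    assignment: Assignment, report: CompositionReport, max_run: int = 3
) -> list[TranspositionEvent]:
    """Transposition events only; see :func:`detect_foreign_runs`."""
    events, _ = detect_foreign_runs(assignment, report, max_run=max_run)
    return events


@dataclass(frozen=True)
class BreakpointGroup:
    target_sequence_id: str
    lsu_id: str
    n_shared: int
    n_breakpoints: int


@dataclass
class BreakpointReport:
    """Per-group breakpoint counts, genome totals, and per-Mbp rates."""

    groups: list[BreakpointGroup]
    breakpoints_within_lsus: int
    transpositions_single: int
    transpositions_grouped: int
    translocated_segments: int = 0
    breakpoints_per_mbp: float | None = None
    transpositions_per_mbp: float | None = None
    denominator_mbp: float | None = None
    length_provenance: str | None = None  # 'supplied' | 'inferred'
    target_name: str = "target"

    def summary_row(self) -> dict:
        return {
            "target": self.target_name,
            "breakpoints_within_lsus": self.breakpoints_within_lsus,
            "breakpoints_per_mbp": self.breakpoints_per_mbp,
            "transpositions_single": self.transpositions_single,
            "transpositions_grouped": self.transpositions_grouped,
            "transpositions_per_mbp": self.transpositions_per_mbp,
        }

    def to_tsv(self) -> str:
        out = io.StringIO()
        out.write("# lsutools breakpoint report\n")
        out.write(
            "# breakpoint rule: within each (target chromosome x unit) group, shared "
            "markers in target order are re-ranked 1..m by anchor rank; a breakpoint "
            "is an adjacent pair with |rank difference| != 1; ends and fusion "
            "junctions are not counted\n"
        )
        if self.denominator_mbp is not None:
            out.write(
                f"# rate denominator: {self.denominator_mbp:.3f} Mbp "
                f"({self.length_provenance} lengths)\n"
            )
        out.write("record\ttarget_sequence\tlsu_id\tn_shared\tn_breakpoints\n")
        for g in self.groups:
            out.write(
                f"group\t{g.target_sequence_id}\t{g.lsu_id}\t{g.n_shared}\t{g.n_breakpoints}\n"
            )
        bp_rate = "" if self.breakpoints_per_mbp is None else f"{self.breakpoints_per_mbp:.4f}"
        tr_rate = (
            "" if self.transpositions_per_mbp is None else f"{self.transpositions_per_mbp:.4f}"
        )
        out.write(
            "summary\tbreakpoints_within_lsus={}\tper_mbp={}\ttranspositions_single={}\t"
            "transpositions_grouped={}\ttranspositions_per_mbp={}\n".format(
                self.breakpoints_within_lsus,
                bp_rate,
                self.transpositions_single,
                self.transpositions_grouped,
                tr_rate,
            )
        )
        return out.getvalue()


def _count_breaks(reranked: Sequence[int]) -> int:
    return sum(
        1 for a, b in zip(reranked, reranked[1:]) if abs(b - a) != 1
    )


def count_breakpoints(
    assignment: Assignment,
    transpositions: Iterable[TranspositionEvent] = (),
    lengths: SequenceLengths | None = None,
    scope: str = "marker_bearing_sequences",
) -> BreakpointReport:
    """Count within-unit order breakpoints across a target genome.

    Markers belonging to detected transposition events are dropped first so
    each relocation is scored once as an event rather than several times as
    breakpoints.  Groups with fewer than two shared markers contribute zero.
    Rates are filled when sequence lengths are available.
    """
    transpositions = list(transpositions)
    moved = {m for ev in transpositions for m in ev.marker_ids}
    groups_rows: dict[tuple[str, str], list[AssignmentRow]] = {}
    for row in assignment.assigned():
        if row.marker_id in moved:
            continue
        groups_rows.setdefault((row.target_sequence_id, row.lsu_id), []).append(row)

    groups: list[BreakpointGroup] = []
    total = 0
    for (seq, lsu), rows in sorted(groups_rows.items()):
        rows.sort(key=lambda r: r.target_rank)
        anchor_ranks = [r.anchor_rank for r in rows]
        # re-rank within the shared set: 1..m by anchor rank
        order = {rank: i + 1 for i, rank in enumerate(sorted(anchor_ranks))}
        reranked = [order[r] for r in anchor_ranks]
        b = _count_breaks(reranked) if len(reranked) >= 2 else 0
        total += b
        groups.append(BreakpointGroup(seq, lsu, len(rows), b))

    singles = sum(1 for ev in transpositions if ev.run_size == 1)
    grouped = sum(1 for ev in transpositions if ev.run_size >= 2)

    report = BreakpointReport(
        groups=groups,
        breakpoints_within_lsus=total,
        transpositions_single=singles,
        transpositions_grouped=grouped,
        target_name=assignment.target_name,
    )
    if lengths is not None:
        marker_sequences = {r.target_sequence_id for r in assignment.rows}
        sequences = marker_sequences if scope == "marker_bearing_sequences" else None
        report.breakpoints_per_mbp = per_mbp(total, lengths, sequences=sequences)
        report.transpositions_per_mbp = per_mbp(
            singles + grouped, lengths, sequences=sequences
        )
        report.denominator_mbp = lengths.total_bp(sequences) / 1e6
        report.length_provenance = "inferred" if lengths.inferred else "supplied"
    return report


def breakpoints_oracle(ranks: Sequence[int]) -> int:
    """Brute-force breakpoint count on a permutation of 1..m.

    Direct enumeration of adjacent pairs with absolute difference != 1;
    independent of the grouped pipeline counter and used to cross-check it.
    """
    m = len(ranks)
    if sorted(ranks) != list(range(1, m + 1)):
        raise ValueError("ranks must be a permutation of 1..m")
    return sum(1 for i in range(m - 1) if abs(ranks[i + 1] - ranks[i]) != 1)


def per_mbp(
    count: int,
    lengths: SequenceLengths,
    scope: str = "marker_bearing_sequences",
    sequences: Iterable[str] | None = None,
) -> float:
    """Convert an event count to a per-Mbp rate.

    ``sequences`` restricts the denominator (e.g. to marker-bearing
    sequences); with ``scope='all_sequences'`` or ``sequences=None`` every
    known sequence counts.
    """
    if scope == "all_sequences":
        sequences = None
    total_bp = lengths.total_bp(sequences)
    if total_bp <= 0:
        raise ValueError("zero-length denominator for per-Mbp rate")
    return count / (total_bp / 1e6)
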