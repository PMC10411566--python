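"""Seeded karyotype-rearrangement simulator with analytic ground truth.

Generates a synthetic anchor genome as a BUSCO-style marker table (by
default 31 chromosomes of ~170 evenly spaced markers over ~17 Mbp each,
the scale of a chromosome-level lepidopteran assembly scored with a
~5,000-marker lineage set), then applies an explicit, ordered list of
rearrangement events — fusions, fissions, inversions, small
transpositions, marker losses and duplications — and emits the rearranged
descendant as a second full table.

For event lists that are *non-overlapping* (each chromosome plays a single
role, inversions are internal and mutually separated, transposed runs are
small and land between native markers) the simulator also computes the
analytic signature the detection pipeline must recover: two order
breakpoints per inversion, one transposition event per relocated run,
``fusion_of_k`` / ``split`` composition calls per fusion / fission.  The
signature assumes the pipeline's documented default thresholds.  Event
lists violating the non-overlap conditions are still applied faithfully,
but no signature is claimed.

All randomness flows from a single integer seed; identical seeds produce
byte-identical tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence, Union

import numpy as np

from .busco_io import MarkerRecord, SequenceLengths, write_full_table

__all__ = [
    "AnchorSpec",
    "Fusion",
    "Fission",
    "Inversion",
    "Transposition",
    "Loss",
    "Duplication",
    "EventSpec",
    "ExpectedSignature",
    "SimulationTruth",
    "SimulationError",
    "make_anchor",
    "apply_events",
    "random_events",
    "sequence_lengths_for",
]

MARKER_SPACING = 100_000  # bp between consecutive markers on emitted chromosomes

# thresholds the analytic signature assumes (the pipeline defaults)
MIN_COMPONENT_MARKERS = 5
MIN_COMPONENT_FRACTION = 0.05
INTACT_FRACTION = 0.95
MAX_RUN = 3


class SimulationError(ValueError):
    pass


@dataclass
class AnchorSpec:
    """Shape of the synthetic anchor genome."""

    n_chromosomes: int = 31
    markers_per_chromosome: Union[int, Sequence[int]] = 170
    chromosome_length: Union[int, Sequence[int]] = 17_000_000
    jitter: float = 0.3  # fraction of the inter-marker spacing used as noise
    seed: int = 0
    z_last: bool = True  # name the last chromosome ChrZ, as in moth karyotypes

    def per_chromosome(self, value, what: str) -> list[int]:
        if isinstance(value, int):
            return [value] * self.n_chromosomes
        out = list(value)
        if len(out) != self.n_chromosomes:
            raise SimulationError(f"{what}: need {self.n_chromosomes} values, got {len(out)}")
        return out

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise SimulationError("n_chromosomes must be >= 1")
        markers = self.per_chromosome(self.markers_per_chromosome, "markers_per_chromosome")
        lengths = self.per_chromosome(self.chromosome_length, "chromosome_length")
        for m, L in zip(markers, lengths):
            if m < 1:
                raise SimulationError("markers_per_chromosome must be >= 1")
            if L <= m:
                raise SimulationError("chromosome_length must exceed marker count")
        if not 0 <= self.jitter < 1:
            raise SimulationError("jitter must be in [0, 1)")

    def chromosome_names(self) -> list[str]:
        names = [f"Chr{i}" for i in range(1, self.n_chromosomes + 1)]
        if self.z_last and self.n_chromosomes >= 2:
            names[-1] = "ChrZ"
        return names


def _place_markers(rng, n: int, length: int, jitter: float):
    """Strictly increasing (start, end) pairs, evenly spaced with noise."""
    spacing = length / (n + 1)
    max_gene = max(200, int(0.08 * spacing))
    positions = []
    for i in range(n):
        base = (i + 1) * spacing
        off = rng.uniform(-jitter, jitter) * spacing * 0.45
        start = max(1, int(round(base + off)))
        gene_len = int(rng.integers(100, max_gene + 1))
        positions.append((start, start + gene_len))
    # jitter bounds guarantee monotonicity, but enforce it defensively
    for i in range(1, n):
        if positions[i][0] <= positions[i - 1][1]:
            s = positions[i - 1][1] + 1
            positions[i] = (s, s + (positions[i][1] - positions[i][0]))
    return positions


def make_anchor(spec: AnchorSpec) -> list[MarkerRecord]:
    """Generate the anchor genome's full table: all markers Complete."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    markers = spec.per_chromosome(spec.markers_per_chromosome, "markers_per_chromosome")
    lengths = spec.per_chromosome(spec.chromosome_length, "chromosome_length")
    records: list[MarkerRecord] = []
    k = 0
    for name, m, L in zip(spec.chromosome_names(), markers, lengths):
        for start, end in _place_markers(rng, m, L, spec.jitter):
            k += 1
            records.append(
                MarkerRecord(
                    marker_id=f"SYNT{k:05d}at0000",
                    status="Complete",
                    sequence_id=name,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    score=float(round(rng.uniform(200, 2000), 1)),
                    length=end - start,
                )
            )
    return records


# --- events ---------------------------------------------------------------


@dataclass(frozen=True)
class Fusion:
    chrom_a: str
    chrom_b: str


@dataclass(frozen=True)
class Fission:
    chrom: str
    at_index: int  # markers [0:at] -> first product, [at:] -> second


@dataclass(frozen=True)
class Inversion:
    chrom: str
    start: int  # 0-based inclusive marker indices
    end: int


@dataclass(frozen=True)
class Transposition:
    chrom_src: str
    run_start: int
    run_size: int
    chrom_dst: str
    insert_at: int  # index in the destination, after the run is excised


@dataclass(frozen=True)
class Loss:
    fraction: float | None = None
    marker_ids: tuple[str, ...] | None = None
    safe_interior: bool = True  # restrict to markers strictly inside collinear runs


@dataclass(frozen=True)
class Duplication:
    fraction: float | None = None
    marker_ids: tuple[str, ...] | None = None
    safe_interior: bool = True


Event = Union[Fusion, Fission, Inversion, Transposition, Loss, Duplication]


@dataclass
class EventSpec:
    events: list = field(default_factory=list)
    seed: int = 0


@dataclass
class ExpectedSignature:
    """Analytic pipeline outcome for a non-overlapping event list."""

    breakpoints_total: int
    transpositions_single: int
    transpositions_grouped: int
    transposition_sizes: list[int]
    chromosome_classes: dict[str, str]  # final chromosome name -> call
    lsu_classes: dict[str, str]  # anchor chromosome name -> call


@dataclass
class SimulationTruth:
    """Resolved event log plus, when claimable, the analytic signature."""

    events: list[dict]
    expected: ExpectedSignature | None
    seed: int

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "events": self.events,
            "expected": asdict(self.expected) if self.expected is not None else None,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


class _State:
    """Mutable genome layout: ordered chromosomes of ordered marker ids."""

    def __init__(self, records: Sequence[MarkerRecord]):
        self.chroms: dict[str, list[str]] = {}
        self.strand: dict[str, str] = {}
        self.status: dict[str, str] = {}
        self.origin: dict[str, tuple[str, int]] = {}
        self.lost: set[str] = set()
        self.duplicated: set[str] = set()
        self.moved: set[str] = set()
        self.extra_records: list[MarkerRecord] = []  # pass-through non-positioned
        by_chrom: dict[str, list[MarkerRecord]] = {}
        for r in records:
            if not r.has_position:
                self.extra_records.append(r)
                continue
            by_chrom.setdefault(r.sequence_id, []).append(r)  # type: ignore[arg-type]
        for name, rs in by_chrom.items():
            rs.sort(key=lambda r: (r.start, r.end, r.marker_id))
            self.chroms[name] = [r.marker_id for r in rs]
            for i, r in enumerate(rs):
                self.strand[r.marker_id] = r.strand
                self.status[r.marker_id] = r.status
                self.origin[r.marker_id] = (name, i)

    def require(self, chrom: str, what: str) -> list[str]:
        if chrom not in self.chroms:
            raise SimulationError(f"{what}: unknown chromosome {chrom!r}")
        return self.chroms[chrom]

    def all_marker_ids(self) -> list[str]:
        return [m for ms in self.chroms.values() for m in ms]

    def interior_collinear(self) -> list[str]:
        """Markers whose removal provably leaves breakpoint counts unchanged.

        Both neighbours on the current chromosome come from the same anchor
        chromosome and have anchor indices consecutive with the marker's —
        i.e. the marker sits strictly inside a collinear (or inverted-
        collinear) run.  Markers relocated by transpositions are excluded so
        event sizes stay exact.
        """
        out = []
        for markers in self.chroms.values():
            for i in range(1, len(markers) - 1):
                a, x, b = markers[i - 1], markers[i], markers[i + 1]
                if x in self.moved or x in self.lost or x in self.duplicated:
                    continue
                ca, ia = self.origin[a]
                cx, ix = self.origin[x]
                cb, ib = self.origin[b]
                if ca == cx == cb and abs(ix - ia) == 1 and abs(ib - ix) == 1:
                    out.append(x)
        return out


def _flip(strand: str) -> str:
    return {"+": "-", "-": "+"}.get(strand, strand)


def _apply_one(state: _State, ev: Event, rng, idx: int) -> dict:
    tag = f"event {idx} ({type(ev).__name__})"
    if isinstance(ev, Fusion):
        a = state.require(ev.chrom_a, tag)
        b = state.require(ev.chrom_b, tag)
        if ev.chrom_a == ev.chrom_b:
            raise SimulationError(f"{tag}: cannot fuse a chromosome with itself")
        name = f"{ev.chrom_a}+{ev.chrom_b}"
        merged = a + b
        new = {}
        for key, value in state.chroms.items():
            if key == ev.chrom_a:
                new[name] = merged
            elif key != ev.chrom_b:
                new[key] = value
        state.chroms = new
        return {"type": "fusion", "chrom_a": ev.chrom_a, "chrom_b": ev.chrom_b,
                "product": name, "n_markers": len(merged)}
    if isinstance(ev, Fission):
        ms = state.require(ev.chrom, tag)
        if not 1 <= ev.at_index <= len(ms) - 1:
            raise SimulationError(f"{tag}: at_index {ev.at_index} out of range 1..{len(ms)-1}")
        left, right = ms[: ev.at_index], ms[ev.at_index :]
        n1, n2 = f"{ev.chrom}.1", f"{ev.chrom}.2"
        new = {}
        for key, value in state.chroms.items():
            if key == ev.chrom:
                new[n1], new[n2] = left, right
            else:
                new[key] = value
        state.chroms = new
        return {"type": "fission", "chrom": ev.chrom, "at_index": ev.at_index,
                "products": [n1, n2], "sizes": [len(left), len(right)]}
    if isinstance(ev, Inversion):
        ms = state.require(ev.chrom, tag)
        if not 0 <= ev.start <= ev.end < len(ms):
            raise SimulationError(f"{tag}: segment {ev.start}..{ev.end} out of range")
        seg = ms[ev.start : ev.end + 1]
        ms[ev.start : ev.end + 1] = seg[::-1]
        for m in seg:
            state.strand[m] = _flip(state.strand[m])
        return {"type": "inversion", "chrom": ev.chrom, "start": ev.start,
                "end": ev.end, "marker_ids": seg}
    if isinstance(ev, Transposition):
        src = state.require(ev.chrom_src, tag)
        if ev.run_size < 1:
            raise SimulationError(f"{tag}: run_size must be >= 1")
        if not 0 <= ev.run_start <= len(src) - ev.run_size:
            raise SimulationError(f"{tag}: run {ev.run_start}+{ev.run_size} out of range")
        run = src[ev.run_start : ev.run_start + ev.run_size]
        del src[ev.run_start : ev.run_start + ev.run_size]
        dst = state.require(ev.chrom_dst, tag)
        if not 0 <= ev.insert_at <= len(dst):
            raise SimulationError(f"{tag}: insert_at {ev.insert_at} out of range")
        dst[ev.insert_at : ev.insert_at] = run
        state.moved.update(run)
        return {"type": "transposition", "chrom_src": ev.chrom_src,
                "chrom_dst": ev.chrom_dst, "run_size": ev.run_size,
                "marker_ids": run}
    if isinstance(ev, (Loss, Duplication)):
        kind = "loss" if isinstance(ev, Loss) else "duplication"
        if ev.marker_ids is not None:
            ids = list(ev.marker_ids)
            missing = [m for m in ids if m not in state.origin]
            if missing:
                raise SimulationError(f"{tag}: unknown markers {missing}")
        else:
            if ev.fraction is None or not 0 <= ev.fraction < 1:
                raise SimulationError(f"{tag}: need marker_ids or fraction in [0,1)")
            pool = (
                state.interior_collinear()
                if ev.safe_interior
                else [m for m in state.all_marker_ids() if m not in state.moved]
            )
            n = min(int(ev.fraction * len(state.all_marker_ids())), len(pool))
            ids = [pool[i] for i in sorted(rng.choice(len(pool), size=n, replace=False))]
        if kind == "loss":
            for m in ids:
                state.lost.add(m)
            for markers in state.chroms.values():
                markers[:] = [m for m in markers if m not in state.lost]
            return {"type": "loss", "marker_ids": ids}
        for m in ids:
            state.duplicated.add(m)
            names = list(state.chroms)
            dst = names[int(rng.integers(0, len(names)))]
            pos = int(rng.integers(0, len(state.chroms[dst]) + 1))
            state.chroms[dst].insert(pos, m)
        return {"type": "duplication", "marker_ids": ids}
    raise SimulationError(f"{tag}: unsupported event type")


def _emit_records(state: _State, rng) -> list[MarkerRecord]:
    records: list[MarkerRecord] = []
    emitted: set[str] = set()
    for name, markers in state.chroms.items():
        length = (len(markers) + 1) * MARKER_SPACING
        for m, (start, end) in zip(markers, _place_markers(rng, len(markers), length, 0.3)):
            status = "Duplicated" if m in state.duplicated else state.status.get(m, "Complete")
            records.append(
                MarkerRecord(
                    marker_id=m,
                    status=status,
                    sequence_id=name,
                    start=start,
                    end=end,
                    strand=state.strand.get(m, "unknown"),
                    score=float(round(rng.uniform(200, 2000), 1)),
                    length=end - start,
                )
            )
            emitted.add(m)
    for m in sorted(state.lost):
        records.append(MarkerRecord(marker_id=m, status="Missing"))
    records.extend(state.extra_records)
    return records


def sequence_lengths_for(records: Sequence[MarkerRecord]) -> SequenceLengths:
    """Nominal emitted chromosome lengths ((m+1) x marker spacing), supplied-grade."""
    counts: dict[str, int] = {}
    for r in records:
        if r.has_position:
            counts[r.sequence_id] = counts.get(r.sequence_id, 0) + 1  # type: ignore[index]
    return SequenceLengths(
        lengths={name: (n + 1) * MARKER_SPACING for name, n in counts.items()},
        inferred=False,
    )


def _verify_non_overlapping(state0: _State, events: Sequence[Event]) -> bool:
    """Check the conditions under which the analytic signature is exact."""
    roles: dict[str, str] = {}
    inversions_by_chrom: dict[str, list[Inversion]] = {}

    def claim(chrom: str, role: str) -> bool:
        if roles.get(chrom, role) != role:
            return False
        if role != "inversion" and chrom in roles:
            return False
        roles[chrom] = role
        return True

    sizes = {name: len(ms) for name, ms in state0.chroms.items()}
    for ev in events:
        if isinstance(ev, Fusion):
            if ev.chrom_a not in sizes or ev.chrom_b not in sizes:
                return False
            if not (claim(ev.chrom_a, "fusion") and claim(ev.chrom_b, "fusion")):
                return False
        elif isinstance(ev, Fission):
            m = sizes.get(ev.chrom)
            if m is None or not claim(ev.chrom, "fission"):
                return False
            margin = max(MIN_COMPONENT_MARKERS, math.floor(MIN_COMPONENT_FRACTION * m) + 1)
            if not margin <= ev.at_index <= m - margin:
                return False
        elif isinstance(ev, Inversion):
            m = sizes.get(ev.chrom)
            if m is None or roles.get(ev.chrom, "inversion") != "inversion":
                return False
            roles[ev.chrom] = "inversion"
            # internal, length >= 2
            if not (1 <= ev.start < ev.end <= m - 2):
                return False
            inversions_by_chrom.setdefault(ev.chrom, []).append(ev)
        elif isinstance(ev, Transposition):
            m_src = sizes.get(ev.chrom_src)
            m_dst = sizes.get(ev.chrom_dst)
            if m_src is None or m_dst is None or ev.chrom_src == ev.chrom_dst:
                return False
            if not (claim(ev.chrom_src, "transposition_src")
                    and claim(ev.chrom_dst, "transposition_dst")):
                return False
            if ev.run_size > MAX_RUN or ev.run_size > math.floor(
                (1 - INTACT_FRACTION) * 0.8 * m_src
            ):
                return False
            if not (1 <= ev.run_start <= m_src - ev.run_size - 1):
                return False
            if not (1 <= ev.insert_at <= m_dst - 1):
                return False
        elif isinstance(ev, (Loss, Duplication)):
            if ev.marker_ids is not None or not ev.safe_interior:
                return False
            # interior-safe fractional loss/duplication is signature-preserving
            # only when no fission margin could be eroded below threshold
            if any(isinstance(e, Fission) for e in events) and (ev.fraction or 0) > 0:
                return False
        else:
            return False
    for chrom, invs in inversions_by_chrom.items():
        ordered = sorted(invs, key=lambda e: e.start)
        for prev, nxt in zip(ordered, ordered[1:]):
            if nxt.start <= prev.end + 1:  # need >= 1 untouched marker between
                return False
    return True


def _signature(state0: _State, events: Sequence[Event]) -> ExpectedSignature:
    chromosome_classes = {name: "single" for name in state0.chroms}
    lsu_classes = {name: "intact" for name in state0.chroms}
    n_inv = 0
    sizes: list[int] = []
    for ev in events:
        if isinstance(ev, Fusion):
            del chromosome_classes[ev.chrom_a]
            del chromosome_classes[ev.chrom_b]
            chromosome_classes[f"{ev.chrom_a}+{ev.chrom_b}"] = "fusion_of_2"
        elif isinstance(ev, Fission):
            del chromosome_classes[ev.chrom]
            chromosome_classes[f"{ev.chrom}.1"] = "single"
            chromosome_classes[f"{ev.chrom}.2"] = "single"
            lsu_classes[ev.chrom] = "split"
        elif isinstance(ev, Inversion):
            n_inv += 1
        elif isinstance(ev, Transposition):
            sizes.append(ev.run_size)
    return ExpectedSignature(
        breakpoints_total=2 * n_inv,
        transpositions_single=sum(1 for s in sizes if s == 1),
        transpositions_grouped=sum(1 for s in sizes if s >= 2),
        transposition_sizes=sorted(sizes),
        chromosome_classes=chromosome_classes,
        lsu_classes=lsu_classes,
    )


def apply_events(
    anchor: Sequence[MarkerRecord], events: EventSpec
) -> tuple[list[MarkerRecord], SimulationTruth]:
    """Apply events in list order and emit the rearranged descendant.

    Coordinates are recomputed per chromosome so marker order is the layout
    order; lost markers become Missing lines, duplicated markers Duplicated
    lines.  The truth log records every resolved event; the analytic
    expected signature is included only when the event list passes the
    non-overlap verification.
    """
    state = _State(anchor)
    non_overlapping = _verify_non_overlapping(state, events.events)
    expected = _signature(_State(anchor), events.events) if non_overlapping else None
    rng = np.random.default_rng(events.seed)
    resolved = [
        _apply_one(state, ev, rng, i) for i, ev in enumerate(events.events)
    ]
    target = _emit_records(state, rng)
    return target, SimulationTruth(events=resolved, expected=expected, seed=events.seed)


def random_events(
    anchor: Sequence[MarkerRecord],
    *,
    n_fusions: int = 0,
    n_fissions: int = 0,
    n_inversions: int = 0,
    n_transpositions: int = 0,
    run_sizes: Sequence[int] = (1, 2, 3),
    loss_fraction: float = 0.0,
    seed: int = 0,
) -> EventSpec:
    """Draw a valid, by-construction non-overlapping event list.

    Event counts per type (rather than continuous rates) keep rejection-free
    sampling exact: each chromosome is given at most one role, inversion
    segments are internal, fission cut points respect the component
    thresholds, and transposed runs are small enough that source units stay
    intact.  Deterministic given the seed.
    """
    for name, n in (
        ("n_fusions", n_fusions),
        ("n_fissions", n_fissions),
        ("n_inversions", n_inversions),
        ("n_transpositions", n_transpositions),
    ):
        if n < 0:
            raise SimulationError(f"{name} must be >= 0")
    if any(s < 1 or s > MAX_RUN for s in run_sizes):
        raise SimulationError(f"run sizes must be within 1..{MAX_RUN}")
    state = _State(anchor)
    sizes = {name: len(ms) for name, ms in state.chroms.items()}
    usable = [name for name, m in sizes.items() if m >= 12]
    need = 2 * n_fusions + n_fissions + n_inversions + 2 * n_transpositions
    if need > len(usable):
        raise SimulationError(
            f"cannot place events: {need} chromosome roles needed, "
            f"{len(usable)} usable chromosomes"
        )
    rng = np.random.default_rng(seed)
    order = [usable[i] for i in rng.permutation(len(usable))]
    events: list[Event] = []
    for _ in range(n_fusions):
        a, b = order.pop(), order.pop()
        events.append(Fusion(a, b))
    for _ in range(n_fissions):
        c = order.pop()
        m = sizes[c]
        margin = max(MIN_COMPONENT_MARKERS, math.floor(MIN_COMPONENT_FRACTION * m) + 1)
        at = int(rng.integers(margin, m - margin + 1))
        events.append(Fission(c, at))
    for _ in range(n_inversions):
        c = order.pop()
        m = sizes[c]
        start = int(rng.integers(1, m - 3))
        max_len = min(10, (m - 2) - start + 1)
        length = int(rng.integers(2, max_len + 1))
        events.append(Inversion(c, start, start + length - 1))
    for _ in range(n_transpositions):
        src, dst = order.pop(), order.pop()
        m_src, m_dst = sizes[src], sizes[dst]
        cap = min(MAX_RUN, math.floor((1 - INTACT_FRACTION) * 0.8 * m_src))
        allowed = [s for s in run_sizes if s <= cap]
        if not allowed:
            raise SimulationError(f"no run size fits source chromosome {src} (m={m_src})")
        size = int(allowed[int(rng.integers(0, len(allowed)))])
        start = int(rng.integers(1, m_src - size))
        insert_at = int(rng.integers(1, m_dst))
        events.append(Transposition(src, start, size, dst, insert_at))
    if loss_fraction > 0:
        events.append(Loss(fraction=loss_fraction, safe_interior=True))
    return EventSpec(events=events, seed=seed)
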