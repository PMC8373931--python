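"""Compile structural rearrangements into segment maps and lift coordinates.

A rearrangement (inversions, deletions, duplications on disjoint wild-type
intervals) is compiled into a :class:`SegmentMap`: an ordered list of colinear
blocks whose mutant intervals tile ``[0, mut_length)``. The map is the single
source of truth for building the mutant sequence, lifting positions and
features between the two coordinate systems, and exporting UCSC chain files.

Internal coordinates are 0-based half-open. Specs written in the 1-based
inclusive style used in publications ("chr2: 74477755-75441001") are converted
on input via the ``convention`` tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio.Seq import Seq

Direction = Literal["wt_to_mut", "mut_to_wt"]

__all__ = [
    "Inversion",
    "Deletion",
    "Duplication",
    "RearrangementSpec",
    "spec_from_dict",
    "Block",
    "SegmentMap",
    "compile_rearrangement",
    "build_mutant_sequence",
    "lift_position",
    "lift_interval",
    "lift_features",
    "write_chain",
    "parse_chain",
]


@dataclass(frozen=True)
class Inversion:
    start: int
    end: int


@dataclass(frozen=True)
class Deletion:
    start: int
    end: int


@dataclass(frozen=True)
class Duplication:
    """Duplication of ``[start, end)``; extra copy inserted after ``insert_after``.

    ``insert_after`` is a wild-type coordinate marking the junction the new copy
    is inserted at (``insert_after == end`` gives a tandem duplication). It must
    not fall strictly inside any rearranged interval.
    """

    start: int
    end: int
    insert_after: int | None = None
    inverted: bool = False


Operation = Inversion | Deletion | Duplication


@dataclass
class RearrangementSpec:
    """Ordered structural operations on one chromosome.

    ``convention`` is the coordinate style of the operation coordinates:
    ``"0based"`` (half-open, internal) or ``"1based"`` (inclusive, publication
    style, converted on compile).
    """

    chrom: str
    operations: list[Operation] = field(default_factory=list)
    convention: Literal["0based", "1based"] = "0based"

    def to_internal(self) -> "RearrangementSpec":
        if self.convention == "0based":
            return self
        ops: list[Operation] = []
        for op in self.operations:
            if isinstance(op, Inversion):
                ops.append(Inversion(op.start - 1, op.end))
            elif isinstance(op, Deletion):
                ops.append(Deletion(op.start - 1, op.end))
            else:
                ins = op.insert_after if op.insert_after is not None else op.end
                ops.append(Duplication(op.start - 1, op.end, ins, op.inverted))
        return RearrangementSpec(self.chrom, ops, "0based")


@dataclass(frozen=True)
class Block:
    """Colinear correspondence between one wild-type and one mutant interval."""

    wt_start: int
    wt_end: int
    mut_start: int
    mut_end: int
    flipped: bool

    def __post_init__(self) -> None:
        if (self.wt_end - self.wt_start) != (self.mut_end - self.mut_start):
            raise ValueError("block length mismatch between axes")


@dataclass
class SegmentMap:
    """Block-wise wild-type <-> mutant correspondence with orientation."""

    chrom: str
    wt_length: int
    mut_length: int
    blocks: list[Block]
    deletions: list[tuple[int, int]] = field(default_factory=list)
    duplications: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.blocks = sorted(self.blocks, key=lambda b: b.mut_start)
        pos = 0
        for b in self.blocks:
            if b.mut_start != pos:
                raise ValueError("mutant blocks must tile [0, mut_length) without gaps")
            pos = b.mut_end
        if pos != self.mut_length:
            raise ValueError("blocks do not cover the mutant axis")
        expected = (
            self.wt_length
            - sum(e - s for s, e in self.deletions)
            + sum(e - s for s, e in self.duplications)
        )
        if expected != self.mut_length:
            raise ValueError("mutant length inconsistent with deletions/duplications")

    @property
    def is_bijective(self) -> bool:
        return not self.deletions and not self.duplications

    def inverse(self) -> "SegmentMap":
        """Swap the two axes. Only defined for bijective (no del/dup) maps."""
        if not self.is_bijective:
            raise ValueError("inverse is only defined for maps without deletions or duplications")
        blocks = [
            Block(b.mut_start, b.mut_end, b.wt_start, b.wt_end, b.flipped)
            for b in self.blocks
        ]
        return SegmentMap(self.chrom, self.mut_length, self.wt_length, blocks)


def spec_from_dict(d: dict) -> RearrangementSpec:
    """Build a spec from a JSON-style dict with an ``operations`` list of
    ``{"type": "inversion"|"deletion"|"duplication", ...}`` records."""
    ops: list[Operation] = []
    for rec in d.get("operations", []):
        kind = rec["type"]
        if kind == "inversion":
            ops.append(Inversion(rec["start"], rec["end"]))
        elif kind == "deletion":
            ops.append(Deletion(rec["start"], rec["end"]))
        elif kind == "duplication":
            ops.append(
                Duplication(
                    rec["start"], rec["end"], rec.get("insert_after"), rec.get("inverted", False)
                )
            )
        else:
            raise ValueError(f"unknown operation type {kind!r}")
    return RearrangementSpec(d["chrom"], ops, d.get("convention", "0based"))


def _validate_ops(ops: Sequence[Operation], chrom_length: int) -> list[Operation]:
    ops = sorted(ops, key=lambda o: o.start)
    prev_end = 0
    for op in ops:
        if not (0 <= op.start < op.end <= chrom_length):
            raise ValueError(f"operation out of bounds: {op}")
        if op.start < prev_end:
            raise ValueError(f"overlapping operations at {op}")
        prev_end = op.end
    for op in ops:
        if isinstance(op, Duplication):
            ins = op.insert_after if op.insert_after is not None else op.end
            if not (0 <= ins <= chrom_length):
                raise ValueError(f"insert_after out of bounds: {op}")
            for other in ops:
                if other is op:
                    continue
                if other.start < ins < other.end:
                    raise ValueError(
                        "duplication insertion point inside another rearranged interval"
                    )
    return ops


def compile_rearrangement(spec: RearrangementSpec, chrom_length: int) -> SegmentMap:
    """Compile a rearrangement spec into a :class:`SegmentMap`.

    Operations must be disjoint on the wild-type axis (nested/overlapping
    rearrangements are rejected). A pure inversion preserves length.
    """
    spec = spec.to_internal()
    ops = _validate_ops(spec.operations, chrom_length)

    # Emission plan: (wt_start, wt_end, flipped) segments in mutant order.
    plan: list[tuple[int, int, bool]] = []
    deletions: list[tuple[int, int]] = []
    duplications: list[tuple[int, int]] = []
    cur = 0
    for op in ops:
        if cur < op.start:
            plan.append((cur, op.start, False))
        if isinstance(op, Inversion):
            plan.append((op.start, op.end, True))
        elif isinstance(op, Deletion):
            deletions.append((op.start, op.end))
        else:  # Duplication: original copy stays in place
            plan.append((op.start, op.end, False))
            duplications.append((op.start, op.end))
        cur = op.end
    if cur < chrom_length:
        plan.append((cur, chrom_length, False))

    # Insert duplicate copies at their junction points.
    for op in ops:
        if not isinstance(op, Duplication):
            continue
        ins = op.insert_after if op.insert_after is not None else op.end
        dup_seg = (op.start, op.end, op.inverted)
        placed = False
        for idx, (s, e, flip) in enumerate(plan):
            if s < ins < e:
                if flip:
                    raise ValueError("insertion point inside an inverted segment")
                plan[idx : idx + 1] = [(s, ins, False), dup_seg, (ins, e, False)]
                placed = True
                break
            if e == ins and not (s, e, flip) == dup_seg:
                plan.insert(idx + 1, dup_seg)
                placed = True
                break
        if not placed:
            if ins == 0:
                plan.insert(0, dup_seg)
            else:
                # junction falls inside a deleted interval or after the original copy
                for idx, (s, e, flip) in enumerate(plan):
                    if e <= ins:
                        continue
                    plan.insert(idx, dup_seg)
                    placed = True
                    break
                if not placed:
                    plan.append(dup_seg)

    # Merge mutually colinear neighbours so each block is a maximal run.
    merged: list[tuple[int, int, bool]] = []
    seen_once: set[tuple[int, int]] = set()
    for seg in plan:
        if merged:
            ps, pe, pf = merged[-1]
            s, e, f = seg
            if not pf and not f and pe == s and (ps, pe) not in seen_once:
                # only merge when neither side is a duplicate copy boundary
                is_dup = any(ds <= s < de for ds, de in duplications) or any(
                    ds < e <= de for ds, de in duplications
                )
                if not is_dup:
                    merged[-1] = (ps, e, False)
                    continue
        merged.append(seg)

    blocks: list[Block] = []
    mut = 0
    for s, e, flip in merged:
        blocks.append(Block(s, e, mut, mut + (e - s), flip))
        mut += e - s
    return SegmentMap(spec.chrom, chrom_length, mut, blocks, deletions, duplications)


_COMPL = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def build_mutant_sequence(wt_sequence: str, segmap: SegmentMap) -> str:
    """Assemble the mutant sequence from wild-type sequence and a segment map.

    Same-orientation blocks copy the wild-type substring; flipped blocks take
    the reverse complement.
    """
    if len(wt_sequence) != segmap.wt_length:
        raise ValueError(
            f"sequence length {len(wt_sequence)} != map wild-type length {segmap.wt_length}"
        )
    parts: list[str] = []
    for b in segmap.blocks:
        sub = wt_sequence[b.wt_start : b.wt_end]
        parts.append(str(Seq(sub).reverse_complement()) if b.flipped else sub)
    out = "".join(parts)
    assert len(out) == segmap.mut_length
    return out


def lift_position(
    segmap: SegmentMap, position: int, direction: Direction = "wt_to_mut"
) -> list[tuple[int, str]]:
    """Lift a single position between axes.

    Returns ``[(position, orientation), ...]`` with orientation ``"same"`` or
    ``"flipped"``. Deleted wild-type positions yield an empty list; positions
    inside duplications yield one hit per copy (sorted by target position).
    """
    if direction == "wt_to_mut":
        if not 0 <= position < segmap.wt_length:
            raise ValueError(f"position {position} outside wild-type axis")
        hits = []
        for b in segmap.blocks:
            if b.wt_start <= position < b.wt_end:
                if b.flipped:
                    hits.append((b.mut_start + (b.wt_end - 1 - position), "flipped"))
                else:
                    hits.append((b.mut_start + (position - b.wt_start), "same"))
        return sorted(hits)
    if not 0 <= position < segmap.mut_length:
        raise ValueError(f"position {position} outside mutant axis")
    for b in segmap.blocks:
        if b.mut_start <= position < b.mut_end:
            if b.flipped:
                return [(b.wt_end - 1 - (position - b.mut_start), "flipped")]
            return [(b.wt_start + (position - b.mut_start), "same")]
    raise AssertionError("mutant axis tiling violated")


def lift_interval(
    segmap: SegmentMap, start: int, end: int, direction: Direction = "wt_to_mut"
) -> list[tuple[int, int, bool]]:
    """Lift ``[start, end)``; returns ``(start, end, flipped)`` pieces, one per
    overlapped block (several pieces for junction-spanning or duplicated input)."""
    if start >= end:
        raise ValueError("empty interval")
    pieces = []
    for b in segmap.blocks:
        if direction == "wt_to_mut":
            src = (b.wt_start, b.wt_end)
        else:
            src = (b.mut_start, b.mut_end)
        lo, hi = max(start, src[0]), min(end, src[1])
        if lo >= hi:
            continue
        if direction == "wt_to_mut":
            if b.flipped:
                pieces.append((b.mut_start + (b.wt_end - hi), b.mut_start + (b.wt_end - lo), True))
            else:
                pieces.append((b.mut_start + (lo - b.wt_start), b.mut_start + (hi - b.wt_start), False))
        else:
            if b.flipped:
                pieces.append((b.wt_end - (hi - b.mut_start), b.wt_end - (lo - b.mut_start), True))
            else:
                pieces.append((b.wt_start + (lo - b.mut_start), b.wt_start + (hi - b.mut_start), False))
    return sorted(pieces)


_FLIP_STRAND = {"+": "-", "-": "+", ".": "."}


def lift_features(
    segmap: SegmentMap,
    features: pd.DataFrame,
    span_policy: Literal["split", "drop"] = "split",
    direction: Direction = "wt_to_mut",
) -> tuple[pd.DataFrame, dict]:
    """Lift a BED-like feature table (columns chrom/start/end/name/score/strand).

    Features crossing a block junction are split into sub-features
    (``span_policy="split"``) or dropped and counted (``"drop"``). Strand is
    inverted inside flipped blocks. The result is re-sorted on the target axis.
    """
    rows = []
    n_dropped = 0
    n_split = 0
    n_deleted = 0
    for rec in features.itertuples(index=False):
        pieces = lift_interval(segmap, int(rec.start), int(rec.end), direction)
        if not pieces:
            n_deleted += 1
            continue
        src_len = int(rec.end) - int(rec.start)
        whole = len(pieces) == 1 and (pieces[0][1] - pieces[0][0]) == src_len
        if not whole:
            if span_policy == "drop":
                n_dropped += 1
                continue
            n_split += 1
        strand = getattr(rec, "strand", ".")
        for k, (s, e, flipped) in enumerate(pieces):
            name = getattr(rec, "name", ".")
            if not whole and len(pieces) > 1:
                name = f"{name}.{k + 1}"
            rows.append(
                {
                    "chrom": segmap.chrom,
                    "start": s,
                    "end": e,
                    "name": name,
                    "score": getattr(rec, "score", 0),
                    "strand": _FLIP_STRAND.get(strand, ".") if flipped else strand,
                }
            )
    out = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    ).sort_values(["start", "end", "name"], kind="mergesort", ignore_index=True)
    report = {"n_dropped": n_dropped, "n_split": n_split, "n_deleted": n_deleted}
    return out, report


def write_chain(segmap: SegmentMap, wt_name: str | None = None, mut_name: str | None = None) -> str:
    """Emit UCSC chain records, one chain per colinear block.

    Target = wild-type axis, query = mutant axis; flipped blocks are written on
    the ``-`` strand of the query with reverse-strand coordinates, as the chain
    format requires.
    """
    tname = wt_name or segmap.chrom
    qname = mut_name or f"{segmap.chrom}_mut"
    lines: list[str] = []
    for i, b in enumerate(sorted(segmap.blocks, key=lambda b: b.mut_start), start=1):
        size = b.wt_end - b.wt_start
        if b.flipped:
            qstart = segmap.mut_length - b.mut_end
            qend = segmap.mut_length - b.mut_start
            strand = "-"
        else:
            qstart, qend = b.mut_start, b.mut_end
            strand = "+"
        lines.append(
            f"chain {size} {tname} {segmap.wt_length} + {b.wt_start} {b.wt_end} "
            f"{qname} {segmap.mut_length} {strand} {qstart} {qend} {i}"
        )
        lines.append(str(size))
        lines.append("")
    return "\n".join(lines) + "\n"


def parse_chain(text: str) -> SegmentMap:
    """Parse chain text produced by :func:`write_chain` back into a SegmentMap."""
    blocks: list[Block] = []
    wt_length = mut_length = None
    chrom = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line.startswith("chain"):
            continue
        f = line.split()
        (_, _, tname, tsize, _, tstart, tend, _, qsize, qstrand, qstart, qend, _) = f
        chrom = tname
        wt_length = int(tsize)
        mut_length = int(qsize)
        if qstrand == "-":
            ms = int(qsize) - int(qend)
            me = int(qsize) - int(qstart)
            flipped = True
        else:
            ms, me = int(qstart), int(qend)
            flipped = False
        blocks.append(Block(int(tstart), int(tend), ms, me, flipped))
    if wt_length is None or chrom is None:
        raise ValueError("no chain records found")

    # Reconstruct deleted (uncovered) and duplicated (multiply covered) wt intervals.
    edges = sorted({0, wt_length, *(b.wt_start for b in blocks), *(b.wt_end for b in blocks)})
    deletions: list[tuple[int, int]] = []
    duplications: list[tuple[int, int]] = []
    for s, e in zip(edges[:-1], edges[1:]):
        cov = sum(1 for b in blocks if b.wt_start <= s and e <= b.wt_end)
        if cov == 0:
            deletions.append((s, e))
        else:
            duplications.extend([(s, e)] * (cov - 1))
    return SegmentMap(chrom, wt_length, mut_length, blocks, deletions, duplications)
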