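"""Interval algebra for peak sets: merging, consensus replicates, overlap reports.

These are bedtools-style primitives (>=1 bp overlap criterion) implemented on
sorted numpy arrays so that every count is brute-force verifiable. A
:class:`PeakSet` is a thin wrapper around a pandas table with columns
``chrom/start/end`` (plus optional ``score``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

__all__ = [
    "PeakSet",
    "OverlapReport",
    "merge_intervals",
    "promoter_windows",
    "consensus_replicates",
    "overlap_report",
    "overlap_percentage",
    "filter_exclude",
]


@dataclass
class PeakSet:
    """A named set of genomic intervals (half-open) with a source label."""

    intervals: pd.DataFrame
    name: str = "peaks"
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.intervals
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"intervals need columns {required}")
        if len(df) and not (df["start"] < df["end"]).all():
            raise ValueError("all intervals must satisfy start < end")
        self.intervals = df.sort_values(
            ["chrom", "start", "end"], kind="mergesort", ignore_index=True
        )

    def __len__(self) -> int:
        return len(self.intervals)

    @classmethod
    def from_arrays(cls, chrom, start, end, name="peaks", **source) -> "PeakSet":
        df = pd.DataFrame(
            {"chrom": chrom, "start": np.asarray(start, dtype=int), "end": np.asarray(end, dtype=int)}
        )
        return cls(df, name=name, source=source)


def merge_intervals(s: PeakSet, max_gap: int = 0) -> PeakSet:
    """Merge overlapping (or within ``max_gap``) intervals into maximal runs.

    Idempotent; per-chromosome sweep over start-sorted intervals.
    """
    out = []
    for chrom, grp in s.intervals.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = None, None
        for st, en in zip(starts, ends):
            if cur_s is None:
                cur_s, cur_e = st, en
            elif st <= cur_e + max_gap:
                cur_e = max(cur_e, en)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = st, en
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    df = pd.DataFrame(out, columns=["chrom", "start", "end"])
    return PeakSet(df, name=f"merge({s.name})", source=dict(s.source))


def promoter_windows(
    genes: pd.DataFrame,
    upstream: int = 1000,
    downstream: int = 100,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Strand-aware promoter windows around each TSS.

    For a + strand gene the window is ``[TSS - upstream, TSS + downstream)``;
    mirrored for - strand. Clipped to ``[0, chromosome length)`` when sizes are
    given. ``genes`` needs columns chrom/tss/strand/name.
    """
    rows = []
    for rec in genes.itertuples(index=False):
        tss = int(rec.tss)
        if rec.strand == "-":
            start, end = tss - downstream, tss + upstream
        else:
            start, end = tss - upstream, tss + downstream
        start = max(start, 0)
        if chrom_sizes is not None and rec.chrom in chrom_sizes:
            end = min(end, chrom_sizes[rec.chrom])
        rows.append({"chrom": rec.chrom, "start": start, "end": end, "name": rec.name})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]).sort_values(
        ["chrom", "start", "end"], kind="mergesort", ignore_index=True
    )


def _overlap_mask(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query interval: has >=1 bp overlap with any subject interval."""
    query = query.reset_index(drop=True)
    mask = np.zeros(len(query), dtype=bool)
    if len(subject) == 0 or len(query) == 0:
        return mask
    merged = merge_intervals(PeakSet(subject[["chrom", "start", "end"]].copy()))
    sub_by_chrom = {c: g for c, g in merged.intervals.groupby("chrom", sort=False)}
    for chrom, grp in query.groupby("chrom", sort=False):
        sub = sub_by_chrom.get(chrom)
        if sub is None:
            continue
        ss = sub["start"].to_numpy()
        se = sub["end"].to_numpy()
        qs = grp["start"].to_numpy()
        qe = grp["end"].to_numpy()
        # merged subject intervals are disjoint & sorted: overlap iff the
        # count of subject starts before query end exceeds subject ends at/ before query start
        n_start_before = np.searchsorted(ss, qe, side="left")
        n_end_before = np.searchsorted(se, qs, side="right")
        mask[grp.index.to_numpy()] = n_start_before > n_end_before
    return mask


@dataclass
class OverlapReport:
    """Directional and union overlap accounting for two (or three) peak sets."""

    n_a: int
    n_b: int
    a_overlapping_b: int
    b_overlapping_a: int
    union_pieces_shared: int
    pct_a: int
    pct_b: int
    n_c: int | None = None
    euler_cells: dict[str, int] | None = None

    def to_dict(self) -> dict:
        d = {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "a_overlapping_b": self.a_overlapping_b,
            "b_overlapping_a": self.b_overlapping_a,
            "union_pieces_shared": self.union_pieces_shared,
            "pct_a_overlapping_b": self.pct_a,
            "pct_b_overlapping_a": self.pct_b,
        }
        if self.n_c is not None:
            d["n_c"] = self.n_c
            d["euler_cells"] = self.euler_cells
        return d


def overlap_percentage(count: int, total: int) -> int:
    """Integer percentage with round-half-up, e.g. (6182, 16740) -> 37."""
    if not 0 <= count <= total or total <= 0:
        raise ValueError("need 0 <= count <= total, total > 0")
    return int((Fraction(100 * count, total) + Fraction(1, 2)).__floor__())


def overlap_report(a: PeakSet, b: PeakSet, c: PeakSet | None = None) -> OverlapReport:
    """Count peaks of each set having >=1 bp overlap in the other.

    ``union_pieces_shared`` counts intervals of ``merge(A + B)`` that contain
    material from both sets. With a third set, ``euler_cells`` holds the seven
    exclusive membership counts of merged union pieces (keys like "ab", "abc").
    """
    a_in_b = int(_overlap_mask(a.intervals, b.intervals).sum())
    b_in_a = int(_overlap_mask(b.intervals, a.intervals).sum())
    union = merge_intervals(
        PeakSet(pd.concat([a.intervals[["chrom", "start", "end"]],
                           b.intervals[["chrom", "start", "end"]]], ignore_index=True))
    )
    shared = int(
        (
            _overlap_mask(union.intervals, a.intervals)
            & _overlap_mask(union.intervals, b.intervals)
        ).sum()
    )
    rep = OverlapReport(
        n_a=len(a),
        n_b=len(b),
        a_overlapping_b=a_in_b,
        b_overlapping_a=b_in_a,
        union_pieces_shared=shared,
        pct_a=overlap_percentage(a_in_b, len(a)) if len(a) else 0,
        pct_b=overlap_percentage(b_in_a, len(b)) if len(b) else 0,
    )
    if c is not None:
        frames = [s.intervals[["chrom", "start", "end"]] for s in (a, b, c)]
        union3 = merge_intervals(PeakSet(pd.concat(frames, ignore_index=True)))
        masks = {
            key: _overlap_mask(union3.intervals, s.intervals)
            for key, s in zip("abc", (a, b, c))
        }
        cells = {}
        for key in ("a", "b", "c", "ab", "ac", "bc", "abc"):
            m = np.ones(len(union3.intervals), dtype=bool)
            for letter in "abc":
                m &= masks[letter] if letter in key else ~masks[letter]
            cells[key] = int(m.sum())
        rep.n_c = len(c)
        rep.euler_cells = cells
    return rep


def consensus_replicates(rep1: PeakSet, rep2: PeakSet) -> PeakSet:
    """Replicate-consensus peaks: rep1 peaks with >=1 bp overlap in rep2.

    The reference convention (reported intervals come from rep1) is recorded in
    the result's source metadata.
    """
    keep = _overlap_mask(rep1.intervals, rep2.intervals)
    df = rep1.intervals.loc[keep].reset_index(drop=True)
    src = dict(rep1.source)
    src["consensus_reference"] = rep1.name
    src["consensus_other"] = rep2.name
    return PeakSet(df, name=f"consensus({rep1.name},{rep2.name})", source=src)


def filter_exclude(s: PeakSet, exclusions: pd.DataFrame) -> PeakSet:
    """Remove peaks with >=1 bp overlap to any exclusion interval."""
    if len(exclusions) == 0 or len(s) == 0:
        return PeakSet(s.intervals.copy(), name=s.name, source=dict(s.source))
    drop = _overlap_mask(s.intervals, exclusions[["chrom", "start", "end"]])
    df = s.intervals.loc[~drop].reset_index(drop=True)
    return PeakSet(df, name=f"exclude({s.name})", source=dict(s.source))
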