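"""CTCF-orientation boundary model: cluster occupied sites into oriented
boundary groups, predict the TAD partition of a chromosome, and report which
enhancers each promoter can reach.

The model is deliberately simple: boundaries are single-linkage clusters of
occupied CTCF sites; a cluster is *bidirectional* when both motif orientations
carry enough occupancy weight; domains are the maximal intervals between
consecutive boundary-cluster midpoints; an enhancer is reachable from a
promoter iff both midpoints fall in the same domain. Loop-level specificity is
intentionally not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "CTCFSite",
    "BoundaryCluster",
    "DomainPartition",
    "cluster_ctcf",
    "predict_partition",
    "assign_enhancers",
    "diff_assignment",
    "insulation_profile",
    "call_boundary_bins",
]


@dataclass(frozen=True)
class CTCFSite:
    position: int
    orientation: str  # "+" forward, "-" reverse
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValueError("orientation must be '+' or '-'")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass
class BoundaryCluster:
    """A group of nearby occupied CTCF sites acting as one insulation boundary."""

    start: int
    end: int
    sites: list[CTCFSite]
    cls: str  # bidirectional | forward-biased | reverse-biased
    label: str | None = None

    @property
    def strength(self) -> float:
        return float(sum(s.weight for s in self.sites))

    @property
    def forward_weight(self) -> float:
        return float(sum(s.weight for s in self.sites if s.orientation == "+"))

    @property
    def reverse_weight(self) -> float:
        return float(sum(s.weight for s in self.sites if s.orientation == "-"))

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class DomainPartition:
    """Ordered domain tiling of a span, with the boundary between each pair.

    ``convergent[i]`` annotates the adjacent boundary pair (i, i+1): True when
    the left boundary carries forward-oriented sites facing reverse-oriented
    sites on the right boundary.
    """

    domains: list[tuple[int, int]]
    boundaries: list[BoundaryCluster]
    convergent: list[bool]
    coordinate_system: str = "wildtype"
    span: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        pos = self.span[0]
        for s, e in self.domains:
            if s != pos or e <= s:
                raise ValueError("domains must tile the span without gaps or overlap")
            pos = e
        if pos != self.span[1]:
            raise ValueError("domains do not cover the span")

    def domain_of(self, position: int) -> int:
        """Index of the domain containing ``position`` (-1 if outside span)."""
        if not (self.span[0] <= position < self.span[1]):
            return -1
        for i, (s, e) in enumerate(self.domains):
            if s <= position < e:
                return i
        raise AssertionError("span tiling violated")

    @property
    def interior_edges(self) -> list[int]:
        return [e for _, e in self.domains[:-1]]


def cluster_ctcf(
    sites: Iterable[CTCFSite],
    max_gap: int,
    min_weight_per_orientation: float = 1.0,
) -> list[BoundaryCluster]:
    """Single-linkage clustering of CTCF sites at gap <= ``max_gap``.

    A cluster is classed bidirectional iff both orientations independently
    reach ``min_weight_per_orientation``; otherwise it is biased toward the
    dominant orientation.
    """
    sites = sorted(sites, key=lambda s: s.position)
    clusters: list[BoundaryCluster] = []
    group: list[CTCFSite] = []

    def _flush(group: list[CTCFSite]) -> None:
        fw = sum(s.weight for s in group if s.orientation == "+")
        rv = sum(s.weight for s in group if s.orientation == "-")
        if fw >= min_weight_per_orientation and rv >= min_weight_per_orientation:
            cls = "bidirectional"
        elif fw >= rv:
            cls = "forward-biased"
        else:
            cls = "reverse-biased"
        clusters.append(
            BoundaryCluster(group[0].position, group[-1].position + 1, list(group), cls)
        )

    for s in sites:
        if group and s.position - group[-1].position > max_gap:
            _flush(group)
            group = []
        group.append(s)
    if group:
        _flush(group)
    for i, c in enumerate(clusters, start=1):
        c.label = f"B{i}"
    return clusters


def predict_partition(
    clusters: Sequence[BoundaryCluster],
    span: tuple[int, int],
    min_strength: float = 1.0,
    coordinate_system: str = "wildtype",
) -> DomainPartition:
    """Domain partition implied by boundary clusters of sufficient strength.

    Domain edges sit at the midpoints of qualifying clusters; the span edges
    close the first and last domain. With zero qualifying clusters the whole
    span is one domain.
    """
    kept = sorted(
        (c for c in clusters if c.strength >= min_strength), key=lambda c: c.midpoint
    )
    kept = [c for c in kept if span[0] < c.midpoint < span[1]]
    edges = [span[0]] + [c.midpoint for c in kept] + [span[1]]
    domains = list(zip(edges[:-1], edges[1:]))
    convergent = [
        left.forward_weight > 0 and right.reverse_weight > 0
        for left, right in zip(kept[:-1], kept[1:])
    ]
    return DomainPartition(domains, list(kept), convergent, coordinate_system, span)


def assign_enhancers(
    partition: DomainPartition,
    enhancers: Mapping[str, int] | Sequence[tuple[str, int]],
    promoters: Mapping[str, int] | Sequence[tuple[str, int]],
) -> tuple[dict[str, set[str]], int]:
    """Same-domain enhancer->gene assignment by feature midpoints.

    ``enhancers`` and ``promoters`` map names to midpoint positions (a mapping
    or (name, position) pairs). Returns ``(gene -> set of enhancer names,
    n_features_outside_span)``.
    """
    enh = dict(enhancers)
    prom = dict(promoters)
    n_excluded = 0
    enh_domains: dict[str, int] = {}
    for name, pos in enh.items():
        d = partition.domain_of(int(pos))
        if d < 0:
            n_excluded += 1
        else:
            enh_domains[name] = d
    mapping: dict[str, set[str]] = {}
    for gene, pos in prom.items():
        d = partition.domain_of(int(pos))
        if d < 0:
            n_excluded += 1
            mapping[gene] = set()
            continue
        mapping[gene] = {name for name, ed in enh_domains.items() if ed == d}
    return mapping, n_excluded


def diff_assignment(
    before: Mapping[str, set[str]], after: Mapping[str, set[str]]
) -> dict[str, dict[str, set[str]]]:
    """Per-gene gained/lost enhancer sets between two assignments."""
    if set(before) != set(after):
        raise ValueError("assignments must share the same gene universe")
    return {
        gene: {
            "gained": set(after[gene]) - set(before[gene]),
            "lost": set(before[gene]) - set(after[gene]),
        }
        for gene in sorted(before)
    }


def insulation_profile(matrix, window: int) -> np.ndarray:
    """Diamond insulation score per bin.

    ``score[i]`` is the mean of entries ``{(a, b): i-w <= a < i <= b < i+w}``,
    i.e. the w x w diamond of contacts crossing between the two sides of bin
    boundary i. Bins within ``window`` of either edge are masked with NaN.
    """
    m = np.asarray(getattr(matrix, "matrix", matrix), dtype=float)
    n = m.shape[0]
    if window < 1:
        raise ValueError("window must be >= 1")
    if 2 * window > n:
        raise ValueError("window larger than matrix")
    score = np.full(n, np.nan)
    for i in range(window, n - window + 1):
        score[i] = m[i - window : i, i : i + window].mean()
    return score


def call_boundary_bins(profile: np.ndarray, min_prominence: float) -> np.ndarray:
    """Local minima of the insulation profile with prominence >= threshold."""
    valid = ~np.isnan(profile)
    if valid.sum() < 3:
        return np.array([], dtype=int)
    idx = np.flatnonzero(valid)
    seg = profile[idx]
    peaks, _ = find_peaks(-seg, prominence=min_prominence)
    return idx[peaks]
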