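"""Contact-matrix operations: normalization, mutant->wild-type remapping,
genotype subtraction, virtual 4C profiles and region-gain scores.

Matrices are dense square symmetric arrays on a named coordinate system
("wildtype" or "mutant:<allele>"). Subtraction maps between genotypes are
computed after scaling both operands to a common total, so only *relative*
contact redistribution is scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rearrange import SegmentMap, lift_position

__all__ = [
    "ContactMatrix",
    "SignedMatrix",
    "GainEstimate",
    "normalize_total",
    "remap_to_reference",
    "subtract",
    "virtual_4c",
    "region_gain",
]

_SYM_RTOL = 1e-9


@dataclass
class ContactMatrix:
    """Binned symmetric non-negative contact counts."""

    matrix: np.ndarray
    bin_size: int
    chrom: str
    coordinate_system: str = "wildtype"
    offset: int = 0  # genomic start of bin 0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if (m < 0).any():
            raise ValueError("contact matrix entries must be >= 0")
        scale = max(np.abs(m).max(), 1.0)
        if not np.allclose(m, m.T, rtol=_SYM_RTOL, atol=_SYM_RTOL * scale):
            raise ValueError("contact matrix must be symmetric")
        self.matrix = m

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def bin_of(self, position: int) -> int:
        b = (position - self.offset) // self.bin_size
        if not 0 <= b < self.n_bins:
            raise ValueError(f"position {position} outside the binned axis")
        return int(b)

    def bins_overlapping(self, start: int, end: int) -> np.ndarray:
        """Indices of bins with >=1 bp overlap with [start, end)."""
        lo = max(0, (start - self.offset) // self.bin_size)
        hi = min(self.n_bins, -(-(end - self.offset) // self.bin_size))
        if lo >= hi:
            raise ValueError("interval overlaps no bins")
        return np.arange(lo, hi)


@dataclass
class SignedMatrix:
    """Difference of two equally normalized contact matrices; antisymmetric
    under operand swap."""

    matrix: np.ndarray
    bin_size: int
    chrom: str
    coordinate_system: str = "wildtype"
    offset: int = 0
    provenance: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def bins_overlapping(self, start: int, end: int) -> np.ndarray:
        return ContactMatrix.bins_overlapping(self, start, end)  # type: ignore[arg-type]


def normalize_total(a: ContactMatrix, target_sum: float) -> ContactMatrix:
    """Scale so the matrix total equals ``target_sum`` (entry ratios unchanged)."""
    total = a.matrix.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero matrix")
    return ContactMatrix(
        a.matrix * (target_sum / total), a.bin_size, a.chrom, a.coordinate_system, a.offset
    )


def remap_to_reference(m: ContactMatrix, segmap: SegmentMap) -> tuple[ContactMatrix, float]:
    """Remap a mutant-system matrix onto the wild-type coordinate system.

    Each mutant bin is assigned to the wild-type bin containing the lift of its
    midpoint; entry mass moves with the bin pair. Bins whose midpoints lift
    nowhere are dropped and their mass returned. When breakpoints are aligned
    to bin edges the assignment is a permutation and mass is conserved exactly.
    """
    if not m.coordinate_system.startswith("mutant"):
        raise ValueError("input matrix must be on a mutant coordinate system")
    n_out = -(-segmap.wt_length // m.bin_size)
    dest = np.full(m.n_bins, -1, dtype=int)
    for i in range(m.n_bins):
        midpoint = m.offset + i * m.bin_size + m.bin_size // 2
        if midpoint >= segmap.mut_length:
            continue
        hits = lift_position(segmap, midpoint, "mut_to_wt")
        if not hits:
            continue
        dest[i] = hits[0][0] // m.bin_size
    keep = dest >= 0
    dropped_mass = float(m.matrix.sum() - m.matrix[np.ix_(keep, keep)].sum())
    out = np.zeros((n_out, n_out))
    ki = np.flatnonzero(keep)
    np.add.at(out, (dest[ki][:, None], dest[ki][None, :]), m.matrix[np.ix_(ki, ki)])
    return (
        ContactMatrix(out, m.bin_size, m.chrom, "wildtype", 0),
        dropped_mass,
    )


def subtract(a: ContactMatrix, b: ContactMatrix, target_sum: float = 1e6) -> SignedMatrix:
    """Equal-total subtraction map S = norm(A) - norm(B).

    Positive entries mark contacts relatively more frequent in A. Operands must
    share shape and coordinate system (remap mutant matrices first).
    """
    if a.matrix.shape != b.matrix.shape:
        raise ValueError("shape mismatch")
    if (a.coordinate_system, a.bin_size, a.offset) != (
        b.coordinate_system,
        b.bin_size,
        b.offset,
    ):
        raise ValueError("operands must be on the same coordinate system and binning")
    an = normalize_total(a, target_sum)
    bn = normalize_total(b, target_sum)
    return SignedMatrix(
        an.matrix - bn.matrix,
        a.bin_size,
        a.chrom,
        a.coordinate_system,
        a.offset,
        provenance={
            "target_sum": target_sum,
            "sum_a": float(a.matrix.sum()),
            "sum_b": float(b.matrix.sum()),
        },
    )


def virtual_4c(m: ContactMatrix, viewpoint: tuple[int, int]) -> np.ndarray:
    """Mean contact profile of a viewpoint interval against all bins.

    Viewpoint bins are masked with NaN in the output.
    """
    vp = m.bins_overlapping(*viewpoint)
    profile = m.matrix[vp, :].mean(axis=0)
    profile = profile.astype(float)
    profile[vp] = np.nan
    return profile


@dataclass(frozen=True)
class GainEstimate:
    score: float
    ci_low: float
    ci_high: float
    n_boot: int

    @property
    def excludes_zero(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


def region_gain(
    s: SignedMatrix,
    viewpoint: tuple[int, int],
    target_region: tuple[int, int],
    n_boot: int = 1000,
    seed: int | None = None,
) -> GainEstimate:
    """Total signed contact change between a viewpoint and a target region.

    Score = sum of S over (viewpoint bins x target bins); the percentile
    bootstrap resamples target bins, so the CI reflects how evenly the gain is
    spread over the target region.
    """
    vp = s.bins_overlapping(*viewpoint)
    tg = s.bins_overlapping(*target_region)
    block = s.matrix[np.ix_(vp, tg)]
    col_sums = block.sum(axis=0)
    score = float(col_sums.sum())
    rng = np.random.default_rng(seed)
    n_t = len(tg)
    idx = rng.integers(0, n_t, size=(n_boot, n_t))
    boot = col_sums[idx].sum(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return GainEstimate(score, float(lo), float(hi), n_boot)
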