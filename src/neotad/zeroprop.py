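"""Zero-proportion (dropout) expression analytics for UMI count matrices.

In droplet scRNA-seq the fraction of cells with zero UMIs for a gene is
strongly anti-correlated with its mean expression, so the zero proportion can
serve as an expression proxy. This module provides detection summaries with
Wilson confidence intervals, conditional-detection contingency tests, exact
hypergeometric depth downsampling, a deterministic rate inference that inverts
the Poisson/negative-binomial zero mass accounting for per-cell depth, and
bootstrap fold-change and rank-correlation-sign reports.

The rate model: for cell c with total depth s_c and relative rate r, the
zero probability is P0(s_c * r) with P0(mu) = exp(-mu) (Poisson) or
(theta / (theta + mu))^theta (negative binomial). The observed zero
proportion p0 = mean_c P0(s_c * r) is strictly decreasing in r, so r is
recovered by bracketed root-finding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import fisher_exact, rankdata, spearmanr
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "CountMatrix",
    "DetectionSummary",
    "RateModel",
    "FoldChangeEstimate",
    "CorrelationReport",
    "detection_summary",
    "conditional_detection",
    "downsample_depth",
    "infer_rate",
    "fold_change",
    "correlation_sign",
]


@dataclass
class CountMatrix:
    """Integer UMI counts (cells x genes) with per-cell metadata.

    ``cells`` must carry columns cell_id/genotype/cluster; the ``depth``
    column is recomputed from row sums, never trusted.
    """

    counts: np.ndarray
    cells: pd.DataFrame
    genes: list[str]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be 2-D (cells x genes)")
        if (c < 0).any():
            raise ValueError("counts must be >= 0")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)):
                raise ValueError("counts must be integers")
            c = c.astype(np.int64)
        self.counts = c
        if c.shape[0] != len(self.cells) or c.shape[1] != len(self.genes):
            raise ValueError("counts shape inconsistent with metadata")
        self.cells = self.cells.reset_index(drop=True).copy()
        self.cells["depth"] = c.sum(axis=1)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def subset_mask(
        self, cluster: str | None = None, genotype: str | None = None
    ) -> np.ndarray:
        mask = np.ones(self.n_cells, dtype=bool)
        if cluster is not None:
            mask &= (self.cells["cluster"] == cluster).to_numpy()
        if genotype is not None:
            mask &= (self.cells["genotype"] == genotype).to_numpy()
        return mask


@dataclass(frozen=True)
class DetectionSummary:
    gene: str
    subset: str
    n: int
    p_zero: float
    p_detect: float
    ci_low: float
    ci_high: float
    level: float = 0.95


@dataclass
class RateModel:
    """Zero-mass rate model: family "poisson" or "nb" with dispersion theta."""

    family: str = "poisson"
    theta: float = math.nan
    rate: float = math.nan
    boundary: str | None = None  # "all_zero" / "none_zero" when p0 hits 0 or 1

    def __post_init__(self) -> None:
        if self.family not in ("poisson", "nb"):
            raise ValueError("family must be 'poisson' or 'nb'")
        if self.family == "nb" and not (self.theta > 0):
            raise ValueError("nb family requires theta > 0")

    def zero_prob(self, mu: np.ndarray) -> np.ndarray:
        if self.family == "poisson":
            return np.exp(-mu)
        return (self.theta / (self.theta + mu)) ** self.theta


@dataclass(frozen=True)
class FoldChangeEstimate:
    gene: str
    cluster: str
    genotype_pair: tuple[str, str]
    fold_change: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None


@dataclass(frozen=True)
class CorrelationReport:
    gene_pair: tuple[str, str]
    subset: str
    rho: float
    ci_low: float
    ci_high: float
    p_opposite: float
    n: int
    n_boot: int
    seed: int | None


def _subset_label(cluster, genotype) -> str:
    return f"cluster={cluster or '*'},genotype={genotype or '*'}"


def detection_summary(
    m: CountMatrix,
    gene: str,
    cluster: str | None = None,
    genotype: str | None = None,
    level: float = 0.95,
) -> DetectionSummary:
    """Zero/detection proportion of a gene in a cell subset, with Wilson CI
    (on the zero proportion)."""
    mask = m.subset_mask(cluster, genotype)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty cell subset")
    counts = m.counts[mask, m.gene_index(gene)]
    n_zero = int((counts == 0).sum())
    lo, hi = proportion_confint(n_zero, n, alpha=1 - level, method="wilson")
    return DetectionSummary(
        gene, _subset_label(cluster, genotype), n, n_zero / n, 1 - n_zero / n,
        float(lo), float(hi), level,
    )


def conditional_detection(
    m: CountMatrix,
    gene_a: str,
    gene_b: str,
    cluster: str | None = None,
    genotype: str | None = None,
) -> dict:
    """2x2 detection contingency (rows: A detected/not; columns: B detected/not)
    with two-sided Fisher exact p and the sample odds ratio.

    Detection threshold is count > 0. A zero margin gives p = 1 and an
    undefined odds ratio (flagged None).
    """
    mask = m.subset_mask(cluster, genotype)
    if mask.sum() == 0:
        raise ValueError("empty cell subset")
    a = m.counts[mask, m.gene_index(gene_a)] > 0
    b = m.counts[mask, m.gene_index(gene_b)] > 0
    table = np.array(
        [
            [int((a & b).sum()), int((a & ~b).sum())],
            [int((~a & b).sum()), int((~a & ~b).sum())],
        ]
    )
    margins_ok = table.sum(axis=0).min() > 0 and table.sum(axis=1).min() > 0
    if margins_ok:
        res = fisher_exact(table, alternative="two-sided")
        p = float(res.pvalue)
        num, den = table[0, 0] * table[1, 1], table[0, 1] * table[1, 0]
        odds = float("inf") if den == 0 else num / den
    else:
        p = 1.0
        odds = None
    return {
        "gene_a": gene_a,
        "gene_b": gene_b,
        "subset": _subset_label(cluster, genotype),
        "table": table,
        "p_value": p,
        "odds_ratio": odds,
    }


def downsample_depth(
    m: CountMatrix, target_depth: int, seed: int | None = None
) -> tuple[CountMatrix, int]:
    """Exact per-cell downsampling to a common depth.

    Each cell's ``target_depth`` UMIs are drawn without replacement from its
    observed UMIs (multivariate hypergeometric), so row sums equal
    ``target_depth`` exactly and zero proportions become comparable across
    depth-imbalanced groups. Cells with depth < target are dropped; their
    number is returned.
    """
    if target_depth < 0:
        raise ValueError("target_depth must be >= 0")
    rng = np.random.default_rng(seed)
    depths = m.counts.sum(axis=1)
    keep = depths >= target_depth
    n_dropped = int((~keep).sum())
    out = np.empty((int(keep.sum()), m.counts.shape[1]), dtype=np.int64)
    for i, row in enumerate(m.counts[keep]):
        if row.sum() == target_depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, target_depth)
    return CountMatrix(out, m.cells.loc[keep, ["cell_id", "genotype", "cluster"]], list(m.genes)), n_dropped


_R_HI = 1e6  # upper bracket for the relative rate (counts per unit depth)


def infer_rate(
    m: CountMatrix,
    gene: str,
    cluster: str | None = None,
    genotype: str | None = None,
    family: str = "poisson",
    theta: float = math.nan,
) -> RateModel:
    """Invert the observed zero proportion into a relative expression rate.

    Solves ``p0_obs = mean_c P0(s_c * r)`` for r by Brent root-finding to
    relative tolerance 1e-8. ``p0_obs = 0`` returns rate = inf (flagged),
    ``p0_obs = 1`` returns rate = 0 (flagged).
    """
    mask = m.subset_mask(cluster, genotype)
    if mask.sum() == 0:
        raise ValueError("empty cell subset")
    counts = m.counts[mask, m.gene_index(gene)]
    depths = m.counts[mask].sum(axis=1).astype(float)
    p0 = float((counts == 0).mean())
    return _solve_rate(p0, depths, family, theta)


def _solve_rate(p0: float, depths: np.ndarray, family: str, theta: float) -> RateModel:
    model = RateModel(family, theta)
    if p0 >= 1.0:
        model.rate = 0.0
        model.boundary = "all_zero"
        return model
    if p0 <= 0.0:
        model.rate = math.inf
        model.boundary = "none_zero"
        return model

    def g(r: float) -> float:
        return float(model.zero_prob(depths * r).mean()) - p0

    lo = 1e-300
    hi = _R_HI / max(depths.mean(), 1.0)
    while g(hi) > 0 and hi < 1e12:  # too many zeros expected: push the bracket up
        hi *= 10
    if g(hi) > 0:  # zero-depth cells force a floor on the zero proportion
        model.rate = hi
        model.boundary = "unidentifiable"
        return model
    model.rate = float(brentq(g, lo, hi, rtol=1e-8))
    return model


def _boot_rates(
    zero: np.ndarray,
    depths: np.ndarray,
    family: str,
    theta: float,
    n_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bootstrap rate estimates by resampling cells (zero flag + depth jointly)."""
    n = len(zero)
    rates = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        p0 = float(zero[idx].mean())
        rates[b] = _solve_rate(p0, depths[idx], family, theta).rate
    return rates


def fold_change(
    m: CountMatrix,
    gene: str,
    cluster: str,
    genotype1: str,
    genotype2: str,
    family: str = "poisson",
    theta: float = math.nan,
    n_boot: int = 1000,
    seed: int | None = None,
) -> FoldChangeEstimate:
    """Zero-proportion fold-change r2/r1 between genotypes within a cluster,
    with a percentile bootstrap CI (cells resampled within each genotype
    independently).

    Bootstrap replicates whose zero proportion hits 0 or 1 use the continuity
    correction p0 -> 1/(2n) or 1 - 1/(2n) so the ratio stays finite.
    """
    rng = np.random.default_rng(seed)
    gi = m.gene_index(gene)
    rates = []
    boots = []
    for genotype in (genotype1, genotype2):
        mask = m.subset_mask(cluster, genotype)
        if mask.sum() == 0:
            raise ValueError(f"no cells for cluster={cluster}, genotype={genotype}")
        zero = (m.counts[mask, gi] == 0).astype(float)
        depths = m.counts[mask].sum(axis=1).astype(float)
        n = len(zero)
        point = _solve_rate(float(zero.mean()), depths, family, theta)
        rates.append(point.rate)
        # continuity-corrected bootstrap to keep replicates finite
        bs = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            p0 = float(zero[idx].mean())
            p0 = min(max(p0, 1.0 / (2 * n)), 1.0 - 1.0 / (2 * n))
            bs[b] = _solve_rate(p0, depths[idx], family, theta).rate
        boots.append(bs)
    point_fc = rates[1] / rates[0] if rates[0] > 0 else math.inf
    ratio = boots[1] / boots[0]
    lo, hi = np.percentile(ratio, [2.5, 97.5])
    return FoldChangeEstimate(
        gene, cluster, (genotype1, genotype2), float(point_fc), float(lo), float(hi),
        n_boot, seed,
    )


def correlation_sign(
    m: CountMatrix,
    gene_a: str,
    gene_b: str,
    cluster: str | None = None,
    genotype: str | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> CorrelationReport:
    """Rank correlation of depth-normalized counts, bootstrap CI, and the
    probability that the correlation has the opposite sign.

    ``p_opposite`` is the fraction of cell-resampling bootstrap replicates
    whose Spearman rho falls on the other side of zero from the point estimate
    (replicates exactly at zero count one half).
    """
    mask = m.subset_mask(cluster, genotype)
    n = int(mask.sum())
    if n < 10:
        raise ValueError("subset must contain at least 10 cells")
    depths = m.counts[mask].sum(axis=1).astype(float)
    depths[depths == 0] = 1.0
    xa = m.counts[mask, m.gene_index(gene_a)] / depths
    xb = m.counts[mask, m.gene_index(gene_b)] / depths
    rho = float(spearmanr(xa, xb).statistic)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        ra = rankdata(xa[idx])
        rb = rankdata(xb[idx])
        ca = ra - ra.mean()
        cb = rb - rb.mean()
        denom = math.sqrt(float((ca**2).sum() * (cb**2).sum()))
        boots[b] = float((ca * cb).sum()) / denom if denom > 0 else 0.0
    lo, hi = np.percentile(boots, [2.5, 97.5])
    sign = np.sign(rho)
    p_opp = float(np.mean((np.sign(boots) == -sign) + 0.5 * (boots == 0.0))) if sign != 0 else 1.0
    return CorrelationReport(
        (gene_a, gene_b), _subset_label(cluster, genotype), rho,
        float(lo), float(hi), p_opp, n, n_boot, seed,
    )
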