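"""Synthetic fixtures: a toy HoxD-like locus, boundary-insulated contact
matrices, replicate peak sets with planted overlap structure, and UMI count
matrices with planted fold-changes and gene-gene coupling.

The toy locus is a ~10x scaled-down cartoon of the murine locus: a 400 kb
chromosome carrying the gene cluster (Evx2, Hoxd13..Hoxd1) flanked by a
centromeric distal-enhancer landscape (islands + Prox) and a telomeric
proximal-enhancer landscape (CS39, CS65, CS68, PLE01-05), with five oriented
CTCF boundary groups B1..B5 (B2/B3 the intra-cluster bidirectional pair).
Inversion-allele analogues (inv2-like, Ulnaless-like) are provided as
rearrangement specs whose breakpoints reproduce which enhancers travel with
the cluster and which stay put. All simulators take explicit seeds and are
bitwise reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boundaries import BoundaryCluster, CTCFSite, DomainPartition
from .contacts import ContactMatrix
from .intervals import PeakSet
from .rearrange import Inversion, RearrangementSpec, SegmentMap
from .zeroprop import CountMatrix

__all__ = [
    "ToyLocus",
    "ContactModelParams",
    "ScrnaSimConfig",
    "make_toy_hoxd_locus",
    "toy_rearrangement_spec",
    "lift_ctcf_sites",
    "simulate_contact_matrix",
    "simulate_counts",
    "simulate_peaksets",
    "simulate_paired_factors",
    "toy_scrna_config",
    "TOY_INV2_BREAKPOINTS",
    "TOY_ULNALESS_BREAKPOINTS",
]

# ---------------------------------------------------------------------------
# Toy locus fixture constants (all coordinates in one place; bp on a 400 kb
# toy chromosome, ~10x scaled down from the ~1 Mb real locus).

_TOY_CHROM = "chr2toy"
_TOY_LENGTH = 400_000

# name -> (TSS, strand)
_TOY_GENES = {
    "Lnpk": (20_000, "+"),
    "Evx2": (158_000, "-"),
    "Hoxd13": (162_000, "-"),
    "Hoxd12": (166_000, "-"),
    "Hoxd11": (174_000, "-"),
    "Hoxd10": (181_000, "-"),
    "Hoxd9": (184_000, "-"),
    "Hoxd8": (187_000, "-"),
    "Hoxd4": (190_000, "-"),
    "Hoxd3": (193_000, "-"),
    "Hoxd1": (196_000, "-"),
    "Mtx2": (370_000, "+"),
}

# name -> (start, end, class); distal = digit (C-DOM side), proximal = forearm
_TOY_ENHANCERS = {
    "Island1": (49_000, 51_000, "distal"),
    "Island2": (79_000, 81_000, "distal"),
    "Island3": (109_000, 111_000, "distal"),
    "Prox": (149_000, 151_000, "distal"),
    "CS39": (229_000, 231_000, "proximal"),
    "CS65": (259_000, 261_000, "proximal"),
    "CS68": (309_000, 311_000, "proximal"),
    "PLE01": (319_000, 321_000, "proximal"),
    "PLE02": (324_000, 326_000, "proximal"),
    "PLE03": (329_000, 331_000, "proximal"),
    "PLE04": (334_000, 336_000, "proximal"),
    "PLE05": (339_000, 341_000, "proximal"),
}

# group -> list of (position, orientation, weight). B1 forward-biased edge of
# the distal landscape, B2/B3 the bidirectional intra-cluster pair, B4 the
# sub-boundary inside the proximal landscape, B5 the telomeric edge.
_TOY_CTCF = {
    1: [(29_500, "+", 2.0), (30_000, "+", 2.0), (30_500, "-", 0.5)],
    2: [(169_000, "+", 2.0), (170_000, "-", 2.0), (171_000, "+", 1.0)],
    3: [(176_000, "-", 2.0), (177_000, "+", 1.5), (178_000, "-", 1.0)],
    4: [(239_500, "+", 1.5), (240_500, "-", 0.5)],
    5: [(349_500, "-", 2.0), (350_000, "-", 2.0), (350_500, "+", 0.8)],
}

# Inversion-allele analogues. The inv2-like allele inverts [130 kb, 300 kb):
# Prox, the cluster, B2-B4 and CS65 travel; CS68/PLE01-05 lie beyond the
# telomeric breakpoint and stay. The Ulnaless-like allele inverts
# [145 kb, 250 kb): the telomeric breakpoint is centromeric of CS65, which
# therefore stays next to the relocated Hoxd13.
TOY_INV2_BREAKPOINTS = (130_000, 300_000)
TOY_ULNALESS_BREAKPOINTS = (145_000, 250_000)

_TOY_MAX_GAP = 2_000  # single-linkage gap for the toy CTCF clusters


@dataclass
class ToyLocus:
    """Deterministic toy HoxD-like locus."""

    chrom: str
    length: int
    genes: pd.DataFrame  # name, tss, strand
    enhancers: pd.DataFrame  # name, start, end, cls
    ctcf: pd.DataFrame  # position, orientation, weight, group

    max_gap: int = _TOY_MAX_GAP

    def __post_init__(self) -> None:
        if self.genes["name"].duplicated().any():
            raise ValueError("gene names must be unique")
        for col, hi in (("tss", self.length),):
            if not self.genes[col].between(0, hi - 1).all():
                raise ValueError("gene TSS out of bounds")
        if not (
            (self.enhancers["start"] >= 0) & (self.enhancers["end"] <= self.length)
        ).all():
            raise ValueError("enhancer interval out of bounds")
        if not self.ctcf["position"].between(0, self.length - 1).all():
            raise ValueError("CTCF site out of bounds")

    def ctcf_sites(self) -> list[CTCFSite]:
        return [
            CTCFSite(int(r.position), r.orientation, float(r.weight))
            for r in self.ctcf.itertuples(index=False)
        ]

    def enhancer_midpoints(self, cls: str | None = None) -> dict[str, int]:
        df = self.enhancers if cls is None else self.enhancers[self.enhancers["cls"] == cls]
        return {r.name: (int(r.start) + int(r.end)) // 2 for r in df.itertuples(index=False)}

    def promoter_positions(self) -> dict[str, int]:
        return {r.name: int(r.tss) for r in self.genes.itertuples(index=False)}

    def random_sequence(self, seed: int = 0) -> str:
        """Seeded random nucleotide sequence of the toy chromosome."""
        rng = np.random.default_rng(seed)
        return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=self.length)])

    @property
    def span(self) -> tuple[int, int]:
        return (0, self.length)


def make_toy_hoxd_locus() -> ToyLocus:
    """Deterministic toy locus with five boundary groups and both enhancer sets."""
    genes = pd.DataFrame(
        [
            {"chrom": _TOY_CHROM, "name": n, "tss": t, "strand": s}
            for n, (t, s) in _TOY_GENES.items()
        ]
    )
    enhancers = pd.DataFrame(
        [
            {"chrom": _TOY_CHROM, "name": n, "start": s, "end": e, "cls": c}
            for n, (s, e, c) in _TOY_ENHANCERS.items()
        ]
    )
    ctcf = pd.DataFrame(
        [
            {"position": p, "orientation": o, "weight": w, "group": g}
            for g, sites in _TOY_CTCF.items()
            for p, o, w in sites
        ]
    )
    return ToyLocus(_TOY_CHROM, _TOY_LENGTH, genes, enhancers, ctcf)


def toy_rearrangement_spec(allele: str) -> RearrangementSpec:
    """Rearrangement spec for a toy allele: "inv2" or "ulnaless"."""
    try:
        start, end = {
            "inv2": TOY_INV2_BREAKPOINTS,
            "ulnaless": TOY_ULNALESS_BREAKPOINTS,
        }[allele]
    except KeyError:
        raise ValueError(f"unknown toy allele: {allele!r}") from None
    return RearrangementSpec(_TOY_CHROM, [Inversion(start, end)], "0based")


def lift_ctcf_sites(sites: list[CTCFSite], segmap: SegmentMap) -> list[CTCFSite]:
    """Lift CTCF sites through a segment map, flipping motif orientation inside
    inverted blocks. Sites in deleted regions are lost; duplicated sites appear
    once per copy."""
    from .rearrange import lift_position

    out: list[CTCFSite] = []
    for s in sites:
        for pos, orient in lift_position(segmap, s.position, "wt_to_mut"):
            o = s.orientation
            if orient == "flipped":
                o = "+" if o == "-" else "-"
            out.append(CTCFSite(pos, o, s.weight))
    return sorted(out, key=lambda s: s.position)


# ---------------------------------------------------------------------------
# Contact-matrix simulator


@dataclass
class ContactModelParams:
    """Generative model for boundary-insulated contact decay.

    E[c_ij] = C * (|i-j| + 1)^(-alpha) * prod(f_b over boundaries between i, j).
    ``f_b`` is a single insulation factor applied at every boundary, or one
    factor per interior domain edge. ``noise="poisson"`` Poisson-samples each
    entry (symmetrically); ``"none"`` returns the expectation.
    """

    C: float = 100.0
    alpha: float = 0.8
    f_b: float | list[float] = 0.5
    noise: str = "none"

    def __post_init__(self) -> None:
        if self.C <= 0 or self.alpha <= 0:
            raise ValueError("C and alpha must be > 0")
        fbs = self.f_b if isinstance(self.f_b, (list, tuple)) else [self.f_b]
        if any(not (0 < f <= 1) for f in fbs):
            raise ValueError("insulation factors must be in (0, 1]")
        if self.noise not in ("none", "poisson"):
            raise ValueError("noise must be 'none' or 'poisson'")


def simulate_contact_matrix(
    partition: DomainPartition,
    params: ContactModelParams,
    n_bins: int,
    bin_size: int,
    seed: int | None = None,
) -> ContactMatrix:
    """Simulate a symmetric contact matrix for a domain partition.

    The partition must tile the binned axis ``[0, n_bins * bin_size)``. Each
    interior domain edge becomes a boundary between bins ``b-1`` and ``b`` with
    ``b = round(edge / bin_size)``.
    """
    if partition.span != (0, n_bins * bin_size):
        raise ValueError(
            f"partition span {partition.span} does not tile the binned axis "
            f"[0, {n_bins * bin_size})"
        )
    edges = partition.interior_edges
    fbs = (
        list(params.f_b)
        if isinstance(params.f_b, (list, tuple))
        else [params.f_b] * len(edges)
    )
    if len(fbs) != len(edges):
        raise ValueError("need one insulation factor per interior domain edge")

    idx = np.arange(n_bins)
    expected = params.C * (np.abs(idx[:, None] - idx[None, :]) + 1.0) ** (-params.alpha)
    for edge, f in zip(edges, fbs):
        b = int(round(edge / bin_size))
        right = idx >= b
        crossing = right[:, None] != right[None, :]
        expected = np.where(crossing, expected * f, expected)

    if params.noise == "poisson":
        rng = np.random.default_rng(seed)
        iu = np.triu_indices(n_bins)
        m = np.zeros_like(expected)
        m[iu] = rng.poisson(expected[iu])
        m = m + np.triu(m, 1).T
    else:
        m = expected
    return ContactMatrix(m, bin_size, _TOY_CHROM, partition.coordinate_system)


# ---------------------------------------------------------------------------
# scRNA-seq UMI count simulator


@dataclass
class ScrnaSimConfig:
    """Cluster-structured negative-binomial UMI model with planted effects.

    Per cell c of cluster k, genotype g: depth ``s_c ~ LogNormal(meanlog,
    sdlog)``; gene counts ``~ NB(mean = s_c * r_gk * fold_change, dispersion
    theta_g)``. Rates are expected UMIs per unit of total depth. An optional
    coupling ``(geneA, geneB, kappa)`` multiplies geneA's rate by a shared
    per-cell latent factor ``exp(kappa * z_c)`` and divides geneB's, planting
    anti-correlation while approximately preserving the NB marginals; kappa = 0
    is independence.
    """

    clusters: list[str]
    genotypes: list[str]
    n_cells: dict[tuple[str, str], int]  # (cluster, genotype) -> cell count
    genes: list[str]
    rates: dict[str, float] | dict[str, dict[str, float]] = field(default_factory=dict)
    fold_changes: dict[tuple[str, str, str], float] = field(default_factory=dict)
    theta: dict[str, float] | float = math.inf
    depth_meanlog: float = math.log(8000.0)
    depth_sdlog: float = 0.4
    coupling: tuple[str, str, float] | None = None
    seed: int | None = None

    def rate(self, gene: str, cluster: str) -> float:
        r = self.rates[gene]
        if isinstance(r, dict):
            r = r.get(cluster, 0.0)
        return float(r)

    def dispersion(self, gene: str) -> float:
        th = self.theta[gene] if isinstance(self.theta, dict) else self.theta
        if th <= 0:
            raise ValueError("dispersion theta must be > 0")
        return float(th)

    def fold_change(self, gene: str, cluster: str, genotype: str) -> float:
        return float(self.fold_changes.get((gene, cluster, genotype), 1.0))

    def validate(self) -> None:
        for g in self.genes:
            for k in self.clusters:
                if self.rate(g, k) < 0:
                    raise ValueError("rates must be >= 0")
        if any(n < 0 for n in self.n_cells.values()):
            raise ValueError("cell counts must be >= 0")


def simulate_counts(config: ScrnaSimConfig, seed: int | None = None) -> CountMatrix:
    """Draw a UMI count matrix from the generative model in ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = list(config.genes)
    blocks: list[np.ndarray] = []
    meta: list[dict] = []
    coupling = config.coupling
    for cluster in config.clusters:
        for genotype in config.genotypes:
            n = config.n_cells.get((cluster, genotype), 0)
            if n == 0:
                continue
            s = rng.lognormal(config.depth_meanlog, config.depth_sdlog, size=n)
            latent = (
                np.exp(coupling[2] * rng.standard_normal(n))
                if coupling is not None
                else None
            )
            counts = np.zeros((n, len(genes)), dtype=np.int64)
            for j, gene in enumerate(genes):
                mu = s * config.rate(gene, cluster) * config.fold_change(gene, cluster, genotype)
                if latent is not None:
                    if gene == coupling[0]:
                        mu = mu * latent
                    elif gene == coupling[1]:
                        mu = mu / latent
                theta = config.dispersion(gene)
                if math.isinf(theta):
                    counts[:, j] = rng.poisson(mu)
                else:
                    lam = rng.gamma(theta, mu / theta)
                    counts[:, j] = rng.poisson(lam)
            blocks.append(counts)
            for i in range(n):
                meta.append(
                    {
                        "cell_id": f"{genotype}_{cluster}_{i}",
                        "genotype": genotype,
                        "cluster": cluster,
                    }
                )
    all_counts = np.vstack(blocks) if blocks else np.zeros((0, len(genes)), dtype=np.int64)
    cells = pd.DataFrame(meta, columns=["cell_id", "genotype", "cluster"])
    return CountMatrix(all_counts, cells, genes)


def toy_scrna_config(
    n_per_group: int = 500,
    hoxd13_gain: float = 2.0,
    hoxa11_loss: float = 0.5,
    hoxd11_loss: float = 0.78,
    coupling: float = 0.6,
    theta: float = 2.0,
) -> ScrnaSimConfig:
    """Study-like default configuration: two proximal clusters (c1, c6) where
    the inverted allele gains Hoxd13 and partially loses Hoxa11/Hoxd11, and a
    distal control cluster (c3) with planted Hoxd13~Hoxa11 anti-correlation."""
    clusters = ["c1", "c6", "c3"]
    genotypes = ["wt", "inv2"]
    rates = {
        "Hoxd13": {"c1": 5e-5, "c6": 5e-5, "c3": 4e-4},
        "Hoxa11": {"c1": 3e-4, "c6": 3e-4, "c3": 1e-4},
        "Hoxd11": {"c1": 2e-4, "c6": 2e-4, "c3": 2e-4},
        "Hoxa13": {"c1": 1e-5, "c6": 1e-5, "c3": 3e-4},
        "Shox2": {"c1": 2e-4, "c6": 2e-4, "c3": 2e-5},
    }
    fold_changes = {}
    for k in ("c1", "c6"):
        fold_changes[("Hoxd13", k, "inv2")] = hoxd13_gain
        fold_changes[("Hoxa11", k, "inv2")] = hoxa11_loss
        fold_changes[("Hoxd11", k, "inv2")] = hoxd11_loss
    return ScrnaSimConfig(
        clusters=clusters,
        genotypes=genotypes,
        n_cells={(k, g): n_per_group for k in clusters for g in genotypes},
        genes=["Hoxd13", "Hoxa11", "Hoxd11", "Hoxa13", "Shox2"],
        rates=rates,
        fold_changes=fold_changes,
        theta=theta,
        coupling=("Hoxd13", "Hoxa11", coupling),
    )


# ---------------------------------------------------------------------------
# Replicate peak-set simulator


def _place_nonoverlapping(
    n: int, genome_length: int, width: int, margin: int, rng: np.random.Generator
) -> np.ndarray:
    """n sorted non-overlapping starts with pairwise spacing >= width + margin."""
    spacing = width + margin
    free = genome_length - n * spacing
    if n > 0 and free < 0:
        raise ValueError(
            f"cannot pack {n} peaks of width {width} (+{margin} margin) into {genome_length} bp"
        )
    if n == 0:
        return np.array([], dtype=int)
    offsets = np.sort(rng.integers(0, free + 1, size=n))
    return offsets + spacing * np.arange(n)


def simulate_peaksets(
    n_consensus: int,
    n_extra_per_rep: int,
    genome_length: int,
    peak_width: int,
    seed: int | None = None,
    jitter: int = 0,
    chrom: str = "chrS",
) -> tuple[PeakSet, PeakSet]:
    """Two replicate peak sets sharing ``n_consensus`` planted peaks.

    Planted peaks are non-overlapping (spacing allows for jitter); each
    replicate jitters them independently and adds ``n_extra_per_rep``
    replicate-private peaks placed clear of the planted ones.
    """
    rng = np.random.default_rng(seed)
    margin = 2 * jitter + 1
    planted = _place_nonoverlapping(n_consensus, genome_length, peak_width, margin, rng)

    reps = []
    occupied_lo = planted - jitter
    occupied_hi = planted + peak_width + jitter
    for r in range(2):
        if jitter > 0 and n_consensus > 0:
            starts = planted + rng.integers(-jitter, jitter + 1, size=n_consensus)
        else:
            starts = planted.copy()
        extra = []
        while len(extra) < n_extra_per_rep:
            cand = int(rng.integers(0, genome_length - peak_width + 1))
            i = np.searchsorted(occupied_hi, cand, side="right")
            clear = i >= len(planted) or cand + peak_width <= occupied_lo[i]
            before_ok = i == 0 or cand >= occupied_hi[i - 1]
            if clear and before_ok:
                extra.append(cand)
        all_starts = np.concatenate([starts, np.array(extra, dtype=int)])
        reps.append(
            PeakSet.from_arrays(
                [chrom] * len(all_starts),
                all_starts,
                all_starts + peak_width,
                name=f"rep{r + 1}",
                replicate=r + 1,
            )
        )
    return reps[0], reps[1]


def simulate_paired_factors(
    n_a: int,
    n_b: int,
    overlap_fraction: float,
    genome_length: int,
    peak_width: int,
    seed: int | None = None,
    chrom: str = "chrS",
) -> tuple[PeakSet, PeakSet]:
    """Two factors' peak sets where a planted fraction of B peaks overlap A.

    Each B peak independently overlaps a random A peak with probability
    ``overlap_fraction`` (offset within +/- (width-1) so the overlap is >=1 bp);
    the remaining B peaks are placed clear of every A peak.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    margin = 2 * peak_width  # leaves room to place non-overlapping B peaks nearby
    a_starts = _place_nonoverlapping(n_a, genome_length, peak_width, margin, rng)
    overlaps = rng.random(n_b) < overlap_fraction
    b_starts = np.empty(n_b, dtype=int)
    n_over = int(overlaps.sum())
    anchors = a_starts[rng.integers(0, n_a, size=n_over)]
    b_starts[overlaps] = anchors + rng.integers(-(peak_width - 1), peak_width, size=n_over)
    a_ends = a_starts + peak_width
    for i in np.flatnonzero(~overlaps):
        while True:
            cand = int(rng.integers(0, genome_length - peak_width + 1))
            j = np.searchsorted(a_starts, cand + peak_width, side="left")
            if (j == 0 or cand >= a_ends[j - 1]) and (j >= n_a or cand + peak_width <= a_starts[j]):
                b_starts[i] = cand
                break
    b_starts = np.clip(b_starts, 0, genome_length - peak_width)
    a = PeakSet.from_arrays([chrom] * n_a, a_starts, a_starts + peak_width, name="factorA")
    b = PeakSet.from_arrays([chrom] * n_b, b_starts, b_starts + peak_width, name="factorB")
    return a, b
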