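import numpy as np
import pytest

import neotad as nt


@pytest.fixture(scope="session")
def locus():
    return nt.make_toy_hoxd_locus()


@pytest.fixture(scope="session")
def wt_partition(locus):
    clusters = nt.cluster_ctcf(locus.ctcf_sites(), locus.max_gap)
    return nt.predict_partition(clusters, locus.span, min_strength=1.0)


@pytest.fixture(scope="session")
def inv2_segmap(locus):
    return nt.compile_rearrangement(nt.toy_rearrangement_spec("inv2"), locus.length)


@pytest.fixture(scope="session")
def inv2_partition(locus, inv2_segmap):
    lifted = nt.lift_ctcf_sites(locus.ctcf_sites(), inv2_segmap)
    clusters = nt.cluster_ctcf(lifted, locus.max_gap)
    return nt.predict_partition(clusters, locus.span, 1.0, "mutant:inv2")


def allele_assignment(locus, allele):
    """Enhancer->gene assignment for a toy allele (None = wild type)."""
    if allele is None:
        clusters = nt.cluster_ctcf(locus.ctcf_sites(), locus.max_gap)
        part = nt.predict_partition(clusters, locus.span, 1.0)
        enh = locus.enhancer_midpoints()
        prom = locus.promoter_positions()
    else:
        segmap = nt.compile_rearrangement(nt.toy_rearrangement_spec(allele), locus.length)
        lifted = nt.lift_ctcf_sites(locus.ctcf_sites(), segmap)
        part = nt.predict_partition(
            nt.cluster_ctcf(lifted, locus.max_gap), locus.span, 1.0, f"mutant:{allele}"
        )
        enh = {
            n: nt.lift_position(segmap, p)[0][0]
            for n, p in locus.enhancer_midpoints().items()
        }
        prom = {
            n: nt.lift_position(segmap, p)[0][0]
            for n, p in locus.promoter_positions().items()
        }
    mapping, _ = nt.assign_enhancers(part, enh, prom)
    return mapping


def random_rearrangement(rng: np.random.Generator, length: int) -> nt.RearrangementSpec:
    """A random valid spec: 1-3 disjoint inversions/deletions/duplications."""
    n_ops = int(rng.integers(1, 4))
    cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_ops, replace=False))
    intervals = [(int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n_ops)]
    intervals = [(s, e) for s, e in intervals if e > s]
    ops = []
    op_intervals = []
    for s, e in intervals:
        kind = rng.integers(0, 3)
        if kind == 0:
            ops.append(nt.Inversion(s, e))
        elif kind == 1:
            ops.append(nt.Deletion(s, e))
        else:
            ops.append(nt.Duplication(s, e, e, bool(rng.integers(0, 2))))
        op_intervals.append((s, e))
    return nt.RearrangementSpec("chrT", ops, "0based")


def marker_track(wt_len: int, segmap, position: int) -> list[tuple[int, str]]:
    """Independent liftover oracle: push a uniquely marked base through
    sequence construction and read off where the marker(s) land."""
    seq = "A" * position + "C" + "A" * (wt_len - position - 1)
    mut = nt.build_mutant_sequence(seq, segmap)
    hits = []
    for i, ch in enumerate(mut):
        if ch == "C":
            hits.append((i, "same"))
        elif ch == "G":  # complement of the marker: came through a flipped block
            hits.append((i, "flipped"))
    return hits
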