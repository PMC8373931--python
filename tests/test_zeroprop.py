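"""Zero-proportion analytics: detection, contingency, downsampling, inference."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import neotad as nt


def matrix_from_counts(counts, genotype="g", cluster="c", genes=None):
    counts = np.asarray(counts)
    cells = pd.DataFrame(
        {
            "cell_id": [f"cell{i}" for i in range(counts.shape[0])],
            "genotype": genotype if isinstance(genotype, str) else genotype,
            "cluster": cluster,
        }
    )
    if not isinstance(genotype, str):
        cells["genotype"] = genotype
    return nt.CountMatrix(counts, cells, genes or [f"g{j}" for j in range(counts.shape[1])])


def nb_sim_matrix(n, rate, theta, seed, depth_sdlog=0.4):
    cfg = nt.ScrnaSimConfig(
        clusters=["c"], genotypes=["g"], n_cells={("c", "g"): n},
        genes=["G", "BG"], rates={"G": rate, "BG": 1.0},
        theta={"G": theta, "BG": 1e6} if not math.isinf(theta) else float("inf"),
        depth_sdlog=depth_sdlog,
    )
    return nt.simulate_counts(cfg, seed=seed)


class TestDetectionSummary:
    def test_all_zero_gene(self):
        m = matrix_from_counts([[0, 5], [0, 3], [0, 1]])
        s = nt.detection_summary(m, "g0")
        assert s.p_zero == 1.0 and s.p_detect == 0.0

    def test_poisson_zero_fraction_closed_form(self):
        # constant depth, mean 1 per cell: p0 -> exp(-1)
        rng = np.random.default_rng(0)
        n = 100_000
        counts = np.column_stack([rng.poisson(1.0, n), np.full(n, 5)])
        m = matrix_from_counts(counts)
        s = nt.detection_summary(m, "g0")
        assert s.p_zero == pytest.approx(math.exp(-1), abs=0.01)
        assert s.ci_low < s.p_zero < s.ci_high

    def test_ci_width_shrinks_with_root_n(self):
        widths = []
        for n in (100, 10_000):
            counts = np.column_stack([np.r_[np.zeros(n // 2), np.ones(n - n // 2)], np.ones(n)])
            m = matrix_from_counts(counts.astype(int))
            s = nt.detection_summary(m, "g0")
            widths.append(s.ci_high - s.ci_low)
        assert widths[0] / widths[1] == pytest.approx(10, rel=0.15)


class TestConditionalDetection:
    def test_perfect_anti_association(self):
        counts = np.zeros((100, 2), dtype=int)
        counts[:50, 0] = 1  # A detected, B not
        counts[50:, 1] = 1  # B detected, A not
        m = matrix_from_counts(counts)
        r = nt.conditional_detection(m, "g0", "g1")
        assert r["odds_ratio"] == 0
        assert r["table"].tolist() == [[0, 50], [50, 0]]

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        # table [[3,7],[5,5]]: enumerate the hypergeometric tail directly
        counts = np.zeros((20, 2), dtype=int)
        counts[:10, 0] = 1  # A detected in first 10
        counts[:3, 1] = 1  # B detected with A in 3
        counts[10:15, 1] = 1  # B detected without A in 5
        m = matrix_from_counts(counts)
        r = nt.conditional_detection(m, "g0", "g1")
        assert r["table"].tolist() == [[3, 7], [5, 5]]
        # two-sided Fisher: sum of P(X=k) <= P(X=3) for X ~ Hypergeom(20, 10, 8)
        rv = hypergeom(20, 10, 8)
        p3 = rv.pmf(3)
        p_exact = sum(rv.pmf(k) for k in range(9) if rv.pmf(k) <= p3 * (1 + 1e-9))
        assert r["p_value"] == pytest.approx(p_exact, rel=1e-6)

    def test_zero_margin_flagged(self):
        m = matrix_from_counts(np.zeros((30, 2), dtype=int))
        r = nt.conditional_detection(m, "g0", "g1")
        assert r["p_value"] == 1.0 and r["odds_ratio"] is None

    def test_independent_genes_odds_ratio_near_one(self):
        # constant depth: with zero coupling the genes are truly independent
        # (depth variation alone induces positive detection association)
        hits = 0
        for seed in range(50):
            cfg = nt.ScrnaSimConfig(
                clusters=["c"], genotypes=["g"], n_cells={("c", "g"): 5000},
                genes=["A", "B", "BG"], rates={"A": 1e-4, "B": 1e-4, "BG": 1.0},
                theta=float("inf"), coupling=("A", "B", 0.0), depth_sdlog=0.0,
            )
            m = nt.simulate_counts(cfg, seed=seed)
            r = nt.conditional_detection(m, "A", "B")
            if r["odds_ratio"] is not None and 0.8 <= r["odds_ratio"] <= 1.25:
                hits += 1
        assert hits >= 45  # >= 90% of null simulations


class TestDownsample:
    def test_target_equal_to_depth_unchanged(self):
        counts = np.array([[3, 7], [2, 8]])
        m = matrix_from_counts(counts)
        out, dropped = nt.downsample_depth(m, 10, seed=0)
        assert dropped == 0
        assert np.array_equal(out.counts, counts)

    def test_row_sums_exact_and_shallow_cells_dropped(self):
        counts = np.array([[30, 70], [2, 3], [50, 50]])
        m = matrix_from_counts(counts)
        out, dropped = nt.downsample_depth(m, 20, seed=0)
        assert dropped == 1
        assert (out.counts.sum(axis=1) == 20).all()

    def test_hypergeometric_mean(self):
        counts = np.tile([40, 60], (1000, 1))
        m = matrix_from_counts(counts)
        out, _ = nt.downsample_depth(m, 50, seed=1)
        assert out.counts[:, 0].mean() == pytest.approx(40 * 50 / 100, rel=0.03)

    def test_seed_reproducibility(self):
        counts = np.tile([40, 60], (50, 1))
        m = matrix_from_counts(counts)
        a, _ = nt.downsample_depth(m, 50, seed=9)
        b, _ = nt.downsample_depth(m, 50, seed=9)
        assert np.array_equal(a.counts, b.counts)


class TestInferRate:
    def test_poisson_closed_form_inversion(self):
        # constant depth 1, p0 = exp(-1) -> r = 1
        n = 1000
        counts = np.zeros((n, 1), dtype=int)
        counts[: round(n * (1 - math.exp(-1)))] = 1
        p0 = (counts == 0).mean()
        from neotad.zeroprop import _solve_rate

        model = _solve_rate(p0, np.ones(n), "poisson", math.nan)
        assert model.rate == pytest.approx(-math.log(p0), rel=1e-6)
        assert model.rate == pytest.approx(1.0, rel=5e-3)

    def test_nb_zero_mass_inversion(self):
        # theta=2, constant depth 1, p0 = (2/3)^2 -> mu = 1
        from neotad.zeroprop import _solve_rate

        model = _solve_rate((2 / 3) ** 2, np.ones(500), "nb", 2.0)
        assert model.rate == pytest.approx(1.0, rel=1e-6)

    def test_boundary_flags(self):
        from neotad.zeroprop import _solve_rate

        assert _solve_rate(1.0, np.ones(10), "poisson", math.nan).boundary == "all_zero"
        assert _solve_rate(0.0, np.ones(10), "poisson", math.nan).rate == math.inf

    @pytest.mark.parametrize("family,theta", [("poisson", float("inf")), ("nb", 2.0)])
    def test_parameter_recovery_from_simulation(self, family, theta):
        rate = 2e-4
        m = nb_sim_matrix(2000, rate, theta, seed=10)
        model = nt.infer_rate(
            m, "G", "c", "g", family, 2.0 if family == "nb" else math.nan
        )
        assert model.rate == pytest.approx(rate, rel=0.1)

    def test_p0_monotone_in_planted_rate(self):
        p0s = []
        for rate in (5e-5, 2e-4, 8e-4):
            m = nb_sim_matrix(5000, rate, float("inf"), seed=11)
            p0s.append(nt.detection_summary(m, "G").p_zero)
        assert p0s[0] > p0s[1] > p0s[2]


class TestFoldChange:
    def two_genotype_matrix(self, fc, n=500, seed=0, theta=2.0):
        cfg = nt.ScrnaSimConfig(
            clusters=["c1"], genotypes=["wt", "mut"],
            n_cells={("c1", "wt"): n, ("c1", "mut"): n},
            genes=["G", "BG"], rates={"G": 2e-4, "BG": 1.0},
            fold_changes={("G", "c1", "mut"): fc},
            theta={"G": theta, "BG": 1e6},
        )
        return nt.simulate_counts(cfg, seed=seed)

    def test_identical_subsets_unit_fold_change(self):
        m = self.two_genotype_matrix(1.0, seed=1)
        est = nt.fold_change(m, "G", "c1", "wt", "wt", "nb", 2.0, n_boot=100, seed=1)
        assert est.fold_change == pytest.approx(1.0)
        assert est.ci_low <= 1.0 <= est.ci_high

    def test_planted_halving_detected_as_decrease(self):
        below = 0
        for seed in range(20):
            m = self.two_genotype_matrix(0.5, seed=seed)
            est = nt.fold_change(m, "G", "c1", "wt", "mut", "nb", 2.0, n_boot=50, seed=seed)
            if est.fold_change < 1:
                below += 1
        assert below >= 19  # >= 95% sign consistency

    def test_bootstrap_reproducible(self):
        m = self.two_genotype_matrix(2.0, seed=3)
        e1 = nt.fold_change(m, "G", "c1", "wt", "mut", "nb", 2.0, n_boot=100, seed=4)
        e2 = nt.fold_change(m, "G", "c1", "wt", "mut", "nb", 2.0, n_boot=100, seed=4)
        assert (e1.fold_change, e1.ci_low, e1.ci_high) == (e2.fold_change, e2.ci_low, e2.ci_high)


class TestCorrelationSign:
    def test_self_correlation_is_one(self):
        m = nb_sim_matrix(200, 5e-4, 2.0, seed=5)
        r = nt.correlation_sign(m, "G", "G", n_boot=100, seed=0)
        assert r.rho == pytest.approx(1.0)
        assert r.p_opposite == 0.0

    def test_null_coupling_ci_covers_zero(self):
        covered = 0
        for seed in range(20):
            cfg = nt.ScrnaSimConfig(
                clusters=["c"], genotypes=["g"], n_cells={("c", "g"): 800},
                genes=["A", "B", "BG"], rates={"A": 3e-4, "B": 3e-4, "BG": 1.0},
                theta=float("inf"), coupling=("A", "B", 0.0),
            )
            m = nt.simulate_counts(cfg, seed=seed)
            r = nt.correlation_sign(m, "A", "B", n_boot=200, seed=seed)
            if r.ci_low <= 0 <= r.ci_high:
                covered += 1
        assert covered >= 17  # ~95% nominal coverage, binomial slack at 20 seeds

    def test_small_subset_rejected(self):
        m = nb_sim_matrix(20, 5e-4, 2.0, seed=6)
        sub = nt.CountMatrix(m.counts[:5], m.cells.iloc[:5][["cell_id", "genotype", "cluster"]], m.genes)
        with pytest.raises(ValueError, match="10"):
            nt.correlation_sign(sub, "G", "BG")


class TestDepthBiasRemoval:
    def test_downsampling_removes_pure_depth_confound(self):
        # equal rates, 2x depth difference: raw zero proportions differ
        # strongly, downsampled fold-change CI covers 1
        cfg_lo = nt.ScrnaSimConfig(
            clusters=["c"], genotypes=["lo"], n_cells={("c", "lo"): 2000},
            genes=["G", "BG"], rates={"G": 2e-4, "BG": 1.0},
            theta=float("inf"), depth_meanlog=math.log(4000),
        )
        cfg_hi = nt.ScrnaSimConfig(
            clusters=["c"], genotypes=["hi"], n_cells={("c", "hi"): 2000},
            genes=["G", "BG"], rates={"G": 2e-4, "BG": 1.0},
            theta=float("inf"), depth_meanlog=math.log(8000),
        )
        m_lo = nt.simulate_counts(cfg_lo, seed=21)
        m_hi = nt.simulate_counts(cfg_hi, seed=22)
        m = nt.CountMatrix(
            np.vstack([m_lo.counts, m_hi.counts]),
            pd.concat(
                [m_lo.cells, m_hi.cells], ignore_index=True
            )[["cell_id", "genotype", "cluster"]],
            ["G", "BG"],
        )
        p_lo = nt.detection_summary(m, "G", "c", "lo")
        p_hi = nt.detection_summary(m, "G", "c", "hi")
        assert p_hi.ci_high < p_lo.ci_low  # naive proxy says "different expression"
        down, _ = nt.downsample_depth(m, 2000, seed=23)
        est = nt.fold_change(down, "G", "c", "lo", "hi", "poisson", n_boot=200, seed=24)
        assert est.ci_low <= 1.0 <= est.ci_high
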