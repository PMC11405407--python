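"""Rank-AUC scoring, bimodal thresholding, SG labels, proportion tests."""

import numpy as np
import pandas as pd
import pytest

from spliceometab import (
    SimulationConfig,
    chi_square_2x2,
    compare_proportions,
    find_threshold,
    generate_cells,
    label_cells,
    rank_auc,
    score_cells,
    spliceosome_gene_set,
)

from .oracles import recovery_auc


def _cell(n_genes, top_genes):
    """Expression vector putting ``top_genes`` at the top ranks, in order."""
    genes = [f"g{i:03d}" for i in range(n_genes)]
    vals = pd.Series(0.0, index=genes)
    rest = [g for g in genes if g not in top_genes]
    ordered = list(top_genes) + rest
    for rank, g in enumerate(ordered):
        vals[g] = float(n_genes - rank)
    return vals


class TestRankAuc:
    def test_set_at_top_is_one(self):
        expr = _cell(100, ["g001", "g002", "g003"])
        assert rank_auc(expr, ["g001", "g002", "g003"], top_fraction=0.05) == 1.0

    def test_set_outside_top_k_is_zero(self):
        expr = _cell(100, [f"g{i:03d}" for i in range(10)])
        assert rank_auc(expr, ["g099"], top_fraction=0.05) == 0.0

    def test_matches_brute_force_recovery_curve(self):
        # 100 genes, k=5, set genes at ranks 2 and 4
        top = ["g050", "g010", "g051", "g011", "g052"]
        expr = _cell(100, top)
        auc = rank_auc(expr, ["g010", "g011"], top_fraction=0.05)
        assert auc == pytest.approx(recovery_auc([2, 4], 100, 2, 5))
        assert auc == pytest.approx(6 / 9)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_random_cells_match_oracle(self, seed):
        r = np.random.default_rng(seed)
        genes = [f"g{i:03d}" for i in range(80)]
        expr = pd.Series(r.permutation(80).astype(float), index=genes)
        gene_set = list(r.choice(genes, size=12, replace=False))
        k = 4  # ceil(0.05 * 80)
        order = sorted(genes, key=lambda g: (-expr[g], g))
        ranks = [order.index(g) + 1 for g in gene_set if order.index(g) < k]
        assert rank_auc(expr, gene_set, 0.05) == pytest.approx(
            recovery_auc(ranks, 80, min(12, k), k)
        )

    def test_invariant_under_monotone_transform(self):
        r = np.random.default_rng(3)
        genes = [f"g{i:03d}" for i in range(200)]
        expr = pd.Series(r.exponential(size=200), index=genes)
        gene_set = genes[::7]
        a1 = rank_auc(expr, gene_set)
        a2 = rank_auc(np.log1p(expr * 100), gene_set)
        assert a1 == a2

    def test_set_larger_than_k_uses_achievable_plateau(self):
        expr = _cell(100, [f"g{i:03d}" for i in range(5)])
        big_set = [f"g{i:03d}" for i in range(40)]  # |set|=40 > k=5
        assert rank_auc(expr, big_set, top_fraction=0.05) == 1.0

    def test_empty_intersection_rejected(self):
        expr = _cell(20, [])
        with pytest.raises(ValueError):
            rank_auc(expr, ["absent"], top_fraction=0.5)


class TestFindThreshold:
    def test_bimodal_valley_between_modes(self):
        r = np.random.default_rng(5)
        aucs = np.clip(
            np.concatenate([r.normal(0.05, 0.01, 500), r.normal(0.30, 0.02, 500)]),
            0, 1,
        )
        res = find_threshold(aucs)
        assert res.method == "bimodal"
        assert 0.10 < res.threshold < 0.25

    def test_unimodal_fallback_flagged(self):
        r = np.random.default_rng(6)
        aucs = r.normal(0.1, 0.01, 400)
        res = find_threshold(aucs)
        assert res.method == "unimodal"
        assert aucs.min() <= res.threshold <= aucs.max()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_threshold_within_observed_range(self, seed):
        r = np.random.default_rng(seed)
        aucs = r.beta(2, 5, size=300)
        res = find_threshold(aucs)
        assert aucs.min() <= res.threshold <= aucs.max()

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError):
            find_threshold(np.full(100, 0.2))


class TestLabelCells:
    def test_boundary_cell_is_negative(self):
        aucs = pd.Series([0.16, 0.161, 0.159], index=["c1", "c2", "c3"])
        labels = label_cells(aucs, 0.16)
        assert labels.tolist() == ["SG-", "SG+", "SG-"]

    def test_all_below_threshold(self):
        labels = label_cells(pd.Series([0.1, 0.1]), 0.5)
        assert (labels == "SG-").all()

    def test_mixture_recovery_with_misclassification_below_one_percent(self):
        r = np.random.default_rng(8)
        truth = np.array(["SG-"] * 500 + ["SG+"] * 500)
        aucs = pd.Series(
            np.clip(np.where(truth == "SG-", r.normal(0.05, 0.01, 1000),
                             r.normal(0.30, 0.02, 1000)), 0, 1)
        )
        thr = find_threshold(aucs.values)
        labels = label_cells(aucs, thr.threshold)
        assert (labels.values != truth).mean() < 0.01


class TestEndToEndRecovery:
    def test_planted_sg_population_recovered(self):
        cfg = SimulationConfig(seed=21, n_cells=600, sg_fraction=0.4)
        gene_set = [f"G{i + 1:04d}" for i in range(42)]
        cells, gt = generate_cells(cfg, gene_set)
        aucs = score_cells(cells, gene_set)
        thr = find_threshold(aucs.values)
        labels = label_cells(aucs, thr.threshold)
        truth = pd.Series(gt.true_cell_label)
        agreement = (labels.loc[truth.index] == truth).mean()
        assert agreement >= 0.95

    def test_no_planted_population_is_unimodal(self):
        cfg = SimulationConfig(seed=22, n_cells=400, sg_fraction=0.0)
        gene_set = [f"G{i + 1:04d}" for i in range(42)]
        cells, _ = generate_cells(cfg, gene_set)
        aucs = score_cells(cells, gene_set)
        assert find_threshold(aucs.values).method == "unimodal"


class TestCompareProportions:
    def test_identical_proportions(self):
        stat, p = chi_square_2x2([[50, 50], [50, 50]])
        assert stat == 0.0
        assert p == 1.0

    def test_hand_computed_expected_counts(self):
        # margins all 40, N=80 -> every expected count 20; chi2 = 4 * 100/20
        tab = np.array([[30, 10], [10, 30]])
        stat, p = chi_square_2x2(tab)
        expected = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
        assert stat == pytest.approx(((tab - expected) ** 2 / expected).sum())
        assert stat == pytest.approx(20.0)

    def test_row_permutation_symmetry(self):
        s1, _ = chi_square_2x2([[30, 10], [10, 30]])
        s2, _ = chi_square_2x2([[10, 30], [30, 10]])
        assert s1 == pytest.approx(s2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="exact"):
            chi_square_2x2([[0, 0], [10, 30]])

    def test_from_labels_and_groups(self):
        labels = pd.Series(["SG+"] * 48 + ["SG-"] * 52 + ["SG+"] * 38 + ["SG-"] * 62)
        groups = pd.Series(["responder"] * 100 + ["non-responder"] * 100)
        stat, p, tab = compare_proportions(labels, groups)
        assert tab.loc["SG+", "responder"] == 48
        assert tab.loc["SG+", "non-responder"] == 38
        assert p > 0.05  # 48% vs 38% at n=100 per arm is not significant


def test_packaged_gene_set_has_42_members():
    genes = spliceosome_gene_set()
    assert len(genes) == 42
    assert "SNRNP200" in genes and "PRPF8" in genes and "EFTUD2" in genes
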