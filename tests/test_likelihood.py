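"""Pruning likelihoods against oracles; optimization; aLRT branch support."""

import numpy as np
import pytest

from minspec import (
    Alignment,
    alrt_branch_support,
    jtt_model,
    optimize_parameters,
    parse_newick,
    simulate_evolution,
    site_likelihoods,
    transition_matrix,
    two_clade_tree,
)
from conftest import enumerate_alignment


class TestPruningOracles:
    def test_two_taxon_closed_form(self, jtt1):
        tree = parse_newick("(A:0.0,B:0.3)r;")
        aln = Alignment(names=["A", "B"], rows=["A", "C"])
        res = site_likelihoods(tree, jtt1, aln)
        p = transition_matrix(jtt1, 0.3).matrix
        a, c = 0, 4  # indices in ARNDCQ... order
        expected = np.log(jtt1.frequencies[a] * p[a, c])
        assert res.total_lnL == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize(
        "newick",
        [
            "((A:0.21,B:0.08)u:0.12,(C:0.3,D:0.05)v:0.07)r;",  # 4 leaves, rooted binary
            "((A:0.15,B:0.2)u:0.1,C:0.25,D:0.3)r;",  # trifurcating root
            "(((A:0.1,B:0.12)u:0.08,C:0.2)v:0.05,(D:0.3,E:0.07)w:0.11)r;",  # 5 leaves
        ],
    )
    def test_pruning_matches_enumeration(self, newick, jtt1):
        tree = parse_newick(newick)
        sim = simulate_evolution(tree, jtt1, 4, seed=11)
        # inject a gap to exercise missing-data handling
        rows = list(sim.alignment.rows)
        rows[0] = "-" + rows[0][1:]
        aln = Alignment(names=sim.alignment.names, rows=rows)
        res = site_likelihoods(tree, jtt1, aln)
        oracle_liks, _ = enumerate_alignment(tree, jtt1, aln)
        assert np.abs(np.exp(res.per_site_lnL) / oracle_liks - 1).max() < 1e-10

    def test_gamma_mixture_is_category_mean(self, four_taxon_tree):
        model = jtt_model(gamma_shape=0.6, n_categories=8)
        sim = simulate_evolution(four_taxon_tree, model, 30, seed=2)
        res = site_likelihoods(sim.tree, model, sim.alignment)
        per_cat = []
        for r in model.category_rates:
            scaled = sim.tree.copy()
            for n in scaled.postorder():
                n.length *= r
            per_cat.append(
                np.exp(site_likelihoods(scaled, jtt_model(n_categories=1),
                                        sim.alignment).per_site_lnL)
            )
        mix = np.log(np.mean(per_cat, axis=0))
        assert np.abs(mix - res.per_site_lnL).max() < 1e-10

    def test_category_weights_sum_to_one(self, four_taxon_tree, jtt_gamma):
        sim = simulate_evolution(four_taxon_tree, jtt_gamma, 50, seed=3)
        res = site_likelihoods(sim.tree, jtt_gamma, sim.alignment)
        assert np.abs(res.per_site_category_weights.sum(axis=1) - 1).max() < 1e-10
        assert res.total_lnL == pytest.approx(res.per_site_lnL.sum(), abs=1e-8)


class TestLikelihoodInvariances:
    def test_rerooting_preserves_likelihood(self, jtt_gamma):
        tree = parse_newick(
            "(((A:0.1,B:0.12)u:0.08,C:0.2)v:0.05,(D:0.3,E:0.07)w:0.11)r;"
        )
        sim = simulate_evolution(tree, jtt_gamma, 100, seed=4)
        base = site_likelihoods(sim.tree, jtt_gamma, sim.alignment).total_lnL
        for label, frac in (("u", 0.5), ("C", 0.3), ("w", 0.9)):
            rr = sim.tree.rerooted_at_edge(label, frac)
            lnl = site_likelihoods(rr, jtt_gamma, sim.alignment).total_lnL
            assert lnl == pytest.approx(base, abs=1e-8)

    def test_zero_length_branch_is_neutral(self, four_taxon_tree, jtt1):
        sim = simulate_evolution(four_taxon_tree, jtt1, 60, seed=5)
        base = site_likelihoods(sim.tree, jtt1, sim.alignment).total_lnL
        grafted = sim.tree.copy()
        u = grafted.find("u")
        from minspec.phylo import TreeNode

        extra = TreeNode("extra", 0.0)
        parent = u.parent
        parent.children.remove(u)
        extra.add_child(u)
        parent.add_child(extra)
        lnl = site_likelihoods(grafted, jtt1, sim.alignment).total_lnL
        assert lnl == pytest.approx(base, abs=1e-8)


class TestOptimization:
    def test_recovers_at_least_generating_likelihood(self, jtt1):
        tree = parse_newick("((A:0.2,B:0.1)u:0.15,(C:0.25,D:0.05)v:0.1)r;")
        sim = simulate_evolution(tree, jtt1, 500, seed=6)
        true_lnl = site_likelihoods(sim.tree, jtt1, sim.alignment).total_lnL
        perturbed = sim.tree.copy()
        for n in perturbed.postorder():
            n.length *= 2.0
        opt_tree, _, res = optimize_parameters(
            perturbed, jtt1, sim.alignment, optimize_gamma_shape=False
        )
        assert res.total_lnL >= true_lnl - 1e-6
        assert res.converged

    def test_two_taxon_branch_matches_grid_oracle(self, jtt1):
        tree = parse_newick("(A:0.0,B:0.2)r;")
        sim = simulate_evolution(tree, jtt1, 800, seed=7)
        opt_tree, _, res = optimize_parameters(
            tree, jtt1, sim.alignment, optimize_gamma_shape=False
        )
        t_hat = opt_tree.find("A").length + opt_tree.find("B").length
        # 1-D oracle: dense golden-section-free grid refinement
        grid = np.linspace(1e-6, 1.0, 2001)
        lnls = []
        for t in grid:
            work = tree.copy()
            work.find("B").length = t
            work.find("A").length = 0.0
            lnls.append(site_likelihoods(work, jtt1, sim.alignment).total_lnL)
        t_grid = grid[int(np.argmax(lnls))]
        assert abs(t_hat - t_grid) < 1e-3  # grid resolution 5e-4
        assert res.total_lnL >= max(lnls) - 1e-6

    def test_gamma_shape_recovery(self):
        # 5-taxon tree, 2000 sites at alpha = 0.8; estimate alpha only
        truth = 0.8
        model = jtt_model(gamma_shape=truth, n_categories=4)
        tree = parse_newick(
            "(((A:0.3,B:0.25)u:0.2,C:0.35)v:0.1,(D:0.15,E:0.4)w:0.2)r;"
        )
        estimates = []
        for seed in range(10):
            sim = simulate_evolution(tree, model, 2000, seed=seed)
            _, m_hat, _ = optimize_parameters(
                sim.tree, model.with_gamma_shape(2.0), sim.alignment,
                optimize_branch_lengths=False,
            )
            estimates.append(m_hat.gamma_shape)
        estimates = np.array(estimates)
        assert np.all(np.abs(estimates / truth - 1) < 0.25)


class TestBranchSupport:
    def test_strong_internal_edge_has_high_confidence(self, jtt1):
        for seed in (0, 1):
            tree = two_clade_tree(4, internal_length=0.5, pendant_length=0.1)
            sim = simulate_evolution(tree, jtt1, 500, seed=seed)
            sup = alrt_branch_support(sim.tree, jtt1, sim.alignment, "bridge")
            assert 2 * np.log(sup.aLR) > 0
            assert sup.chi2_confidence > 0.99

    def test_signal_free_data_gives_unit_ratio(self, jtt1):
        # perfectly symmetric (constant) alignment: every resolution of the
        # focal edge fits equally well, so the likelihood ratio is exactly 1
        # and the mixture null sits at its lower bound of 0.5
        tree = two_clade_tree(4, internal_length=0.0, pendant_length=0.1)
        names = sorted(tree.leaf_labels())
        aln = Alignment(names=names, rows=["AAWWLK"] * len(names))
        sup = alrt_branch_support(tree, jtt1, aln, "bridge")
        assert sup.aLR == pytest.approx(1.0, abs=1e-6)
        assert sup.chi2_confidence == pytest.approx(0.0, abs=1e-4)
        mix = alrt_branch_support(tree, jtt1, aln, "bridge", null="mixture")
        assert mix.chi2_confidence == pytest.approx(0.5, abs=1e-4)

    def test_zero_length_edge_is_not_significant(self, jtt1):
        # with a true zero-length edge the statistic is a null draw
        # (approximately chi-squared with 1 df), far from significance
        tree = two_clade_tree(4, internal_length=0.0, pendant_length=0.1)
        sim = simulate_evolution(tree, jtt1, 200, seed=8)
        sup = alrt_branch_support(sim.tree, jtt1, sim.alignment, "bridge")
        assert sup.chi2_confidence < 0.95

    def test_pendant_edge_rejected(self, jtt1):
        tree = two_clade_tree(4)
        sim = simulate_evolution(tree, jtt1, 10, seed=9)
        with pytest.raises(Exception, match="internal"):
            alrt_branch_support(sim.tree, jtt1, sim.alignment, "a1")
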