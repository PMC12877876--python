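import math

import numpy as np
import pytest

from divtree import (
    ModelParams,
    ReconTree,
    SimConfig,
    TimeGrid,
    bonferroni_select,
    fit_clock_mle,
    fit_mle,
    heterogeneity_test,
    likelihood_landscape,
    select_postnatal_clades,
    simulate_tree,
    tree_log_likelihood,
)
from divtree.inference import FitResult, LRTResult


def _lrt(p_value, clade=0, lam=1.0):
    dummy = FitResult(params=ModelParams(0.5, 1.0), log_likelihood=0.0)
    return LRTResult(
        focal_clade=clade, homogeneous=dummy, main=dummy, distinct=dummy,
        lambda_lr=lam, p_value=p_value,
    )


class TestFit:
    def test_pure_birth_boundary_recovery(self):
        tree = simulate_tree(SimConfig(q=0.0, mu=1.0, stop_size=200, seed=12))
        res = fit_mle(tree, 1.0, n_subintervals=200, coarse_shape=(5, 5))
        assert res.q <= 0.15  # truth q=0 sits on the boundary
        assert 0.7 < res.mu < 1.3

    def test_single_tree_estimates_inside_reference_envelope(self):
        """One 300-cell tree at (q, mu) = (0.75, 1): the MLE must land within
        the replicate-to-replicate scatter seen at this size."""
        tree = simulate_tree(SimConfig(q=0.75, mu=1.0, stop_size=300, seed=42))
        res = fit_mle(tree, 1.0, n_subintervals=200, coarse_shape=(7, 7))
        assert 0.55 <= res.q <= 0.92
        assert 0.75 <= res.mu <= 1.35
        assert np.isfinite(res.log_likelihood)

    def test_small_size_recovery_second_parameter_point(self):
        """Reduced-size recovery at (q, mu) = (0.25, 1)."""
        qs, mus = [], []
        for s in range(10):
            tree = simulate_tree(SimConfig(q=0.25, mu=1.0, stop_size=120, seed=300 + s))
            res = fit_mle(tree, 1.0, n_subintervals=150, coarse_shape=(5, 5))
            qs.append(res.q)
            mus.append(res.mu)
        assert abs(np.mean(qs) - 0.25) < 0.12
        assert abs(np.mean(mus) - 1.0) < 0.15

    def test_subsampled_tree_recovery_and_rho_misspecification(self):
        """At the true rho the MLE recovers the generating parameters; with a
        10x smaller assumed rho the fit compensates the extra implied hidden
        divisions with a lower mutation mean per division."""
        tree = simulate_tree(SimConfig(q=0.5, mu=1.0, rho=0.01, stop_size=8000, seed=8))
        assert tree.n_leaves >= 50
        kw = dict(n_subintervals=150, coarse_shape=(5, 5), i_max=200)
        r1 = fit_mle(tree, 0.01, **kw)
        assert abs(r1.q - 0.5) < 0.15
        assert abs(r1.mu - 1.0) < 0.25
        r2 = fit_mle(tree, 0.001, **kw)
        assert r2.mu < r1.mu  # fewer mutations per division when more
        assert np.isfinite(r2.log_likelihood)  # divisions are implied hidden

    def test_clock_fit_runs_and_reports_finite_likelihood(self, small_sim_tree):
        res = fit_clock_mle(small_sim_tree, 1.0, n_subintervals=150, coarse_shape=(5, 5))
        assert np.isfinite(res.log_likelihood)
        assert 0.0 <= res.params.q <= 0.98

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_mle([], 1.0)


class TestLandscape:
    def test_maximum_matches_coarse_fit_stage(self, small_sim_tree):
        qs = np.linspace(0.0, 0.9, 7)
        mus = np.linspace(0.5, 2.0, 7)
        mat = likelihood_landscape(small_sim_tree, 1.0, qs, mus, n_subintervals=150)
        assert mat.shape == (7, 7)
        res = fit_mle(small_sim_tree, 1.0, n_subintervals=150,
                      q_bounds=(0.0, 0.9), mu_bounds=(0.5, 2.0), coarse_shape=(7, 7))
        coarse = [t for t in res.trace[: qs.size * mus.size]]
        best_coarse = max(v for _, _, v in coarse)
        # fit's coarse stage scans mu geometrically; compare maxima loosely
        assert res.log_likelihood >= np.nanmax(mat) - 1e-6
        assert np.isfinite(best_coarse)

    def test_invariant_under_leaf_order(self, small_sim_tree):
        t = small_sim_tree
        swapped = ReconTree(t.parent, t.mutations, t.labels)
        for v in range(swapped.n_nodes):
            swapped.children[v] = swapped.children[v][::-1]
        qs, mus = [0.3, 0.6], [0.8, 1.2]
        a = likelihood_landscape(t, 1.0, qs, mus, n_subintervals=150)
        b = likelihood_landscape(swapped, 1.0, qs, mus, n_subintervals=150)
        np.testing.assert_array_equal(a, b)

    def test_two_leaf_pure_birth_matches_closed_form(self):
        tree = ReconTree([-1, 0, 0], [0, 1, 2])
        mus = np.array([0.5, 1.0, 1.5])
        mat = likelihood_landscape(tree, 1.0, [0.0], mus, n_subintervals=400)
        for j, mu in enumerate(mus):
            direct = tree_log_likelihood(
                tree, ModelParams(0.0, mu, 1.0),
                grid=TimeGrid(2 * math.log(2), 400),
            )
            assert mat[0, j] == pytest.approx(direct, abs=1e-12)

    def test_floor_masking(self, small_sim_tree):
        mat = likelihood_landscape(
            small_sim_tree, 1.0, [0.0, 0.5], [1.0], n_subintervals=100, floor=-1e8
        )
        assert not np.any(np.isnan(mat))


class TestCladeSelection:
    def build(self, depths_and_sizes):
        """Tree whose root has one shallow cherry plus deep clades at the
        given (root distance, n_leaves)."""
        parent, mut = [-1], [0]

        def add(p, m):
            parent.append(p)
            mut.append(m)
            return len(parent) - 1

        # root children: a backbone node and a shallow leaf
        backbone = add(0, 1)
        add(0, 5)
        for depth, size in depths_and_sizes:
            top = add(backbone, depth - 1)  # backbone edge carries depth-1
            # caterpillar clade with `size` leaves, tiny internal branches
            node = top
            for k in range(size - 1):
                add(node, 2)  # leaf
                if k < size - 2:
                    node = add(node, 1)
                else:
                    add(node, 2)  # final leaf
            backbone = add(backbone, 0)
        # make backbone tip a leaf
        return ReconTree(parent, mut)

    def test_all_tips_shallow_gives_empty_list(self):
        star = ReconTree([-1, 0, 0, 1, 1], [0, 10, 20, 30, 30])
        assert select_postnatal_clades(star, 100, 2) == []

    def test_threshold_is_strict(self):
        # clade root at exactly 100 mutations from the root -> excluded
        parent = [-1, 0, 0, 1, 1]
        tree_eq = ReconTree(parent, [0, 100, 1, 5, 5])
        assert select_postnatal_clades(tree_eq, 100, 2) == []
        tree_gt = ReconTree(parent, [0, 101, 1, 5, 5])
        assert select_postnatal_clades(tree_gt, 100, 2) == [1]

    def test_size_filter_keeps_only_large_deep_clade(self):
        tree = self.build([(150, 30), (150, 10)])
        got = select_postnatal_clades(tree, 100, 23)
        nleaves = tree.leaf_counts()
        assert len(got) == 1
        assert nleaves[got[0]] == 30

    def test_selected_clades_are_disjoint_and_maximal(self):
        tree = self.build([(150, 30), (160, 25)])
        got = select_postnatal_clades(tree, 100, 23)
        assert len(got) == 2
        dist = tree.root_distances()
        assert all(dist[v] > 100 for v in got)
        # no selected clade is an ancestor of another
        for v in got:
            sub = tree.subtree(v)
            assert sub.n_leaves >= 23


class TestHeterogeneityTest:
    @pytest.mark.parametrize("lam, expected_p", [(16.23, 3.0e-4), (6.17, 0.046)])
    def test_chi2_two_df_p_values(self, lam, expected_p):
        """chi-squared(2) survival function: p = exp(-lambda/2)."""
        r = LRTResult(
            focal_clade=0,
            homogeneous=FitResult(params=ModelParams(0.5, 1.0), log_likelihood=0.0),
            main=FitResult(params=ModelParams(0.5, 1.0), log_likelihood=0.0),
            distinct=FitResult(params=ModelParams(0.5, 1.0), log_likelihood=0.0),
            lambda_lr=lam,
        )
        assert r.p_value == pytest.approx(math.exp(-lam / 2), rel=1e-10)
        assert r.p_value == pytest.approx(expected_p, abs=0.5e-3)

    def test_nesting_heterogeneous_at_least_homogeneous(self):
        rng = np.random.default_rng(77)
        clades = [
            simulate_tree(SimConfig(q=0.5, mu=1.0, stop_size=25), rng)
            for _ in range(3)
        ]
        res = heterogeneity_test(
            clades, 0, 1.0, n_subintervals=100, coarse_shape=(5, 5)
        )
        assert res.lambda_lr >= -0.2  # optimizer tolerance
        assert res.df == 2
        assert 0.0 <= res.p_value <= 1.0

    def test_detects_planted_heterogeneous_clade(self):
        rng = np.random.default_rng(78)
        clades = [
            simulate_tree(SimConfig(q=0.2, mu=1.0, stop_size=40), rng)
            for _ in range(3)
        ] + [simulate_tree(SimConfig(q=0.2, mu=4.0, stop_size=40), rng)]
        res = heterogeneity_test(
            clades, 3, 1.0, n_subintervals=100, coarse_shape=(5, 5)
        )
        assert res.p_value < 1e-4
        assert res.distinct.mu > res.main.mu + 1.0


class TestBonferroni:
    def test_reference_eight_clade_scenario(self):
        """Eight tested scenarios; only the p=3e-4 one clears alpha/8."""
        pvals = [0.046, 0.549, 0.321, 0.484, 0.419, 0.657, 0.0003, 0.338]
        results = [_lrt(p, clade=k) for k, p in enumerate(pvals)]
        kept = bonferroni_select(results, alpha=0.05)
        assert [r.focal_clade for r in kept] == [6]

    def test_empty_input(self):
        assert bonferroni_select([], alpha=0.05) == []

    def test_alpha_one_threshold_formula(self):
        results = [_lrt(p) for p in (0.1, 0.3, 0.6)]
        kept = bonferroni_select(results, alpha=1.0)
        assert [r.p_value for r in kept] == [0.1, 0.3]
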