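import itertools

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from portalphylo.trees import (
    BALANCED,
    BRANCH_NAMES,
    CATERPILLAR,
    PARAM_NAMES,
    DistanceMatrix,
    RootedTopology,
    TreeInferenceError,
    build_design,
    distance_matrix_from_alignments,
    enumerate_varieties,
    evolutionary_distance,
    fit_tree,
    r_factor,
    rank_trees,
    ranking_table,
    solve_fit,
    to_newick,
)
from portalphylo.synthetic import (
    SyntheticTreeSpec,
    distances_from_tree,
    random_tree_spec,
    ultrametric_branches,
)
from oracles import brute_force_varieties

LABELS = ("A", "B", "C", "D")


def _spec(shape, leaves=LABELS, heights=(13.0, 29.0, 71.0), **kw):
    return SyntheticTreeSpec(
        shape=shape, leaves=leaves,
        branches=ultrametric_branches(shape, heights), **kw,
    )


class TestEvolutionaryDistance:
    @pytest.mark.parametrize(
        "P,r,scheme,expected",
        [
            (600, 600, "subtractive", 0.0),
            (600, 600, "ratio", 100.0),
            (600, 200, "subtractive", 400.0),
            (600, 200, "ratio", 300.0),
        ],
    )
    def test_arithmetic(self, P, r, scheme, expected):
        assert evolutionary_distance(P, r, scheme) == pytest.approx(expected)

    def test_r_exceeding_P_rejected_for_subtractive(self):
        with pytest.raises(TreeInferenceError, match="exceeds"):
            evolutionary_distance(600, 601, "subtractive")

    def test_zero_r_rejected_for_ratio(self):
        with pytest.raises(TreeInferenceError, match="r > 0"):
            evolutionary_distance(600, 0, "ratio")

    def test_unknown_scheme(self):
        with pytest.raises(TreeInferenceError, match="scheme"):
            evolutionary_distance(600, 100, "loglinear")


class TestDistanceMatrixFromAlignments:
    def _equivs(self, rs):
        return {
            frozenset(pair): r
            for pair, r in zip(itertools.combinations(LABELS, 2), rs)
        }

    def test_equal_r_gives_equal_distances(self):
        D = distance_matrix_from_alignments(self._equivs([300] * 6), P=600,
                                            scheme="subtractive")
        off = D.d[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 300.0)

    def test_matches_hand_computation(self):
        rs = [500, 400, 300, 450, 350, 250]
        D = distance_matrix_from_alignments(self._equivs(rs), P=600,
                                            scheme="ratio")
        for (t1, t2), r in zip(itertools.combinations(LABELS, 2), rs):
            assert D.get(t1, t2) == pytest.approx(100.0 * 600 / r)

    def test_missing_pair_rejected(self):
        eq = self._equivs([300] * 6)
        del eq[frozenset(("A", "B"))]
        with pytest.raises(TreeInferenceError, match="missing pair"):
            distance_matrix_from_alignments(eq)


class TestEnumeration:
    def test_counts(self):
        ts = enumerate_varieties(LABELS)
        assert len(ts) == 15
        assert sum(t.shape == BALANCED for t in ts) == 3
        assert sum(t.shape == CATERPILLAR for t in ts) == 12

    def test_matches_brute_force_canonicalisation(self):
        ts = enumerate_varieties(LABELS)
        for shape, expected_n in ((BALANCED, 3), (CATERPILLAR, 12)):
            oracle = brute_force_varieties(shape, LABELS)
            assert len(oracle) == expected_n
            mine = {t.leaves for t in ts if t.shape == shape}
            assert len(mine) == expected_n
            # one enumerated variety per symmetry orbit, covering all orbits
            assert {min(_orbit(shape, leaves)) for leaves in mine} == oracle

    def test_ids_stable_and_deterministic(self):
        a = enumerate_varieties(LABELS)
        b = enumerate_varieties(LABELS)
        assert [(t.variety_id, t.leaves) for t in a] == \
               [(t.variety_id, t.leaves) for t in b]
        assert [t.variety_id for t in a][:4] == ["1.1", "1.2", "1.3", "2.1"]

    def test_label_order_irrelevant(self):
        a = {(t.shape, t.leaves) for t in enumerate_varieties(("D", "B", "A", "C"))}
        b = {(t.shape, t.leaves) for t in enumerate_varieties(LABELS)}
        assert a == b

    def test_three_labels_rejected(self):
        with pytest.raises(TreeInferenceError, match="4 distinct"):
            enumerate_varieties(("A", "B", "C"))

    def test_duplicate_labels_rejected(self):
        with pytest.raises(TreeInferenceError, match="4 distinct"):
            enumerate_varieties(("A", "A", "B", "C"))


def _orbit(shape, leaves):
    from oracles import _BALANCED_GENS, _CATERPILLAR_GENS, _close_group

    gens = _BALANCED_GENS if shape == BALANCED else _CATERPILLAR_GENS
    return {tuple(leaves[g[i]] for i in range(4)) for g in _close_group(gens)}


def _uniform_matrix(value=100.0):
    d = np.full((4, 4), value)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=list(LABELS), d=d)


class TestDesignSystem:
    def test_dimensions_with_root_rows(self):
        for topo in enumerate_varieties(LABELS):
            sys = build_design(topo, _uniform_matrix(), include_root_rows=True)
            assert sys.A.shape == (10, 7)
            assert sys.row_kind.count("pairwise") == 6
            assert sys.row_kind.count("root") == 4

    def test_dimensions_without_root_rows(self):
        topo = enumerate_varieties(LABELS)[0]
        sys = build_design(topo, _uniform_matrix(), include_root_rows=False)
        assert sys.A.shape == (6, 7)

    def test_row_structure(self):
        topo = enumerate_varieties(LABELS)[0]
        sys = build_design(topo, _uniform_matrix(), include_root_rows=True)
        A = sys.A
        pair_rows, root_rows = A[:6], A[6:]
        assert set(np.unique(pair_rows)) <= {0.0, 1.0}
        assert np.all(pair_rows[:, 6] == 0)
        assert np.all(root_rows[:, 6] == -1)
        assert np.all(sys.y[6:] == 0)

    def test_caterpillar_cherry_row(self):
        """The AB row of (((A,B),C),D) touches exactly the two cherry branches."""
        topo = RootedTopology(shape=CATERPILLAR, leaves=LABELS, variety_id="x")
        sys = build_design(topo, _uniform_matrix(), include_root_rows=False)
        ab_row = sys.A[sys.pair_order.index(("A", "B"))]
        np.testing.assert_array_equal(ab_row, [1, 1, 0, 0, 0, 0, 0])

    def test_paths_against_explicit_edge_list(self):
        """Pairwise rows equal path indicators from an explicit edge list."""
        # caterpillar (((A,B),C),D): edges (node, parent, branch)
        edges = {
            "A": ("n1", "a"), "B": ("n1", "b"), "n1": ("n2", "c"),
            "C": ("n2", "d"), "n2": ("R", "e"), "D": ("R", "f"),
        }

        def path_to_root(leaf):
            branches, node = [], leaf
            while node != "R":
                parent, br = edges[node]
                branches.append(br)
                node = parent
            return branches

        topo = RootedTopology(shape=CATERPILLAR, leaves=LABELS, variety_id="x")
        sys = build_design(topo, _uniform_matrix(), include_root_rows=True)
        for row, (t1, t2) in zip(sys.A[:6], sys.pair_order):
            p1, p2 = path_to_root(t1), path_to_root(t2)
            expected = set(p1).symmetric_difference(p2)
            got = {BRANCH_NAMES[i] for i in range(6) if row[i] == 1}
            assert got == expected, (t1, t2)
        for row, leaf in zip(sys.A[6:], sorted(LABELS)):
            got = {BRANCH_NAMES[i] for i in range(6) if row[i] == 1}
            assert got == set(path_to_root(leaf))

    def test_label_mismatch(self):
        topo = enumerate_varieties(("W", "X", "Y", "Z"))[0]
        with pytest.raises(TreeInferenceError, match="absent"):
            build_design(topo, _uniform_matrix())


class TestSolveFit:
    def test_exact_recovery_full_rank(self):
        topo = enumerate_varieties(LABELS)[5]
        rng = np.random.default_rng(0)
        true = rng.uniform(5, 50, size=7)
        sys = build_design(topo, _uniform_matrix(), include_root_rows=True)
        sys.y = sys.A @ true
        sol = solve_fit(sys)
        assert not sol.rank_deficient
        np.testing.assert_allclose(sol.params, true, atol=1e-10)

    def test_pairwise_only_reproduces_additive_distances(self):
        """Min-norm 6-row fit reproduces additive observations exactly but
        flags the non-identifiable root-adjacent branches."""
        spec = _spec(CATERPILLAR)
        D, _ = distances_from_tree(spec)
        topo = next(t for t in enumerate_varieties(LABELS)
                    if t.shape == CATERPILLAR and t.leaves == LABELS)
        sys = build_design(topo, D, include_root_rows=False)
        sol = solve_fit(sys)
        assert sol.rank_deficient
        np.testing.assert_allclose(sys.A @ sol.params, sys.y, atol=1e-9)

    def test_perturbation_bounds_residual(self):
        topo = enumerate_varieties(LABELS)[5]
        rng = np.random.default_rng(1)
        true = rng.uniform(5, 50, size=7)
        sys = build_design(topo, _uniform_matrix(), include_root_rows=True)
        sys.y = sys.A @ true
        eps = 0.3
        sys.y[2] += eps
        sol = solve_fit(sys)
        assert np.linalg.norm(sol.residuals) <= eps + 1e-12


class TestRFactor:
    def test_perfect_fit(self):
        obs = np.array([10.0, 20, 30, 40, 50, 60])
        assert r_factor(obs, obs) == 0.0

    def test_proportional_offset(self):
        obs = np.array([10.0, 20, 30, 40, 50, 60])
        assert r_factor(obs, 1.1 * obs) == pytest.approx(0.1)

    def test_single_element_arithmetic(self):
        obs = np.full(6, 10.0)
        calc = np.array([10.0, 10, 10, 10, 10, 16])
        assert r_factor(obs, calc) == pytest.approx(0.1)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(TreeInferenceError, match="non-positive"):
            r_factor(np.zeros(6), np.ones(6))

    @given(scale=st.floats(0.1, 1000.0), seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        obs = rng.uniform(1, 100, 6)
        calc = rng.uniform(1, 100, 6)
        assert r_factor(scale * obs, scale * calc) == pytest.approx(
            r_factor(obs, calc))


class TestFitTree:
    def test_ultrametric_truth_fits_exactly(self):
        spec = _spec(CATERPILLAR)
        D, truth = distances_from_tree(spec)
        topo = next(t for t in enumerate_varieties(LABELS) if truth.matches(t))
        fit = fit_tree(topo, D)
        assert fit.r_all <= 1e-10
        assert fit.feasible
        for name in BRANCH_NAMES:
            assert fit.params[name] == pytest.approx(spec.branches[name], abs=1e-8)
        assert fit.params["g"] == pytest.approx(71.0, abs=1e-8)

    def test_wrong_topologies_have_positive_residual(self):
        spec = _spec(CATERPILLAR)
        D, truth = distances_from_tree(spec)
        for topo in enumerate_varieties(LABELS):
            fit = fit_tree(topo, D)
            if truth.matches(topo):
                assert fit.r_all <= 1e-10
            else:
                assert fit.r_all > 1e-6

    def test_additive_but_not_ultrametric(self):
        """Clock violation: the pairwise fit is exact, the 10-row fit is not."""
        branches = dict(zip(BRANCH_NAMES, (1.0, 5.0, 2.0, 3.0, 2.0, 10.0)))
        spec = SyntheticTreeSpec(shape=CATERPILLAR, leaves=LABELS,
                                 branches=branches, ultrametric=False)
        D, truth = distances_from_tree(spec)
        topo = next(t for t in enumerate_varieties(LABELS) if truth.matches(t))
        fit = fit_tree(topo, D)
        assert fit.r_pair <= 1e-10
        assert fit.r_all > 1e-4


class TestRankTrees:
    @pytest.mark.parametrize("shape", [CATERPILLAR, BALANCED])
    def test_noiseless_truth_ranks_first(self, shape):
        spec = _spec(shape)
        D, truth = distances_from_tree(spec)
        fits = rank_trees(D)
        assert truth.matches(fits[0].topology)
        assert fits[0].r_all <= 1e-10
        assert fits[0].feasible

    def test_generating_variety_minimises_r_all(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            spec = random_tree_spec(rng)
            D, truth = distances_from_tree(spec)
            fits = rank_trees(D)
            best_r = min(f.r_all for f in fits)
            truth_fit = next(f for f in fits if truth.matches(f.topology))
            assert truth_fit.r_all <= best_r + 1e-12

    def test_stochastic_recovery(self):
        """σ = 2% noise, 200 frozen replicates: truth ranks first ≥ 95%."""
        wins = 0
        for s in range(200):
            rng = np.random.default_rng(10_000 + s)
            spec = random_tree_spec(rng, noise_sigma=0.02, shape=CATERPILLAR)
            D, truth = distances_from_tree(spec)
            wins += truth.matches(rank_trees(D)[0].topology)
        assert wins >= 190

    def test_scheme_robustness(self):
        """Best variety identical under subtractive and ratio schemes."""
        rs = {
            frozenset(p): r for p, r in zip(
                itertools.combinations(LABELS, 2),
                [520, 430, 300, 460, 310, 330],
            )
        }
        bests = {}
        for scheme in ("subtractive", "ratio"):
            D = distance_matrix_from_alignments(rs, P=600, scheme=scheme)
            bests[scheme] = rank_trees(D)[0].variety_id
        assert bests["subtractive"] == bests["ratio"]

    def test_ratio_ranking_invariant_to_P(self):
        rs = {
            frozenset(p): r for p, r in zip(
                itertools.combinations(LABELS, 2),
                [520, 430, 300, 460, 310, 330],
            )
        }
        orders = []
        for P in (300, 600, 1000):
            D = distance_matrix_from_alignments(rs, P=P, scheme="ratio")
            orders.append([f.variety_id for f in rank_trees(D)])
        assert orders[0] == orders[1] == orders[2]

    def test_report_includes_both_r_factors(self):
        D, _ = distances_from_tree(_spec(BALANCED))
        table = ranking_table(rank_trees(D))
        assert len(table) == 15
        assert {"r_all", "r_pair", "feasible", "arrangement"} <= set(table.columns)

    def test_wrong_taxon_count_rejected(self):
        d = np.zeros((3, 3))
        D = DistanceMatrix(labels=["A", "B", "C"], d=d)
        with pytest.raises(TreeInferenceError, match="4 taxa"):
            rank_trees(D)


class TestNewick:
    def test_unit_caterpillar_string(self):
        from portalphylo.trees import TreeFit

        topo = RootedTopology(shape=CATERPILLAR, leaves=LABELS, variety_id="2.1")
        unit = dict(zip(PARAM_NAMES, [1.0] * 7))
        fit = TreeFit(
            topology=topo, params=unit, params_pair=unit,
            fitted_pairwise=np.ones(6), observed_pairwise=np.ones(6),
            pair_order=list(itertools.combinations(LABELS, 2)),
            r_all=0.0, r_pair=0.0, feasible=True, pair_rank_deficient=False,
        )
        assert to_newick(fit).replace(" ", "") == "(((A:1,B:1):1,C:1):1,D:1);"

    def test_round_trip_topology_and_lengths(self):
        D, _ = distances_from_tree(_spec(CATERPILLAR))
        fit = rank_trees(D)[0]
        tree = dendropy.Tree.get(data=to_newick(fit), schema="newick")
        lengths = {leaf.taxon.label: leaf.edge.length
                   for leaf in tree.leaf_node_iter()}
        l1, l2, l3, l4 = fit.topology.leaves
        assert lengths[l1] == pytest.approx(fit.params["a"], abs=1e-9)
        assert lengths[l4] == pytest.approx(fit.params["f"], abs=1e-9)

    def test_balanced_shape_has_two_internal_nodes(self):
        D, _ = distances_from_tree(_spec(BALANCED))
        fit = next(f for f in rank_trees(D) if f.topology.shape == BALANCED)
        tree = dendropy.Tree.get(data=to_newick(fit), schema="newick")
        internal = [n for n in tree.preorder_node_iter()
                    if not n.is_leaf() and n is not tree.seed_node]
        assert len(internal) == 2

    def test_infeasible_fit_flagged(self):
        D, truth = distances_from_tree(_spec(CATERPILLAR))
        worst = rank_trees(D)[-1]
        assert not worst.feasible
        assert to_newick(worst).startswith("[&infeasible]")


class TestDistanceMatrixIO:
    def test_phylip_square_round_trip(self, tmp_path):
        D, _ = distances_from_tree(_spec(BALANCED))
        p = tmp_path / "d.phy"
        D.to_phylip(p)
        D2 = DistanceMatrix.from_phylip(p)
        assert D2.labels == D.labels
        np.testing.assert_allclose(D2.d, D.d, atol=1e-6)

    def test_lower_triangle_read(self, tmp_path):
        p = tmp_path / "lt.phy"
        p.write_text("4\nA\nB 12.0\nC 13.0 23.0\nD 14.0 24.0 34.0\n")
        D = DistanceMatrix.from_phylip(p)
        assert D.get("A", "B") == 12.0
        assert D.get("C", "D") == 34.0
        np.testing.assert_allclose(D.d, D.d.T)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1, 2, 3], [1, 0, 4, 5], [2, 4, 0, 6], [3, 5, 7, 0]])
        with pytest.raises(TreeInferenceError, match="symmetric"):
            DistanceMatrix(labels=list(LABELS), d=d)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(TreeInferenceError, match="unique"):
            DistanceMatrix(labels=["A", "A", "B", "C"], d=np.zeros((4, 4)))
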