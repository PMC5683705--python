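import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_expr, make_labels
from netmod.errors import ConfigError, DataError
from netmod.io import ExpressionMatrix, GeneModule, PPINetwork, PhenotypeLabels
from netmod.modules import (activity_score, build_module_set,
                            coexpression_fraction, default_bins, discretize,
                            grow_module, module_expression)
from oracles import exhaustive_best_module, mi_oracle


class TestModuleExpression:
    def test_single_member_is_gene_row(self, small_expr):
        np.testing.assert_array_equal(
            module_expression(["GA"], small_expr), small_expr.gene_row("GA"))

    def test_opposite_rows_cancel(self):
        labels = make_labels(2, 2)
        z = np.array([1.0, -2.0, 0.5, 3.0])
        expr = make_expr(["p", "m"], np.vstack([z, -z]), labels)
        np.testing.assert_allclose(module_expression(["p", "m"], expr), 0.0)

    def test_matches_direct_column_mean(self, rng):
        labels = make_labels(3, 3)
        vals = rng.normal(0, 1, (3, 6))
        expr = make_expr(["a", "b", "c"], vals, labels)
        np.testing.assert_allclose(module_expression(["a", "b", "c"], expr),
                                   vals.mean(axis=0))

    def test_unknown_member_errors(self, small_expr):
        with pytest.raises(DataError, match="GHOST"):
            module_expression(["GA", "GHOST"], small_expr)


class TestDiscretize:
    def test_four_bins_arithmetic(self):
        x = np.array([-2.0, -1.5, -0.5, 0.5, 1.5, 2.0])
        b = discretize(x, 4)
        # splits at -1, 0, 1; value 0.5 -> third bin (index 2)
        assert b.tolist() == [0, 0, 1, 2, 3, 3]

    def test_split_point_goes_to_higher_bin(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        b = discretize(x, 4)  # splits at 1, 2, 3
        assert b[1] == 1 and b[2] == 2 and b[3] == 3

    def test_max_in_last_bin_and_constant_in_first(self):
        assert discretize(np.array([0.0, 5.0]), 3)[1] == 2
        assert discretize(np.full(4, 2.5), 5).tolist() == [0, 0, 0, 0]

    def test_too_few_bins(self):
        with pytest.raises(ConfigError):
            discretize(np.array([1.0, 2.0]), 1)

    def test_default_bins_sturges_capped(self):
        assert default_bins(100) == 7
        assert default_bins(10 ** 6) == 10
        assert default_bins(2) == 2


class TestActivityScore:
    def test_constant_x_gives_zero(self):
        assert activity_score(np.full(8, 1.0),
                              np.array([0, 1] * 4), 3) == 0.0

    def test_perfectly_separating_diagonal(self):
        x = np.array([-1.0, -1.0, 1.0, 1.0])
        y = np.array([0, 0, 1, 1])
        assert activity_score(x, y, 2) == pytest.approx(1.0)

    def test_bounded_by_label_entropy(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, 30)
            y = rng.integers(0, 2, 30)
            py = y.mean()
            hy = 0.0 if py in (0, 1) else -(py * np.log2(py)
                                            + (1 - py) * np.log2(1 - py))
            assert 0 <= activity_score(x, y, 4) <= hy + 1e-12

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            activity_score(np.zeros(3), np.zeros(4, dtype=int), 2)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(6, 60))
            x = rng.normal(0, 1, n)
            y = rng.integers(0, 2, n)
            nb = int(rng.integers(2, 9))
            assert activity_score(x, y, nb) == pytest.approx(
                mi_oracle(x, y, nb), abs=1e-12)

    def test_class_relabel_invariance(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.integers(0, 2, 40)
        assert activity_score(x, y, 5) == pytest.approx(
            activity_score(x, 1 - y, 5), abs=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1),
           st.sampled_from([0.5, 1.0, 2.0, 3.0]),
           st.sampled_from([-1.0, 0.0, 0.5, 2.0]))
    def test_affine_invariance(self, seed, a, b):
        r = np.random.default_rng(seed)
        x = r.normal(0, 1, 30)
        y = r.integers(0, 2, 30)
        assert activity_score(a * x + b, y, 4) == pytest.approx(
            activity_score(x, y, 4), abs=1e-9)


def _planted_path_data(rng, shift=2.0, sd=0.5, n=40):
    """6-node path A-B-C-D-E-F; A,B,C carry the tumor shift."""
    labels = make_labels(n, n)
    genes = ["A", "B", "C", "D", "E", "F"]
    Z = rng.normal(0, 1, (6, 2 * n))
    for i in range(3):
        Z[i] = rng.normal(0, sd, 2 * n)
        Z[i, :n] += shift
    expr = make_expr(genes, Z, labels)
    net = PPINetwork.from_edges(zip(genes[:-1], genes[1:]))
    return expr, labels, net


class TestGrowModule:
    def test_isolated_seed_stays_singleton(self, small_expr, small_labels):
        net = PPINetwork.from_edges([("GB", "GC")])
        mod = grow_module("GA", net, small_expr, small_labels, n_bins=2)
        assert mod.members == ("GA",)
        assert mod.activity_score == pytest.approx(
            activity_score(small_expr.gene_row("GA"),
                           small_labels.labels, 2))

    def test_recovers_planted_block_on_path(self):
        # complementary 3-gene signal block: each member separates the
        # classes only partially, their average separates perfectly, so
        # the greedy must take exactly A, B, C and then stop
        labels = make_labels(3, 3)
        rows = np.array([
            [3, 0, 0, 0, 0, -3],
            [0, 3, 0, 0, -3, 0],
            [0, 0, 3, -3, 0, 0],
            [0.1, -0.2, 0.3, -0.1, 0.2, -0.3],
            [-0.2, 0.1, 0.0, 0.3, -0.1, 0.2],
            [0.0, 0.2, -0.1, 0.1, -0.3, 0.0],
        ], dtype=float)
        expr = make_expr(list("ABCDEF"), rows, labels)
        net = PPINetwork.from_edges(zip("ABCDE", "BCDEF"))
        mod = grow_module("A", net, expr, labels, n_bins=2, max_size=6)
        assert mod.members == ("A", "B", "C")
        assert mod.activity_score == pytest.approx(1.0)

    def test_greedy_bounded_by_exhaustive(self, rng):
        expr, labels, net = _planted_path_data(rng)
        y = labels.labels
        graph = net.to_networkx()

        def score(sub):
            return activity_score(module_expression(list(sub), expr), y, 4)

        best, _ = exhaustive_best_module(graph, score, 6)
        for seed in "ABCDEF":
            mod = grow_module(seed, net, expr, labels, n_bins=4, max_size=6)
            assert mod.activity_score <= best + 1e-12

    def test_score_strictly_increases_along_growth(self, rng):
        expr, labels, net = _planted_path_data(rng)
        mod = grow_module("A", net, expr, labels, n_bins=4, max_size=6)
        prefix_scores = [
            activity_score(module_expression(mod.members[:k], expr),
                           labels.labels, 4)
            for k in range(1, mod.size + 1)]
        assert np.all(np.diff(prefix_scores) > 0)

    def test_missing_seed_errors(self, small_expr, small_labels, path_network):
        with pytest.raises(DataError):
            grow_module("NOPE", path_network, small_expr, small_labels)


class TestBuildModuleSet:
    def test_duplicate_member_sets_collapsed(self):
        # complementary noise pair: from either seed the greedy grows the
        # same two-gene set, which dedups to a single module record
        labels = make_labels(4, 4)
        s = np.array([2, 2, 2, 2, -2, -2, -2, -2], dtype=float)
        e = np.array([1, -3, 0, 2, -1, 3, 0, -2], dtype=float)
        expr = make_expr(["a", "b"], np.vstack([s + e, s - e]), labels)
        net = PPINetwork.from_edges([("a", "b")])
        mods = build_module_set(net, expr, labels, n_bins=2)
        assert len(mods) == 1
        assert set(mods[0].members) == {"a", "b"}

    def test_at_most_one_module_per_gene(self, rng):
        expr, labels, net = _planted_path_data(rng)
        mods = build_module_set(net, expr, labels, n_bins=4)
        assert len(mods) <= expr.n_genes
        assert len({frozenset(m.members) for m in mods}) == len(mods)

    def test_result_deterministic(self, rng):
        expr, labels, net = _planted_path_data(rng)
        a = build_module_set(net, expr, labels, n_bins=4)
        b = build_module_set(net, expr, labels, n_bins=4)
        assert a == b


class TestCoexpressionFraction:
    def test_identical_members_fully_coexpressed(self):
        labels = make_labels(3, 3)
        row = np.arange(6.0)
        expr = make_expr(["a", "b", "c"], np.vstack([row, row, row]), labels)
        mod = GeneModule("a", ("a", "b", "c"), 0.5)
        assert coexpression_fraction(mod, expr) == 1.0

    def test_anticorrelated_pair_not_coexpressed(self):
        labels = make_labels(3, 3)
        row = np.arange(6.0)
        expr = make_expr(["a", "b"], np.vstack([row, -row]), labels)
        mod = GeneModule("a", ("a", "b"), 0.5)
        assert coexpression_fraction(mod, expr) == 0.0

    def test_independent_members_rarely_exceed_threshold(self, rng):
        labels = make_labels(100, 100)
        vals = rng.normal(0, 1, (6, 200))
        expr = make_expr([f"g{i}" for i in range(6)], vals, labels)
        mod = GeneModule("g0", tuple(f"g{i}" for i in range(6)), 0.5)
        # null P(r >= 0.3) at n=200 is ~1e-5; the fraction should be ~0
        assert coexpression_fraction(mod, expr) < 0.2

    def test_singleton_returns_one_with_warning(self, small_expr, caplog):
        mod = GeneModule("GA", ("GA",), 0.5)
        with caplog.at_level("WARNING"):
            assert coexpression_fraction(mod, small_expr) == 1.0
        assert "singleton" in caplog.text
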