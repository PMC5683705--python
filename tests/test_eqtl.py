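import numpy as np
import pytest
from scipy import stats

from conftest import make_expr, make_labels
from netmod.errors import DataError
from netmod.eqtl import (driver_summary, eqtl_scan, link_mutations_to_modules,
                         mutual_exclusivity_test)
from netmod.io import GeneModule, MutationMatrix
from oracles import fisher_two_sided_oracle


def _mut(genes, samples, status):
    return MutationMatrix(tuple(genes), tuple(samples), np.asarray(status))


class TestEqtlScan:
    def test_null_gene_has_flat_association(self, rng):
        labels = make_labels(30, 0)
        expr = make_expr(["e"], np.tile([1.0], (1, 30)), labels)
        status = np.zeros((1, 30), dtype=int)
        status[0, :5] = 1
        mut = _mut(["m"], labels.sample_ids, status)
        out = eqtl_scan(mut, expr, ["e"])
        assert out.loc[0, "beta"] == pytest.approx(0.0)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_strong_signal_tiny_pvalue(self, rng):
        labels = make_labels(60, 0)
        status = (rng.random(60) < 0.5).astype(int)
        e = status + rng.normal(0, 0.1, 60)
        expr = make_expr(["e"], e[None, :], labels)
        mut = _mut(["m"], labels.sample_ids, status[None, :])
        out = eqtl_scan(mut, expr, ["e"])
        assert out.loc[0, "p_value"] < 1e-10

    def test_equals_two_sample_ttest(self, rng):
        # binary-predictor regression t-test == pooled-variance t-test
        labels = make_labels(40, 0)
        status = (rng.random(40) < 0.4).astype(int)
        E = rng.normal(0, 1, (6, 40))
        expr = make_expr([f"e{i}" for i in range(6)], E, labels)
        mut = _mut(["m"], labels.sample_ids, status[None, :])
        out = eqtl_scan(mut, expr)
        for _, row in out.iterrows():
            e = expr.gene_row(row.expression_gene)
            t_ref = stats.ttest_ind(e[status == 1], e[status == 0],
                                    equal_var=True)
            assert row.p_value == pytest.approx(t_ref.pvalue, abs=1e-10)

    def test_tumor_restriction_excludes_normals(self, rng):
        # expression differs tumor-vs-normal but not by mutation within
        # tumors: with the restriction, no association survives
        labels = make_labels(30, 30)
        e = np.where(labels.labels == 1, 5.0, 0.0) + rng.normal(0, 1, 60)
        expr = make_expr(["e"], e[None, :], labels)
        status = np.zeros(60, dtype=int)
        status[:10] = 1  # mutations only in tumors
        mut = _mut(["m"], labels.sample_ids, status[None, :])
        p_restricted = eqtl_scan(mut, expr, labels=labels).loc[0, "p_value"]
        p_pooled = eqtl_scan(mut, expr).loc[0, "p_value"]
        assert p_restricted > 0.001
        assert p_pooled < p_restricted  # pooling inflates the association

    def test_low_frequency_mutations_skipped(self, rng):
        labels = make_labels(20, 0)
        status = np.zeros((2, 20), dtype=int)
        status[0, :5] = 1
        status[1, 0] = 1  # below min_mutated
        mut = _mut(["common", "rare"], labels.sample_ids, status)
        expr = make_expr(["e"], rng.normal(0, 1, (1, 20)), labels)
        out = eqtl_scan(mut, expr)
        assert set(out.mutated_gene) == {"common"}

    def test_no_shared_samples_errors(self, rng):
        labels = make_labels(4, 0)
        expr = make_expr(["e"], rng.normal(0, 1, (1, 4)), labels)
        mut = _mut(["m"], ["X1", "X2", "X3"], np.ones((1, 3), dtype=int))
        with pytest.raises(DataError):
            eqtl_scan(mut, expr)


class TestLinking:
    def _assoc(self):
        import pandas as pd
        return pd.DataFrame({
            "mutated_gene": ["m1", "m1", "m1", "m2"],
            "expression_gene": ["a", "b", "c", "a"],
            "beta": [1.0, 0.2, 0.1, 0.3],
            "p_value": [1e-9, 0.005, 0.6, 0.004],
            "fdr": [1e-5, 0.01, 0.7, 0.01],
        })

    def test_any_member_rule(self):
        dgms = [GeneModule("a", ("a", "b", "c"), 0.5)]
        links = link_mutations_to_modules(self._assoc(), dgms, 1e-4)
        assert len(links) == 1
        ln = links[0]
        assert (ln.module_seed, ln.mutated_gene) == ("a", "m1")
        assert ln.supporting_members == ("a",)

    def test_no_member_below_cutoff(self):
        dgms = [GeneModule("b", ("b", "c"), 0.5)]
        assert link_mutations_to_modules(self._assoc(), dgms, 1e-4) == []

    def test_empty_dgms(self):
        assert link_mutations_to_modules(self._assoc(), [], 1e-4) == []

    def test_monotone_in_fdr_cutoff(self):
        dgms = [GeneModule("a", ("a", "b", "c"), 0.5)]
        loose = {(l.module_seed, l.mutated_gene)
                 for l in link_mutations_to_modules(self._assoc(), dgms, 0.05)}
        strict = {(l.module_seed, l.mutated_gene)
                  for l in link_mutations_to_modules(self._assoc(), dgms, 1e-4)}
        assert strict <= loose

    def test_driver_summary_counts(self):
        dgms = [GeneModule("a", ("a",), 0.5), GeneModule("b", ("b",), 0.5)]
        import pandas as pd
        assoc = pd.DataFrame({
            "mutated_gene": ["G", "G"],
            "expression_gene": ["a", "b"],
            "beta": [1, 1], "p_value": [1e-9, 1e-9], "fdr": [1e-6, 1e-6]})
        links = link_mutations_to_modules(assoc, dgms, 1e-4)
        module_table, gene_table, hist = driver_summary(links, dgms)
        assert gene_table.iloc[0].tolist() == ["G", 2]
        assert module_table["n_mutated_genes"].tolist() == [1, 1]
        assert hist.set_index("n_mutated_genes").loc[1, "n_modules"] == 2

    def test_driver_summary_empty(self):
        module_table, gene_table, hist = driver_summary([], [])
        assert gene_table.empty and module_table.empty and hist.empty


class TestMutualExclusivity:
    def test_degenerate_margin_gives_p_one(self):
        # gene B mutated nowhere: [[3,0],[2,0]] margins degenerate
        status = np.array([[1, 1, 1, 1, 1, 0, 0],
                           [1, 1, 1, 0, 0, 1, 1]])
        mut = _mut(["A", "B"], [f"S{i}" for i in range(7)], status)
        # build the exact degenerate pattern: B never mutated
        mut2 = _mut(["A", "B"], [f"S{i}" for i in range(5)],
                    np.array([[1, 1, 1, 0, 0], [0, 0, 0, 0, 0]]))
        _, p = mutual_exclusivity_test(mut2, "A", "B")
        assert p == pytest.approx(1.0)

    def test_perfect_exclusivity_matches_enumeration(self):
        status = np.zeros((2, 20), dtype=int)
        status[0, :10] = 1
        status[1, 10:] = 1
        mut = _mut(["A", "B"], [f"S{i}" for i in range(20)], status)
        odds, p = mutual_exclusivity_test(mut, "A", "B")
        table = [[0, 10], [10, 0]]
        assert p == pytest.approx(fisher_two_sided_oracle(table), abs=1e-10)
        assert odds < 1

    def test_cooccurrence_direction(self):
        status = np.zeros((2, 12), dtype=int)
        status[:, :5] = 1
        mut = _mut(["A", "B"], [f"S{i}" for i in range(12)], status)
        odds, _ = mutual_exclusivity_test(mut, "A", "B")
        assert odds > 1

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(30):
            n = int(rng.integers(8, 41))
            status = rng.integers(0, 2, (2, n))
            mut = _mut(["A", "B"], [f"S{i}" for i in range(n)], status)
            a = status[0].astype(bool)
            b = status[1].astype(bool)
            table = [[int((a & b).sum()), int((a & ~b).sum())],
                     [int((~a & b).sum()), int((~a & ~b).sum())]]
            _, p = mutual_exclusivity_test(mut, "A", "B")
            assert p == pytest.approx(fisher_two_sided_oracle(table), abs=1e-10)

    def test_unknown_gene_errors(self):
        mut = _mut(["A"], ["S1", "S2"], np.zeros((1, 2), dtype=int))
        with pytest.raises(DataError):
            mutual_exclusivity_test(mut, "A", "Z")
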