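import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from icemod.modstats import (
    OrderedPhenotype,
    bh_fdr,
    jt_exact_p,
    jt_test,
    module_expression,
    reproducibility,
    screen_modules,
)
from icemod.preprocess import ExpressionMatrix


@pytest.fixture
def tiny_std_expr():
    values = np.array([
        [1.0, -1.0, 0.0, 0.5],
        [-1.0, 1.0, 0.0, -0.5],
        [0.5, 0.5, -1.0, 0.0],
    ])
    return ExpressionMatrix(["g", "h", "k"], ["s1", "s2", "s3", "s4"],
                            values, standardized=True)


class TestModuleExpression:
    def test_single_gene_module_is_that_row(self, tiny_std_expr):
        me = module_expression(tiny_std_expr, {"g"})
        np.testing.assert_allclose(me.values, tiny_std_expr.row("g"))

    def test_opposite_genes_cancel(self, tiny_std_expr):
        me = module_expression(tiny_std_expr, {"g", "h"})
        np.testing.assert_allclose(me.values, 0.0)

    def test_mean_of_three(self):
        expr = ExpressionMatrix(["a", "b", "c"], ["s"], [[1.0], [2.0], [3.0]],
                                standardized=True)
        me = module_expression(expr, {"a", "b", "c"})
        assert me.values[0] == pytest.approx(2.0)

    def test_absent_genes_counted(self, tiny_std_expr):
        me = module_expression(tiny_std_expr, {"g", "missing1", "missing2"})
        assert me.n_missing_genes == 2
        assert me.n_genes_used == 1

    def test_fully_absent_module_errors(self, tiny_std_expr):
        with pytest.raises(ValueError, match="no gene"):
            module_expression(tiny_std_expr, {"nope"})


class TestJTTest:
    def test_worked_example(self):
        # three ordered groups of two, perfectly increasing
        r = jt_test([1, 2, 3, 4, 5, 6], [0, 0, 1, 1, 2, 2])
        assert r.W == pytest.approx(12.0)
        assert r.mean0 == pytest.approx(6.0)
        assert r.var0 == pytest.approx(6.3333, abs=1e-4)
        assert r.z == pytest.approx(2.3842, abs=1e-4)
        assert r.p == pytest.approx(0.0171, abs=1e-4)

    def test_reversed_order_antisymmetry(self):
        fwd = jt_test([1, 2, 3, 4, 5, 6], [0, 0, 1, 1, 2, 2])
        rev = jt_test([1, 2, 3, 4, 5, 6], [2, 2, 1, 1, 0, 0])
        assert rev.W == pytest.approx(0.0)
        assert rev.z == pytest.approx(-fwd.z)
        assert rev.p == pytest.approx(fwd.p)

    def test_perfectly_ordered_attains_maximum(self):
        sizes = (3, 4, 5)
        values = list(range(sum(sizes)))
        ranks = [i for i, n in enumerate(sizes) for _ in range(n)]
        r = jt_test(values, ranks)
        expected_max = sum(
            sizes[i] * sizes[j]
            for i in range(3) for j in range(i + 1, 3)
        )
        assert r.W == pytest.approx(expected_max)

    def test_all_tied_values(self):
        r = jt_test([1.0] * 6, [0, 0, 1, 1, 2, 2])
        assert r.z == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_single_category_errors(self):
        with pytest.raises(ValueError, match="2 non-empty"):
            jt_test([1, 2, 3], [0, 0, 0])

    def test_missing_phenotype_dropped(self):
        pheno = OrderedPhenotype(
            {"s1": "1", "s2": "1", "s3": "2", "s4": None, "s5": "2"},
            order=["1", "2"],
        )
        r = jt_test([1, 2, 3, 99, 4], pheno, sample_ids=["s1", "s2", "s3", "s4", "s5"])
        assert r.n_used == 4

    def test_exact_permutation_oracle(self):
        # 90 distinct arrangements; only the fully ordered one reaches W=12
        p_one = jt_exact_p([1, 2, 3, 4, 5, 6], [0, 0, 1, 1, 2, 2],
                           alternative="greater")
        assert p_one == pytest.approx(1 / 90)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.integers(-1000, 1000), min_size=6, max_size=6, unique=True))
    def test_invariant_to_monotone_transform(self, values):
        # rank-based statistic: any strictly monotone transform leaves W unchanged
        ranks = [0, 0, 1, 1, 2, 2]
        base = jt_test(values, ranks)
        transformed = jt_test([v**3 + 7 for v in values], ranks)
        assert transformed.W == pytest.approx(base.W)
        assert transformed.p == pytest.approx(base.p)

    def test_normal_vs_exact_rejection_agreement_small_n(self):
        # approximation-quality check: decisions at alpha=0.05 agree >= 90%
        rng = np.random.default_rng(12)
        ranks = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        agree = 0
        n_inst = 60
        for _ in range(n_inst):
            values = rng.standard_normal(9)
            approx = jt_test(values, ranks).p < 0.05
            exact = jt_exact_p(values, ranks) < 0.05
            agree += approx == exact
        assert agree / n_inst >= 0.9


class TestBhFdr:
    def test_step_up_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_is_itself(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_empty(self):
        assert bh_fdr([]) == []

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_output_dominates_input_and_is_monotone(self, pvals):
        adj = np.asarray(bh_fdr(pvals))
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        adj_sorted = np.asarray(bh_fdr(sorted(pvals)))
        assert np.all(np.diff(adj_sorted) >= -1e-12)


class TestScreening:
    def test_single_module_family_fdr_equals_raw_p(self):
        rng = np.random.default_rng(0)
        expr = ExpressionMatrix(
            ["a", "b"], [f"s{i}" for i in range(12)],
            rng.standard_normal((2, 12)), standardized=True,
        )
        pheno = OrderedPhenotype(
            {f"s{i}": str(i % 3 + 1) for i in range(12)}, order=["1", "2", "3"]
        )
        out = screen_modules(expr, {"m1": {"a", "b"}}, pheno)
        assert out[0].trend.fdr == pytest.approx(out[0].trend.p)

    def test_untestable_module_excluded_from_family(self):
        rng = np.random.default_rng(1)
        expr = ExpressionMatrix(
            ["a", "b"], [f"s{i}" for i in range(12)],
            rng.standard_normal((2, 12)), standardized=True,
        )
        pheno = OrderedPhenotype(
            {f"s{i}": str(i % 3 + 1) for i in range(12)}, order=["1", "2", "3"]
        )
        out = screen_modules(expr, {"bad": {"zz"}, "ok": {"a"}}, pheno)
        by_id = {sm.module_id: sm for sm in out}
        assert by_id["bad"].error is not None
        assert by_id["ok"].trend.fdr == pytest.approx(by_id["ok"].trend.p)

    def test_all_null_modules_rarely_flagged(self):
        rng = np.random.default_rng(2)
        n_mod, n_samp = 30, 60
        expr = ExpressionMatrix(
            [f"g{i}" for i in range(n_mod)], [f"s{j}" for j in range(n_samp)],
            rng.standard_normal((n_mod, n_samp)), standardized=True,
        )
        pheno = OrderedPhenotype(
            {f"s{j}": str(j % 3 + 1) for j in range(n_samp)}, order=["1", "2", "3"]
        )
        out = screen_modules(expr, {f"m{i}": {f"g{i}"} for i in range(n_mod)}, pheno,
                             fdr_cut=0.01)
        assert sum(sm.significant for sm in out) == 0


class TestReproducibility:
    @pytest.mark.parametrize(
        "disc, val, pct",
        [(19, 17, 89.47), (5107, 1569, 30.72), (3758, 1569, 41.75), (352, 330, 93.75)],
    )
    def test_cross_cohort_percentages(self, disc, val, pct):
        assert reproducibility(disc, val).percentage == pytest.approx(pct)

    def test_flag_iterables_and_full_overlap(self):
        rep = reproducibility([True] * 4, [True, True, True, True])
        assert rep.percentage == pytest.approx(100.0)

    def test_zero_discovery_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            reproducibility(0, 0)

    def test_validation_exceeding_discovery_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            reproducibility(3, 5)
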