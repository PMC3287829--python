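"""Association statistics: partition retention I, ANOVA, chi-square,
Fisher exact 2xc, selection rules."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from raregene_ipwc import (
    SelectionRule,
    TestResult as AssocResult,
    TraitVector,
    anova_test,
    apply_selection,
    chisq_test,
    fisher_exact_rxc,
    partition_retention_i,
)
from raregene_ipwc.association import (
    chisq_from_table,
    null_expected_i,
    permutation_pvalue,
)

from conftest import make_partition


def quant(values, name="y"):
    return TraitVector(np.asarray(values, float), kind="quantitative", name=name)


def dich(values, name="Affected"):
    return TraitVector(np.asarray(values, float), kind="dichotomous", name=name)


class TestPartitionRetention:
    def test_constant_trait_gives_zero(self):
        part = make_partition([1, 1, 2, 2])
        res = partition_retention_i(quant([3, 3, 3, 3]), part)
        assert res.i_score == 0.0 and res.degenerate

    def test_hand_example(self):
        # y=(0,0,0,1,1,1), halves: ybar=.5, s2=.25, sum n_i^2 dev^2 = 4.5
        part = make_partition([1, 1, 1, 2, 2, 2])
        res = partition_retention_i(quant([0, 0, 0, 1, 1, 1]), part)
        assert res.i_score == pytest.approx(3.0)
        assert res.overall_sd == pytest.approx(0.5)

    def test_applies_to_dichotomous_identically(self):
        part = make_partition([1, 1, 1, 2, 2, 2])
        a = partition_retention_i(quant([0, 0, 0, 1, 1, 1]), part).i_score
        b = partition_retention_i(dich([0, 0, 0, 1, 1, 1]), part).i_score
        assert a == b

    def test_single_element_partition_gives_zero(self):
        part = make_partition([1, 1, 1, 1])
        res = partition_retention_i(quant([1, 2, 3, 4]), part)
        assert res.i_score == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        alpha=st.floats(min_value=0.1, max_value=10),
        beta=st.floats(min_value=-5, max_value=5),
    )
    def test_affine_invariance(self, alpha, beta):
        rng = np.random.default_rng(7)
        y = rng.normal(size=30)
        labels = rng.integers(1, 4, 30)
        labels[:3] = [1, 2, 3]  # all elements nonempty
        part = make_partition(labels)
        base = partition_retention_i(quant(y), part).i_score
        moved = partition_retention_i(quant(alpha * y + beta), part).i_score
        assert moved == pytest.approx(base, rel=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            partition_retention_i(quant([1, 2]), make_partition([1, 2, 2]))

    def test_null_mean_closed_form(self):
        # E[I] = 1 - sum n_i^2/n^2 for i.i.d. traits, checked by simulation
        rng = np.random.default_rng(11)
        labels = np.repeat(np.arange(1, 11), 20)
        part = make_partition(labels)
        expected = null_expected_i(part)
        assert expected == pytest.approx(1 - 10 * (20 / 200) ** 2)
        sims = np.array(
            [
                partition_retention_i(quant(rng.standard_normal(200)), part).i_score
                for _ in range(2000)
            ]
        )
        se = sims.std(ddof=1) / np.sqrt(len(sims))
        assert abs(sims.mean() - expected) < 3 * se


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        part = make_partition([1, 1, 1, 2, 2, 2])
        res = anova_test(quant([1, 2, 3, 1, 2, 3]), part)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_anova_table(self):
        # groups (1,2,3) vs (4,5,6): SSB=13.5, SSW=4, F = 13.5/(4/4) = 13.5
        part = make_partition([1, 1, 1, 2, 2, 2])
        res = anova_test(quant([1, 2, 3, 4, 5, 6]), part)
        assert res.statistic == pytest.approx(13.5)
        assert res.df == (1, 4)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=40)
        labels = rng.integers(1, 5, 40)
        labels[:4] = [1, 2, 3, 4]
        part = make_partition(labels)
        res = anova_test(quant(y), part)
        groups = [y[labels == g] for g in range(1, 5)]
        ref = stats.f_oneway(*groups)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_equals_squared_t_for_two_groups(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=20)
        labels = np.array([1] * 10 + [2] * 10)
        res = anova_test(dich((y > 0).astype(float)), make_partition(labels))
        t = stats.ttest_ind((y > 0)[:10].astype(float), (y > 0)[10:].astype(float))
        assert res.statistic == pytest.approx(t.statistic**2)

    def test_null_pvalues_uniform(self):
        # permuted traits -> p ~ U(0,1); KS must not reject at 0.01
        rng = np.random.default_rng(9)
        y = rng.normal(size=50)
        labels = rng.integers(1, 6, 50)
        labels[:5] = [1, 2, 3, 4, 5]
        part = make_partition(labels)
        pvals = [
            anova_test(quant(rng.permutation(y)), part).p_value
            for _ in range(2000)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_within_variance_flagged(self):
        part = make_partition([1, 1, 2, 2])
        res = anova_test(quant([0, 0, 1, 1]), part)
        assert res.p_value == 0.0
        assert "zero_within_variance" in res.flags

    def test_single_element_rejected(self):
        with pytest.raises(ValueError, match="2 partition elements"):
            anova_test(quant([1, 2, 3]), make_partition([1, 1, 1]))


class TestChisq:
    def test_balanced_table_statistic_zero(self):
        res = chisq_from_table([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_diagonal_table_statistic_n(self):
        res = chisq_from_table([[20, 0], [0, 20]])
        assert res.statistic == pytest.approx(40.0)
        assert res.p_value == pytest.approx(stats.chi2.sf(40, 1))

    def test_sparse_flag_on_diagnostic_table(self):
        res = chisq_from_table([[41, 29, 3, 9, 11], [525, 59, 5, 8, 7]])
        assert "sparse" in res.flags
        assert res.statistic > 0

    def test_matches_scipy_on_random_table(self):
        rng = np.random.default_rng(6)
        y = (rng.random(60) < 0.4).astype(float)
        labels = rng.integers(1, 4, 60)
        labels[:3] = [1, 2, 3]
        part = make_partition(labels)
        res = chisq_test(dich(y), part)
        table = np.array(
            [[np.sum((y == r) & (labels == c)) for c in range(1, 4)]
             for r in (0, 1)]
        )
        ref = stats.chi2_contingency(table, correction=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_constant_trait_degenerate(self):
        res = chisq_test(dich([0, 0, 0, 0]), make_partition([1, 1, 2, 2]))
        assert res.statistic == 0.0 and "degenerate" in res.flags

    def test_quantitative_trait_rejected(self):
        with pytest.raises(ValueError, match="dichotomous"):
            chisq_test(quant([0.5, 1, 2, 3]), make_partition([1, 1, 2, 2]))


class TestFisherExact:
    def test_hypergeometric_enumeration(self):
        # [[3,0],[0,3]]: P(k=0)+P(k=3) = 1/20 + 1/20 = 0.1
        assert fisher_exact_rxc([[3, 0], [0, 3]]).p_value == pytest.approx(0.1)

    def test_proportional_rows_give_one(self):
        assert fisher_exact_rxc([[2, 4, 6], [1, 2, 3]]).p_value == pytest.approx(1.0)

    def test_matches_scipy_two_by_two(self):
        for table in ([[5, 1], [2, 7]], [[8, 2], [3, 9]], [[1, 9], [7, 2]]):
            mine = fisher_exact_rxc(table).p_value
            ref = stats.fisher_exact(table).pvalue
            assert mine == pytest.approx(ref, rel=1e-9)

    def test_matches_r_fisher_test(self):
        # independent oracle: R's fisher.test on 2xc tables
        tables = [
            [[5, 1, 3], [2, 7, 4]],
            [[10, 0, 2, 5], [3, 6, 8, 1]],
        ]
        for table in tables:
            flat = ",".join(str(v) for row in zip(*table) for v in row)
            script = (
                f"cat(fisher.test(matrix(c({flat}), nrow=2))$p.value)"
            )
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True,
                check=True,
            )
            ref = float(out.stdout.strip())
            assert fisher_exact_rxc(table).p_value == pytest.approx(ref, rel=1e-6)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_rxc([[0, 0], [1, 2]])


class TestSelection:
    @staticmethod
    def results(pvalues=None, statistics=None):
        out = []
        n = len(pvalues) if pvalues is not None else len(statistics)
        for i in range(n):
            out.append(
                AssocResult(
                    "anova" if pvalues is not None else "partition_retention",
                    statistics[i] if statistics is not None else 1.0,
                    p_value=None if pvalues is None else pvalues[i],
                    gene=f"G{i:04d}",
                )
            )
        return out

    def test_top_fraction_uses_ceiling(self):
        stats_ = list(range(3205))
        res = self.results(statistics=stats_)
        rule = SelectionRule("top_fraction", fraction=0.001)
        chosen = apply_selection(res, rule)
        assert len(chosen) == 4  # ceil(3.205)
        assert chosen == {"G3204", "G3203", "G3202", "G3201"}

    def test_bonferroni_single_test_is_plain_alpha(self):
        res = self.results(pvalues=[0.04, 0.06])
        # two tests: threshold 0.025
        assert apply_selection(res, SelectionRule("bonferroni", 0.05)) == set()
        single = self.results(pvalues=[0.04])
        assert apply_selection(single, SelectionRule("bonferroni", 0.05)) == {
            "G0000"
        }

    def test_all_p_one_selects_nothing(self):
        res = self.results(pvalues=[1.0] * 10)
        assert apply_selection(res, SelectionRule("bonferroni", 0.05)) == set()

    def test_ties_broken_by_gene_id(self):
        res = self.results(statistics=[5.0, 5.0, 1.0])
        chosen = apply_selection(res, SelectionRule("top_fraction", fraction=0.33))
        assert chosen == {"G0000"}  # ceil(0.99) = 1; tie on 5.0 broken by id

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            SelectionRule("top_fraction", fraction=1.5)

    def test_selected_flag_is_set(self):
        res = self.results(pvalues=[0.001, 0.9])
        apply_selection(res, SelectionRule("bonferroni", 0.05))
        assert res[0].selected is True and res[1].selected is False


class TestPermutationPvalue:
    def test_seeded_and_bounded(self):
        rng = np.random.default_rng(12)
        y = quant(rng.normal(size=30))
        labels = rng.integers(1, 4, 30)
        labels[:3] = [1, 2, 3]
        part = make_partition(labels)
        p1 = permutation_pvalue(y, part, "anova", 99, np.random.default_rng(1))
        p2 = permutation_pvalue(y, part, "anova", 99, np.random.default_rng(1))
        assert p1 == p2
        assert 1 / 100 <= p1 <= 1.0
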