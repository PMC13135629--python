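"""Balance tests, effect sizes and the composite score."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from batchbalance import (
    Allocation,
    CovariateSpec,
    ValidationError,
    balance_score,
    combine_scores,
    cramers_v,
    eta_effect,
    fisher_exact_p,
    kruskal_wallis_p,
    simulate_basic_cohort,
)
from batchbalance.metadata import SampleTable

from _oracles import fisher_exact_enum_p, labels_batches_from_table


class TestKruskalWallis:
    def test_symmetric_groups_give_p_one(self):
        assert kruskal_wallis_p([1, 2, 3, 1, 2, 3], list("aaabbb")) == 1.0

    def test_separated_groups_match_direct_formula(self):
        # ranks 1..6: H = 12/(6*7) * (6^2/3 + 15^2/3) - 3*7 = 27/7
        p = kruskal_wallis_p([1, 2, 3, 4, 5, 6], list("aaabbb"))
        assert p == pytest.approx(stats.chi2.sf(27 / 7, 1), rel=1e-12)
        assert p == pytest.approx(0.0495, abs=5e-4)

    @pytest.mark.parametrize(
        "values,groups",
        [
            ([1, 1, 2, 1, 2, 2], list("aaabbb")),
            ([3, 3, 3, 1, 2, 9, 9], list("aaabbbb")),
            ([1.5, 2.5, 2.5, 2.5, 7, 7, 1.5, 3], list("aabbccdd")),
        ],
    )
    def test_tie_correction_matches_reference_implementation(self, values, groups):
        grouped = [
            [v for v, g in zip(values, groups) if g == label] for label in sorted(set(groups))
        ]
        expected = stats.kruskal(*grouped).pvalue
        assert kruskal_wallis_p(values, groups) == pytest.approx(expected, rel=1e-12)

    def test_all_identical_values_give_p_one(self):
        assert kruskal_wallis_p([2, 2, 2, 2], list("aabb")) == 1.0

    def test_single_nonempty_group_gives_p_one(self):
        assert kruskal_wallis_p([1, 2, np.nan, np.nan], list("aabb")) == 1.0

    def test_missing_values_are_dropped_casewise(self):
        full = kruskal_wallis_p([1, 2, 3, 4, 5, 6], list("aaabbb"))
        padded = kruskal_wallis_p([1, 2, 3, np.nan, 4, 5, 6], ["a"] * 3 + ["c"] + ["b"] * 3)
        assert padded == pytest.approx(full, rel=1e-12)


class TestFisherExact:
    def test_2x2_against_enumeration_examples(self):
        labels, batches = labels_batches_from_table([[3, 1], [1, 3]])
        assert fisher_exact_p(labels, batches) == pytest.approx(34 / 70, rel=1e-9)
        labels, batches = labels_batches_from_table([[4, 0], [0, 4]])
        assert fisher_exact_p(labels, batches) == pytest.approx(2 / 70, rel=1e-9)

    def test_single_category_gives_p_one(self):
        assert fisher_exact_p(["x"] * 6, list("aaabbb")) == 1.0

    def test_missing_labels_dropped(self):
        labels, batches = labels_batches_from_table([[3, 1], [1, 3]])
        labels = np.concatenate([labels, [None, None]])
        batches = np.concatenate([batches, ["batch0", "batch1"]])
        assert fisher_exact_p(labels, batches) == pytest.approx(34 / 70, rel=1e-9)

    @pytest.mark.parametrize(
        "table",
        [
            [[2, 1, 1], [1, 2, 1], [1, 1, 2]],
            [[3, 0, 1], [0, 3, 1], [1, 1, 2]],
            [[2, 2, 0], [0, 2, 2], [2, 0, 2]],
        ],
    )
    def test_monte_carlo_converges_to_enumeration_on_3x3(self, table):
        exact = fisher_exact_enum_p(table)
        labels, batches = labels_batches_from_table(table)
        mc = fisher_exact_p(labels, batches, mc_replicates=20_000, sub_seed=7)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_monte_carlo_deterministic_given_sub_seed(self):
        labels, batches = labels_batches_from_table([[2, 1, 1], [1, 2, 1], [1, 1, 2]])
        p1 = fisher_exact_p(labels, batches, mc_replicates=500, sub_seed=3)
        p2 = fisher_exact_p(labels, batches, mc_replicates=500, sub_seed=3)
        assert p1 == p2

    def test_monte_carlo_p_is_strictly_positive(self):
        # add-one estimator: p >= 1/(B+1)
        labels, batches = labels_batches_from_table([[4, 0, 0], [0, 4, 0], [0, 0, 4]])
        p = fisher_exact_p(labels, batches, mc_replicates=200, sub_seed=1)
        assert 0 < p <= 1


class TestEffectSizes:
    def test_eta_zero_for_equal_group_means(self):
        assert eta_effect([1, 2, 1, 2], list("aabb")) == 0.0

    def test_eta_one_for_zero_within_group_variance(self):
        assert eta_effect([1, 1, 2, 2], list("aabb")) == 1.0

    def test_eta_matches_direct_sums_of_squares(self):
        # groups {1,2} and {2,3}: SS_between = 1, SS_total = 2
        assert eta_effect([1, 2, 2, 3], list("aabb")) == pytest.approx(math.sqrt(0.5), rel=1e-12)

    def test_cramers_v_zero_under_independence(self):
        labels, batches = labels_batches_from_table([[2, 2], [2, 2]])
        assert cramers_v(labels, batches) == 0.0

    def test_cramers_v_one_for_perfect_association(self):
        labels, batches = labels_batches_from_table([[4, 0], [0, 4]])
        assert cramers_v(labels, batches) == 1.0

    def test_cramers_v_matches_direct_chi2(self):
        # [[3,1],[1,3]]: chi2 = 2, n = 8 -> V = sqrt(2/8) = 0.5
        labels, batches = labels_batches_from_table([[3, 1], [1, 3]])
        assert cramers_v(labels, batches) == pytest.approx(0.5, rel=1e-12)

    def test_degenerate_table_gives_zero(self):
        assert cramers_v(["x"] * 4, list("aabb")) == 0.0


class TestCombineScores:
    @pytest.mark.parametrize(
        "values,method,expected",
        [
            ([1, 1, 1], "harmonic", 1.0),
            ([0.5, 0.5], "harmonic", 0.5),
            ([0.2, 0.8], "harmonic", 0.32),
            ([0.2, 0.8], "product", 0.16),
        ],
    )
    def test_examples(self, values, method, expected):
        assert combine_scores(values, method) == pytest.approx(expected, rel=1e-12)

    def test_non_positive_values_clamped(self):
        assert combine_scores([0.0, 1.0], "harmonic") > 0.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            combine_scores([], "harmonic")


def _table_from_columns(**columns):
    frame = pd.DataFrame({"sample_id": [f"S{i}" for i in range(len(next(iter(columns.values()))))]})
    spec_cat, spec_cont = [], []
    for name, values in columns.items():
        frame[name] = values
        (spec_cont if isinstance(values[0], (int, float)) else spec_cat).append(name)
    return SampleTable(frame, CovariateSpec.of(categorical=spec_cat, continuous=spec_cont))


class TestBalanceScore:
    def test_identical_batches_score_one(self):
        table = _table_from_columns(
            age=[50.0, 60.0, 50.0, 60.0], sex=["m", "f", "m", "f"]
        )
        alloc = Allocation({"S0": 0, "S1": 0, "S2": 1, "S3": 1}, 2, 2)
        report = balance_score(table, alloc)
        assert report.score == 1.0
        assert all(c.p_value == 1.0 for c in report.per_covariate)

    def test_confounded_binary_covariate_scores_2_over_70(self):
        table = _table_from_columns(sex=["m"] * 4 + ["f"] * 4)
        alloc = Allocation({f"S{i}": i // 4 for i in range(8)}, 2, 4)
        report = balance_score(table, alloc)
        assert report.score == pytest.approx(2 / 70, rel=1e-9)

    def test_score_is_harmonic_mean_of_per_covariate_p(self):
        table = _table_from_columns(
            age=[1.0, 2.0, 3.0, 4.0, 5.0, 6.0], sex=["m", "m", "f", "m", "f", "f"]
        )
        alloc = Allocation({f"S{i}": i // 3 for i in range(6)}, 2, 3)
        report = balance_score(table, alloc)
        p = [c.p_value for c in report.per_covariate]
        assert report.score == pytest.approx(2 / (1 / p[0] + 1 / p[1]), rel=1e-12)

    def test_single_covariate_harmonic_score_equals_p(self):
        table = _table_from_columns(age=[1.0, 5.0, 2.0, 7.0, 3.0, 4.0])
        alloc = Allocation({f"S{i}": i % 2 for i in range(6)}, 2, 3)
        report = balance_score(table, alloc)
        assert report.score == report.per_covariate[0].p_value

    def test_effect_size_method_uses_one_minus_effect(self):
        table = _table_from_columns(age=[1.0, 1.0, 2.0, 2.0])
        alloc = Allocation({"S0": 0, "S1": 0, "S2": 1, "S3": 1}, 2, 2)
        report = balance_score(table, alloc, method="effect_size")
        assert report.per_covariate[0].effect_size == 1.0
        assert report.score == pytest.approx(1e-12, rel=1e-6)  # clamped 1 - eta

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20)
    def test_score_invariant_under_batch_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        table = simulate_basic_cohort(20, seed=seed)
        batch = rng.integers(0, 3, size=20)
        perm = rng.permutation(3)
        a1 = Allocation({s: int(b) for s, b in zip(table.sample_ids, batch)}, 3, 8)
        a2 = Allocation({s: int(perm[b]) for s, b in zip(table.sample_ids, batch)}, 3, 8)
        s1 = balance_score(table, a1, mc_replicates=300, seed=9).score
        s2 = balance_score(table, a2, mc_replicates=300, seed=9).score
        # equal up to floating-point summation order in the rank sums
        assert s1 == pytest.approx(s2, rel=1e-9)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20)
    def test_score_invariant_under_sample_order_permutation(self, seed):
        rng = np.random.default_rng(seed)
        table = simulate_basic_cohort(20, seed=seed)
        batch = rng.integers(0, 3, size=20)
        alloc = Allocation({s: int(b) for s, b in zip(table.sample_ids, batch)}, 3, 8)
        shuffled = SampleTable(
            table.frame.sample(frac=1.0, random_state=seed).reset_index(drop=True),
            table.spec,
        )
        s1 = balance_score(table, alloc, mc_replicates=300, seed=9).score
        s2 = balance_score(shuffled, alloc, mc_replicates=300, seed=9).score
        # equal up to floating-point summation order in the rank sums
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_missing_covariate_cells_excluded_from_test_only(self):
        table = _table_from_columns(
            age=[1.0, 2.0, np.nan, 4.0, 5.0, 6.0], sex=["m", "m", "f", "m", "f", "f"]
        )
        alloc = Allocation({f"S{i}": i // 3 for i in range(6)}, 2, 3)
        report = balance_score(table, alloc)
        by_name = {c.name: c for c in report.per_covariate}
        assert by_name["age"].n_used == 5
        assert by_name["sex"].n_used == 6
        assert 0 < report.score <= 1
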