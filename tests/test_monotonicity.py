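import numpy as np
import pytest

from scalemok import (
    GRMConfig,
    ViolationSpec,
    check_monotonicity,
    generate_grm,
    inject_violation,
    irf_table,
    make_restscore_groups,
)
from scalemok.monotonicity import crit_value, default_minsize, group_rest_scores

from conftest import guttman_matrix, make_matrix, single_factor_config


class TestRestScoreGrouping:
    def test_minsize_one_gives_one_group_per_distinct_rest_score(self):
        g = group_rest_scores(np.array([0, 1, 1, 2, 3, 3, 3]), minsize=1)
        assert g.n_groups == 4
        assert list(g.group_sizes) == [1, 2, 1, 3]

    def test_oversized_minsize_forces_a_single_group(self, rng):
        m = make_matrix(rng.integers(0, 5, (100, 3)))
        g = make_restscore_groups(m, "q1", minsize=60)
        assert g.n_groups == 1
        result, _ = check_monotonicity(m, minsize=60)
        assert result.ac.sum() == 0 and result.vi.sum() == 0

    def test_hand_merged_fixture_of_twelve_respondents(self):
        # listed rest scores; minsize 4 merges from the low end into
        # exactly three groups of four
        rest = np.array([0, 0, 1, 2, 3, 3, 4, 4, 5, 6, 6, 7])
        g = group_rest_scores(rest, minsize=4)
        assert g.n_groups == 3
        assert list(g.group_sizes) == [4, 4, 4]
        assert g.group_edges == [(0, 2), (3, 4), (5, 7)]

    def test_trailing_undersized_group_merges_left(self):
        rest = np.array([0, 0, 0, 5])
        g = group_rest_scores(rest, minsize=3)
        assert g.n_groups == 1

    def test_default_minsize_ladder(self):
        assert default_minsize(3268) == 326
        assert default_minsize(400) == 80
        assert default_minsize(100) == 50


def two_group_item_fixture(p_high_a=0.60, p_high_b=0.50, n_per_group=50):
    """Three-item matrix where the target item's second step has
    P(X>=2) = p_high_a in the low rest-score group and p_high_b in the
    high group, by exact construction of the group compositions."""
    ka = int(round(p_high_a * n_per_group))
    kb = int(round(p_high_b * n_per_group))
    target = np.concatenate(
        [np.repeat(2, ka), np.repeat(1, n_per_group - ka),
         np.repeat(2, kb), np.repeat(1, n_per_group - kb)]
    )
    helper = np.concatenate(
        [np.repeat(1, n_per_group), np.repeat(3, n_per_group)]
    )
    return make_matrix(np.column_stack([target, helper, helper]))


class TestCheckMonotonicity:
    def test_deterministic_monotone_data_has_no_misfit(self):
        g = guttman_matrix(n_per_level=5)
        result, _ = check_monotonicity(g, minsize=10)
        assert result.vi.sum() == 0
        assert np.all(result.crit == 0.0)
        assert result.ac.sum() > 0

    def test_constructed_drop_of_010_is_one_violation(self):
        m = two_group_item_fixture(0.60, 0.50)
        result, _ = check_monotonicity(m, minsize=50)
        k = result.item_ids.index("q1")
        assert result.vi[k] == 1
        assert result.maxvi[k] == pytest.approx(0.10)
        assert result.crit[k] > 0

    def test_drop_below_minvi_is_not_reported(self):
        m = two_group_item_fixture(0.60, 0.58)
        result, _ = check_monotonicity(m, minvi=0.03, minsize=50)
        assert result.vi[result.item_ids.index("q1")] == 0
        assert result.crit[result.item_ids.index("q1")] == 0.0

    def test_active_comparisons_count_steps_times_group_pairs(self):
        m = two_group_item_fixture()
        result, _ = check_monotonicity(m, minsize=50)
        # 2 groups -> 1 ordered pair, 4 steps per item
        assert result.ac[result.item_ids.index("q1")] == 4

    def test_adjacent_only_mode_is_a_subset_of_all_pairs(self, rng):
        m, _, _ = generate_grm(single_factor_config(seed=5, n=800))
        full, _ = check_monotonicity(m)
        adj, _ = check_monotonicity(m, adjacent_only=True)
        assert np.all(adj.ac <= full.ac)
        assert np.all(adj.vi <= full.vi)

    def test_false_positive_rate_on_fitting_data_is_low(self):
        flagged = 0
        for s in range(25):
            m, _, _ = generate_grm(single_factor_config(seed=7000 + s, n=2000))
            result, _ = check_monotonicity(m)
            flagged += result.total_violations > 0
        assert flagged <= 3

    def test_injected_isrf_dip_is_detected_in_target_item_only(self):
        hits = clean = 0
        for s in range(25):
            spec = ViolationSpec(
                "loneliness", "non_monotone", depth=0.15,
                theta_interval=(1.0, np.inf), step=1,
            )
            m, _, _ = inject_violation(single_factor_config(seed=8000 + s), spec)
            result, _ = check_monotonicity(m)
            k = result.item_ids.index("loneliness")
            hits += result.vi[k] >= 1
            clean += all(
                result.crit[j] == 0 for j in range(9) if j != k
            )
        assert hits >= 23
        assert clean >= 23


class TestIrf:
    def test_extreme_probabilities_give_extreme_curves(self):
        m = make_matrix([[0, 0], [4, 4], [0, 4], [4, 0]])
        _, isrf = check_monotonicity(m, minsize=4)
        for item in isrf.item_ids:
            curve = isrf.irf(item)
            assert np.all(curve >= 0) and np.all(curve <= 4)

    def test_irf_is_the_sum_of_isrf_rows(self):
        m = two_group_item_fixture()
        _, isrf = check_monotonicity(m, minsize=50)
        p = isrf.probs["q1"]
        np.testing.assert_allclose(isrf.irf("q1"), p.sum(axis=0))
        # fixture row sum: step probabilities (1, .6, 0, 0) -> IRF 1.6
        assert isrf.irf("q1")[0] == pytest.approx(1.60)

    def test_hand_summed_isrf_rows(self):
        # direct sum: (0.9, 0.5, 0.2, 0.1) -> 1.7
        assert float(np.sum([0.9, 0.5, 0.2, 0.1])) == pytest.approx(1.7)

    def test_irf_monotone_whenever_every_isrf_row_is(self):
        g = guttman_matrix(n_per_level=5)
        _, isrf = check_monotonicity(g, minsize=10)
        for item in isrf.item_ids:
            p = isrf.probs[item]
            assert np.all(np.diff(p, axis=1) >= -1e-12)
            assert np.all(np.diff(isrf.irf(item)) >= -1e-12)

    def test_table_export_is_long_format(self):
        m = two_group_item_fixture()
        _, isrf = check_monotonicity(m, minsize=50)
        table = irf_table(isrf)
        assert set(table.columns) == {"item", "group", "rest_lo", "rest_hi", "n", "irf"}
        assert len(table) == sum(isrf.groupings[i].n_groups for i in isrf.item_ids)


class TestCrit:
    def test_zero_iff_no_violations(self):
        assert crit_value(0.5, 100, 0, 0.0, 0.0, 0) == 0.0
        assert crit_value(0.5, 100, 1, 0.04, 0.04, 0) > 0.0

    def test_monotone_in_each_ingredient(self):
        base = crit_value(0.45, 100, 2, 0.05, 0.08, 0)
        assert crit_value(0.30, 100, 2, 0.05, 0.08, 0) >= base  # lower H
        assert crit_value(0.45, 100, 3, 0.05, 0.09, 0) >= base  # more vi
        assert crit_value(0.45, 100, 2, 0.09, 0.08, 0) >= base  # bigger maxvi
        assert crit_value(0.45, 100, 2, 0.05, 0.08, 2) >= base  # significant
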