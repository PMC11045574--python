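import numpy as np
import pytest

from scalemok import (
    GRMConfig,
    ScaleDefinition,
    ViolationSpec,
    check_miio,
    compute_HT,
    generate_grm,
    inject_violation,
)
from scalemok.errors import ScalemokError
from scalemok.iio import classify_HT

from conftest import make_matrix, single_factor_config
from oracles import brute_force_H


def _mean_block(mu: float, n: int) -> np.ndarray:
    """n internal responses around level 2 with exact mean mu (|mu-2| <= 1)."""
    k = int(round(abs(mu - 2.0) * n))
    shifted = 3 if mu > 2.0 else 1
    return np.concatenate([np.repeat(shifted, k), np.repeat(2, n - k)])


def reversal_fixture(low_mean_b=1.8, n_per_group=50):
    """Four five-level items; the pair (A, B) has a conditional-mean gap
    of (2.0 - low_mean_b) in A's favour in the low rest-score group while
    B's overall mean stays above A's.  Helper items C, D sit at least one
    level above A and B in every group, so no other pair can reverse."""
    n = n_per_group
    # balanced +/-1 jitter: exact mean 2.0 per group with positive variance
    a_block = np.concatenate([np.repeat(1, 5), np.repeat(2, n - 10), np.repeat(3, 5)])
    a_col = np.concatenate([a_block, a_block])
    b_col = np.concatenate([_mean_block(low_mean_b, n), np.repeat(3, n)])
    helper = np.concatenate([np.repeat(3, n), np.repeat(4, n)])
    return make_matrix(
        np.column_stack([a_col, b_col, helper, helper]),
        item_ids=["A", "B", "C", "D"],
    )


class TestCheckMiio:
    def test_constant_conditional_shift_has_no_violations(self):
        m = reversal_fixture(low_mean_b=2.5)  # B above A in every group
        result = check_miio(m, minsize=50, compute_ht=False)
        assert result.total_violations == 0
        assert result.removed_items == []

    def test_reversal_of_020_is_one_violation_for_five_level_items(self):
        m = reversal_fixture(low_mean_b=1.8)  # A - B = +0.20 in low group
        result = check_miio(m, minsize=50, compute_ht=False)
        assert result.minvi_pair == pytest.approx(0.12)
        assert result.pair_violations[("A", "B")] == 1
        assert result.total_violations == 1
        k = result.item_ids.index("A")
        assert result.maxvi[k] == pytest.approx(0.20)

    def test_reversal_of_010_is_below_the_pair_threshold(self):
        m = reversal_fixture(low_mean_b=1.9)  # A - B = +0.10 < 0.12
        result = check_miio(m, minsize=50, compute_ht=False)
        assert result.total_violations == 0

    def test_items_ordered_by_ascending_overall_mean(self):
        m = reversal_fixture()
        result = check_miio(m, minsize=50, compute_ht=False)
        means = dict(zip(result.item_ids, result.overall_means))
        ordered = [means[i] for i in result.item_order]
        assert ordered == sorted(ordered)

    def test_tied_means_resolved_by_item_index_and_flagged(self):
        v = np.column_stack(
            [[0, 1, 2, 3, 4] * 4, [4, 3, 2, 1, 0] * 4, [0, 4, 0, 4, 2] * 4]
        )
        result = check_miio(make_matrix(v), minsize=20, compute_ht=False)
        assert result.tied_means
        assert result.item_order[0] == "q1"  # lower index first among ties

    def test_no_false_violations_on_well_separated_grm_items(self):
        flagged = 0
        for s in range(25):
            m, _, _ = generate_grm(single_factor_config(seed=9000 + s, n=2000))
            result = check_miio(m, compute_ht=False)
            flagged += result.total_violations > 0
        assert flagged <= 3

    def test_swapping_two_difficulty_vectors_only_relabels_the_order(self):
        cfg = single_factor_config(seed=77, n=3000)
        th = cfg.thresholds.copy()
        cfg_sw = GRMConfig(
            n=3000, seed=77,
            discriminations=cfg.discriminations.copy(),
            thresholds=th[[1, 0, 2, 3, 4, 5, 6, 7, 8]],
            cluster_assignment=np.zeros(9, dtype=int),
        )
        r1 = check_miio(generate_grm(cfg)[0], compute_ht=False)
        r2 = check_miio(generate_grm(cfg_sw)[0], compute_ht=False)
        assert r1.total_violations == r2.total_violations
        relabel = {"anxiety": "sad", "sad": "anxiety"}
        expected = [relabel.get(i, i) for i in r1.item_order]
        assert r2.item_order == expected

    def test_backward_selection_removes_the_crossing_item(self):
        spec = ViolationSpec(
            "no_control", "crossing", depth=0.3, theta_interval=(0.4, 1.8)
        )
        m, _, _ = inject_violation(single_factor_config(seed=321), spec)
        result = check_miio(m, compute_ht=False)
        assert result.total_violations >= 1
        assert any(
            "no_control" in pair for pair, v in result.pair_violations.items() if v
        )
        assert len(result.removed_items) <= 7  # J - 2 bound
        # surviving set is violation-free
        survivors = [i for i in result.item_ids if i not in result.removed_items]
        recheck = check_miio(
            m.select_items(survivors), compute_ht=False
        )
        assert recheck.total_violations == 0


class TestHT:
    def test_parallel_item_profiles_order_perfectly(self):
        # every person's scores are a common shift of one item profile, so
        # the transposed data is Guttman-perfect and H^T = 1
        persons = np.arange(3).repeat(4)
        items = np.array([0, 1, 2, 2, 1, 0, 1, 2])
        v = persons[:, None] + items[None, :]
        ht = compute_HT(make_matrix(v))
        assert ht.value == pytest.approx(1.0, abs=1e-12)
        assert ht.label == "highly accurate"

    def test_matches_brute_force_oracle_on_transposed_matrix(self, rng):
        v = rng.integers(0, 5, (6, 5))
        v[0] = [0, 1, 2, 3, 4]  # guarantee at least one non-constant row
        m = make_matrix(v)
        ht = compute_HT(m)
        keep = v.std(axis=1) > 0
        _, _, expected = brute_force_H(v[keep].T, levels=5)
        assert ht.value == pytest.approx(expected, abs=1e-12)

    def test_constant_respondents_are_excluded_and_counted(self, rng):
        v = rng.integers(0, 5, (10, 4))
        v[3] = 2
        v[7] = 0
        ht = compute_HT(make_matrix(v))
        assert ht.n_constant_excluded == 2
        assert ht.n_respondents_used == 8

    def test_needs_at_least_three_items(self, rng):
        with pytest.raises(ScalemokError):
            compute_HT(make_matrix(rng.integers(0, 5, (10, 2))))

    @pytest.mark.parametrize(
        "value,label",
        [
            (0.219, "cannot be ordered"),
            (0.35, "low"),
            (0.45, "accurate"),
            (0.5, "accurate"),
            (0.51, "highly accurate"),
        ],
    )
    def test_ordering_accuracy_labels(self, value, label):
        assert classify_HT(value) == label

    def test_check_miio_attaches_HT(self):
        m, _, _ = generate_grm(single_factor_config(seed=4, n=500))
        result = check_miio(m)
        assert result.HT is not None
        assert result.HT.value <= 1.0
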