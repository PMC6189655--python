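"""Gwet AC1, percent agreement, intrarater agreement and the jackknife SD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panelagree import (
    RatingsMatrix,
    ReplicateTable,
    ac1_jackknife,
    ac1_sd,
    gwet_ac1,
    intrarater_ac1,
    percent_agreement,
)
from panelagree.agreement import InsufficientRatingsError

from conftest import make_matrix
from oracles import ac1_oracle, cohen_kappa_oracle, jackknife_sd_oracle, percent_oracle, random_grid


class TestGwetAC1:
    def test_unanimous_single_category_is_perfect(self, unanimous_matrix):
        est = gwet_ac1(unanimous_matrix)
        assert est.coefficient == pytest.approx(1.0)
        assert est.pa == pytest.approx(1.0)
        assert est.pe == pytest.approx(0.0)  # pi concentrated on one category

    def test_balanced_binary_chance_is_half(self):
        # category marginals exactly 0.5 -> pe = 2 * 0.25 = 0.5
        m = make_matrix([["1", "1"], ["0", "0"], ["1", "0"], ["0", "1"]])
        assert gwet_ac1(m).pe == pytest.approx(0.5)

    def test_known_grid_matches_hand_computation(self, known_matrix, known_grid):
        est = gwet_ac1(known_matrix)
        assert est.coefficient == pytest.approx(1 / 3, abs=1e-12)
        assert est.coefficient == pytest.approx(ac1_oracle(known_grid, ("0", "1")), abs=1e-12)
        assert est.n_items_used == 4

    def test_matches_oracle_on_random_panels_with_missing(self):
        rng = np.random.default_rng(20240917)
        for _ in range(150):
            grid = random_grid(rng, int(rng.integers(2, 9)), int(rng.integers(2, 6)))
            m = make_matrix(grid)
            assert gwet_ac1(m).coefficient == pytest.approx(
                ac1_oracle(grid, ("0", "1")), abs=1e-12
            )

    @settings(derandomize=True, max_examples=60)
    @given(st.data())
    def test_invariant_under_permutations_and_relabeling(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        grid = random_grid(rng, 6, 4, missing_prob=0.1)
        m = make_matrix(grid)
        base = gwet_ac1(m).coefficient
        perm_items = m.ratings.sample(frac=1, random_state=1)
        perm = RatingsMatrix("f", perm_items[list(reversed(m.rater_ids))], m.categories)
        assert gwet_ac1(perm).coefficient == pytest.approx(base, abs=1e-12)
        # category relabeling: swap codes
        swapped = m.ratings.replace({"0": "1", "1": "0"})
        m2 = RatingsMatrix("f", swapped, ("0", "1"))
        assert gwet_ac1(m2).coefficient == pytest.approx(base, abs=1e-12)

    def test_bounded_above_by_one_and_attained_only_at_pa_one(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            grid = random_grid(rng, 6, 4)
            est = gwet_ac1(make_matrix(grid))
            assert est.coefficient <= 1.0 + 1e-12
            if est.coefficient == pytest.approx(1.0):
                assert est.pa == pytest.approx(1.0)

    def test_robust_to_kappa_paradox_at_extreme_prevalence(self):
        # two raters, 95% raw agreement, prevalence ~0.97 and disjoint rare
        # calls: kappa collapses, AC1 stays near the percent agreement
        a = ["1"] * 97 + ["0"] * 3
        b = ["0", "0"] + ["1"] * 98
        grid = [[x, y] for x, y in zip(a, b)]
        est = gwet_ac1(make_matrix(grid))
        kappa = cohen_kappa_oracle(a, b)
        assert est.coefficient >= kappa
        assert abs(est.coefficient - est.pa) < 0.05
        assert kappa < 0.1  # the paradox: raw agreement is 0.95

    def test_items_without_two_ratings_are_excluded(self):
        m = make_matrix([["1", "1", "1"], ["0", None, None], [None, None, None]])
        est = gwet_ac1(m)
        assert est.n_items_used == 1
        assert est.pa == pytest.approx(1.0)

    def test_all_items_underrated_is_hard_error(self):
        m = make_matrix([["1", None], [None, "0"]])
        with pytest.raises(InsufficientRatingsError):
            gwet_ac1(m)

    def test_single_rater_is_hard_error(self):
        m = make_matrix([["1"], ["0"]])
        with pytest.raises(InsufficientRatingsError):
            gwet_ac1(m)


class TestPercentAgreement:
    def test_perfect_and_total_disagreement(self, unanimous_matrix):
        assert percent_agreement(unanimous_matrix).coefficient == pytest.approx(1.0)
        m = make_matrix([["1", "0"], ["0", "1"], ["1", "0"]])
        assert percent_agreement(m).coefficient == pytest.approx(0.0)

    def test_known_grid_matches_pairwise_oracle(self, known_matrix, known_grid):
        est = percent_agreement(known_matrix)
        assert est.coefficient == pytest.approx(2 / 3, abs=1e-12)
        assert est.coefficient == pytest.approx(percent_oracle(known_grid), abs=1e-12)
        assert est.pe == 0.0


class TestJackknifeSD:
    def test_zero_for_perfect_agreement(self, unanimous_matrix):
        assert ac1_sd(unanimous_matrix) == pytest.approx(0.0)

    def test_zero_for_two_identical_items(self):
        m = make_matrix([["1", "0", "1"], ["1", "0", "1"]])
        assert ac1_sd(m) == pytest.approx(0.0)

    def test_known_grid_matches_looped_oracle(self, known_matrix, known_grid):
        assert ac1_sd(known_matrix) == pytest.approx(
            jackknife_sd_oracle(known_grid, ("0", "1")), abs=1e-12
        )

    def test_random_panels_match_looped_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            grid = random_grid(rng, int(rng.integers(3, 9)), int(rng.integers(2, 6)))
            if sum(sum(v is not None for v in row) >= 2 for row in grid) < 2:
                continue
            m = make_matrix(grid)
            assert ac1_sd(m) == pytest.approx(
                jackknife_sd_oracle(grid, ("0", "1")), abs=1e-12
            )
            assert ac1_jackknife(m).size == sum(
                sum(v is not None for v in row) >= 2 for row in grid
            )

    def test_single_usable_item_is_hard_error(self):
        m = make_matrix([["1", "1"], ["0", None]])
        with pytest.raises(InsufficientRatingsError):
            ac1_sd(m)


class TestIntrarater:
    @staticmethod
    def table(occ1, occ2):
        items = tuple(f"i{k}" for k in range(len(occ1)))
        return ReplicateTable("f", "r1", items, tuple(occ1), tuple(occ2))

    def test_identical_occasions_is_perfect(self):
        occ = ["1", "0"] * 17 + ["1"]  # 35 repeated items
        est = intrarater_ac1(self.table(occ, occ))
        assert est.coefficient == pytest.approx(1.0)
        assert est.n_items_used == 35
        assert est.n_raters == 2

    def test_complementary_balanced_occasions_is_minus_one(self):
        occ1 = ["1", "0"] * 10
        occ2 = ["0", "1"] * 10
        est = intrarater_ac1(self.table(occ1, occ2))
        assert est.pa == pytest.approx(0.0)
        assert est.pe == pytest.approx(0.5)
        assert est.coefficient == pytest.approx(-1.0)

    def test_high_prevalence_pair_matches_oracle(self):
        rng = np.random.default_rng(5)
        occ1 = ["1" if rng.random() < 0.9 else "0" for _ in range(50)]
        occ2 = [v if rng.random() < 0.8 else ("0" if v == "1" else "1") for v in occ1]
        est = intrarater_ac1(self.table(occ1, occ2), categories=("0", "1"))
        grid = [[a, b] for a, b in zip(occ1, occ2)]
        assert est.coefficient == pytest.approx(ac1_oracle(grid, ("0", "1")), abs=1e-12)

    def test_single_item_is_hard_error(self):
        with pytest.raises(InsufficientRatingsError):
            intrarater_ac1(self.table(["1"], ["1"]))
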