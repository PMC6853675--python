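"""Unit and property tests for the active-rank losses and rank assignment."""

import itertools

import numpy as np
import pytest
from scipy.stats import chisquare

from qab.losses import (
    RankedPrediction,
    assign_ranks,
    evaluate_losses,
    loss_min,
    loss_sum,
    mse,
    select_actives,
)


class TestAssignRanks:
    def test_strict_ordering(self):
        np.testing.assert_array_equal(
            assign_ranks(np.array([0.1, 0.9, 0.5])), [2, 0, 1]
        )

    def test_single_molecule(self):
        np.testing.assert_array_equal(assign_ranks(np.array([3.0])), [0])

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            assign_ranks(np.array([1.0, np.nan]))

    def test_tied_predictions_rank_uniformly(self):
        # with all-equal predictions, molecule 0 should land on each of the
        # 4 ranks equally often across seeds
        counts = np.zeros(4)
        for seed in range(2000):
            counts[assign_ranks(np.zeros(4), tie_seed=seed)[0]] += 1
        assert chisquare(counts).pvalue > 1e-3

    def test_partial_ties_respect_strict_order(self):
        pred = np.array([1.0, 2.0, 2.0, 0.5])
        for seed in range(20):
            r = assign_ranks(pred, tie_seed=seed)
            assert sorted(r[[1, 2]]) == [0, 1]  # tied top pair fills ranks 0,1
            assert r[0] == 2 and r[3] == 3


class TestLossMin:
    def test_active_on_top_is_zero(self):
        assert loss_min(np.array([0, 47]), n_test=100, n_active=2) == 0.0

    def test_all_actives_last_is_one(self):
        assert loss_min(np.array([8, 9]), n_test=10, n_active=2) == 1.0

    def test_interior_value(self):
        assert loss_min(np.array([3, 7]), n_test=10, n_active=2) == pytest.approx(0.375)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            loss_min(np.array([0, 1]), n_test=2, n_active=2)


class TestLossSum:
    def test_actives_fill_top_ranks_is_zero(self):
        assert loss_sum(np.array([0, 1]), n_test=10, n_active=2) == 0.0

    def test_corrected_maximum_is_one(self):
        assert loss_sum(np.array([8, 9]), n_test=10, n_active=2) == pytest.approx(1.0)

    def test_single_active_equals_loss_min(self):
        assert loss_sum(np.array([2]), n_test=5, n_active=1) == pytest.approx(0.5)
        assert loss_min(np.array([2]), n_test=5, n_active=1) == pytest.approx(0.5)

    def test_as_printed_denominator_exceeds_one_at_maximum(self):
        # the uncorrected denominator n_act(n_test-n_act-1) is too small by
        # one unit per active, so the worst case lands above 1
        worst = loss_sum(np.array([8, 9]), n_test=10, n_active=2, variant="as_printed")
        assert worst == pytest.approx(8 / 7)

    def test_unknown_variant(self):
        with pytest.raises(ValueError, match="variant"):
            loss_sum(np.array([0]), 5, 1, variant="bogus")


class TestMse:
    def test_identical_vectors(self):
        assert mse(np.arange(4.0), np.arange(4.0)) == 0.0

    def test_hand_value(self):
        assert mse(np.zeros(2), np.array([1.0, 3.0])) == pytest.approx(5.0)

    def test_constant_shift(self):
        y = np.random.default_rng(0).normal(size=50)
        assert mse(y + 0.7, y) == pytest.approx(0.49)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mse(np.zeros(3), np.zeros(4))


class TestExhaustiveSmallInstances:
    """Brute-force enumeration over all rank permutations, Ntest <= 6."""

    @pytest.mark.parametrize("n_test", range(2, 7))
    def test_range_and_attainment(self, n_test):
        for n_act in range(1, n_test):
            top = frozenset(range(n_act))
            last = frozenset(range(n_test - n_act, n_test))
            for active_ranks in itertools.combinations(range(n_test), n_act):
                ar = np.array(active_ranks)
                lm = loss_min(ar, n_test, n_act)
                ls = loss_sum(ar, n_test, n_act)
                assert 0.0 <= lm <= 1.0 and 0.0 <= ls <= 1.0
                assert (ls == 0.0) == (frozenset(active_ranks) == top)
                assert (lm == 1.0) == (frozenset(active_ranks) == last)
                if n_act == 1:
                    assert lm == pytest.approx(ls)

    @pytest.mark.parametrize("n_test", range(3, 7))
    def test_demoting_an_active_never_decreases_loss(self, n_test):
        # swap an active with the adjacent lower-ranked inactive
        for n_act in range(1, n_test - 1):
            for active_ranks in itertools.combinations(range(n_test), n_act):
                s = set(active_ranks)
                for r in active_ranks:
                    if r + 1 < n_test and r + 1 not in s:
                        demoted = np.array(sorted(s - {r} | {r + 1}))
                        before = np.array(sorted(s))
                        assert loss_sum(demoted, n_test, n_act) >= loss_sum(
                            before, n_test, n_act
                        )
                        if r == min(s):
                            assert loss_min(demoted, n_test, n_act) >= loss_min(
                                before, n_test, n_act
                            )


class TestSelectActives:
    def test_ceiling_names_at_least_one(self):
        y = np.arange(100.0)
        actives = select_actives(y, active_fraction=0.001)
        assert actives.n_active == 1
        np.testing.assert_array_equal(actives.active_indices, [99])

    def test_top_fraction_by_true_activity(self):
        y = np.array([5.0, 9.0, 6.0, 8.0, 7.0])
        actives = select_actives(y, active_fraction=0.4)
        np.testing.assert_array_equal(actives.active_indices, [1, 3])

    def test_exact_count_mode(self):
        actives = select_actives(np.arange(10.0), n_active=3)
        np.testing.assert_array_equal(actives.active_indices, [7, 8, 9])

    def test_threshold_ties_resolved_to_exact_size(self, caplog):
        y = np.array([1.0, 2.0, 2.0, 2.0, 3.0])
        with caplog.at_level("WARNING"):
            actives = select_actives(y, n_active=2)
        assert actives.active_indices.size == 2
        assert "ties" in caplog.text

    @pytest.mark.parametrize("kw", [{}, {"active_fraction": 0.1, "n_active": 2}])
    def test_exactly_one_mode_required(self, kw):
        with pytest.raises(ValueError):
            select_actives(np.arange(10.0), **kw)


class TestEvaluateLosses:
    def test_perfect_prediction_has_zero_rank_losses(self):
        y = np.random.default_rng(3).normal(size=40)
        rp = RankedPrediction.from_predictions(y, y)
        actives = select_actives(y, active_fraction=0.1)
        out = evaluate_losses(rp, actives)
        assert out["lmin"] == 0.0
        assert out["lsum"] == 0.0
        assert out["mse"] == 0.0

    def test_inverted_prediction_has_unit_lmin(self):
        y = np.arange(20.0)
        rp = RankedPrediction.from_predictions(-y, y)
        actives = select_actives(y, active_fraction=0.1)
        assert evaluate_losses(rp, actives)["lmin"] == 1.0

    def test_random_predictions_match_order_statistic_mean(self):
        # active ranks of a random ranking are a uniform random subset, so
        # E[lmin] = E[min of n_act draws]/(n_test-n_act) = 1/(n_act+1)
        rng = np.random.default_rng(12)
        y = np.arange(50.0)
        actives = select_actives(y, n_active=4)
        sims = [
            evaluate_losses(
                RankedPrediction.from_predictions(rng.normal(size=50), y), actives
            )["lmin"]
            for _ in range(3000)
        ]
        se = np.std(sims) / np.sqrt(len(sims))
        assert np.mean(sims) == pytest.approx(1 / 5, abs=4 * se + 0.01)
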