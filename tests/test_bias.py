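"""Region classification, accuracy maps and permutation tests."""

import numpy as np
import pandas as pd
import pytest

from tonebias.bias import (
    BIAS_MINUS,
    BIAS_PLUS,
    STRADDLE,
    bias_map,
    classify_region,
    permutation_test_accuracy,
    permutation_test_jnd,
    region_codes,
    region_performance,
)


def make_trials(f1, f2, correct, block_id=0):
    f1 = np.asarray(f1, dtype=float)
    return pd.DataFrame(
        {
            "block_id": block_id,
            "trial_index": np.arange(1, len(f1) + 1),
            "f1_hz": f1,
            "f2_hz": np.asarray(f2, dtype=float),
            "response_first_higher": np.asarray(correct, dtype=int),  # dummy
            "correct": np.asarray(correct, dtype=int),
            "analysis_eligible": True,
            "condition": "none",
        }
    )


class TestClassifyRegion:
    @pytest.mark.parametrize(
        "f1,f2,expected",
        [
            (900.0, 950.0, BIAS_MINUS),  # both low, first lower
            (900.0, 850.0, BIAS_PLUS),  # both low, first higher
            (1100.0, 1150.0, BIAS_PLUS),  # both high, first lower
            (1150.0, 1100.0, BIAS_MINUS),
            (950.0, 1050.0, STRADDLE),  # spans the median
            (1000.0, 1100.0, STRADDLE),  # tone exactly at the median
            (1100.0, 1000.0, STRADDLE),
        ],
    )
    def test_examples(self, f1, f2, expected):
        assert classify_region(f1, f2) == expected

    def test_nonpositive_median_rejected(self):
        with pytest.raises(ValueError):
            classify_region(900.0, 950.0, median_hz=0.0)

    def test_swap_maps_plus_to_minus_and_fixes_straddle(self, rng):
        """Brute force over random pairs: exhaustive, exclusive, swap-dual."""
        f1 = rng.uniform(700.0, 1400.0, size=3000)
        f2 = rng.uniform(700.0, 1400.0, size=3000)
        labels = np.array([classify_region(a, b) for a, b in zip(f1, f2)])
        swapped = np.array([classify_region(b, a) for a, b in zip(f1, f2)])
        assert set(labels) <= {BIAS_PLUS, BIAS_MINUS, STRADDLE}
        assert np.all((labels == BIAS_PLUS) == (swapped == BIAS_MINUS))
        assert np.all((labels == STRADDLE) == (swapped == STRADDLE))
        codes = region_codes(f1, f2)
        assert np.all((codes == 1) == (labels == BIAS_PLUS))
        assert np.all((codes == -1) == (labels == BIAS_MINUS))


class TestRegionPerformance:
    def test_hand_built_counts(self):
        trials = make_trials(
            f1=[1100, 1150, 900, 950],
            f2=[1150, 1100, 1050, 900],
            correct=[1, 0, 1, 1],
        )
        stats = region_performance(trials)
        assert stats[BIAS_PLUS]["n"] == 2  # (1100,1150) and (950,900)
        assert stats[BIAS_MINUS]["n"] == 1
        assert stats[STRADDLE]["n"] == 1
        assert stats[BIAS_PLUS]["frac_correct"] == pytest.approx(1.0)
        assert stats[BIAS_MINUS]["frac_correct"] == pytest.approx(0.0)

    def test_empty_region_is_nan_not_zero(self):
        trials = make_trials(f1=[1100.0], f2=[1150.0], correct=[1])
        stats = region_performance(trials)
        assert np.isnan(stats[BIAS_MINUS]["frac_correct"])

    def test_contraction_direction_from_memory_observer(self, imm_exp1_frame):
        eligible = imm_exp1_frame[imm_exp1_frame["analysis_eligible"]]
        stats = region_performance(eligible, fisher=True)
        assert (
            stats[BIAS_PLUS]["frac_correct"]
            > stats[BIAS_MINUS]["frac_correct"]
        )
        assert stats.fisher_p < 1e-6

    def test_no_bias_for_naive_observer(self, naive_exp1_frame):
        eligible = naive_exp1_frame[naive_exp1_frame["analysis_eligible"]]
        stats = region_performance(eligible)
        diff = (
            stats[BIAS_PLUS]["frac_correct"]
            - stats[BIAS_MINUS]["frac_correct"]
        )
        se = np.hypot(stats[BIAS_PLUS]["sem"], stats[BIAS_MINUS]["sem"])
        assert abs(diff) < 3 * se


class TestBiasMap:
    def test_single_bin_equals_overall_accuracy(self):
        trials = make_trials(
            f1=np.full(60, 950.0),
            f2=np.full(60, 955.0),
            correct=[1] * 45 + [0] * 15,
        )
        edges = np.array([900.0, 1000.0])
        bmap = bias_map(trials, bin_edges=edges, min_count=50)
        assert bmap.counts.sum() == 60
        assert bmap.frac_correct[0, 0] == pytest.approx(0.75)

    def test_under_sampled_bin_masked(self):
        trials = make_trials(
            f1=np.full(49, 950.0), f2=np.full(49, 955.0), correct=[1] * 49
        )
        edges = np.array([900.0, 1000.0])
        bmap = bias_map(trials, bin_edges=edges, min_count=50)
        assert np.isnan(bmap.frac_correct[0, 0])

    def test_counts_partition_trials(self, imm_exp1_frame):
        eligible = imm_exp1_frame[imm_exp1_frame["analysis_eligible"]]
        edges = np.geomspace(500.0, 2000.0, 11)  # covers the full range
        bmap = bias_map(eligible, bin_edges=edges, min_count=50)
        assert bmap.counts.sum() == len(eligible)

    def test_naive_map_roughly_symmetric(self, naive_exp1_frame):
        """History-free data: accuracy depends only on |f1 - f2| distance."""
        eligible = naive_exp1_frame[naive_exp1_frame["analysis_eligible"]]
        edges = np.geomspace(750.0, 1350.0, 7)
        bmap = bias_map(eligible, bin_edges=edges, min_count=50)
        both = ~np.isnan(bmap.frac_correct) & ~np.isnan(bmap.frac_correct.T)
        diffs = (bmap.frac_correct - bmap.frac_correct.T)[both]
        assert np.nanmax(np.abs(diffs)) < 0.15

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bias_map(make_trials([], [], []))


class TestPermutationAccuracy:
    def test_zero_statistic_gives_half_p(self):
        trials = make_trials(
            f1=[1100.0] * 100 + [1150.0] * 100,
            f2=[1150.0] * 100 + [1100.0] * 100,
            correct=[1] * 50 + [0] * 50 + [1] * 50 + [0] * 50,
        )
        res = permutation_test_accuracy(trials, n_perm=4000, seed=0)
        assert res.observed == pytest.approx(0.0)
        assert 0.4 < res.p_value < 0.7

    def test_strong_bias_reaches_minimum_p(self, imm_exp1_frame):
        eligible = imm_exp1_frame[imm_exp1_frame["analysis_eligible"]]
        n_perm = 999
        res = permutation_test_accuracy(eligible, n_perm=n_perm, seed=0)
        assert res.p_value == pytest.approx(1.0 / (1 + n_perm))

    def test_empty_region_rejected(self):
        trials = make_trials(f1=[1100.0] * 60, f2=[1150.0] * 60, correct=[1] * 60)
        with pytest.raises(ValueError, match="region is empty"):
            permutation_test_accuracy(trials, n_perm=10)

    def test_zero_permutations_rejected(self, imm_exp1_frame):
        eligible = imm_exp1_frame[imm_exp1_frame["analysis_eligible"]]
        with pytest.raises(ValueError):
            permutation_test_accuracy(eligible, n_perm=0)


class TestPermutationJnd:
    def test_memory_population_has_small_p(self, imm_exp1_frame):
        eligible = imm_exp1_frame[imm_exp1_frame["analysis_eligible"]]
        sub = eligible[eligible["block_id"] < 15]
        res = permutation_test_jnd(sub, n_perm=99, seed=0)
        assert res.observed > 0  # JND- exceeds JND+
        assert res.p_value <= 0.05

    def test_zero_permutations_rejected(self, imm_exp1_frame):
        eligible = imm_exp1_frame[imm_exp1_frame["analysis_eligible"]]
        with pytest.raises(ValueError):
            permutation_test_jnd(eligible, n_perm=0)
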