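"""Array-stage operations: background, detection, normalization, DE, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirserca.array_de import (
    average_linkage,
    cluster_order,
    correct_background,
    cyclic_lowess,
    de_test,
    detection_call,
    dye_swap_ratio,
)
from mirserca.model_io import ModelIOError


class TestCorrectBackground:
    def test_constant_background_subtracted(self):
        sig = np.full(50, 500.0)
        bg = np.full(50, 100.0)
        assert np.allclose(correct_background(sig, bg), 400.0)

    def test_floor_clamp(self):
        out = correct_background(np.full(30, 10.0), np.full(30, 100.0))
        assert np.all(out >= 1.0)

    def test_gradient_removed(self):
        rng = np.random.default_rng(3)
        n = 400
        idx = np.arange(n)
        bg_true = 100 + 0.5 * idx
        sig = 800.0 + bg_true + rng.normal(0, 5, n)
        pre_slope = stats.linregress(idx, sig).slope
        post_slope = stats.linregress(idx, correct_background(sig, bg_true)).slope
        assert abs(post_slope) < 0.01 * abs(pre_slope)

    def test_negative_signal_rejected(self):
        with pytest.raises(ModelIOError):
            correct_background([-1.0] * 30, [0.0] * 30)


class TestDetectionCall:
    @pytest.mark.parametrize(
        "reps,expected",
        [
            ([10, 10, 10, 1, 1], True),  # 3 of 5 above
            ([10, 10, 1, 1, 1], False),  # only 2 above
            ([5, 5, 5, 5, 5], False),  # equality is not "above"
        ],
    )
    def test_three_of_five_rule(self, reps, expected):
        assert detection_call(reps, level=5.0) is expected

    def test_wrong_replicate_count_rejected(self):
        with pytest.raises(ModelIOError):
            detection_call([1, 2, 3], level=0.0)

    def test_monotone_in_level(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            reps = rng.uniform(0, 100, 5)
            calls = [detection_call(reps, lv) for lv in np.linspace(0, 120, 25)]
            assert all(a or not b for a, b in zip(calls, calls[1:]))  # never re-detects


class TestCyclicLowess:
    def test_constant_scale_removed(self):
        rng = np.random.default_rng(11)
        ch1 = rng.normal(10, 1.5, 200)
        mat = np.column_stack([ch1, ch1 + np.log2(3.0)])  # channel2 = 3x channel1
        norm = cyclic_lowess(mat)
        assert abs(np.median(norm[:, 0] - norm[:, 1])) <= 0.01

    def test_total_intensity_preserved(self):
        rng = np.random.default_rng(12)
        mat = rng.normal(10, 1.5, size=(150, 2))
        norm = cyclic_lowess(mat)
        assert np.allclose(norm.sum(axis=1), mat.sum(axis=1), atol=1e-8)

    def test_sigmoid_dye_bias_flattened_per_decile(self):
        rng = np.random.default_rng(13)
        a = rng.normal(10, 1.5, 500)
        m_true = rng.normal(0, 0.1, 500)
        bias = 1.0 / (1 + np.exp(-(a - 10)))
        ch1 = a + (m_true + bias) / 2
        ch2 = a - (m_true + bias) / 2
        norm = cyclic_lowess(np.column_stack([ch1, ch2]))
        m = norm[:, 0] - norm[:, 1]
        deciles = pd.qcut(0.5 * (norm[:, 0] + norm[:, 1]), 10, labels=False)
        for d in range(10):
            assert abs(np.median(m[deciles == d])) < 0.05

    def test_already_normalized_input_unchanged(self):
        rng = np.random.default_rng(14)
        a = rng.normal(10, 1.5, 150)
        m = rng.normal(0, 0.3, 150)
        m -= np.median(m)  # bias-free: median M is exactly 0
        mat = np.column_stack([a + m / 2, a - m / 2])
        out = cyclic_lowess(mat)
        assert np.max(np.abs(out - mat)) < 0.01

    def test_too_few_probes_rejected(self):
        with pytest.raises(ModelIOError):
            cyclic_lowess(np.zeros((10, 2)))


class TestDyeSwapRatio:
    @pytest.mark.parametrize("mf,ms,expected", [(2.0, -2.0, 2.0), (0.0, 0.0, 0.0)])
    def test_examples(self, mf, ms, expected):
        assert dye_swap_ratio(mf, ms) == expected

    def test_additive_dye_offset_cancels(self):
        m, d = 1.7, 0.9
        assert dye_swap_ratio(m + d, -m + d) == pytest.approx(m)


class TestDETest:
    def test_all_zero_ratios_not_de(self):
        res = de_test([0.0, 0.0, 0.0, 0.0])
        assert res.mean_log2 == 0.0
        assert not res.de
        assert res.degenerate  # zero variance

    def test_single_ratio_degenerate(self):
        res = de_test([1.0])
        assert res.degenerate and res.p_value is None

    def test_planted_shift_power(self):
        # 2-pooled-SD shift with 15 ratios: detected in >= 95% of simulations
        rng = np.random.default_rng(15)
        hits = 0
        n_sim = 300
        for _ in range(n_sim):
            ratios = rng.normal(2.0, 1.0, 15)
            if de_test(ratios, alpha=0.01).de:
                hits += 1
        assert hits / n_sim >= 0.95

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(16)
        calls = sum(
            de_test(rng.normal(0, 1, 15), alpha=0.01).de for _ in range(400)
        )
        assert calls / 400 <= 0.05


class TestClusterOrder:
    def test_identical_rows_are_adjacent(self):
        rng = np.random.default_rng(17)
        data = rng.normal(0, 1, size=(6, 8))
        data[4] = data[1]  # duplicate row
        frame = pd.DataFrame(data, index=[f"m{i}" for i in range(6)])
        order = cluster_order(frame)
        assert abs(order.index("m1") - order.index("m4")) == 1

    def test_four_row_tree_matches_exhaustive_average_linkage(self):
        rng = np.random.default_rng(18)
        for _ in range(10):
            data = rng.normal(0, 1, size=(4, 10))
            z = average_linkage(data)
            merge_heights = sorted(z[:, 2])
            expected = sorted(_brute_average_linkage_heights(data))
            assert np.allclose(merge_heights, expected, atol=1e-9)

    def test_constant_row_handled(self):
        data = np.vstack([np.ones(6), np.arange(6.0), -np.arange(6.0)])
        frame = pd.DataFrame(data, index=["flat", "up", "down"])
        order = cluster_order(frame)
        assert sorted(order) == ["down", "flat", "up"]


def _brute_average_linkage_heights(data):
    """Average-linkage merge heights by direct simulation on 1 - Pearson."""
    n = data.shape[0]
    d = {}
    for i, j in itertools.combinations(range(n), 2):
        d[frozenset((i, j))] = 1 - np.corrcoef(data[i], data[j])[0, 1]
    clusters = {frozenset((i,)) for i in range(n)}
    heights = []

    def dist(c1, c2):
        return np.mean([d[frozenset((a, b))] for a in c1 for b in c2])

    while len(clusters) > 1:
        best = min(
            (c for c in itertools.combinations(clusters, 2)),
            key=lambda c: dist(*c),
        )
        heights.append(dist(*best))
        clusters -= set(best)
        clusters.add(best[0] | best[1])
    return heights
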