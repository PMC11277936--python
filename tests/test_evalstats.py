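"""Validation-statistics unit tests with independent oracles.

AUC is checked against exhaustive concordant-pair counting, the DeLong
variance against a bootstrap, and Wilson/chi-square values against the
published clinical tables they reconstruct.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pneumocl.evalstats import (
    MetricEstimate,
    auc,
    chi_square_test,
    confusion_counts,
    delong_ci,
    delong_variance,
    majority_vote,
    one_sample_z,
    subgroup_report,
    wilson_ci,
)


def pair_count_auc(scores, labels):
    """Brute-force AUC oracle: concordant pairs, ties count 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionCounts:
    def test_hand_example(self):
        cc = confusion_counts([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0], threshold=0.75)
        assert (cc.tp, cc.fp, cc.fn, cc.tn) == (1, 1, 1, 1)

    def test_perfect_scores(self):
        cc = confusion_counts([0.9, 0.1, 0.95, 0.05], [1, 0, 1, 0], 0.5)
        assert cc.fn == 0 and cc.fp == 0

    def test_ties_call_positive(self):
        cc = confusion_counts([0.5, 0.5, 0.5], [1, 0, 1], threshold=0.5)
        assert cc.fn == 0 and cc.tn == 0 and cc.fp == 1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            confusion_counts([], [], 0.5)


class TestWilson:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (66, 68, (0.90, 0.99)),   # overall sensitivity row
            (225, 232, (0.94, 0.99)),  # overall specificity row
            (24, 24, (0.86, 1.00)),   # all-detected subgroup
        ],
    )
    def test_published_rows(self, k, n, expected):
        lo, hi = wilson_ci(k, n, 0.95)
        assert (round(lo, 2), round(hi, 2)) == expected

    @pytest.mark.parametrize("n", [2, 10, 100])
    def test_symmetric_at_half(self, n):
        lo, hi = wilson_ci(n // 2, n, 0.95)
        assert lo + hi == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("k,n", [(0, 5), (5, 5), (3, 7), (50, 80)])
    def test_contains_point_estimate(self, k, n):
        lo, hi = wilson_ci(k, n)
        assert lo <= k / n <= hi
        assert 0.0 <= lo and hi <= 1.0

    def test_width_shrinks_with_n(self):
        widths = []
        for n in (10, 40, 160, 640):
            lo, hi = wilson_ci(int(0.8 * n), n)
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wilson_ci(1, 0)
        with pytest.raises(ValueError):
            wilson_ci(6, 5)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(1, 500).flatmap(
        lambda n: st.tuples(st.integers(0, n), st.just(n))
    ))
    def test_interval_always_valid(self, kn):
        k, n = kn
        lo, hi = wilson_ci(k, n)
        assert 0.0 <= lo <= k / n <= hi <= 1.0


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_hand_example(self):
        assert auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 13))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            # coarse grid scores force plenty of ties
            scores = rng.integers(0, 4, size=n) / 3.0
            assert auc(scores, labels) == pytest.approx(
                pair_count_auc(scores, labels)
            )


class TestDeLong:
    def test_perfect_separation_zero_variance(self):
        scores = np.r_[np.linspace(0.8, 1.0, 30), np.linspace(0.0, 0.2, 30)]
        labels = np.r_[np.ones(30), np.zeros(30)]
        est = delong_ci(scores, labels)
        assert est.estimate == 1.0
        assert est.ci_low == est.ci_high == 1.0

    def test_label_swap_symmetry(self, rng):
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.5).astype(int)
        labels[:2], labels[-2:] = 1, 0
        a1, v1 = delong_variance(scores, labels)
        a2, v2 = delong_variance(scores, 1 - labels)
        assert a2 == pytest.approx(1.0 - a1)
        assert v2 == pytest.approx(v1)

    def test_se_close_to_bootstrap(self, rng):
        n = 100
        scores = np.r_[rng.normal(1.0, 1, n), rng.normal(0.0, 1, n)]
        labels = np.r_[np.ones(n, int), np.zeros(n, int)]
        _, var = delong_variance(scores, labels)
        boot = []
        for _ in range(2000):
            ip = rng.integers(0, n, n)
            ineg = rng.integers(0, n, n) + n
            idx = np.r_[ip, ineg]
            boot.append(auc(scores[idx], labels[idx]))
        boot_se = np.std(boot, ddof=1)
        assert abs(np.sqrt(var) - boot_se) / boot_se < 0.15

    def test_degenerate_class_errors(self):
        with pytest.raises(ValueError):
            delong_ci([0.1, 0.9, 0.5], [1, 0, 0])


class TestOneSampleZ:
    def test_sensitivity_vs_goal(self):
        res = one_sample_z(66 / 68, p0=0.8, n=68, alpha=0.025)
        assert res.statistic == pytest.approx(3.52, abs=0.01)
        assert res.reject

    def test_null_value_gives_half(self):
        res = one_sample_z(0.8, p0=0.8, n=50)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.5)
        assert not res.reject

    def test_below_goal_upper_tail(self):
        res = one_sample_z(0.7, p0=0.8, n=50, sided="upper")
        assert res.p_value > 0.5 and not res.reject

    def test_auc_variance_route(self):
        res = one_sample_z(0.98, p0=0.95, variance=1e-4, alpha=0.025)
        assert res.statistic == pytest.approx(3.0)
        assert res.reject


class TestChiSquare:
    def test_gender_table(self):
        res = chi_square_test(((114, 24), (118, 44)))
        assert round(res.p_value, 4) == 0.0607

    def test_source_table(self):
        res = chi_square_test(((158, 42), (74, 26)))
        assert round(res.p_value, 4) == 0.4072

    def test_independent_table(self):
        res = chi_square_test(((20, 40), (10, 20)), correction="never")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_uncorrected_matches_hand_pearson(self):
        tab = np.array([[30, 10], [20, 40]], dtype=float)
        exp = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
        hand = ((tab - exp) ** 2 / exp).sum()
        res = chi_square_test(tab, correction="never")
        assert res.statistic == pytest.approx(hand)

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError):
            chi_square_test(((0, 0), (5, 7)))


class TestMajorityVote:
    def test_two_of_three_present(self):
        gt = majority_vote([True, True, False], ["large", "large", None])
        assert gt.present and gt.size_class == "large" and not gt.size_tie

    def test_all_absent(self):
        gt = majority_vote([False, False, False])
        assert not gt.present and gt.size_class == "none"

    def test_size_tie_resolves_small(self):
        gt = majority_vote(
            [True, True, False], ["large", "small", None], ["RUL", "RUL", None]
        )
        assert gt.present and gt.size_class == "small" and gt.size_tie
        assert gt.location == "RUL"

    def test_wrong_reader_count_errors(self):
        with pytest.raises(ValueError):
            majority_vote([True, False])


class TestSubgroupReport:
    def _toy(self, rng, n=80):
        import pandas as pd

        y = (rng.random(n) < 0.4).astype(int)
        y[:2] = [0, 1]
        scores = np.clip(0.5 + 0.3 * (y - 0.5) + rng.normal(0, 0.2, n), 0, 1)
        meta = pd.DataFrame(
            {
                "sex": rng.choice(["male", "female"], n),
                "size_class": np.where(
                    y == 1, rng.choice(["large", "small"], n), "none"
                ),
            }
        )
        return scores, y, meta

    def test_single_stratum_equals_overall(self, rng):
        import pandas as pd

        scores, y, _ = self._toy(rng)
        meta = pd.DataFrame({"sex": ["female"] * len(y)})
        table = subgroup_report(scores, y, meta, variables=("sex",))
        overall = table[table.variable == "overall"].iloc[0]
        row = table[table.variable == "sex"].iloc[0]
        assert row.sensitivity == overall.sensitivity
        assert row.auc == pytest.approx(overall.auc)

    def test_wilson_bounds_compositional(self, rng):
        scores, y, meta = self._toy(rng)
        table = subgroup_report(scores, y, meta, variables=("sex",))
        for _, row in table[table.variable == "sex"].iterrows():
            mask = meta["sex"].to_numpy() == row.stratum
            cc = confusion_counts(scores[mask], y[mask], 0.5)
            lo, hi = wilson_ci(cc.tp, cc.n_positive)
            assert row.sens_low == pytest.approx(lo)
            assert row.sens_high == pytest.approx(hi)

    def test_no_positive_stratum_flagged(self):
        import pandas as pd

        scores = [0.1, 0.2, 0.9, 0.8]
        y = [0, 0, 1, 1]
        meta = pd.DataFrame({"sex": ["male", "male", "female", "female"]})
        table = subgroup_report(scores, y, meta, variables=("sex",))
        male = table[(table.variable == "sex") & (table.stratum == "male")].iloc[0]
        assert "no-positives" in male.flag


def test_metric_estimate_rejects_inverted_interval():
    with pytest.raises(ValueError):
        MetricEstimate("x", 0.5, 0.6, 0.9, "wilson")
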