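import numpy as np
import pytest

import mircervix as mc
from mircervix.config import InterpretConfig
from mircervix.evaluate import (
    CATEGORY_CONFIRM,
    CATEGORY_ELEVATED,
    CATEGORY_NORMAL,
    categorize,
)


def _results(pairs):
    """pairs: list of (diagnosis, score[, hpv])."""
    out = []
    for i, item in enumerate(pairs):
        diag, score, *rest = item
        hpv = rest[0] if rest else "UNKNOWN"
        out.append(
            mc.ScoreResult(f"S{i}", score, diagnosis=diag, hpv_status=hpv)
        )
    return out


def _pair_counting_auc(scores, y):
    """O(n^2) concordance oracle: fraction of (positive, negative) pairs
    ranked correctly, ties counted half."""
    pos = [s for s, label in zip(scores, y) if label == 1]
    neg = [s for s, label in zip(scores, y) if label == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (len(pos) * len(neg))


class TestClassify:
    @pytest.mark.parametrize(
        "score, cutoff, expected",
        [(0.49, 0.49, "POSITIVE"), (0.48, 0.49, "NEGATIVE"), (0.80, 0.77, "POSITIVE")],
    )
    def test_boundary_inclusive(self, score, cutoff, expected):
        assert mc.classify(score, cutoff) == expected

    def test_boundary_flippable(self):
        assert mc.classify(0.49, 0.49, positive_at_cutoff=False) == "NEGATIVE"

    def test_three_band_categories(self):
        config = InterpretConfig()
        assert categorize(0.2, config) == CATEGORY_NORMAL
        assert categorize(0.49, config) == CATEGORY_ELEVATED
        assert categorize(0.60, config) == CATEGORY_ELEVATED
        assert categorize(0.77, config) == CATEGORY_CONFIRM
        assert categorize(0.95, config) == CATEGORY_CONFIRM


class TestConfusion:
    def test_hand_enumerated_six_sample_toy(self):
        results = _results(
            [("HSIL", 0.9), ("HSIL", 0.6), ("HSIL", 0.3),
             ("NILM", 0.7), ("NILM", 0.2), ("NILM", 0.1)]
        )
        counts = mc.confusion(results, cutoff=0.49)
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (2, 1, 2, 1)

    def test_perfect_separation_has_no_errors(self):
        results = _results([("HSIL", 1.0)] * 3 + [("NILM", 0.0)] * 3)
        counts = mc.confusion(results, cutoff=0.5)
        assert counts.fp == counts.fn == 0

    def test_all_zero_scores_call_nothing_positive(self):
        results = _results([("HSIL", 0.0), ("NILM", 0.0)])
        counts = mc.confusion(results, cutoff=0.5)
        assert counts.tp == counts.fp == 0

    def test_unknown_diagnosis_is_error(self):
        results = _results([("UNKNOWN", 0.5)])
        with pytest.raises(ValueError, match="UNKNOWN"):
            mc.confusion(results, cutoff=0.5)


class TestMetrics:
    def test_perfect_classifier_rates_all_100(self):
        rates = mc.metrics(mc.ConfusionCounts(tp=10, fp=0, tn=10, fn=0))
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            assert rates[name] == pytest.approx(100.0)

    def test_zero_denominator_is_undefined_not_zero(self):
        rates = mc.metrics(mc.ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert rates["ppv"] is None
        assert rates["sensitivity"] is None
        assert rates["specificity"] == pytest.approx(100.0)

    def test_precision_is_ppv(self):
        rates = mc.metrics(mc.ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
        assert rates["precision"] == rates["ppv"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mc.ConfusionCounts(tp=-1, fp=0, tn=1, fn=0)


class TestROC:
    def test_perfect_separation_auc_1(self):
        _, auc = mc.roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert auc == pytest.approx(1.0)

    def test_all_ties_auc_half(self):
        _, auc = mc.roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert auc == pytest.approx(0.5)

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            mc.roc_auc([0.1, 0.9], [1, 1])

    @pytest.mark.parametrize("seed", range(6))
    def test_trapezoid_equals_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        y = np.zeros(n, dtype=int)
        y[: n // 2] = 1
        rng.shuffle(y)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        scores = rng.choice(np.linspace(0, 1, 11), size=n)  # force ties
        _, auc = mc.roc_auc(scores, y)
        assert auc == pytest.approx(_pair_counting_auc(scores, y), abs=1e-12)

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(1)
        scores = rng.random(60)
        y = (rng.random(60) > 0.5).astype(int)
        curve, _ = mc.roc_auc(scores, y)
        tprs = [tpr for _, tpr, _ in curve]
        fprs = [fpr for _, _, fpr in curve]
        assert all(a <= b + 1e-12 for a, b in zip(tprs, tprs[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(fprs, fprs[1:]))

    def test_confusion_sweep_reproduces_roc_points(self):
        rng = np.random.default_rng(4)
        scores = np.round(rng.random(40), 2)
        labels = (rng.random(40) > 0.5).astype(int)
        results = _results(
            [("HSIL" if l else "NILM", s) for s, l in zip(scores, labels)]
        )
        curve, _ = mc.roc_auc(scores, labels)
        for threshold, tpr, fpr in curve:
            if not 0.0 <= threshold <= 1.0:  # sentinel endpoint
                continue
            counts = mc.confusion(results, cutoff=threshold)
            assert counts.tp / (counts.tp + counts.fn) == pytest.approx(tpr)
            assert counts.fp / (counts.fp + counts.tn) == pytest.approx(fpr)

    def test_sensitivity_specificity_monotone_in_cutoff(self):
        rng = np.random.default_rng(2)
        results = _results(
            [("HSIL" if rng.random() > 0.4 else "NILM", float(np.round(rng.random(), 3)))
             for _ in range(80)]
        )
        sens, spec = [], []
        for cutoff in np.linspace(0.01, 0.99, 25):
            rates = mc.metrics(mc.confusion(results, cutoff))
            sens.append(rates["sensitivity"])
            spec.append(rates["specificity"])
        assert all(a >= b - 1e-9 for a, b in zip(sens, sens[1:]))
        assert all(a <= b + 1e-9 for a, b in zip(spec, spec[1:]))


class TestMannWhitney:
    def test_identical_multisets_are_symmetric(self):
        a = [0.1, 0.4, 0.4, 0.9]
        u, p = mc.mann_whitney(a, list(a))
        assert u == pytest.approx(len(a) ** 2 / 2)
        assert p > 0.9

    def test_fully_separated_triples_exact_p(self):
        u, p = mc.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 * 1/C(6,3)

    def test_rank_invariance_under_scaling(self):
        a, b = [0.1, 0.5, 0.2], [0.7, 0.9, 0.3, 0.4]
        assert mc.mann_whitney(a, b) == mc.mann_whitney([2 * x for x in a], [2 * x for x in b])

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            mc.mann_whitney([], [1.0])

    def test_agrees_with_permutation_test(self):
        """Asymptotic tie-corrected p within Monte-Carlo error of a
        100,000-shuffle permutation null on a toy with ties."""
        rng = np.random.default_rng(0)
        a = np.array([0.1, 0.2, 0.2, 0.5, 0.6, 0.8, 0.9, 1.0, 0.4, 0.3])
        b = np.array([0.05, 0.1, 0.3, 0.3, 0.4, 0.2, 0.6, 0.7, 0.15, 0.25])
        u_obs, p = mc.mann_whitney(a, b)
        pooled = np.concatenate([a, b])
        n_a = len(a)
        n_shuffles = 100_000
        from scipy.stats import rankdata

        ranks = rankdata(pooled)
        count = 0
        null_center = n_a * len(b) / 2
        for _ in range(n_shuffles):
            perm = rng.permutation(len(pooled))
            u_perm = ranks[perm[:n_a]].sum() - n_a * (n_a + 1) / 2
            if abs(u_perm - null_center) >= abs(u_obs - null_center):
                count += 1
        p_perm = count / n_shuffles
        se = np.sqrt(p_perm * (1 - p_perm) / n_shuffles)
        assert abs(p - p_perm) < 3 * se + 0.01


class TestKruskalWallis:
    def test_identical_groups_give_zero_h(self):
        h, p, means = mc.kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-9)
        assert means == [2.0, 2.0, 2.0]

    def test_two_groups_reduce_to_squared_mw_deviate(self):
        """For two tie-free groups H equals the squared standardized U
        (no continuity correction) — checked numerically."""
        rng = np.random.default_rng(3)
        a = rng.random(12)
        b = rng.random(15) + 0.2
        h, _, _ = mc.kruskal_wallis([a, b])
        u, _ = mc.mann_whitney(a, b)
        n1, n2 = len(a), len(b)
        z = (u - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert h == pytest.approx(z**2, rel=1e-9)

    def test_three_separated_groups_significant(self):
        h, p, means = mc.kruskal_wallis(
            [[0.1, 0.15, 0.2, 0.25], [0.5, 0.55, 0.6, 0.65], [0.8, 0.85, 0.9, 0.95]]
        )
        assert p < 0.05
        assert means[0] < means[1] < means[2]

    def test_single_group_is_error(self):
        with pytest.raises(ValueError):
            mc.kruskal_wallis([[1, 2, 3]])


class TestEvaluateScores:
    def test_full_report_structure(self):
        rng = np.random.default_rng(5)
        pairs = []
        for _ in range(30):
            pairs.append(("NILM", float(rng.uniform(0, 0.6)), "NEG"))
        for _ in range(30):
            hpv = "POS" if rng.random() < 0.7 else "NEG"
            pairs.append(("HSIL", float(rng.uniform(0.3, 1.0)), hpv))
        report = mc.evaluate_scores(_results(pairs))
        payload = report.to_dict()
        assert payload["n_scored"] == 60
        assert 0 <= payload["auc"] <= 1
        assert payload["metrics"]["screen"]["sensitivity"] is not None
        assert payload["kruskal_wallis"] is not None
        assert report.group_means["HSIL"] > report.group_means["NILM"]

    def test_single_class_is_error(self):
        with pytest.raises(ValueError, match="both NILM and HSIL"):
            mc.evaluate_scores(_results([("NILM", 0.2), ("NILM", 0.4)]))
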