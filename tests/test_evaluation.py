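"""ROC/AUC, DeLong, threshold selection, diagnostic indices and NRI, each
checked against an independent brute-force oracle."""

import numpy as np
import pytest

from elshydro.evaluation import (
    closest_topleft,
    continuous_nri,
    delong_test,
    indices_at,
    reclassification_data,
    roc,
)


def pair_counting_auc(probs, labels):
    """O(n^2) Mann-Whitney oracle: P(case > control) + half ties."""
    x = probs[labels == 1]
    y = probs[labels == 0]
    wins = sum((xi > y).sum() + 0.5 * (xi == y).sum() for xi in x)
    return wins / (len(x) * len(y))


class TestRoc:
    def test_perfect_separation(self):
        r = roc([0.9, 0.8, 0.3, 0.2], np.array([1, 1, 0, 0]))
        assert r.auc == pytest.approx(1.0)

    def test_constant_probs_auc_half(self):
        r = roc([0.4] * 6, np.array([1, 0, 1, 0, 0, 1]))
        assert r.auc == pytest.approx(0.5)

    def test_trapezoid_equals_pair_counting(self, rng):
        """Trapezoidal area equals the Mann-Whitney pair count, with and
        without ties."""
        for _ in range(10):
            n = 200
            labels = rng.integers(0, 2, n).astype(float)
            if labels.sum() in (0, n):
                continue
            probs = np.round(rng.random(n), 2)  # rounding forces ties
            assert roc(probs, labels).auc == pytest.approx(
                pair_counting_auc(probs, labels), abs=1e-12
            )

    def test_curve_monotone_and_endpoints(self, rng):
        labels = rng.integers(0, 2, 50).astype(float)
        labels[:2] = [0, 1]
        probs = rng.random(50)
        r = roc(probs, labels)
        assert (np.diff(r.fpr) >= 0).all() and (np.diff(r.tpr) >= 0).all()
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)

    def test_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        labels = rng.integers(0, 2, 300).astype(float)
        labels[:2] = [0, 1]
        probs = rng.random(300)
        assert roc(probs, labels).auc == pytest.approx(
            sk.roc_auc_score(labels, probs), abs=1e-12
        )

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc([0.1, 0.2], np.array([1, 1]))


class TestClosestTopLeft:
    def test_perfect_classifier_zero_distance(self):
        r = roc([0.9, 0.8, 0.3, 0.2], np.array([1, 1, 0, 0]))
        thr = closest_topleft(r)
        idx = indices_at([0.9, 0.8, 0.3, 0.2], np.array([1, 1, 0, 0]), thr)
        assert idx.sensitivity == 1.0 and idx.specificity == 1.0

    def test_exhaustive_argmin(self, rng):
        """Matches brute-force argmin over all ROC points (higher threshold
        on ties)."""
        for _ in range(20):
            labels = rng.integers(0, 2, 50).astype(float)
            labels[:2] = [0, 1]
            probs = np.round(rng.random(50), 1)
            r = roc(probs, labels)
            d2 = (1 - r.tpr) ** 2 + r.fpr**2
            best = max(r.thresholds[i] for i in range(len(d2)) if d2[i] == d2.min())
            assert closest_topleft(r) == best or (
                not np.isfinite(best) and np.isfinite(closest_topleft(r))
            )

    def test_tie_takes_higher_threshold(self):
        # symmetric two-point ROC: (0, .5) at t=.8 and (.5, 1) at t=.2
        probs = np.array([0.8, 0.2, 0.8, 0.2])
        labels = np.array([1, 1, 0, 0])
        r = roc(probs, labels)
        assert closest_topleft(r) == pytest.approx(0.8)


class TestIndices:
    def test_threshold_extremes(self):
        probs = np.array([0.2, 0.6, 0.9])
        labels = np.array([0, 1, 1])
        assert indices_at(probs, labels, 0.0).sensitivity == 1.0
        assert indices_at(probs, labels, 0.95).specificity == 1.0

    def test_reported_confusion_counts(self):
        """Counts mirroring the published 3D-model confusion: sensitivity
        71/86, specificity 88/94."""
        probs = np.r_[np.full(71, 0.9), np.full(15, 0.1), np.full(6, 0.9), np.full(88, 0.1)]
        labels = np.r_[np.ones(86), np.zeros(94)]
        idx = indices_at(probs, labels, 0.5)
        assert (idx.tp, idx.fn, idx.fp, idx.tn) == (71, 15, 6, 88)
        assert idx.sensitivity == pytest.approx(71 / 86)
        assert idx.specificity == pytest.approx(88 / 94)
        assert idx.ppv == pytest.approx(71 / 77)
        assert idx.npv == pytest.approx(88 / 103)

    def test_undefined_index_is_nan(self):
        probs = np.array([0.1, 0.2])
        labels = np.array([0, 1])
        idx = indices_at(probs, labels, 0.9)  # nobody predicted positive
        assert np.isnan(idx.ppv)
        assert idx.specificity == 1.0


class TestDelong:
    def test_identical_models(self, rng):
        labels = rng.integers(0, 2, 40).astype(float)
        labels[:2] = [0, 1]
        p = rng.random(40)
        res = delong_test(p, p, labels)
        assert res.p_value == 1.0 and res.degenerate

    def test_swap_symmetry(self, rng):
        labels = rng.integers(0, 2, 100).astype(float)
        labels[:2] = [0, 1]
        a, b = rng.random(100), rng.random(100)
        r1 = delong_test(a, b, labels)
        r2 = delong_test(b, a, labels)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_variance_against_paired_bootstrap(self, rng):
        """DeLong's analytic variance of the AUC difference agrees with a
        500-replicate paired bootstrap within 20%."""
        n = 300
        labels = (rng.random(n) < 0.5).astype(float)
        signal = labels + rng.standard_normal(n)
        probs_a = 1 / (1 + np.exp(-(signal + rng.standard_normal(n))))
        probs_b = 1 / (1 + np.exp(-(signal + 0.5 * rng.standard_normal(n))))
        res = delong_test(probs_a, probs_b, labels)
        diffs = []
        for _ in range(500):
            idx = rng.integers(0, n, n)
            if labels[idx].sum() in (0, n):
                continue
            diffs.append(
                pair_counting_auc(probs_b[idx], labels[idx])
                - pair_counting_auc(probs_a[idx], labels[idx])
            )
        boot_var = np.var(diffs, ddof=1)
        assert res.var_diff == pytest.approx(boot_var, rel=0.2)

    def test_unpaired_rejected(self, rng):
        with pytest.raises(ValueError):
            delong_test(rng.random(5), rng.random(6), np.array([0, 1, 0, 1, 0]))


class TestNri:
    def test_no_movement(self, rng):
        labels = np.array([0, 1, 0, 1])
        p = rng.random(4)
        res = continuous_nri(p, p, labels)
        assert res.nri == 0.0 and res.degenerate

    def test_maximum(self):
        labels = np.array([1, 1, 0, 0])
        old = np.array([0.5, 0.5, 0.5, 0.5])
        new = np.array([0.9, 0.8, 0.1, 0.2])
        assert continuous_nri(old, new, labels).nri == pytest.approx(2.0)

    def test_counting_oracle(self, rng):
        """NRI equals the direct four-proportion count."""
        n = 200
        labels = rng.integers(0, 2, n).astype(float)
        labels[:2] = [0, 1]
        old = np.round(rng.random(n), 2)
        new = np.round(rng.random(n), 2)
        res = continuous_nri(old, new, labels)
        case, ctrl = labels == 1, labels == 0
        expect = (
            (np.sum(new[case] > old[case]) - np.sum(new[case] < old[case])) / case.sum()
            + (np.sum(new[ctrl] < old[ctrl]) - np.sum(new[ctrl] > old[ctrl])) / ctrl.sum()
        )
        assert res.nri == pytest.approx(expect, abs=1e-12)
        assert -2.0 <= res.nri <= 2.0

    def test_antisymmetry(self, rng):
        labels = rng.integers(0, 2, 60).astype(float)
        labels[:2] = [0, 1]
        a, b = rng.random(60), rng.random(60)
        assert continuous_nri(a, b, labels).nri == pytest.approx(
            -continuous_nri(b, a, labels).nri
        )


class TestReclassification:
    def test_movement_marginals_match_nri(self, rng):
        n = 120
        labels = rng.integers(0, 2, n).astype(float)
        labels[:2] = [0, 1]
        old, new = rng.random(n), rng.random(n)
        df = reclassification_data(old, new, labels)
        assert len(df) == n
        res = continuous_nri(old, new, labels)
        case = df[df["label"] == 1]
        assert (case["movement"] == "up").mean() == pytest.approx(res.p_up_case)
        assert (case["movement"] == "down").mean() == pytest.approx(res.p_down_case)

    def test_all_tied(self):
        df = reclassification_data([0.1, 0.5], [0.1, 0.5], np.array([0, 1]))
        assert (df["movement"] == "tied").all()
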