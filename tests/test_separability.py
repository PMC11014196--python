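"""Manual ROC/AUC and cross-validated classifiers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glandeis.separability import (
    SeparabilityAnalysis,
    best_direction_auc,
    cross_validate_classifiers,
    roc_auc,
)


def pair_statistic(pos, neg):
    """Oracle: (#correctly ordered pairs + ½·ties) / (n_pos·n_neg)."""
    pos, neg = np.asarray(pos), np.asarray(neg)
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)


class TestManualROC:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3], [4, 5, 6], "p>t")
        assert r.auc == pytest.approx(1.0)

    def test_all_ties_is_chance(self):
        r = roc_auc([1, 2, 3], [1, 2, 3], "p>t")
        assert r.auc == pytest.approx(0.5)

    def test_partial_overlap_pair_count(self):
        # 9 pairs, 8 correctly ordered under parathyroid-higher
        r = roc_auc([1, 2, 3], [2.5, 4, 5], "p>t")
        assert r.auc == pytest.approx(8.0 / 9.0)

    def test_curve_anchored_and_monotone(self):
        r = roc_auc([1, 3, 2, 5], [4, 6, 7], "p>t")
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(r.fpr) >= 0)
        assert np.all(np.diff(r.tpr) >= 0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            roc_auc([], [1.0], "t>p")

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            roc_auc([1.0, np.nan], [2.0], "t>p")

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), n1=st.integers(2, 15), n2=st.integers(2, 15))
    def test_trapezoid_equals_pair_statistic(self, seed, n1, n2):
        """Threshold-sweep AUC ≡ Mann–Whitney pair statistic, ties included."""
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 8, n1).astype(float)  # integers force ties
        p = rng.integers(0, 8, n2).astype(float)
        assert roc_auc(t, p, "t>p").auc == pytest.approx(pair_statistic(t, p), abs=1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_directions_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 6, 9).astype(float)
        p = rng.integers(0, 6, 7).astype(float)
        a = roc_auc(t, p, "t>p").auc
        b = roc_auc(t, p, "p>t").auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        t = rng.normal(1.0, 1.0, 40)
        p = rng.normal(0.0, 1.0, 30)
        ours = roc_auc(t, p, "t>p").auc
        y = np.concatenate([np.ones(40), np.zeros(30)])
        ref = roc_auc_score(y, np.concatenate([t, p]))
        assert ours == pytest.approx(ref, abs=1e-12)


class TestBestDirection:
    def test_thyroid_uniformly_larger(self):
        r = best_direction_auc([4, 5, 6], [1, 2, 3])
        assert r.direction == "t>p"
        assert r.auc == pytest.approx(1.0)

    def test_unfavourable_direction_complemented(self):
        # AUC(p>t) = 0.12 → the favourable direction is t>p with 1 − 0.12
        t = [1.0, 2.0, 3.0, 4.0, 5.0]
        p = [0.5, 1.5, 2.5, 0.2, 0.1]
        assert roc_auc(t, p, "p>t").auc == pytest.approx(0.12)
        r = best_direction_auc(t, p)
        assert r.direction == "t>p"
        assert r.auc == pytest.approx(0.88)
        assert r.auc >= 0.5


class TestCrossValidation:
    def separable_features(self, rng, n=100):
        X0 = rng.normal(0.0, 0.3, (n, 3))
        X1 = rng.normal(3.0, 0.3, (n, 3))
        X = pd.DataFrame(np.vstack([X0, X1]), columns=["Z1", "Z14", "fmid"])
        y = np.array(["parathyroid"] * n + ["thyroid"] * n)
        return X, y

    def test_separable_classes_score_high(self, rng):
        X, y = self.separable_features(rng)
        reports = cross_validate_classifiers(X, y, k=20, seed=0)
        assert {r.classifier for r in reports} == {"SVM", "KNN", "RFC"}
        for r in reports:
            assert r.mean_auc >= 0.95

    def test_permuted_labels_are_chance(self, rng):
        X, y = self.separable_features(rng)
        y_perm = rng.permutation(y)
        reports = cross_validate_classifiers(X, y_perm, k=20, seed=0)
        for r in reports:
            assert abs(r.mean_accuracy - 0.5) < 0.15

    def test_twenty_folds_of_ten_on_200(self, rng):
        X, y = self.separable_features(rng, n=100)
        reports = cross_validate_classifiers(X, y, k=20, seed=0)
        for r in reports:
            assert r.k == 20
            assert len(r.fold_auc) == 20
            assert len(r.fold_accuracy) == 20
            assert r.mean_auc == pytest.approx(np.mean(r.fold_auc))

    def test_fewer_samples_than_folds_rejected(self, rng):
        X = pd.DataFrame(rng.random((10, 3)), columns=["Z1", "Z14", "fmid"])
        y = np.array(["thyroid", "parathyroid"] * 5)
        with pytest.raises(ValueError, match="k="):
            cross_validate_classifiers(X, y, k=20)


class TestSeparabilityAnalysisObject:
    def test_fit_reports_all_indices_and_classifiers(self, rng):
        n = 60
        df = pd.DataFrame(
            {
                "z1_ohm": np.concatenate([rng.normal(5, 1, n), rng.normal(0, 1, n)]),
                "z14_ohm": np.concatenate([rng.normal(0, 1, n), rng.normal(4, 1, n)]),
                "fmid_hz": rng.random(2 * n),
                "gland": ["thyroid"] * n + ["parathyroid"] * n,
            }
        )
        res = SeparabilityAnalysis(df).fit(k=10, seed=1)
        table = res.roc_table.set_index("index")
        assert table.loc["Z1", "direction"] == "t>p"
        assert table.loc["Z1", "auc"] > 0.95
        assert table.loc["Z14", "direction"] == "p>t"
        assert abs(table.loc["fmid", "auc"] - 0.5) < 0.2
        assert len(res.cv_table) == 3
        assert "Separability" in res.summary()
        d = res.to_dict()
        assert set(d) == {"roc", "cv"}
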