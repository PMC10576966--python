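"""F-score ranking, NearMiss, metrics, cross validation, selection."""

import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from topoptm import (
    ModelConfig,
    confusion_metrics,
    cross_validate,
    f_scores,
    incremental_selection,
    independent_test,
    near_miss,
    roc_auc,
)


def _brute_f_scores(X, y):
    """Literal reimplementation of the F-score definition."""
    out = np.zeros(X.shape[1])
    pos, neg = X[y == 1], X[y == 0]
    for i in range(X.shape[1]):
        mp, mn, m = pos[:, i].mean(), neg[:, i].mean(), X[:, i].mean()
        num = (mp - m) ** 2 + (mn - m) ** 2
        den = (
            np.sum((pos[:, i] - mp) ** 2) / (len(pos) - 1)
            + np.sum((neg[:, i] - mn) ** 2) / (len(neg) - 1)
        )
        out[i] = num / den if den > 0 else 0.0
    return out


def _separable_data(n=30, d=6, gap=8.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n, d))
    y = np.array([1] * n + [0] * n)
    X[:n, 0] += gap
    return X, y


class TestFScores:
    def test_hand_computed_toy(self):
        X = np.array([[0.0], [2.0], [4.0], [6.0]])
        y = np.array([1, 1, 0, 0])
        r = f_scores(X, y)
        assert r.scores[0] == pytest.approx(2.0)

    def test_constant_feature_scores_zero(self):
        X = np.column_stack([np.ones(8), np.arange(8.0)])
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        assert f_scores(X, y).scores[0] == 0.0

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 5))
        y = rng.integers(0, 2, 20)
        while y.sum() < 2 or y.sum() > 18:
            y = rng.integers(0, 2, 20)
        np.testing.assert_allclose(
            f_scores(X, y).scores, f_scores(X, 1 - y).scores, atol=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_reimplementation(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(25, 8))
        y = np.r_[np.ones(12, int), np.zeros(13, int)]
        np.testing.assert_allclose(
            f_scores(X, y).scores, _brute_f_scores(X, y), atol=1e-12
        )

    def test_order_sorts_descending_with_index_ties(self):
        X, y = _separable_data(n=10, d=4)
        r = f_scores(X, y)
        s = r.scores[r.order]
        assert np.all(np.diff(s) <= 1e-12)
        assert r.order[0] == 0  # the informative feature ranks first

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            f_scores(np.zeros((4, 2)), np.ones(4, int))


class TestNearMiss:
    def test_balanced_input_unchanged(self):
        X = np.arange(12.0).reshape(6, 2)
        y = np.array([1, 1, 1, 0, 0, 0])
        np.testing.assert_array_equal(near_miss(X, y), np.arange(6))

    def test_one_d_toy_selects_closest(self):
        X = np.array([[0.0], [1.0], [5.0], [10.0]])
        y = np.array([1, 0, 0, 0])
        keep = near_miss(X, y)
        np.testing.assert_array_equal(keep, [0, 1])

    @pytest.mark.parametrize("n_maj", [10, 25, 77])
    def test_exact_balance(self, n_maj):
        rng = np.random.default_rng(n_maj)
        X = rng.normal(size=(5 + n_maj, 3))
        y = np.r_[np.ones(5, int), np.zeros(n_maj, int)]
        keep = near_miss(X, y)
        assert len(keep) == 10
        assert y[keep].sum() == 5

    def test_empty_minority_rejected(self):
        with pytest.raises(ValueError):
            near_miss(np.zeros((3, 1)), np.zeros(3, int))


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        assert confusion_metrics(5, 7, 0, 0) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_computed_example(self):
        sp, sn, acc, mcc = confusion_metrics(9, 8, 2, 1)
        assert sn == pytest.approx(0.9)
        assert sp == pytest.approx(0.8)
        assert acc == pytest.approx(0.85)
        assert mcc == pytest.approx(70 / math.sqrt(9900))

    def test_degenerate_all_positive(self):
        sp, sn, acc, mcc = confusion_metrics(3, 0, 2, 0)
        assert mcc == 0.0 and sp == 0.0 and sn == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(0, 0, 0, 0)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_toy_three_quarters(self):
        assert roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(3))
    def test_complement_and_sklearn_agreement(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        y[0], y[1] = 1, 0
        assert roc_auc(s, y) + roc_auc(-s, y) == pytest.approx(1.0)
        assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestCrossValidate:
    def test_separable_data_is_perfect(self):
        X, y = _separable_data()
        rep = cross_validate(X, y, ModelConfig("gbc", seed=0), k=5, seed=0)
        assert rep.acc == 1.0 and rep.mcc == 1.0 and rep.auc == 1.0
        assert rep.tp + rep.tn + rep.fp + rep.fn == len(y)
        assert len(rep.folds) == 5

    def test_k_larger_than_minority_rejected(self):
        X, y = _separable_data(n=4)
        with pytest.raises(ValueError):
            cross_validate(X, y, ModelConfig("gbc"), k=5, seed=0)

    def test_seed_reproducibility(self):
        X, y = _separable_data(gap=1.0, seed=5)
        a = cross_validate(X, y, ModelConfig("rfc", seed=1), k=3, seed=7)
        b = cross_validate(X, y, ModelConfig("rfc", seed=1), k=3, seed=7)
        assert a.to_dict() == b.to_dict()

    @pytest.mark.parametrize("kind", ["gbc", "rfc", "svc"])
    def test_all_classifier_kinds_run(self, kind):
        X, y = _separable_data(n=15)
        rep = cross_validate(
            X, y, ModelConfig(kind, seed=0, n_estimators=50), k=3, seed=0
        )
        # trees split the gap perfectly; the RBF SVC may leave margin
        # points on the wrong side but must still rank them correctly
        assert rep.auc == 1.0
        assert rep.acc == 1.0 if kind != "svc" else rep.acc >= 0.85


class TestIndependentTest:
    def test_separable_single_repeat(self):
        X, y = _separable_data()
        reports, summary = independent_test(
            X, y, ModelConfig("gbc", seed=0), test_size=0.3, repeats=1, seed=0
        )
        assert len(reports) == 1 and reports[0].mcc == 1.0
        assert set(summary.columns) == {"sp", "sn", "acc", "mcc", "auc"}
        assert list(summary.index) == ["mean", "sd"]

    def test_summary_over_repeats(self):
        X, y = _separable_data(gap=2.0)
        reports, summary = independent_test(
            X, y, ModelConfig("rfc", seed=0, n_estimators=50),
            test_size=0.25, repeats=4, seed=0,
        )
        assert len(reports) == 4
        accs = [r.acc for r in reports]
        assert summary.loc["mean", "acc"] == pytest.approx(np.mean(accs))
        assert summary.loc["sd", "acc"] == pytest.approx(np.std(accs, ddof=1))


class TestModelPersistence:
    def test_round_trip_preserves_predictions(self, tmp_path):
        from topoptm.modeling import load_model, save_model

        X, y = _separable_data(n=10)
        model = ModelConfig("rfc", seed=0, n_estimators=20).build().fit(X, y)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.predict(X), model.predict(X))

    def test_metrics_json_round_trip(self, tmp_path):
        import json

        from topoptm.modeling import EvalReport, write_metrics_json

        rep = EvalReport.from_counts(9, 8, 2, 1, auc=0.9)
        path = tmp_path / "metrics.json"
        write_metrics_json(rep, path)
        back = json.loads(path.read_text())
        assert back["tp"] == 9 and back["mcc"] == pytest.approx(rep.mcc)

    def test_foreign_payload_rejected(self, tmp_path):
        import joblib

        from topoptm.modeling import load_model

        path = tmp_path / "junk.joblib"
        joblib.dump({"something": 1}, path)
        with pytest.raises(ValueError):
            load_model(path)


class TestIncrementalSelection:
    def test_single_perfect_feature_first(self):
        X, y = _separable_data(n=12, d=8, gap=10.0)
        r = f_scores(X, y)
        curve, optimal = incremental_selection(
            X, y, r, ModelConfig("gbc", seed=0, n_estimators=50), k=3, seed=0
        )
        assert curve.iloc[0]["mcc"] == 1.0
        assert list(optimal) == [0]

    @pytest.mark.parametrize("seed", range(5))
    def test_two_informative_features_recovered(self, seed):
        rng = np.random.default_rng(seed)
        n, d = 40, 10
        X = rng.normal(size=(2 * n, d))
        y = np.array([1] * n + [0] * n)
        X[:n, 3] += 2.0
        X[:n, 7] -= 2.0
        r = f_scores(X, y)
        _, optimal = incremental_selection(
            X, y, r, ModelConfig("gbc", seed=0, n_estimators=50),
            k=3, seed=0, stride=2,
        )
        assert {3, 7} <= set(optimal)
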