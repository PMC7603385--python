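import numpy as np
import pytest

import tsfs.selection as sel
from tsfs.selection import (
    SelectionConfig,
    SelectionResult,
    SequentialPrefixSelector,
    accuracy_curve_report,
    common_features,
    cumulative_sets,
    make_classifier,
    sffs_select,
)


class TestCumulativeSets:
    def test_paper_scale_prefixes(self):
        prefixes = cumulative_sets(np.arange(4005), step=50)
        assert len(prefixes[0]) == 50 and len(prefixes[1]) == 100
        assert len(prefixes[-1]) == 4005

    def test_truncation_at_max_features(self):
        prefixes = cumulative_sets(np.arange(4005), step=50, max_features=120)
        assert [len(p) for p in prefixes] == [50, 100, 120]

    def test_step_one_enumeration(self):
        order = np.array([2, 0, 1])
        prefixes = cumulative_sets(order, step=1)
        assert [p.tolist() for p in prefixes] == [[2], [2, 0], [2, 0, 1]]

    def test_nestedness(self):
        prefixes = cumulative_sets(np.random.default_rng(0).permutation(37), step=4)
        for a, b in zip(prefixes[:-1], prefixes[1:]):
            assert set(a.tolist()) < set(b.tolist())

    def test_rejects_empty_ranking(self):
        with pytest.raises(ValueError):
            cumulative_sets(np.array([]), step=5)


@pytest.fixture()
def toy_data():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((40, 12))
    y = np.array([0, 1] * 20)
    X[y == 1, 0] += 3.0  # only feature 0 is informative
    return X, y


class TestSffsSelect:
    def test_stubbed_curve_argmax(self, toy_data, monkeypatch):
        X, y = toy_data
        forced = iter([0.5, 0.7, 0.6])
        monkeypatch.setattr(sel, "_prefix_accuracy", lambda *a, **k: next(forced))
        res = sffs_select(X, y, np.arange(12), SelectionConfig(step=4, cv_folds=2))
        assert res.best_step == 1
        assert res.n_selected == 8
        assert res.accuracies == [0.5, 0.7, 0.6]

    def test_tie_prefers_fewer_features(self, toy_data, monkeypatch):
        X, y = toy_data
        forced = iter([0.7, 0.7, 0.5])
        monkeypatch.setattr(sel, "_prefix_accuracy", lambda *a, **k: next(forced))
        res = sffs_select(X, y, np.arange(12), SelectionConfig(step=4, cv_folds=2))
        assert res.best_step == 0 and res.n_selected == 4

    def test_threshold_early_stop(self, toy_data, monkeypatch):
        X, y = toy_data
        forced = iter([0.5, 0.9, 0.95])
        monkeypatch.setattr(sel, "_prefix_accuracy", lambda *a, **k: next(forced))
        res = sffs_select(
            X, y, np.arange(12), SelectionConfig(step=4, cv_folds=2, threshold=0.85)
        )
        assert len(res.accuracies) == 2  # stopped at the first prefix >= 0.85
        assert res.best_step == 1

    def test_equals_exhaustive_prefix_scan(self, toy_data):
        X, y = toy_data
        order = np.arange(12)
        config = SelectionConfig(step=3, classifier="lr", cv_folds=5, seed=0)
        res = sffs_select(X, y, order, config)
        # independent oracle: evaluate every prefix directly and take argmax
        from sklearn.model_selection import StratifiedKFold, cross_val_score

        oracle_accs = []
        for stop in range(3, 13, 3):
            cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
            clf = make_classifier("lr", seed=0)
            oracle_accs.append(
                cross_val_score(clf, X[:, order[:stop]], y, cv=cv).mean()
            )
        np.testing.assert_allclose(res.accuracies, oracle_accs)
        assert res.best_step == int(np.argmax(oracle_accs))

    def test_accuracies_bounded_and_deterministic(self, toy_data):
        X, y = toy_data
        config = SelectionConfig(step=6, cv_folds=4, seed=1)
        a = sffs_select(X, y, np.arange(12), config)
        b = sffs_select(X, y, np.arange(12), config)
        assert a.accuracies == b.accuracies
        assert all(0.0 <= acc <= 1.0 for acc in a.accuracies)

    def test_rejects_single_class_and_unknown_classifier(self, toy_data):
        X, y = toy_data
        with pytest.raises(ValueError):
            sffs_select(X, np.zeros_like(y), np.arange(12), SelectionConfig(cv_folds=2))
        with pytest.raises(ValueError, match="unknown classifier"):
            sffs_select(X, y, np.arange(12), SelectionConfig(classifier="nope"))


class TestSequentialPrefixSelector:
    def test_sklearn_transform_contract(self, toy_data):
        X, y = toy_data
        selector = SequentialPrefixSelector(
            order=np.arange(12), step=4, classifier="lr", cv_folds=4, seed=0
        ).fit(X, y)
        Xt = selector.transform(X)
        assert Xt.shape == (40, selector.result_.n_selected)
        assert selector.get_support().sum() == selector.result_.n_selected

    def test_requires_order(self, toy_data):
        X, y = toy_data
        with pytest.raises(ValueError, match="ranking"):
            SequentialPrefixSelector().fit(X, y)


class TestReports:
    def _result(self, name, accs, step=4):
        best = int(np.argmax(accs))
        return SelectionResult(
            steps=[step * (i + 1) for i in range(len(accs))],
            accuracies=accs,
            best_step=best,
            selected_indices=np.arange(step * (best + 1)),
            classifier=name,
        )

    def test_one_row_per_classifier(self):
        table = accuracy_curve_report(
            [self._result("lr", [0.5, 0.8]), self._result("svm", [0.9, 0.7])]
        )
        assert len(table) == 2
        assert table.loc[0, "features_count"] == 8
        assert table.loc[1, "max_cumulative_feature_step"] == 1

    def test_report_rejects_empty(self):
        with pytest.raises(ValueError):
            accuracy_curve_report([])

    def test_common_features_intersection(self):
        a = self._result("lr", [0.5])
        a.selected_indices = np.array([1, 2, 3])
        b = self._result("svm", [0.5])
        b.selected_indices = np.array([2, 3, 4])
        np.testing.assert_array_equal(common_features([a, b]), [2, 3])

    def test_common_features_idempotent_and_disjoint(self):
        a = self._result("lr", [0.5])
        a.selected_indices = np.array([5, 6])
        np.testing.assert_array_equal(common_features([a, a]), [5, 6])
        b = self._result("svm", [0.5])
        b.selected_indices = np.array([7])
        with pytest.warns(UserWarning, match="common"):
            assert common_features([a, b]).size == 0

    def test_common_features_needs_two(self):
        with pytest.raises(ValueError):
            common_features([self._result("lr", [0.5])])


def test_all_default_classifiers_construct_and_fit(toy_data):
    X, y = toy_data
    for name in sel.CLASSIFIERS:
        clf = make_classifier(name, seed=0)
        assert clf.fit(X, y).predict(X).shape == y.shape
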