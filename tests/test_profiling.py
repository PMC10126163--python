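import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fractometry as fm
from fractometry.exceptions import InsufficientDataError, ParameterError

from oracles import cliffs_delta_enum


def labeled_table(values, labels, names=None):
    values = np.asarray(values, float)
    names = names or [f"f{i}" for i in range(values.shape[1])]
    return fm.FeatureTable(values=values, feature_names=names, labels=np.asarray(labels))


class TestFeatureTable:
    def test_nonfinite_rows_dropped(self):
        v = np.array([[1.0, 2.0], [np.nan, 1.0], [3.0, np.inf], [2.0, 2.0]])
        t = fm.FeatureTable(values=v, feature_names=["a", "b"])
        assert t.n_cells == 2 and t.n_dropped == 2

    def test_csv_round_trip(self, tmp_path, rng):
        t = labeled_table(rng.normal(size=(10, 3)), ["x"] * 5 + ["y"] * 5)
        path = tmp_path / "t.csv"
        t.to_csv(path)
        back = fm.FeatureTable.read_csv(path)
        assert back.feature_names == t.feature_names
        assert np.allclose(back.values, t.values)
        assert list(back.labels) == list(t.labels)


class TestZscore:
    def test_columns_standardized(self, rng):
        t = fm.FeatureTable(values=rng.normal(3, 5, (200, 4)),
                            feature_names=list("abcd"))
        z = fm.zscore(t)
        assert np.allclose(z.values.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.values.std(axis=0), 1, atol=1e-12)

    def test_constant_feature_dropped(self, rng):
        v = np.column_stack([rng.normal(size=50), np.full(50, 7.0)])
        z = fm.zscore(fm.FeatureTable(values=v, feature_names=["a", "const"]))
        assert z.feature_names == ["a"]

    def test_idempotent(self, rng):
        t = fm.FeatureTable(values=rng.normal(size=(100, 3)), feature_names=list("abc"))
        z1 = fm.zscore(t)
        z2 = fm.zscore(z1)
        assert np.allclose(z1.values, z2.values, atol=1e-12)


class TestCliffsDelta:
    def test_identical_samples_zero(self, rng):
        x = rng.normal(size=40)
        assert fm.cliffs_delta(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_full_separation(self):
        assert fm.cliffs_delta([5, 6, 7], [1, 2]) == 1.0
        assert fm.cliffs_delta([1, 2], [5, 6, 7]) == -1.0

    def test_worked_example_with_tie(self):
        assert fm.cliffs_delta([1, 2], [2, 3]) == pytest.approx(-0.75, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            fm.cliffs_delta([], [1.0])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rank_method_equals_pair_enumeration(self, seed):
        r = np.random.default_rng(seed)
        x = r.integers(0, 6, r.integers(1, 15)).astype(float)
        y = r.integers(0, 6, r.integers(1, 15)).astype(float)
        assert fm.cliffs_delta(x, y) == pytest.approx(cliffs_delta_enum(x, y), abs=1e-12)


class TestAuroc:
    def test_perfect_separation(self):
        r = fm.auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auroc == 1.0

    def test_all_tied_scores_half(self):
        r = fm.auroc(np.ones(10), [0, 1] * 5)
        assert r.auroc == pytest.approx(0.5, abs=1e-12)

    def test_curve_monotone_endpoints(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, 100)
        res = fm.auroc(scores, labels)
        for v in (res.tpr, res.fpr):
            assert v[0] == 0.0 and v[-1] == 1.0
            assert np.all(np.diff(v) >= 0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_auroc_cliffs_identity(self, seed):
        r = np.random.default_rng(seed)
        pos = r.normal(0.4, 1, 25)
        neg = r.normal(0, 1, 30)
        scores = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(25), np.zeros(30)])
        a = fm.auroc(scores, labels).auroc
        d = fm.cliffs_delta(pos, neg)
        assert a == pytest.approx((d + 1) / 2, abs=1e-12)

    def test_permutation_invariance(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        perm = rng.permutation(60)
        assert fm.auroc(scores, labels).auroc == pytest.approx(
            fm.auroc(scores[perm], labels[perm]).auroc, abs=1e-12
        )


class TestLinearOvaClassifier:
    def test_single_class_rejected(self, rng):
        t = labeled_table(rng.normal(size=(10, 2)), ["a"] * 10)
        with pytest.raises(ParameterError):
            fm.linear_ova_classifier(t, "a")

    def test_perfectly_separating_feature(self):
        v = np.column_stack([np.r_[np.zeros(20), np.ones(20)]])
        t = labeled_table(v, ["a"] * 20 + ["b"] * 20)
        clf = fm.linear_ova_classifier(t, "b")
        assert clf.auroc == 1.0

    def test_duplicated_feature_scores_unchanged(self, rng):
        X = rng.normal(size=(80, 3))
        labels = np.array(["p"] * 40 + ["q"] * 40)
        t1 = labeled_table(X, labels)
        t2 = labeled_table(np.column_stack([X, X[:, 0]]), labels,
                           names=["f0", "f1", "f2", "dup"])
        s1 = fm.linear_ova_classifier(t1, "p").scores
        s2 = fm.linear_ova_classifier(t2, "p").scores
        assert np.allclose(s1, s2, atol=1e-10)

    def test_permuted_labels_near_chance(self):
        spec = fm.CohortSpec(
            classes=(fm.ClassSpec("a", tuple(np.zeros(17))),
                     fm.ClassSpec("b", tuple(np.zeros(17)))),
            n_per_class=1000, seed=5,
        )
        t = fm.synth_cohort(spec)
        z = fm.zscore(t)
        clf = fm.linear_ova_classifier(z, "a")
        assert 0.45 <= clf.auroc <= 0.60


class TestSpearman:
    def test_monotone_transform_rho_one(self, rng):
        x = rng.normal(size=100)
        t = fm.FeatureTable(values=np.column_stack([x, np.exp(x)]),
                            feature_names=["x", "expx"])
        mat, edges = fm.spearman_matrix(t)
        assert mat.loc["x", "expx"] == pytest.approx(1.0, abs=1e-12)
        assert edges == [("x", "expx", pytest.approx(1.0))]

    def test_sign_flip_rho_minus_one(self, rng):
        x = rng.normal(size=50)
        t = fm.FeatureTable(values=np.column_stack([x, -x]), feature_names=["x", "negx"])
        mat, _ = fm.spearman_matrix(t)
        assert mat.loc["x", "negx"] == pytest.approx(-1.0, abs=1e-12)

    def test_independent_columns_near_zero(self, rng):
        t = fm.FeatureTable(values=rng.uniform(size=(5000, 3)),
                            feature_names=list("abc"))
        mat, edges = fm.spearman_matrix(t)
        off = mat.values[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)
        assert edges == []


class TestRankFeatures:
    def test_uninformative_feature_scores_half(self, rng):
        v = rng.normal(size=(90, 1))
        t = labeled_table(v, np.repeat(["a", "b", "c"], 30))
        name, a = fm.rank_features(t)[0]
        assert abs(a - 0.5) < 0.15  # finite-sample chance level

    def test_identical_feature_across_classes_exactly_half(self):
        v = np.tile(np.arange(30.0), 3)[:, None]
        t = labeled_table(v, np.repeat(["a", "b", "c"], 30))
        assert fm.rank_features(t)[0][1] == pytest.approx(0.5, abs=1e-12)

    def test_perfectly_ordering_feature(self):
        v = np.repeat([0.0, 1.0, 2.0], 40)[:, None]
        t = labeled_table(v, np.repeat(["lo", "mid", "hi"], 40))
        name, mean_auc = fm.rank_features(t)[0]
        # outer classes separate perfectly (AUROC 1), middle is at chance
        assert mean_auc == pytest.approx((1.0 + 1.0 + 0.5) / 3, abs=1e-12)

    def test_every_feature_reported_once(self, rng):
        t = labeled_table(rng.normal(size=(40, 5)), ["a"] * 20 + ["b"] * 20)
        ranked = fm.rank_features(t)
        assert sorted(n for n, _ in ranked) == sorted(t.feature_names)

    def test_row_permutation_invariance(self, rng):
        v = rng.normal(size=(60, 3))
        labels = np.array(["a"] * 30 + ["b"] * 30)
        t1 = labeled_table(v, labels)
        perm = rng.permutation(60)
        t2 = labeled_table(v[perm], labels[perm])
        assert fm.rank_features(t1) == fm.rank_features(t2)
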