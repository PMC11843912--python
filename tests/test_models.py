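import numpy as np
import pytest
from sklearn.base import BaseEstimator

from courtbeat.models import (
    CVReport,
    ModelBundle,
    ThresholdedBinaryClassifier,
    classify_events,
    grid_search,
    kfold_cv,
    make_rebound_pipeline,
    train_impact_model,
    train_rebound_ensemble,
)


def toy_binary(n_per_class=40, n_features=12, gap=3.0, seed=0, labels=("impact", "noise")):
    """Linearly separable two-class toy set with string labels."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_per_class, n_features))
    b = rng.standard_normal((n_per_class, n_features))
    a[:, 0] += gap
    X = np.vstack([a, b])
    y = np.array([labels[0]] * n_per_class + [labels[1]] * n_per_class)
    return X, y


class _ConstantProba(BaseEstimator):
    """Stub pipeline returning a fixed positive-class probability."""

    def __init__(self, p=0.5):
        self.p = p

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        return np.column_stack([np.full(len(X), 1 - self.p), np.full(len(X), self.p)])


class TestThresholdedClassifier:
    def test_learns_separable_toy(self):
        X, y = toy_binary()
        model = train_impact_model(X, y, k_best=5, seed=0)
        assert np.mean(model.predict(X) == y) == 1.0
        assert set(model.classes_) == {"impact", "noise"}

    def test_tie_goes_to_noise(self):
        """P(positive) exactly 0.5 is classified as noise (strict >)."""
        X, y = toy_binary(n_per_class=5)
        model = ThresholdedBinaryClassifier(_ConstantProba(0.5), "impact").fit(X, y)
        assert list(model.predict(X[:3])) == ["noise"] * 3
        just_over = ThresholdedBinaryClassifier(_ConstantProba(0.5001), "impact").fit(X, y)
        assert list(just_over.predict(X[:3])) == ["impact"] * 3

    def test_rejects_wrong_class_set(self):
        X, y = toy_binary(labels=("impact", "rebound"))
        with pytest.raises(ValueError, match="classes"):
            train_impact_model(X, y)


class TestReboundEnsemble:
    def test_soft_vote_is_mean_of_members(self):
        """The ensemble probability equals the arithmetic mean of its
        three members' probabilities on the selected features."""
        X, y = toy_binary(n_per_class=25, labels=("rebound", "noise"))
        model = train_rebound_ensemble(X, y, k_best=5, seed=0)
        pipe = model.model_
        selected = pipe.named_steps["select"].transform(X[:10])
        member_probs = [
            est.predict_proba(selected)
            for est in pipe.named_steps["vote"].estimators_
        ]
        expect = np.mean(member_probs, axis=0)
        assert np.allclose(pipe.predict_proba(X[:10]), expect, atol=1e-9)

    def test_member_names(self):
        pipe = make_rebound_pipeline()
        names = [name for name, _ in pipe.named_steps["vote"].estimators]
        assert names == ["xgb", "svm", "mlp"]


class _Majority(BaseEstimator):
    """Fast stand-in model for CV bookkeeping tests."""

    def fit(self, X, y):
        values, counts = np.unique(y, return_counts=True)
        self.majority_ = values[np.argmax(counts)]
        return self

    def predict(self, X):
        return np.full(len(X), self.majority_)


class TestKfoldCV:
    def test_1400_sample_split_bookkeeping(self):
        """A 1400-sample bank gives 1120-train / 280-test folds."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((1400, 3))
        y = np.array(["noise"] * 509 + ["rebound"] * 443 + ["impact"] * 448)
        report = kfold_cv(X, y, _Majority, k=5, seed=42)
        assert report.fold_train_sizes == (1120,) * 5
        assert report.fold_test_sizes == (280,) * 5

    def test_folds_partition_data(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.array(["a"] * 30 + ["b"] * 20)
        X = np.zeros((50, 2))
        splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=1)
        seen = []
        for _, test_idx in splitter.split(X, y):
            seen.extend(test_idx)
        assert sorted(seen) == list(range(50))

    def test_deterministic_given_seed(self):
        X, y = toy_binary(n_per_class=30, gap=0.5)
        r1 = kfold_cv(X, y, _Majority, seed=3)
        r2 = kfold_cv(X, y, _Majority, seed=3)
        assert r1.fold_accuracies == r2.fold_accuracies

    def test_rejects_class_smaller_than_k(self):
        X = np.zeros((10, 2))
        y = np.array(["a"] * 7 + ["b"] * 3)
        with pytest.raises(ValueError, match="stratified"):
            kfold_cv(X, y, _Majority, k=5)

    def test_report_median_mean(self):
        report = CVReport((0.9, 1.0, 0.8), (10,) * 3, (5,) * 3)
        assert report.median_accuracy == pytest.approx(0.9)
        assert report.mean_accuracy == pytest.approx(0.9)


class TestGridSearch:
    def test_singleton_grid(self):
        X, y = toy_binary(n_per_class=20)
        best, table = grid_search(X, y, lambda: _Majority(), {}, k=5)
        assert best == {}
        assert len(table) == 1

    def test_tie_keeps_first(self):
        X, y = toy_binary(n_per_class=20)

        def factory(tag):
            return _Majority()

        best, table = grid_search(X, y, factory, {"tag": ["first", "second"]}, k=5)
        assert best == {"tag": "first"}
        assert len(table) == 2
        assert table[0]["mean_accuracy"] == table[1]["mean_accuracy"]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search(np.zeros((10, 2)), np.array(["a"] * 5 + ["b"] * 5), _Majority, {"x": []})


class TestModelBundle:
    def test_save_load_roundtrip(self, trained_bundle, tmp_path):
        path = tmp_path / "bundle.joblib"
        trained_bundle.save(path)
        back = ModelBundle.load(path)
        assert back.metadata == trained_bundle.metadata
        X = np.zeros((1, 854))
        assert back.rebound_model.positive_proba(X).shape == (1,)

    def test_integrity_check(self, trained_bundle, tmp_path):
        import joblib

        path = tmp_path / "bundle.joblib"
        trained_bundle.save(path)
        payload = joblib.load(path)
        payload["bundle"].metadata["seed"] = 999  # tamper after hashing
        joblib.dump(payload, path)
        with pytest.raises(ValueError, match="integrity"):
            ModelBundle.load(path)


class TestClassifyEvents:
    def test_requires_trained_bundle(self):
        from courtbeat.audio_io import AudioClip
        from courtbeat.features import FeatureConfig
        from courtbeat.models import make_impact_pipeline

        bundle = ModelBundle(
            impact_model=ThresholdedBinaryClassifier(make_impact_pipeline(), "impact"),
            rebound_model=ThresholdedBinaryClassifier(make_rebound_pipeline(), "rebound"),
            feature_config=FeatureConfig(),
        )
        clip = AudioClip(samples=np.zeros(48000), sample_rate=48000)
        with pytest.raises(RuntimeError, match="trained"):
            classify_events(clip, [object()], [], bundle)

    def test_empty_candidates(self, trained_bundle):
        from courtbeat.audio_io import AudioClip

        clip = AudioClip(samples=np.zeros(48000), sample_rate=48000)
        assert classify_events(clip, [], [], trained_bundle) == []
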