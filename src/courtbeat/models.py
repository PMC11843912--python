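"""The two sound classifiers, cross-validation, and event validation.

Candidate peaks from the rule-based detectors are validated by two
binary classifiers:

* **impact vs noise** — a gradient-boosted tree classifier (XGBoost;
  learning rate 0.1, 300 trees, max depth 3) on the base feature set.
* **rebound vs noise** — a soft-voting ensemble (arithmetic mean of
  member class probabilities) of a boosted-tree model (learning rate
  0.05, 500 trees, depth 5), an RBF max-margin classifier (C = 1.0,
  gamma = "scale") and a single-hidden-layer perceptron (100 ReLU units,
  Adam), on the extended feature set. The kernel and perceptron members
  see z-scored features (fit on training data only); tree members
  consume raw features.

Both models embed the ANOVA-F top-k feature selector so that k-fold
cross-validation fits selection and scaling inside each training fold.
Classification is conservative: a candidate counts as a ball sound only
when the positive-class probability strictly exceeds 0.5 (ties go to
noise).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import VotingClassifier
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from courtbeat.audio_io import AudioClip
from courtbeat.events import IMPACT, NOISE, REBOUND, EventRecord
from courtbeat.features import (
    AnovaKBest,
    FeatureConfig,
    base_features,
    extended_features,
    n_base_features,
)
from courtbeat.peaks import Peak, PeakConfig, window_rebound_candidates

ARCHIVE_VERSION = 1


@dataclass(frozen=True)
class ImpactModelConfig:
    """Boosted-tree hyperparameters for the impact-vs-noise model."""

    learning_rate: float = 0.1
    n_trees: int = 300
    max_depth: int = 3

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.n_trees, self.max_depth) <= 0:
            raise ValueError("hyperparameters must be positive")


@dataclass(frozen=True)
class EnsembleConfig:
    """Hyperparameters of the three rebound-ensemble members."""

    boosted_learning_rate: float = 0.05
    boosted_n_trees: int = 500
    boosted_max_depth: int = 5
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    mlp_hidden: int = 100
    mlp_max_iter: int = 500


@dataclass(frozen=True)
class CVReport:
    """Per-fold accuracies of a k-fold cross-validation."""

    fold_accuracies: tuple[float, ...]
    fold_train_sizes: tuple[int, ...]
    fold_test_sizes: tuple[int, ...]

    @property
    def median_accuracy(self) -> float:
        return float(np.median(self.fold_accuracies))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


class ThresholdedBinaryClassifier(BaseEstimator, ClassifierMixin):
    """Binary classifier predicting the positive class only when
    P(positive) strictly exceeds 0.5 (ties break toward noise).

    Wraps an inner pipeline; labels are the original strings.
    """

    def __init__(self, pipeline, positive_label: str, negative_label: str = NOISE):
        self.pipeline = pipeline
        self.positive_label = positive_label
        self.negative_label = negative_label

    def fit(self, X, y):
        y = np.asarray(y)
        present = set(np.unique(y))
        if present != {self.positive_label, self.negative_label}:
            raise ValueError(
                f"training data must contain exactly the classes "
                f"{{{self.positive_label!r}, {self.negative_label!r}}}, got {present}"
            )
        y_bin = (y == self.positive_label).astype(int)
        self.model_ = clone(self.pipeline)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence chatter
            self.model_.fit(np.asarray(X), y_bin)
        self.classes_ = np.array([self.negative_label, self.positive_label])
        return self

    def predict_proba(self, X):
        """Columns ordered (negative, positive)."""
        return self.model_.predict_proba(np.asarray(X))

    def positive_proba(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        pos = self.positive_proba(X) > 0.5
        return np.where(pos, self.positive_label, self.negative_label)


def make_impact_pipeline(
    config: ImpactModelConfig = ImpactModelConfig(), k_best: int = 150, seed: int = 0
) -> Pipeline:
    return Pipeline(
        [
            ("select", AnovaKBest(k=k_best)),
            (
                "xgb",
                XGBClassifier(
                    learning_rate=config.learning_rate,
                    n_estimators=config.n_trees,
                    max_depth=config.max_depth,
                    objective="binary:logistic",
                    eval_metric="logloss",
                    random_state=seed,
                    n_jobs=1,
                ),
            ),
        ]
    )


def make_rebound_pipeline(
    config: EnsembleConfig = EnsembleConfig(), k_best: int = 150, seed: int = 0
) -> Pipeline:
    members = [
        (
            "xgb",
            XGBClassifier(
                learning_rate=config.boosted_learning_rate,
                n_estimators=config.boosted_n_trees,
                max_depth=config.boosted_max_depth,
                objective="binary:logistic",
                eval_metric="logloss",
                random_state=seed,
                n_jobs=1,
            ),
        ),
        (
            "svm",
            Pipeline(
                [
                    ("scale", StandardScaler()),
                    (
                        "svc",
                        SVC(
                            kernel="rbf",
                            C=config.svm_c,
                            gamma=config.svm_gamma,
                            probability=True,
                            random_state=seed,
                        ),
                    ),
                ]
            ),
        ),
        (
            "mlp",
            Pipeline(
                [
                    ("scale", StandardScaler()),
                    (
                        "mlp",
                        MLPClassifier(
                            hidden_layer_sizes=(config.mlp_hidden,),
                            activation="relu",
                            solver="adam",
                            max_iter=config.mlp_max_iter,
                            random_state=seed,
                        ),
                    ),
                ]
            ),
        ),
    ]
    return Pipeline(
        [
            ("select", AnovaKBest(k=k_best)),
            ("vote", VotingClassifier(members, voting="soft")),
        ]
    )


def train_impact_model(
    features: np.ndarray,
    labels: np.ndarray,
    config: ImpactModelConfig = ImpactModelConfig(),
    seed: int = 0,
    k_best: int = 150,
) -> ThresholdedBinaryClassifier:
    """Fit the impact-vs-noise boosted-tree model."""
    model = ThresholdedBinaryClassifier(
        make_impact_pipeline(config, k_best, seed), positive_label=IMPACT
    )
    return model.fit(features, labels)


def train_rebound_ensemble(
    features: np.ndarray,
    labels: np.ndarray,
    config: EnsembleConfig = EnsembleConfig(),
    seed: int = 0,
    k_best: int = 150,
) -> ThresholdedBinaryClassifier:
    """Fit the rebound-vs-noise soft-voting ensemble."""
    model = ThresholdedBinaryClassifier(
        make_rebound_pipeline(config, k_best, seed), positive_label=REBOUND
    )
    return model.fit(features, labels)


def kfold_cv(
    features: np.ndarray,
    labels: np.ndarray,
    model_factory,
    k: int = 5,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold cross-validation with per-fold accuracy.

    ``model_factory()`` must return a fresh unfitted estimator. Folds
    partition the data; each iteration trains on k-1 folds and scores
    accuracy on the holdout. Deterministic given ``seed``.
    """
    X = np.asarray(features)
    y = np.asarray(labels)
    if len(y) < k:
        raise ValueError(f"need at least k={k} samples, got {len(y)}")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError("every class needs >= k samples for stratified folds")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs, train_sizes, test_sizes = [], [], []
    for train_idx, test_idx in splitter.split(X, y):
        model = model_factory()
        model.fit(X[train_idx], y[train_idx])
        accs.append(float(np.mean(model.predict(X[test_idx]) == y[test_idx])))
        train_sizes.append(len(train_idx))
        test_sizes.append(len(test_idx))
    return CVReport(
        fold_accuracies=tuple(accs),
        fold_train_sizes=tuple(train_sizes),
        fold_test_sizes=tuple(test_sizes),
    )


def grid_search(
    features: np.ndarray,
    labels: np.ndarray,
    model_factory,
    param_grid: dict,
    k: int = 5,
    seed: int = 0,
) -> tuple[dict, list[dict]]:
    """Exhaustive grid search by mean CV accuracy.

    ``model_factory(**params)`` builds an unfitted estimator for one grid
    point. Returns ``(best_params, table)`` where the table has one row
    per grid entry; ties keep the first entry in grid order.
    """
    grid = list(ParameterGrid(param_grid))
    if not grid:
        raise ValueError("param_grid must be non-empty")
    table = []
    best_params, best_mean = None, -np.inf
    for params in grid:
        report = kfold_cv(features, labels, lambda: model_factory(**params), k, seed)
        row = dict(params)
        row["mean_accuracy"] = report.mean_accuracy
        row["median_accuracy"] = report.median_accuracy
        table.append(row)
        if report.mean_accuracy > best_mean:  # strict: ties keep first
            best_mean = report.mean_accuracy
            best_params = dict(params)
    return best_params, table


# ---------------------------------------------------------------------------
# bundle + event validation


@dataclass
class ModelBundle:
    """Trained impact model + rebound ensemble + shared feature config."""

    impact_model: ThresholdedBinaryClassifier
    rebound_model: ThresholdedBinaryClassifier
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    metadata: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "version": ARCHIVE_VERSION,
                "feature_config": vars(self.feature_config)
                if not hasattr(self.feature_config, "__dataclass_fields__")
                else {
                    f: getattr(self.feature_config, f)
                    for f in self.feature_config.__dataclass_fields__
                },
                "metadata": {k: v for k, v in sorted(self.metadata.items())},
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {"version": ARCHIVE_VERSION, "hash": self.config_hash(), "bundle": self},
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        payload = joblib.load(path)
        bundle = payload["bundle"]
        if payload.get("hash") != bundle.config_hash():
            raise ValueError(f"model archive {path} failed its integrity check")
        return bundle


def train_bundle(
    features_extended: np.ndarray,
    labels: np.ndarray,
    feature_config: FeatureConfig = FeatureConfig(),
    impact_config: ImpactModelConfig = ImpactModelConfig(),
    ensemble_config: EnsembleConfig = EnsembleConfig(),
    seed: int = 0,
    k_best: int = 150,
) -> ModelBundle:
    """Train both classifiers from one extended-feature bank matrix.

    The impact model sees the base-feature prefix of the extended matrix
    and the impact/noise rows; the rebound ensemble sees the full
    extended matrix and the rebound/noise rows.
    """
    labels = np.asarray(labels)
    nb = n_base_features(feature_config)
    imp_rows = np.isin(labels, [IMPACT, NOISE])
    reb_rows = np.isin(labels, [REBOUND, NOISE])
    impact_model = train_impact_model(
        features_extended[imp_rows][:, :nb], labels[imp_rows], impact_config, seed, k_best
    )
    rebound_model = train_rebound_ensemble(
        features_extended[reb_rows], labels[reb_rows], ensemble_config, seed, k_best
    )
    return ModelBundle(
        impact_model=impact_model,
        rebound_model=rebound_model,
        feature_config=feature_config,
        metadata={"seed": seed, "k_best": k_best},
    )


def classify_events(
    clip: AudioClip,
    impact_candidates: list[Peak],
    lesser_candidates: list[Peak],
    bundle: ModelBundle,
    peak_config: PeakConfig = PeakConfig(),
) -> list[EventRecord]:
    """Validate candidate peaks and pair each impact with its true rebound.

    Impact candidates are kept when the impact model's P(impact) > 0.5.
    For each kept impact, the rebound candidates inside its window are
    scored by the ensemble; accepted candidates (P(rebound) > 0.5) yield
    the true rebound as the highest-probability one, ties resolved toward
    the later (closer to the impact) time. Impacts with no accepted
    rebound stay as impact-only records. Segments for feature extraction
    are cut from the unfiltered clip.
    """
    if not hasattr(bundle.impact_model, "model_") or not hasattr(
        bundle.rebound_model, "model_"
    ):
        raise RuntimeError("classify_events requires a trained ModelBundle")
    if not impact_candidates:
        return []
    cfg = bundle.feature_config

    imp_X = np.vstack(
        [
            base_features(_segment(clip, p.time_s), cfg).values
            for p in impact_candidates
        ]
    )
    imp_prob = bundle.impact_model.positive_proba(imp_X)
    kept = [(p, float(pr)) for p, pr in zip(impact_candidates, imp_prob) if pr > 0.5]

    windows = window_rebound_candidates(
        [p for p, _ in kept], lesser_candidates, peak_config
    )
    records: list[EventRecord] = []
    for peak, prob in kept:
        records.append(
            EventRecord(
                time_s=peak.time_s, label=IMPACT, amplitude=peak.amplitude, probability=prob
            )
        )
        cands = windows.get(peak.time_s, [])
        if not cands:
            continue
        reb_X = np.vstack(
            [extended_features(_segment(clip, c.time_s), cfg).values for c in cands]
        )
        reb_prob = bundle.rebound_model.positive_proba(reb_X)
        accepted = [
            (c, float(pr)) for c, pr in zip(cands, reb_prob) if pr > 0.5
        ]
        if not accepted:
            continue
        # highest probability wins; ties -> later time (closer to impact)
        best = max(accepted, key=lambda cp: (cp[1], cp[0].time_s))
        records.append(
            EventRecord(
                time_s=best[0].time_s,
                label=REBOUND,
                amplitude=best[0].amplitude,
                probability=best[1],
            )
        )
    return sorted(records, key=lambda r: r.time_s)


def _segment(clip: AudioClip, time_s: float) -> AudioClip:
    from courtbeat.features import extract_segment

    return extract_segment(clip, time_s)
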