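"""Consensus salt-status classification.

Thirteen binary classifiers — one per family of the original portal's
ensemble (naive Bayes, multilayer perceptron, support-vector, 1-NN,
distance-weighted NN, locally weighted learner, decision stump, a
conservative incremental-style tree, a pruned C4.5-style tree, a logistic
model, random forest, fully random tree, and a cost-complexity-pruned
tree) — are trained on standardized per-seed feature rows, each seed
inheriting its training plate's salt/non-salt condition.  A plate's status
is called by consensus: for each algorithm, the percentage of the plate's
seeds it labels salt; the consensus is the unweighted mean of the 13
percentages, and the plate is marked salt iff the consensus exceeds 50.

A ZeroR majority-class baseline exists behind a flag but never enters the
consensus (it adds no information beyond class priors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import COLOR_COLUMNS, FEATURE_COLUMNS, MORPHO_COLUMNS, SeedRecord
from .io_config import InputError

SALT = "salt"
NON_SALT = "non-salt"

ALGORITHM_NAMES = (
    "NaiveBayes", "MultilayerPerceptron", "SMO", "IBk", "KStar", "LWL",
    "DecisionStump", "HoeffdingTree", "J48", "LMT", "RandomForest",
    "RandomTree", "REPTree",
)

SUBSET_COLUMNS = {
    "all": FEATURE_COLUMNS,
    "morpho": MORPHO_COLUMNS,
    "color": COLOR_COLUMNS,
}


class TrainingError(ValueError):
    """Raised when the training set cannot support fitting."""


def _make_members(seed: int, n_train: int) -> list:
    """Instantiate the 13 ensemble members with documented defaults.

    Neighbor counts are clipped to the training-set size.  Families without
    a scikit-learn counterpart use the closest available model: the
    incremental Hoeffding tree becomes a conservative entropy tree (splits
    only on well-supported leaves) and the logistic model tree becomes a
    logistic regression (its single-node degenerate form).
    """
    k = lambda n: max(1, min(n, n_train))
    return [
        GaussianNB(),
        MLPClassifier(hidden_layer_sizes=(20,), max_iter=300, random_state=seed),
        SVC(kernel="rbf", random_state=seed),
        KNeighborsClassifier(n_neighbors=k(1)),
        KNeighborsClassifier(n_neighbors=k(5), weights="distance"),
        KNeighborsClassifier(n_neighbors=k(25), weights="distance"),
        DecisionTreeClassifier(max_depth=1, random_state=seed),
        DecisionTreeClassifier(criterion="entropy", min_samples_leaf=10,
                               random_state=seed),
        DecisionTreeClassifier(criterion="entropy", min_samples_leaf=2,
                               random_state=seed),
        LogisticRegression(max_iter=1000, random_state=seed),
        RandomForestClassifier(n_estimators=100, random_state=seed),
        DecisionTreeClassifier(splitter="random", max_features="sqrt",
                               random_state=seed),
        DecisionTreeClassifier(criterion="entropy", ccp_alpha=0.01,
                               random_state=seed),
    ]


@dataclass
class EnsembleModel:
    members: list  # 13 (name, fitted estimator) pairs, Table-4 order
    scaler: StandardScaler
    subset: str
    seed: int
    baseline: Optional[object] = None  # fitted ZeroR when requested


@dataclass
class PlatePrediction:
    """Per-algorithm percent-salt calls and the consensus for one plate."""

    plate: str
    algorithm_percent_salt: dict[str, float]
    consensus: float
    status: str


def _design_matrix(records: Sequence[SeedRecord], subset: str) -> np.ndarray:
    columns = SUBSET_COLUMNS[subset]
    X = np.array([r.values(columns) for r in records], dtype=np.float64)
    if len(records) and not np.isfinite(X).all():
        raise InputError("records contain missing or non-finite feature values")
    return X


def train_ensemble(train: Sequence[SeedRecord], subset: str = "all",
                   seed: int = 0, with_baseline: bool = False) -> EnsembleModel:
    """Fit the 13 classifiers on labeled seed records.

    Every record must carry a condition label and both classes must be
    present.  Fitting is reproducible for a given seed.
    """
    if subset not in SUBSET_COLUMNS:
        raise InputError(f"unknown attribute subset {subset!r}; expected one of "
                         f"{tuple(SUBSET_COLUMNS)}")
    labels = [r.condition for r in train]
    if any(lab is None for lab in labels):
        raise InputError("all training records must carry a condition label")
    classes = set(labels)
    if classes != {SALT, NON_SALT}:
        raise TrainingError(f"training set must contain both classes, got {sorted(classes)}")
    X = _design_matrix(train, subset)
    y = np.array(labels)
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    members = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for name, est in zip(ALGORITHM_NAMES, _make_members(seed, len(train))):
            members.append((name, est.fit(Xs, y)))
    baseline = DummyClassifier(strategy="most_frequent").fit(Xs, y) if with_baseline else None
    return EnsembleModel(members=members, scaler=scaler, subset=subset,
                         seed=seed, baseline=baseline)


def predict_seeds(model: EnsembleModel, records: Sequence[SeedRecord]) -> np.ndarray:
    """Hard per-seed labels, one row per algorithm (13 x n_seeds)."""
    if len(records) == 0:
        return np.empty((len(model.members), 0), dtype=object)
    Xs = model.scaler.transform(_design_matrix(records, model.subset))
    return np.vstack([est.predict(Xs) for _, est in model.members])


def classify_plate(plate: str, label_matrix: np.ndarray) -> PlatePrediction:
    """Consensus call for one plate from its 13 x n_seeds label matrix.

    Consensus is the mean over algorithms of the percentage of seeds
    labeled salt; status is salt iff the consensus is strictly greater
    than 50 (a consensus of exactly 50 is non-salt).
    """
    label_matrix = np.asarray(label_matrix)
    if label_matrix.ndim != 2 or label_matrix.shape[1] == 0:
        raise InputError(f"plate {plate!r} has no seeds to classify")
    percents = 100.0 * (label_matrix == SALT).mean(axis=1)
    consensus = float(percents.mean())
    if label_matrix.shape[0] == len(ALGORITHM_NAMES):
        names = ALGORITHM_NAMES
    else:
        names = tuple(f"algorithm_{i + 1}" for i in range(label_matrix.shape[0]))
    return PlatePrediction(
        plate=plate,
        algorithm_percent_salt=dict(zip(names, map(float, percents))),
        consensus=consensus,
        status=SALT if consensus > 50.0 else NON_SALT,
    )


def classify_plates(model: EnsembleModel,
                    records: Sequence[SeedRecord]) -> list[PlatePrediction]:
    """Group records by plate id and produce one consensus call per plate,
    in first-appearance order."""
    order: dict[str, list[SeedRecord]] = {}
    for r in records:
        order.setdefault(r.plate, []).append(r)
    predictions = []
    for plate, recs in order.items():
        matrix = predict_seeds(model, recs)
        predictions.append(classify_plate(plate, matrix))
    return predictions
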