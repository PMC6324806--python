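"""Balanced-subset classifier ensembles and their evaluation.

One base classifier is fitted per balanced training subset; the ensemble
prediction for a bond is the mean of the base models' predicted cleavage
probabilities for that bond's window.  Bonds too close to a terminus to
carry a full window (k = 4 near either end) receive probability 0, the same
convention used for external scores that a method does not produce.

Backends are standard scikit-learn classifiers — the contribution is the
pipeline around them, not the learners: logistic regression, RBF-kernel SVM
(hyperparameters chosen by grid search per subset, probabilities via Platt
calibration), random forest and gradient boosting, all with library
defaults otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix,
    matthews_corrcoef,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dataset import TrainingSubset
from .descriptors import DescriptorTable, pattern_features
from .peptide_core import Peptide, window_at

__all__ = [
    "CLASSIFIER_KINDS",
    "ClassifierSpec",
    "EnsembleModel",
    "MetricsReport",
    "train_ensemble",
    "cross_validate",
    "predict_bond_probabilities",
    "save_ensemble",
    "load_ensemble",
]

CLASSIFIER_KINDS = ("logistic-regression", "svm-rbf", "random-forest", "gradient-boosting")

# grid for the RBF SVM; the other backends run with library defaults
DEFAULT_SVM_GRID = {"C": [0.1, 1, 10, 100], "gamma": ["scale", 0.01, 0.1, 1]}


@dataclass(frozen=True)
class ClassifierSpec:
    """Which base learner to fit on each subset, and with what settings."""

    kind: str = "logistic-regression"
    hyperparameters: dict = field(default_factory=dict)
    grid: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; "
                             f"choose one of {CLASSIFIER_KINDS}")
        if self.grid is not None and self.kind != "svm-rbf":
            raise ValueError("a hyperparameter grid is only supported for svm-rbf")

    def make_estimator(self, cv: int = 5):
        """Fresh unfitted estimator.

        The scale-sensitive backends (logistic regression, RBF SVM) are
        wrapped with an internal feature standardizer fitted on each
        subset's training data; descriptor tables mix heterogeneous units
        and neither backend is scale-invariant.  The classifier settings
        themselves stay at library defaults.
        """
        hp = dict(self.hyperparameters)
        if self.kind == "logistic-regression":
            hp.setdefault("max_iter", 2000)
            return Pipeline([
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(random_state=self.seed, **hp)),
            ])
        if self.kind == "random-forest":
            return RandomForestClassifier(random_state=self.seed, **hp)
        if self.kind == "gradient-boosting":
            return GradientBoostingClassifier(random_state=self.seed, **hp)
        # svm-rbf: grid-searched C/gamma on decision values, then a Platt
        # (sigmoid) calibration maps them to probabilities
        grid = self.grid if self.grid is not None else DEFAULT_SVM_GRID
        search = GridSearchCV(SVC(kernel="rbf", random_state=self.seed, **hp),
                              grid, cv=cv, scoring="roc_auc", n_jobs=1)
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", CalibratedClassifierCV(search, method="sigmoid",
                                           ensemble=False, cv=cv)),
        ])


@dataclass
class EnsembleModel:
    """A set of base classifiers, one per balanced subset."""

    protease_id: str
    k: int
    table_fingerprint: str
    base_models: list
    spec: ClassifierSpec
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.base_models:
            raise ValueError("ensemble needs at least one base model")

    def predict_window_probabilities(self, X: np.ndarray) -> np.ndarray:
        """Mean cleavage probability over base models, per row of X."""
        probs = np.stack([m.predict_proba(X)[:, 1] for m in self.base_models])
        return probs.mean(axis=0)


@dataclass(frozen=True)
class MetricsReport:
    """Mean cross-validation metrics, averaged over folds then subsets."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc_roc: float
    auc_prc: float
    mcc: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc_roc": self.auc_roc,
            "auc_prc": self.auc_prc,
            "mcc": self.mcc,
        }


def train_ensemble(
    subsets: list[TrainingSubset],
    spec: ClassifierSpec,
    protease_id: str = "",
    table: DescriptorTable | None = None,
) -> EnsembleModel:
    """Fit one base classifier per subset; deterministic given the spec seed."""
    if not subsets:
        raise ValueError("no training subsets")
    dims = {s.X.shape[1] for s in subsets}
    if len(dims) != 1:
        raise ValueError(f"subsets disagree on feature dimension: {sorted(dims)}")
    models = []
    for s in subsets:
        if len(np.unique(s.y)) < 2:
            raise ValueError(f"subset {s.index} has a single class; cannot train")
        est = spec.make_estimator()
        est.fit(s.X, s.y)
        models.append(est)
    d = dims.pop()
    k = d_to_k(d, table)
    return EnsembleModel(
        protease_id=protease_id,
        k=k,
        table_fingerprint=table.fingerprint() if table is not None else "",
        base_models=models,
        spec=spec,
        metadata={"n_subsets": len(subsets), "feature_dim": d, "seed": spec.seed},
    )


def d_to_k(feature_dim: int, table: DescriptorTable | None) -> int:
    """Recover the window half-width from the feature dimension, if possible."""
    if table is None or feature_dim % (2 * table.d) != 0:
        return 0
    return feature_dim // (2 * table.d)


def _fold_metrics(y_true, y_pred, y_prob) -> dict:
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    return {
        "accuracy": (tp + tn) / (tp + tn + fp + fn),
        "sensitivity": sens,
        "specificity": spec,
        "auc_roc": roc_auc_score(y_true, y_prob),
        "auc_prc": average_precision_score(y_true, y_prob),
        "mcc": matthews_corrcoef(y_true, y_pred),
    }


def cross_validate(
    subsets: list[TrainingSubset],
    spec: ClassifierSpec,
    folds: int = 5,
) -> MetricsReport:
    """Stratified k-fold CV per subset, metrics averaged over folds then subsets."""
    if not subsets:
        raise ValueError("no training subsets")
    per_subset = []
    for s in subsets:
        counts = np.bincount(s.y, minlength=2)
        if counts.min() < folds:
            raise ValueError(
                f"subset {s.index}: minority class has {counts.min()} member(s), "
                f"fewer than {folds} folds"
            )
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
        fold_rows = []
        for tr, te in skf.split(s.X, s.y):
            est = spec.make_estimator()
            est.fit(s.X[tr], s.y[tr])
            prob = est.predict_proba(s.X[te])[:, 1]
            pred = (prob >= 0.5).astype(int)
            fold_rows.append(_fold_metrics(s.y[te], pred, prob))
        per_subset.append({m: float(np.mean([r[m] for r in fold_rows]))
                           for m in fold_rows[0]})
    mean = {m: float(np.mean([r[m] for r in per_subset])) for m in per_subset[0]}
    return MetricsReport(**mean)


def predict_bond_probabilities(
    p: Peptide,
    model: EnsembleModel,
    table: DescriptorTable,
    k: int | None = None,
) -> np.ndarray:
    """Per-bond predicted cleavage probability for one peptide.

    Bonds lacking a full window (near a terminus at k > 1) get probability
    exactly 0.  The descriptor table must be the one the ensemble was
    trained with (fingerprint-checked when recorded).
    """
    if len(p.blocks) < 2:
        raise ValueError("peptide must have at least 2 blocks")
    if model.table_fingerprint and model.table_fingerprint != table.fingerprint():
        raise ValueError("descriptor table does not match the one used in training")
    kk = k if k is not None else model.k
    if kk < 1:
        raise ValueError("window half-width unknown; pass k explicitly")
    probs = np.zeros(p.n_bonds)
    rows, bond_ids = [], []
    for b in range(p.n_bonds):
        w = window_at(p, b, kk)
        if w is not None:
            rows.append(pattern_features(w.pattern, table))
            bond_ids.append(b)
    if rows:
        probs[bond_ids] = model.predict_window_probabilities(np.vstack(rows))
    return probs


def save_ensemble(model: EnsembleModel, directory) -> None:
    """Persist a model bundle: model.json metadata + one joblib per base model."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "protease_id": model.protease_id,
        "k": model.k,
        "table_fingerprint": model.table_fingerprint,
        "n_base_models": len(model.base_models),
        "spec": {
            "kind": model.spec.kind,
            "hyperparameters": model.spec.hyperparameters,
            "grid": model.spec.grid,
            "seed": model.spec.seed,
        },
        "metadata": model.metadata,
    }
    (d / "model.json").write_text(json.dumps(meta, indent=2))
    for i, m in enumerate(model.base_models):
        joblib.dump(m, d / f"base_{i:03d}.joblib")


def load_ensemble(directory) -> EnsembleModel:
    """Load a bundle written by :func:`save_ensemble`."""
    d = Path(directory)
    meta = json.loads((d / "model.json").read_text())
    models = [joblib.load(d / f"base_{i:03d}.joblib")
              for i in range(meta["n_base_models"])]
    return EnsembleModel(
        protease_id=meta["protease_id"],
        k=meta["k"],
        table_fingerprint=meta["table_fingerprint"],
        base_models=models,
        spec=ClassifierSpec(**meta["spec"]),
        metadata=meta.get("metadata", {}),
    )
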