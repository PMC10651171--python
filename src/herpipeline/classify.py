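"""Linear discriminant classification of the combined-effect features.

The four per-subject features (ERP global, ERP local, HER global, HER
local combined clustered effects) are fed to a two-class linear
discriminant with pooled within-class covariance and equal priors, in a
seeded stratified fivefold cross-validation.  All feature triads and the
full quadruple share the same fold assignments so their accuracies are
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FEATURE_NAMES",
    "FeatureTable",
    "ClassificationReport",
    "lda_crossval",
    "run_all_subsets",
]

FEATURE_NAMES = ("ERP_global", "ERP_local", "HER_global", "HER_local")


@dataclass
class FeatureTable:
    """Subjects x four combined effects, with binary diagnosis labels."""

    X: np.ndarray            # (n_subjects, 4) uV
    y: np.ndarray            # 1 = MCS-like, 0 = UWS-like
    subject_ids: list[str] | None = None
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features must be finite")
        if len(self.X) != len(self.y):
            raise ValueError("feature/label length mismatch")
        for cls in (0, 1):
            if (self.y == cls).sum() < 2:
                raise ValueError("need at least 2 subjects per class")

    def columns(self, names: list[str]) -> np.ndarray:
        idx = [self.feature_names.index(n) for n in names]
        return self.X[:, idx]


@dataclass
class ClassificationReport:
    feature_subset: tuple[str, ...]
    fold_assignments: np.ndarray
    accuracy: float
    confusion: np.ndarray  # 2x2, rows true (0,1), columns predicted
    seed: int


class _PooledLDA:
    """Two-class linear discriminant, pooled covariance, equal priors.

    Falls back to a ridge (1e-6 of the covariance trace) when the pooled
    covariance is singular.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_PooledLDA":
        X0, X1 = X[y == 0], X[y == 1]
        self.mu0 = X0.mean(axis=0)
        self.mu1 = X1.mean(axis=0)
        n0, n1 = len(X0), len(X1)
        S = ((X0 - self.mu0).T @ (X0 - self.mu0)
             + (X1 - self.mu1).T @ (X1 - self.mu1))
        dof = max(n0 + n1 - 2, 1)
        cov = S / dof
        d = X.shape[1]
        try:
            w = np.linalg.solve(cov, self.mu1 - self.mu0)
            if not np.all(np.isfinite(w)) or np.linalg.cond(cov) > 1e12:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            ridge = 1e-6 * max(np.trace(cov), 1.0) / d
            w = np.linalg.solve(cov + ridge * np.eye(d), self.mu1 - self.mu0)
        self.w = w
        self.threshold = float(w @ (self.mu0 + self.mu1) / 2.0)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (X @ self.w > self.threshold).astype(int)


def lda_crossval(
    features: FeatureTable,
    subset: list[str] | None = None,
    k: int = 5,
    seed: int = 0,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> ClassificationReport:
    """Stratified k-fold linear discriminant cross-validation.

    Returns the pooled confusion matrix over held-out folds and its
    accuracy (trace / n).  Precomputed ``folds`` may be passed so several
    feature subsets share identical assignments.
    """
    subset = list(subset) if subset is not None else list(features.feature_names)
    if not subset:
        raise ValueError("feature subset must be non-empty")
    X = features.columns(subset)
    y = features.y
    if k > min((y == 0).sum(), (y == 1).sum()):
        raise ValueError("k exceeds the smaller class size")
    if folds is None:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))
    fold_assign = np.full(len(y), -1, dtype=int)
    confusion = np.zeros((2, 2), dtype=int)
    for f, (train, test) in enumerate(folds):
        assert np.intersect1d(train, test).size == 0
        fold_assign[test] = f
        model = _PooledLDA().fit(X[train], y[train])
        pred = model.predict(X[test])
        for t, p in zip(y[test], pred):
            confusion[t, p] += 1
    accuracy = float(np.trace(confusion) / len(y))
    return ClassificationReport(
        feature_subset=tuple(subset), fold_assignments=fold_assign,
        accuracy=accuracy, confusion=confusion, seed=seed,
    )


def run_all_subsets(
    features: FeatureTable, seed: int = 0, k: int = 5
) -> list[ClassificationReport]:
    """Reports for the four feature triads plus the full quadruple.

    Fold assignments are computed once and shared across subsets.
    """
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(features.X, features.y))
    subsets = [list(c) for c in combinations(features.feature_names, 3)]
    subsets.append(list(features.feature_names))
    return [lda_crossval(features, s, k=k, seed=seed, folds=folds) for s in subsets]
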