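"""Weighted-trait water-stress classification benchmark.

Plant height and petiole count are z-scored (scaler fitted on the training
split only), multiplied by a weight pair (w_petiole, w_height) summing to
one, and fed as a two-column feature to seven classical classifier
families.  Scaling a standardized column by a constant is irrelevant to
tree-based models (splits are order statistics) but matters to margin- or
distance-based models whose regularization or metric is scale-sensitive -
which is exactly the contrast the weight sweep probes: tree rows stay flat
while logistic regression degrades as the height weight shrinks.

Feature relevance is measured by permutation importance: the mean accuracy
drop on held-out data when one feature column is shuffled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigError

FEATURES = ("petiole_count", "height_cm")
TREE_FAMILIES = ("random-forest", "decision-tree", "gradient-boosting")


@dataclass(frozen=True)
class WeightCombo:
    """Non-negative (petiole, height) weights summing to one."""

    w_petiole: float
    w_height: float

    def __post_init__(self):
        if self.w_petiole < 0 or self.w_height < 0:
            raise ConfigError("weights must be non-negative")
        if abs(self.w_petiole + self.w_height - 1.0) > 1e-9:
            raise ConfigError(f"weights must sum to 1: {self}")

    @property
    def label(self) -> str:
        return f"{self.w_petiole:.1f}-{self.w_height:.1f}"


DEFAULT_COMBOS = (
    WeightCombo(0.5, 0.5),
    WeightCombo(0.6, 0.4),
    WeightCombo(0.7, 0.3),
    WeightCombo(0.8, 0.2),
    WeightCombo(0.9, 0.1),
)


def make_classifier(family: str, seed: int = 0):
    """Instantiate one of the seven benchmark families with its standard
    hyperparameters (L2 logistic capped at 100 iterations; RBF SVM C=1 with
    scaled gamma; 100-tree Gini forest; unbounded Gini tree; k=5 Minkowski
    KNN; Gaussian NB; 0.1-rate, 100-stage, depth-3 boosting)."""
    factories = {
        "logistic-regression": lambda: LogisticRegression(
            penalty="l2", solver="lbfgs", max_iter=100
        ),
        "svm-rbf": lambda: SVC(kernel="rbf", C=1.0, gamma="scale", probability=True,
                               random_state=seed),
        "random-forest": lambda: RandomForestClassifier(
            n_estimators=100, max_depth=None, criterion="gini", random_state=seed
        ),
        "decision-tree": lambda: DecisionTreeClassifier(
            criterion="gini", max_depth=None, random_state=seed
        ),
        "knn": lambda: KNeighborsClassifier(n_neighbors=5, metric="minkowski"),
        "gaussian-naive-bayes": lambda: GaussianNB(),
        "gradient-boosting": lambda: GradientBoostingClassifier(
            learning_rate=0.1, n_estimators=100, max_depth=3, random_state=seed
        ),
    }
    if family not in factories:
        raise ConfigError(f"unknown classifier family {family!r}; one of {sorted(factories)}")
    return factories[family]()


ALL_FAMILIES = (
    "logistic-regression",
    "svm-rbf",
    "random-forest",
    "decision-tree",
    "knn",
    "gaussian-naive-bayes",
    "gradient-boosting",
)


def standardize(train: np.ndarray, test: np.ndarray | None = None):
    """Z-score features with statistics fitted on the training split only.

    Returns (train_z, test_z, scaler); fitting on train and merely applying
    to test avoids information leakage.
    """
    train = np.asarray(train, dtype=float)
    scaler = StandardScaler().fit(train)
    if np.any(scaler.var_ == 0):
        raise ConfigError("constant feature on the training split; cannot standardize")
    test_z = scaler.transform(np.asarray(test, dtype=float)) if test is not None else None
    return scaler.transform(train), test_z, scaler


def weighted_features(z: np.ndarray, combo: WeightCombo, scalar: bool = False) -> np.ndarray:
    """Apply the weight pair to standardized (petiole, height) columns.

    Default output keeps two columns (w_p * z_petiole, w_h * z_height), so
    per-feature importances remain defined; ``scalar`` collapses them to
    the single weighted sum instead.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[1] != 2:
        raise ConfigError("expected an (n, 2) standardized feature matrix")
    w = np.array([combo.w_petiole, combo.w_height])
    return (z @ w)[:, None] if scalar else z * w


def split_train_test(
    records: pd.DataFrame,
    test_fraction: float = 0.2,
    seed: int = 42,
    stratify_by: str = "treatment",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic stratified train/test split of a traits table."""
    if not (0.0 < test_fraction < 1.0):
        raise ConfigError(f"test_fraction must be in (0,1): {test_fraction}")
    train, test = train_test_split(
        records,
        test_size=test_fraction,
        random_state=seed,
        stratify=records[stratify_by],
    )
    return train, test


@dataclass
class AccuracyTable:
    """Classifier x weight-combo test accuracies plus per-feature importances.

    ``accuracy`` is indexed by family with one column per combo label;
    ``importances`` holds permutation importances per (family, combo,
    feature).  Cells whose fit failed carry NaN and an entry in ``failures``.
    """

    accuracy: pd.DataFrame
    importances: pd.DataFrame
    failures: dict[tuple[str, str], str]


def permutation_importance(
    model, X: np.ndarray, y: np.ndarray, n_repeats: int = 10, seed: int = 0
) -> np.ndarray:
    """Mean held-out accuracy drop when each feature column is shuffled."""
    res = _sk_permutation_importance(
        model, X, y, n_repeats=n_repeats, random_state=seed, scoring="accuracy"
    )
    return res.importances_mean


def run_benchmark(
    records: pd.DataFrame,
    combos: Sequence[WeightCombo] = DEFAULT_COMBOS,
    families: Sequence[str] = ALL_FAMILIES,
    seed: int = 42,
    test_fraction: float = 0.2,
    n_repeats_importance: int = 10,
    scalar_features: bool = False,
) -> AccuracyTable:
    """Fit every (family, combo) cell on one stratified split.

    ``records`` needs columns petiole_count, height_cm and treatment.
    The split and every stochastic fit are seeded, so the table is
    reproducible bit-for-bit for a given seed.
    """
    if records["treatment"].nunique() < 2:
        raise ConfigError("need >= 2 treatment classes")
    train, test = split_train_test(records, test_fraction, seed)
    X_train = train[list(FEATURES)].to_numpy(dtype=float)
    X_test = test[list(FEATURES)].to_numpy(dtype=float)
    y_train = train["treatment"].to_numpy()
    y_test = test["treatment"].to_numpy()
    z_train, z_test, _ = standardize(X_train, X_test)

    acc = pd.DataFrame(index=list(families), columns=[c.label for c in combos], dtype=float)
    imp_rows = []
    failures: dict[tuple[str, str], str] = {}
    for combo in combos:
        f_train = weighted_features(z_train, combo, scalar=scalar_features)
        f_test = weighted_features(z_test, combo, scalar=scalar_features)
        for family in families:
            model = make_classifier(family, seed=seed)
            try:
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # LR capped at 100 iterations
                    model.fit(f_train, y_train)
                acc.loc[family, combo.label] = float(model.score(f_test, y_test))
                imps = permutation_importance(
                    model, f_test, y_test, n_repeats=n_repeats_importance, seed=seed
                )
                feature_names = ("weighted_sum",) if scalar_features else FEATURES
                for fname, v in zip(feature_names, imps):
                    imp_rows.append(
                        {"family": family, "combo": combo.label, "feature": fname,
                         "importance": float(v)}
                    )
            except Exception as exc:  # record per-cell failure, keep going
                acc.loc[family, combo.label] = np.nan
                failures[(family, combo.label)] = str(exc)
    importances = pd.DataFrame(imp_rows)
    return AccuracyTable(accuracy=acc, importances=importances, failures=failures)


def repeated_benchmark(
    records: pd.DataFrame,
    combos: Sequence[WeightCombo] = DEFAULT_COMBOS,
    families: Sequence[str] = ALL_FAMILIES,
    split_seeds: Sequence[int] = tuple(range(10)),
    test_fraction: float = 0.2,
) -> tuple[pd.DataFrame, list[AccuracyTable]]:
    """Mean test accuracy over repeated stratified splits.

    A single 20% split of a small cohort is high-variance; averaging over
    independent split seeds gives a stable accuracy estimate for rank
    comparisons between families.  Returns (mean accuracy frame, per-split
    tables).
    """
    tables = [
        run_benchmark(records, combos, families, seed=s, test_fraction=test_fraction,
                      n_repeats_importance=2)
        for s in split_seeds
    ]
    mean_acc = sum(t.accuracy for t in tables) / len(tables)
    return mean_acc, tables
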