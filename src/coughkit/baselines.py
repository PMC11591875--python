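"""Classical-ML reference classifiers for the cough-detection task.

Four scikit-learn models run on the flatten → PCA → standardize feature
track: logistic regression (L2, C=1.0, lbfgs, max_iter=1000), a decision
tree (entropy criterion, unlimited depth, min split 2), a random forest
(100 trees, entropy criterion, random_state 42), and an RBF-kernel SVM
(C=1.0, gamma="scale").  These consume the amplitude-filtered segment set;
the CRNN track does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

BASELINE_NAMES = ("logistic_regression", "decision_tree", "random_forest",
                  "svm_rbf")


@dataclass
class BaselineSpec:
    """A named baseline with its hyperparameter overrides."""

    name: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in BASELINE_NAMES:
            raise ValueError(f"unknown baseline {self.name!r}; "
                             f"expected one of {BASELINE_NAMES}")


def make_baseline(spec: "BaselineSpec | str", seed: int = 0):
    """Instantiate a baseline classifier with its reference hyperparameters.

    The random forest keeps its fixed seed of 42 unless overridden; the
    other stochastic models take the pipeline seed.
    """
    if isinstance(spec, str):
        spec = BaselineSpec(spec)
    defaults = {
        # L2 penalty is scikit-learn's default (passing penalty= explicitly
        # is deprecated since 1.8)
        "logistic_regression": lambda: LogisticRegression(
            C=1.0, max_iter=1000, solver="lbfgs"),
        "decision_tree": lambda: DecisionTreeClassifier(
            criterion="entropy", max_depth=None, min_samples_split=2,
            random_state=seed),
        "random_forest": lambda: RandomForestClassifier(
            n_estimators=100, criterion="entropy", random_state=42),
        "svm_rbf": lambda: SVC(kernel="rbf", C=1.0, gamma="scale", degree=3,
                               random_state=seed),
    }
    model = defaults[spec.name]()
    if spec.hyperparameters:
        model.set_params(**spec.hyperparameters)
    return model


def fit_baseline(spec: "BaselineSpec | str", train_features: np.ndarray,
                 train_labels, seed: int = 0):
    """Fit one baseline on (already PCA'd, standardized) training features."""
    y = np.asarray(train_labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("training labels contain a single class")
    model = make_baseline(spec, seed=seed)
    model.fit(np.asarray(train_features), y)
    return model


def score_baseline(fitted, test_features: np.ndarray) -> np.ndarray:
    """Continuous cough-likeness score per segment (for ROC analysis).

    Probability of the positive class where the model provides one,
    otherwise the signed decision margin.
    """
    X = np.asarray(test_features)
    if hasattr(fitted, "predict_proba"):
        try:
            proba = fitted.predict_proba(X)
            pos = list(fitted.classes_).index(True)
            return proba[:, pos]
        except AttributeError:
            pass
    return fitted.decision_function(X)
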