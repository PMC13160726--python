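"""Registry of the supported model families.

Families mirror the six baseline classifier configurations (decision tree,
polynomial-kernel SVM, kNN with k=10, Gaussian naive Bayes, logistic
regression, and a gradient-boosted tree ensemble with 100 trees at learning
rate 0.1) and provide a regression counterpart per family for logit-residual
stages. Distance/margin/linear families are flagged as needing standardized
inputs; tree ensembles are not.
"""

from __future__ import annotations

from sklearn.ensemble import GradientBoostingClassifier, GradientBoostingRegressor
from sklearn.linear_model import BayesianRidge, LogisticRegression, Ridge
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

FAMILIES = (
    "decision_tree",
    "svm_poly",
    "knn",
    "naive_bayes_gaussian",
    "logistic",
    "gbt",
)

#: families whose classifiers are sensitive to feature scale
NEEDS_STANDARDIZATION = frozenset({"svm_poly", "knn", "logistic"})


def make_classifier(family: str, seed: int | None = 0, **overrides):
    """Probabilistic binary classifier for a named family."""
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **overrides)
    if family == "svm_poly":
        params = {"kernel": "poly", "degree": 3, "probability": True}
        params.update(overrides)
        return SVC(random_state=seed, **params)
    if family == "knn":
        params = {"n_neighbors": 10}
        params.update(overrides)
        return KNeighborsClassifier(**params)
    if family == "naive_bayes_gaussian":
        return GaussianNB(**overrides)
    if family == "logistic":
        params = {"max_iter": 1000}
        params.update(overrides)
        return LogisticRegression(random_state=seed, **params)
    if family == "gbt":
        params = {"n_estimators": 100, "learning_rate": 0.1}
        params.update(overrides)
        return GradientBoostingClassifier(random_state=seed, **params)
    raise ValueError(f"unknown model family {family!r}; choose from {FAMILIES}")


def make_regressor(family: str, seed: int | None = 0, **overrides):
    """Regression counterpart used for logit-residual stages."""
    if family == "decision_tree":
        return DecisionTreeRegressor(random_state=seed, **overrides)
    if family == "svm_poly":
        params = {"kernel": "poly", "degree": 3}
        params.update(overrides)
        return SVR(**params)
    if family == "knn":
        params = {"n_neighbors": 10}
        params.update(overrides)
        return KNeighborsRegressor(**params)
    if family == "naive_bayes_gaussian":
        return BayesianRidge(**overrides)
    if family == "logistic":
        params = {"alpha": 1.0}
        params.update(overrides)
        return Ridge(random_state=seed, **params)
    if family == "gbt":
        params = {"n_estimators": 100, "learning_rate": 0.1}
        params.update(overrides)
        return GradientBoostingRegressor(random_state=seed, **params)
    raise ValueError(f"unknown model family {family!r}; choose from {FAMILIES}")
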