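"""Exploratory classifier search over a nested feature-policy ladder.

The ladder starts from the ledger's main features (P0) and escalates by
adding reserved features one category at a time — intensities, then
positions, then FWHM (then ratios, if any are reserved).  Each round runs
all 19 registered classifiers under stratified fivefold cross-validation
with fold-internal z-score standardization, keeps the top-3 by pooled
held-out accuracy, and stops at the first policy whose best accuracy meets
the target (default 100 %).

The registry mirrors the classic interactive classifier-app lineup the
model names come from: 3 decision trees, 2 discriminants, 6 SVMs, 4 KNNs
and 4 ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier, RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ValidationError
from .io import FEATURE_NAMES, RipenessLabel, validate_feature_table
from .stats import SignificanceLedger

__all__ = [
    "FeaturePolicy",
    "ClassifierSpec",
    "CVResult",
    "SearchReport",
    "classifier_registry",
    "build_policy_ladder",
    "crossval_score",
    "exploratory_search",
]

DEFAULT_CV_SEED = 20210915


def _inverse_square_distance(distances: np.ndarray) -> np.ndarray:
    """Squared-inverse-distance KNN weights; exact matches dominate."""
    with np.errstate(divide="ignore"):
        w = 1.0 / np.maximum(distances, 1e-12) ** 2
    return w


class RegularizedQDA(BaseEstimator, ClassifierMixin):
    """Gaussian quadratic discriminant with ridge-regularized covariances.

    Per class k: Sigma_k = (1 - reg) * S_k + reg * (tr(S_k)/P) * I (plus a
    tiny absolute ridge), so the classifier stays defined when a training
    class has fewer samples than features — which happens routinely in
    small cross-validation folds.
    """

    def __init__(self, reg: float = 0.01, eps: float = 1e-8):
        self.reg = reg
        self.eps = eps

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        self.priors_ = counts / counts.sum()
        p = X.shape[1]
        self.means_, self._inv, self._logdet = [], [], []
        for cls in self.classes_:
            sub = X[y == cls]
            mu = sub.mean(axis=0)
            centered = sub - mu
            cov = centered.T @ centered / max(len(sub) - 1, 1)
            shrink = np.trace(cov) / p if np.trace(cov) > 0 else 1.0
            cov = (1 - self.reg) * cov + (self.reg * shrink + self.eps) * np.eye(p)
            sign, logdet = np.linalg.slogdet(cov)
            self.means_.append(mu)
            self._inv.append(np.linalg.inv(cov))
            self._logdet.append(logdet)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        scores = np.empty((X.shape[0], len(self.classes_)))
        for idx, (mu, inv, logdet, prior) in enumerate(
            zip(self.means_, self._inv, self._logdet, self.priors_)
        ):
            d = X - mu
            maha = np.einsum("ij,jk,ik->i", d, inv, d)
            scores[:, idx] = -0.5 * (logdet + maha) + np.log(prior)
        return self.classes_[np.argmax(scores, axis=1)]


class KernelScaleSVC(BaseEstimator, ClassifierMixin):
    """RBF SVC whose kernel width scales with the feature count.

    Kernel K(x, y) = exp(-||x-y||^2 / sigma^2) with
    sigma = scale_factor * sqrt(P) for P features (fine = 1/4, medium = 1,
    coarse = 4), i.e. gamma = 1 / sigma^2 resolved at fit time.
    """

    def __init__(self, scale_factor: float = 1.0, C: float = 1.0):
        self.scale_factor = scale_factor
        self.C = C

    def fit(self, X, y):
        sigma = self.scale_factor * np.sqrt(X.shape[1])
        self.svc_ = SVC(kernel="rbf", C=self.C, gamma=1.0 / sigma**2)
        self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        return self

    def predict(self, X):
        return self.svc_.predict(X)


class CappedKNN(BaseEstimator, ClassifierMixin):
    """KNN whose neighbor count is capped at n_train - 1 at fit time."""

    def __init__(self, n_neighbors: int = 100):
        self.n_neighbors = n_neighbors

    def fit(self, X, y):
        k = min(self.n_neighbors, len(X) - 1)
        self.knn_ = KNeighborsClassifier(n_neighbors=max(1, k))
        self.knn_.fit(X, y)
        self.classes_ = self.knn_.classes_
        return self

    def predict(self, X):
        return self.knn_.predict(X)


@dataclass(frozen=True)
class ClassifierSpec:
    """A registry entry: name, family and a documented estimator recipe."""

    name: str
    family: str
    estimator: BaseEstimator
    hyperparameters: dict

    def build(self, seed: int) -> BaseEstimator:
        est = clone(self.estimator)
        if "random_state" in est.get_params():
            est.set_params(random_state=seed)
        return est


def classifier_registry() -> list[ClassifierSpec]:
    """The 19 evaluated classifiers across the 5 families (CRT/DA/SVM/KNN/ensemble)."""
    specs: list[ClassifierSpec] = []

    def add(name, family, estimator, **hp):
        specs.append(ClassifierSpec(name, family, estimator, hp))

    add("fine tree", "CRT", DecisionTreeClassifier(max_leaf_nodes=100), max_leaf_nodes=100)
    add("medium tree", "CRT", DecisionTreeClassifier(max_leaf_nodes=20), max_leaf_nodes=20)
    add("coarse tree", "CRT", DecisionTreeClassifier(max_leaf_nodes=4), max_leaf_nodes=4)

    add("linear discriminant", "DA", LinearDiscriminantAnalysis(), solver="svd")
    # ridge regularization keeps per-class covariances invertible in small folds
    add("quadratic discriminant", "DA", RegularizedQDA(reg=0.01), reg=0.01)

    add("SVM linear kernel", "SVM", SVC(kernel="linear", C=1.0), kernel="linear", C=1.0)
    add(
        "SVM quadratic kernel",
        "SVM",
        SVC(kernel="poly", degree=2, gamma="scale", coef0=1.0, C=1.0),
        kernel="poly",
        degree=2,
        coef0=1.0,
    )
    add(
        "SVM cubic kernel",
        "SVM",
        SVC(kernel="poly", degree=3, gamma="scale", coef0=1.0, C=1.0),
        kernel="poly",
        degree=3,
        coef0=1.0,
    )
    add("SVM fine Gaussian", "SVM", KernelScaleSVC(scale_factor=0.25), kernel_scale="sqrt(P)/4")
    add("SVM medium Gaussian", "SVM", KernelScaleSVC(scale_factor=1.0), kernel_scale="sqrt(P)")
    add("SVM coarse Gaussian", "SVM", KernelScaleSVC(scale_factor=4.0), kernel_scale="4 sqrt(P)")

    add("fine KNN", "KNN", KNeighborsClassifier(n_neighbors=1), k=1)
    add("medium KNN", "KNN", KNeighborsClassifier(n_neighbors=10), k=10)
    add("coarse KNN", "KNN", CappedKNN(n_neighbors=100), k="min(100, n-1)")
    add(
        "weighted KNN",
        "KNN",
        KNeighborsClassifier(n_neighbors=10, weights=_inverse_square_distance),
        k=10,
        weights="squared inverse distance",
    )

    add(
        "boosted trees",
        "ensemble",
        AdaBoostClassifier(estimator=DecisionTreeClassifier(max_leaf_nodes=20), n_estimators=30),
        n_estimators=30,
        learner="tree(max_leaf_nodes=20)",
    )
    add("bagged trees", "ensemble", RandomForestClassifier(n_estimators=30), n_estimators=30)
    add(
        "subspace discriminant",
        "ensemble",
        BaggingClassifier(
            estimator=LinearDiscriminantAnalysis(),
            n_estimators=30,
            max_features=0.5,
            bootstrap=False,
        ),
        n_estimators=30,
        subspace="P/2",
    )
    add(
        "subspace KNN",
        "ensemble",
        BaggingClassifier(
            estimator=KNeighborsClassifier(n_neighbors=1),
            n_estimators=30,
            max_features=0.5,
            bootstrap=False,
        ),
        n_estimators=30,
        subspace="P/2",
    )

    assert len(specs) == 19 and len({s.name for s in specs}) == 19
    return specs


@dataclass(frozen=True)
class FeaturePolicy:
    """A named subset of the 15 feature columns used as predictors."""

    name: str
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = [f for f in self.feature_names if f not in FEATURE_NAMES]
        if unknown:
            raise ValidationError(f"unknown features in policy {self.name}: {unknown}")
        if not self.feature_names:
            raise ValidationError(f"policy {self.name} selects no features")


_CATEGORIES = ("int_", "pos_", "fwhm_", "ratio_")


def build_policy_ladder(ledger: SignificanceLedger) -> list[FeaturePolicy]:
    """Nested policies: P0 = main; then + reserved intensities, positions,
    FWHM (and ratios, if any are reserved).  Stages that add nothing are
    skipped; features keep canonical column order."""
    main = [f for f in FEATURE_NAMES if f in set(ledger.main)]
    if not main:
        raise ValidationError(
            "significance ledger has no main-tier features; review the alpha level"
        )
    reserved = set(ledger.reserved)
    current = list(main)
    ladder = [FeaturePolicy("P0", tuple(current))]
    for prefix in _CATEGORIES:
        extra = [f for f in FEATURE_NAMES if f.startswith(prefix) and f in reserved and f not in current]
        if extra:
            current = [f for f in FEATURE_NAMES if f in set(current) | set(extra)]
            ladder.append(FeaturePolicy(f"P{len(ladder)}", tuple(current)))
    return ladder


@dataclass(frozen=True)
class CVResult:
    classifier: str
    policy: str
    fold_accuracies: tuple[float, ...]
    overall_accuracy: float
    confusion: np.ndarray


def crossval_score(
    table: pd.DataFrame,
    policy: FeaturePolicy,
    spec: ClassifierSpec,
    folds: int = 5,
    seed: int = DEFAULT_CV_SEED,
) -> CVResult:
    """Stratified k-fold CV with fold-internal z-scoring.

    The split depends only on the labels and the seed, so policies are
    compared on identical folds.  Overall accuracy pools the held-out
    predictions of every fold.
    """
    table = validate_feature_table(table)
    if table["label"].isna().any() or (table["label"] == "").any():
        raise ValidationError("cross-validation requires every sample to be labeled")
    y = np.array([int(lab) for lab in table["label"]])
    counts = np.bincount(y, minlength=3)
    if np.any(counts < folds):
        raise ValidationError(
            f"every class needs >= {folds} samples for {folds}-fold CV (counts {counts.tolist()})"
        )
    X = table.loc[:, list(policy.feature_names)].to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_acc = []
    y_pred = np.empty_like(y)
    for train, test in skf.split(X, y):
        model = make_pipeline(StandardScaler(), spec.build(seed))
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        y_pred[test] = pred
        fold_acc.append(float(np.mean(pred == y[test])))
    overall = float(np.mean(y_pred == y))
    conf = confusion_matrix(y, y_pred, labels=[0, 1, 2])
    return CVResult(spec.name, policy.name, tuple(fold_acc), overall, conf)


@dataclass(frozen=True)
class PolicyRound:
    policy: FeaturePolicy
    results: tuple[CVResult, ...]
    top3: tuple[str, ...]

    @property
    def best(self) -> CVResult:
        return max(self.results, key=lambda r: r.overall_accuracy)


@dataclass(frozen=True)
class SearchReport:
    """Per-policy results plus the terminating policy and best classifier."""

    rounds: tuple[PolicyRound, ...]
    terminating_policy: FeaturePolicy
    best_classifier: str
    best_accuracy: float
    target: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rnd in self.rounds:
            for res in rnd.results:
                rows.append(
                    {
                        "policy": rnd.policy.name,
                        "n_features": len(rnd.policy.feature_names),
                        "classifier": res.classifier,
                        "overall_accuracy": res.overall_accuracy,
                        "top3": res.classifier in rnd.top3,
                    }
                )
        return pd.DataFrame.from_records(rows)


def _top3(results: tuple[CVResult, ...]) -> tuple[str, ...]:
    # stable sort: ties keep registry order
    ranked = sorted(range(len(results)), key=lambda i: -results[i].overall_accuracy)
    return tuple(results[i].classifier for i in ranked[:3])


def exploratory_search(
    table: pd.DataFrame,
    ledger: SignificanceLedger,
    target: float = 1.0,
    folds: int = 5,
    seed: int = DEFAULT_CV_SEED,
    registry: list[ClassifierSpec] | None = None,
    stop_at_target: bool = True,
) -> SearchReport:
    """Run the policy ladder until the target accuracy is met.

    Each round evaluates all registered classifiers on the current policy,
    records the top-3, and escalates to the next policy unless the best
    accuracy has reached ``target`` (set ``stop_at_target=False`` to always
    evaluate the full ladder; the terminating round is then the first that
    met the target, or the last).
    """
    registry = registry if registry is not None else classifier_registry()
    ladder = build_policy_ladder(ledger)
    rounds: list[PolicyRound] = []
    terminating: PolicyRound | None = None
    for policy in ladder:
        results = tuple(
            crossval_score(table, policy, spec, folds=folds, seed=seed) for spec in registry
        )
        rnd = PolicyRound(policy, results, _top3(results))
        rounds.append(rnd)
        if terminating is None and rnd.best.overall_accuracy >= target:
            terminating = rnd
            if stop_at_target:
                break
    if terminating is None:
        terminating = rounds[-1]
    best = terminating.best
    return SearchReport(
        rounds=tuple(rounds),
        terminating_policy=terminating.policy,
        best_classifier=best.classifier,
        best_accuracy=best.overall_accuracy,
        target=target,
    )
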