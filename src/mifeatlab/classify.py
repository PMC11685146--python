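"""Nine-family classifier benchmark under stratified 5-fold cross-validation.

Families follow the common toolbox presets: decision trees (fine/medium/
coarse), discriminant analysis (linear/quadratic), logistic regression,
naive Bayes (Gaussian/kernel), SVM (linear, quadratic, cubic and
fine/medium/coarse Gaussian), kNN (fine/medium/coarse/cubic/cosine/
weighted), ensembles (bagged trees, boosted trees, subspace discriminant,
subspace kNN), neural networks (narrow/medium/wide/bi-layer/tri-layer) and
kernel approximation (Nystroem features + linear SVM or logistic
regression).  Each family reports its best variant by mean fold accuracy,
mirroring how benchmark tables print one number per family; per-variant
results stay in the report payload.

Scale-sensitive estimators are wrapped in a standardization pipeline.  A
variant that fails to fit (e.g., singular covariance of quadratic
discriminant analysis on wide matrices) is recorded as failed, never
aborting the run; a family is failed only if every variant fails.

Accuracy is ACC = (TP + TN) / (TP + FN + TN + FP); for more than two
classes the confusion counts are aggregated one-vs-rest over classes while
the reported accuracy is the fraction of correctly labeled test samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.kernel_approximation import Nystroem
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

CLASSIFIER_FAMILIES: tuple[str, ...] = (
    "DT", "DA", "LR", "NB", "SVM", "kNN", "EL", "NN", "KA",
)

__all__ = [
    "CLASSIFIER_FAMILIES",
    "ConfusionCounts",
    "FamilyResult",
    "CVReport",
    "KernelNaiveBayes",
    "accuracy",
    "run_cv",
]


@dataclass
class ConfusionCounts:
    """TP/TN/FP/FN totals (one-vs-rest aggregated when K > 2)."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def accuracy(c: ConfusionCounts) -> float:
    """ACC = (TP + TN) / (TP + FN + TN + FP)."""
    if c.total == 0:
        raise ValueError("confusion counts are empty")
    return (c.TP + c.TN) / c.total


def _confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    classes = np.unique(y_true)
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    if classes.size == 2:
        tn, fp, fn, tp = cm.ravel()
        return ConfusionCounts(int(tp), int(tn), int(fp), int(fn))
    n = y_true.size
    tp = np.diag(cm)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = n - tp - fn - fp
    return ConfusionCounts(int(tp.sum()), int(tn.sum()), int(fp.sum()), int(fn.sum()))


class KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with a per-feature Gaussian kernel density per class.

    Class-conditional densities are products of univariate kernel density
    estimates with Silverman's bandwidth; prediction maximizes the log
    posterior under uniform-prior-free class frequencies.  Quadratic in the
    training-set size, so intended for moderate sample counts.
    """

    def __init__(self, min_bandwidth: float = 1e-9):
        self.min_bandwidth = min_bandwidth

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.X_by_class_ = []
        self.bandwidth_ = []
        self.log_prior_ = []
        for c in self.classes_:
            Xc = X[y == c]
            nc = Xc.shape[0]
            sigma = Xc.std(axis=0, ddof=1) if nc > 1 else np.ones(X.shape[1])
            h = np.maximum(sigma * (4.0 / (3.0 * nc)) ** 0.2, self.min_bandwidth)
            self.X_by_class_.append(Xc)
            self.bandwidth_.append(h)
            self.log_prior_.append(np.log(nc / X.shape[0]))
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=np.float64)
        n_test = X.shape[0]
        jll = np.empty((n_test, self.classes_.size))
        for k, (Xc, h, lp) in enumerate(
            zip(self.X_by_class_, self.bandwidth_, self.log_prior_)
        ):
            total = np.full(n_test, lp)
            for f in range(X.shape[1]):  # feature-wise keeps memory bounded
                z = (X[:, f, None] - Xc[None, :, f]) / h[f]
                log_k = -0.5 * z**2 - np.log(h[f] * np.sqrt(2 * np.pi))
                m = log_k.max(axis=1)
                total += m + np.log(
                    np.exp(log_k - m[:, None]).mean(axis=1)
                )
            jll[:, k] = total
        return jll

    def predict(self, X):
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


def _scaled(est) -> object:
    return make_pipeline(StandardScaler(), est)


def _family_variants(seed: int, n_features: int) -> dict[str, dict[str, object]]:
    """Estimator per (family, variant); random_state fixed from ``seed``."""
    rs = int(seed) % (2**31)
    gamma_med = 1.0 / max(n_features, 1)  # kernel scale sqrt(P): gamma = 1/P
    return {
        "DT": {
            "fine": DecisionTreeClassifier(max_leaf_nodes=100, random_state=rs),
            "medium": DecisionTreeClassifier(max_leaf_nodes=20, random_state=rs),
            "coarse": DecisionTreeClassifier(max_leaf_nodes=4, random_state=rs),
        },
        "DA": {
            "linear": LinearDiscriminantAnalysis(),
            "quadratic": QuadraticDiscriminantAnalysis(),
        },
        "LR": {
            "logistic": _scaled(LogisticRegression(max_iter=1000)),
        },
        "NB": {
            "gaussian": GaussianNB(),
            "kernel": _scaled(KernelNaiveBayes()),
        },
        "SVM": {
            "linear": _scaled(SVC(kernel="linear")),
            "quadratic": _scaled(SVC(kernel="poly", degree=2, gamma="scale", coef0=1.0)),
            "cubic": _scaled(SVC(kernel="poly", degree=3, gamma="scale", coef0=1.0)),
            "fine_gaussian": _scaled(SVC(kernel="rbf", gamma=16.0 * gamma_med)),
            "medium_gaussian": _scaled(SVC(kernel="rbf", gamma=gamma_med)),
            "coarse_gaussian": _scaled(SVC(kernel="rbf", gamma=gamma_med / 16.0)),
        },
        "kNN": {
            "fine": _scaled(KNeighborsClassifier(n_neighbors=1)),
            "medium": _scaled(KNeighborsClassifier(n_neighbors=10)),
            "coarse": _scaled(KNeighborsClassifier(n_neighbors=100)),
            "cubic": _scaled(KNeighborsClassifier(n_neighbors=10, p=3)),
            "cosine": _scaled(KNeighborsClassifier(n_neighbors=10, metric="cosine")),
            "weighted": _scaled(KNeighborsClassifier(n_neighbors=10, weights="distance")),
        },
        "EL": {
            "bagged_trees": RandomForestClassifier(n_estimators=30, random_state=rs),
            "boosted_trees": AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_leaf_nodes=20, random_state=rs),
                n_estimators=30,
                learning_rate=0.1,
                random_state=rs,
            ),
            "subspace_discriminant": BaggingClassifier(
                estimator=LinearDiscriminantAnalysis(),
                n_estimators=30,
                max_features=0.5,
                bootstrap=False,
                random_state=rs,
            ),
            "subspace_knn": _scaled(
                BaggingClassifier(
                    estimator=KNeighborsClassifier(n_neighbors=10),
                    n_estimators=30,
                    max_features=0.5,
                    bootstrap=False,
                    random_state=rs,
                )
            ),
        },
        "NN": {
            "narrow": _scaled(MLPClassifier((10,), max_iter=300, random_state=rs)),
            "medium": _scaled(MLPClassifier((25,), max_iter=300, random_state=rs)),
            "wide": _scaled(MLPClassifier((100,), max_iter=300, random_state=rs)),
            "bilayer": _scaled(MLPClassifier((10, 10), max_iter=300, random_state=rs)),
            "trilayer": _scaled(
                MLPClassifier((10, 10, 10), max_iter=300, random_state=rs)
            ),
        },
        "KA": {
            "svm_kernel": make_pipeline(
                StandardScaler(),
                Nystroem(n_components=100, random_state=rs),
                LinearSVC(),
            ),
            "logistic_kernel": make_pipeline(
                StandardScaler(),
                Nystroem(n_components=100, random_state=rs),
                LogisticRegression(max_iter=1000),
            ),
        },
    }


@dataclass
class VariantResult:
    name: str
    status: str  # "ok" | "failed"
    fold_accuracies: list[float] = field(default_factory=list)
    mean_accuracy: float = float("nan")
    confusion: ConfusionCounts | None = None
    reason: str = ""


@dataclass
class FamilyResult:
    family: str
    status: str
    best_variant: str = ""
    fold_accuracies: list[float] = field(default_factory=list)
    mean_accuracy: float = float("nan")
    confusion: ConfusionCounts | None = None
    variants: dict[str, VariantResult] = field(default_factory=dict)


@dataclass
class CVReport:
    """Cross-validation outcome per classifier family."""

    families: dict[str, FamilyResult]
    n_folds: int
    seed: int

    def to_frame(self):
        import pandas as pd

        rows = []
        for fam in self.families.values():
            rows.append(
                {
                    "family": fam.family,
                    "status": fam.status,
                    "best_variant": fam.best_variant,
                    "mean_accuracy": fam.mean_accuracy,
                    **{f"fold{i + 1}": a for i, a in enumerate(fam.fold_accuracies)},
                }
            )
        return pd.DataFrame(rows)


def _run_variant(est, X, y, splits) -> VariantResult:
    name = type(est).__name__
    res = VariantResult(name=name, status="ok")
    y_pred = np.empty_like(y)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for train, test in splits:
                model = clone(est)
                model.fit(X[train], y[train])
                pred = model.predict(X[test])
                y_pred[test] = pred
                res.fold_accuracies.append(float(np.mean(pred == y[test])))
    except Exception as exc:  # recorded, never aborts the benchmark
        return VariantResult(name=name, status="failed", reason=f"{type(exc).__name__}: {exc}")
    res.mean_accuracy = float(np.mean(res.fold_accuracies))
    res.confusion = _confusion_counts(y, y_pred)
    return res


def run_cv(
    fm,
    classifiers: tuple[str, ...] = CLASSIFIER_FAMILIES,
    seed: int = 0,
    *,
    n_folds: int = 5,
    variants: dict[str, tuple[str, ...]] | None = None,
) -> CVReport:
    """Benchmark classifier families on a feature matrix with k-fold CV.

    ``fm`` is a :class:`~mifeatlab.selection.FeatureMatrix` or a
    ``(values, labels)`` pair.  Folds are stratified and seeded, shared by
    every variant, and each sample is tested exactly once.  ``variants``
    optionally restricts the variant names run per family.
    """
    if hasattr(fm, "values") and hasattr(fm, "labels"):
        X, y = np.asarray(fm.values, dtype=np.float64), np.asarray(fm.labels)
    else:
        X, y = (np.asarray(a) for a in fm)
    bad = [c for c in classifiers if c not in CLASSIFIER_FAMILIES]
    if bad:
        raise ValueError(f"unknown classifier families: {bad}")
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    X = np.nan_to_num(X, nan=0.0, posinf=0.0, neginf=0.0)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed) % (2**31))
    splits = list(skf.split(X, y))
    catalog = _family_variants(seed, X.shape[1])
    families: dict[str, FamilyResult] = {}
    for fam in classifiers:
        fam_res = FamilyResult(family=fam, status="failed")
        for vname, est in catalog[fam].items():
            if variants and fam in variants and vname not in variants[fam]:
                continue
            vres = _run_variant(est, X, y, splits)
            vres.name = vname
            fam_res.variants[vname] = vres
            if vres.status == "failed":
                logger.warning("%s/%s failed: %s", fam, vname, vres.reason)
        ok = [v for v in fam_res.variants.values() if v.status == "ok"]
        if ok:
            best = max(ok, key=lambda v: v.mean_accuracy)
            fam_res.status = "ok"
            fam_res.best_variant = best.name
            fam_res.fold_accuracies = best.fold_accuracies
            fam_res.mean_accuracy = best.mean_accuracy
            fam_res.confusion = best.confusion
        families[fam] = fam_res
    return CVReport(families=families, n_folds=n_folds, seed=seed)
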