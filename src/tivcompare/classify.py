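"""Multi-classifier sex-prediction harness with accuracy-profile clustering.

Twelve supervised classifiers (LDA, QDA, KNN, logistic regression, elastic-net
logistic regression, FDA, a single classification tree, a random forest, a
small neural network, and linear / RBF / cubic-polynomial SVMs) are trained on
z-scored features and evaluated on train / test / external-validation
subsamples for each dataset (TIV-only, raw, and every adjusted table).
Performance is summarized as overall accuracy with an exact (Clopper-Pearson)
binomial CI and Cohen's kappa with an asymptotic CI. Datasets with similar
accuracy profiles across classifiers are then grouped by PAM (k-medoids,
K chosen in 2..5 by maximum average silhouette) and ordered by average-linkage
hierarchical clustering on Euclidean distances.

Conventions: KNN uses k = round(sqrt(n_train)); the random forest uses 500
trees with 10 candidate features per split; SVM hyperparameters are chosen by
stratified 10-fold cross-validation over C in 10^-3..10^3 and gamma in
{0.0001, 0.001, 0.01, 0.1, 0.5, 1, 2, 3, 4, 5}, ties broken toward the
smaller C then the smaller gamma. FDA is realized as LDA on a fixed cubic
spline basis expansion of each feature.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import dendrogram, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import silhouette_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

CLASSIFIER_NAMES = (
    "LDA", "QDA", "KNN", "LR", "LR_EN", "FDA",
    "TREE", "RF", "ANN", "SVM_LIN", "SVM_RBF", "SVM_POLY3",
)

SVM_C_GRID = tuple(10.0**k for k in range(-3, 4))
SVM_GAMMA_GRID = (0.0001, 0.001, 0.01, 0.1, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0)


class ClassificationError(ValueError):
    pass


def knn_k_rule(n_train: int) -> int:
    """k = round(sqrt(n)) to the nearest integer, never below 1 (k(622) = 25)."""
    if n_train < 1:
        raise ClassificationError("training sample must be non-empty")
    return max(1, int(np.floor(np.sqrt(n_train) + 0.5)))


@dataclass
class FeatureStandardizer:
    """Per-feature z-scoring fitted on one sample; zero-variance features dropped."""

    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None
    keep_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FeatureStandardizer":
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            raise ClassificationError("fit sample is empty")
        mean = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        keep = scale > 0
        if not keep.any():
            raise ClassificationError("all features are constant in the fit sample")
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance feature(s)", stacklevel=2
            )
        self.mean_, self.scale_, self.keep_ = mean[keep], scale[keep], keep
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X[:, self.keep_] - self.mean_) / self.scale_


def standardize(features: np.ndarray, fit_sample: np.ndarray):
    """z-score `features` with location/scale estimated on `fit_sample` only."""
    st = FeatureStandardizer().fit(fit_sample)
    return st.transform(features), st


@dataclass(frozen=True)
class ClassifierSpec:
    """Named classifier with its hyperparameters (see module docstring for defaults)."""

    name: str
    hyper: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in CLASSIFIER_NAMES:
            raise ClassificationError(f"unknown classifier {self.name!r}")


def default_specs(
    svm_c_grid=SVM_C_GRID,
    svm_gamma_grid=SVM_GAMMA_GRID,
    cv: int = 10,
    rf_trees: int = 500,
    rf_features: int = 10,
) -> list[ClassifierSpec]:
    """The full 12-classifier roster with the standard hyperparameters."""
    svm = {"c_grid": tuple(svm_c_grid), "gamma_grid": tuple(svm_gamma_grid), "cv": cv}
    return [
        ClassifierSpec("LDA"),
        ClassifierSpec("QDA"),
        ClassifierSpec("KNN"),
        ClassifierSpec("LR"),
        ClassifierSpec("LR_EN", {"l1_ratio": 0.5, "cv": cv}),
        ClassifierSpec("FDA"),
        ClassifierSpec("TREE"),
        ClassifierSpec("RF", {"n_trees": rf_trees, "max_features": rf_features}),
        ClassifierSpec("ANN"),
        ClassifierSpec("SVM_LIN", dict(svm, kernel="linear")),
        ClassifierSpec("SVM_RBF", dict(svm, kernel="rbf")),
        ClassifierSpec("SVM_POLY3", dict(svm, kernel="poly")),
    ]


def tune_svm(X, y, kernel: str, c_grid, gamma_grid, cv: int = 10, seed: int = 0):
    """Pick (C, gamma) maximizing stratified k-fold CV accuracy.

    Ties break toward the smaller C, then the smaller gamma; the fold split is
    deterministic under `seed`. If a class has fewer members than `cv`, the
    fold count is reduced with a warning. For the linear kernel the gamma grid
    is ignored (single pass with sklearn's default gamma).
    """
    y = np.asarray(y)
    _, class_counts = np.unique(y, return_counts=True)
    n_folds = min(cv, int(class_counts.min()))
    if n_folds < cv:
        warnings.warn(f"reducing CV folds from {cv} to {n_folds}", stacklevel=2)
    if n_folds < 2:
        raise ClassificationError("need at least 2 members per class to cross-validate")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    gammas = ("scale",) if kernel == "linear" else tuple(gamma_grid)
    best = None
    for c in sorted(c_grid):
        for g in gammas:
            correct = 0
            for tr, va in folds:
                model = SVC(kernel=kernel, C=c, gamma=g, degree=3, max_iter=200_000)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # capped-iteration fits
                    model.fit(X[tr], y[tr])
                correct += int((model.predict(X[va]) == y[va]).sum())
            acc = correct / len(y)
            if best is None or acc > best[0] + 1e-12:
                best = (acc, c, g)
    return best[1], best[2], best[0]


def _build_and_fit(spec: ClassifierSpec, X, y, seed: int):
    h = spec.hyper
    n, p = X.shape
    name = spec.name
    if name == "LDA":
        model = LinearDiscriminantAnalysis()
    elif name == "QDA":
        reg = h.get("reg_param", 0.0)
        _, counts = np.unique(y, return_counts=True)
        if reg == 0.0 and counts.min() <= p:
            raise ClassificationError(
                "QDA within-class covariance is singular when a class has no more "
                "subjects than features; supply hyper={'reg_param': ...} to regularize"
            )
        model = QuadraticDiscriminantAnalysis(reg_param=reg)
    elif name == "KNN":
        model = KNeighborsClassifier(n_neighbors=knn_k_rule(n))
    elif name == "LR":
        model = LogisticRegression(penalty=None, max_iter=2000)
    elif name == "LR_EN":
        model = LogisticRegressionCV(
            penalty="elasticnet",
            solver="saga",
            l1_ratios=[h.get("l1_ratio", 0.5)],
            Cs=h.get("Cs", 5),
            cv=h.get("cv", 10),
            max_iter=h.get("max_iter", 2000),
            tol=1e-3,
            random_state=seed,
        )
    elif name == "FDA":
        model = make_pipeline(
            SplineTransformer(n_knots=h.get("n_knots", 5), degree=3),
            LinearDiscriminantAnalysis(),
        )
    elif name == "TREE":
        model = DecisionTreeClassifier(random_state=seed)
    elif name == "RF":
        model = RandomForestClassifier(
            n_estimators=h.get("n_trees", 500),
            max_features=min(h.get("max_features", 10), p),
            random_state=seed,
        )
    elif name == "ANN":
        model = MLPClassifier(
            hidden_layer_sizes=(1,),
            activation="logistic",
            solver="lbfgs",
            max_iter=h.get("max_iter", 5000),
            random_state=seed,
        )
    elif name in ("SVM_LIN", "SVM_RBF", "SVM_POLY3"):
        kernel = h.get("kernel", {"SVM_LIN": "linear", "SVM_RBF": "rbf", "SVM_POLY3": "poly"}[name])
        c, g, _ = tune_svm(
            X, y, kernel,
            h.get("c_grid", SVM_C_GRID),
            h.get("gamma_grid", SVM_GAMMA_GRID),
            cv=h.get("cv", 10),
            seed=seed,
        )
        model = SVC(kernel=kernel, C=c, gamma=g, degree=3, max_iter=200_000)
    else:  # pragma: no cover - guarded by ClassifierSpec
        raise ClassificationError(name)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model


def fit_predict(
    spec: ClassifierSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    eval_sets: dict[str, np.ndarray],
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Fit one classifier on the training set and predict every evaluation set."""
    y_train = np.asarray(y_train)
    classes, counts = np.unique(y_train, return_counts=True)
    if len(classes) != 2 or counts[0] != counts[1]:
        raise ClassificationError("training labels must be binary and balanced")
    model = _build_and_fit(spec, np.asarray(X_train, dtype=float), y_train, seed)
    return {
        name: np.asarray(model.predict(np.asarray(X, dtype=float)))
        for name, X in eval_sets.items()
    }


def evaluate(predicted, actual, level: float = 0.95) -> dict:
    """Accuracy (%) with exact binomial CI, and Cohen's kappa with asymptotic CI."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if len(predicted) != len(actual):
        raise ClassificationError("length mismatch")
    if len(actual) == 0:
        raise ClassificationError("empty input")
    n = len(actual)
    k = int((predicted == actual).sum())
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=level, method="exact")
    labels = np.unique(np.concatenate([actual, predicted]))
    table = np.zeros((len(labels), len(labels)))
    idx = {lab: i for i, lab in enumerate(labels)}
    for a, p_ in zip(actual, predicted):
        table[idx[a], idx[p_]] += 1
    kappa, k_lo, k_hi = _kappa_ci(table, level)
    return {
        "accuracy": 100.0 * k / n,
        "acc_lo": 100.0 * ci.low,
        "acc_hi": 100.0 * ci.high,
        "kappa": kappa,
        "kappa_lo": k_lo,
        "kappa_hi": k_hi,
        "n": n,
    }


def _kappa_ci(table: np.ndarray, level: float):
    """Cohen's kappa with its large-sample (Fleiss-Cohen-Everitt) CI."""
    from statsmodels.stats.inter_rater import cohens_kappa

    n = table.sum()
    po = np.trace(table) / n
    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    pe = float(row @ col)
    if pe >= 1.0 - 1e-12:  # degenerate marginals
        return 0.0, 0.0, 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = cohens_kappa(table)
    kappa = float(res.kappa)
    if not np.isfinite(kappa):
        kappa = (po - pe) / (1 - pe)
    se = float(np.sqrt(res.var_kappa)) if np.isfinite(res.var_kappa) else 0.0
    z = stats.norm.ppf((1 + level) / 2)
    return kappa, kappa - z * se, kappa + z * se


def _stable_seed(*parts) -> int:
    return zlib.crc32(":".join(str(p) for p in parts).encode()) & 0x7FFFFFFF


def run_suite(
    datasets: dict[str, dict[str, np.ndarray]],
    labels: dict[str, np.ndarray],
    specs: list[ClassifierSpec] | None = None,
    seed: int = 0,
    standardize_per_subsample: bool = False,
) -> pd.DataFrame:
    """Run every classifier on every dataset and evaluate every subsample.

    `datasets` maps dataset label -> {subsample -> feature matrix}; `labels`
    maps subsample -> sex labels (shared across datasets). Features are
    z-scored with parameters fitted on the training subsample of each dataset
    (leakage-safe default); `standardize_per_subsample=True` instead z-scores
    each subsample within itself. One row per (classifier, dataset, subsample)
    is returned; per-cell seeds are derived stably from `seed`, the dataset,
    and the classifier name.
    """
    specs = specs if specs is not None else default_specs()
    if "train" not in labels:
        raise ClassificationError("labels must include a 'train' subsample")
    rows = []
    for ds_label, tables in datasets.items():
        if standardize_per_subsample:
            z = {sub: standardize(X, X)[0] for sub, X in tables.items()}
        else:
            st = FeatureStandardizer().fit(tables["train"])
            z = {sub: st.transform(X) for sub, X in tables.items()}
        for spec in specs:
            cell_seed = _stable_seed(seed, ds_label, spec.name)
            preds = fit_predict(spec, z["train"], labels["train"], z, seed=cell_seed)
            for sub, pred in preds.items():
                row = {"classifier": spec.name, "dataset": ds_label, "subsample": sub}
                row.update(evaluate(pred, labels[sub]))
                rows.append(row)
    return pd.DataFrame(rows)


def accuracy_profiles(results: pd.DataFrame, subsample: str = "test") -> pd.DataFrame:
    """Pivot a run_suite table into dataset (rows) x classifier (columns) accuracies."""
    sub = results[results["subsample"] == subsample]
    return sub.pivot(index="dataset", columns="classifier", values="accuracy")


@dataclass(frozen=True)
class ClusterSolution:
    """PAM clustering of dataset accuracy profiles."""

    K: int
    labels: dict
    medoids: tuple
    average_silhouette: float
    separation_ratio: float
    degenerate: bool = False


def _pam(D: np.ndarray, k: int) -> np.ndarray:
    """Deterministic PAM (BUILD + SWAP) on a precomputed distance matrix."""
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:  # BUILD: greedy gain maximization, ties to lowest index
        best_gain, best_j = -np.inf, None
        current = D[:, medoids].min(axis=1)
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(current - D[:, j], 0.0).sum()
            if gain > best_gain + 1e-12:
                best_gain, best_j = gain, j
        medoids.append(best_j)
    improved = True
    while improved:  # SWAP: steepest descent on total within-cluster cost
        improved = False
        cost = D[:, medoids].min(axis=1).sum()
        best = (cost, None)
        for mi, m in enumerate(medoids):
            for j in range(n):
                if j in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = j
                c = D[:, trial].min(axis=1).sum()
                if c < best[0] - 1e-12:
                    best = (c, (mi, j))
        if best[1] is not None:
            mi, j = best[1]
            medoids[mi] = j
            improved = True
    medoids = sorted(medoids)
    return np.array(medoids), np.argmin(D[:, medoids], axis=1)


def pam_cluster(profiles: pd.DataFrame, k_range=(2, 3, 4, 5)) -> ClusterSolution:
    """PAM over K in `k_range`; keep the solution maximizing average silhouette.

    Profiles are dataset (rows) x classifier (columns) accuracy vectors;
    distances are Euclidean. With identical profiles the silhouette is
    undefined and a degenerate single-cluster solution is flagged instead.
    `separation_ratio` is the mean between-cluster dissimilarity divided by
    the mean within-cluster dissimilarity.
    """
    if len(profiles) < 3:
        raise ClassificationError("need at least 3 datasets to cluster")
    names = list(profiles.index)
    D = squareform(pdist(profiles.to_numpy(), metric="euclidean"))
    if D.max() == 0:
        return ClusterSolution(
            K=1, labels={nm: 0 for nm in names}, medoids=(names[0],),
            average_silhouette=float("nan"), separation_ratio=float("nan"),
            degenerate=True,
        )
    k_values = [k for k in k_range if 2 <= k <= len(names) - 1]
    if len(k_values) < len(list(k_range)):
        warnings.warn("k_range truncated to the feasible 2..n-1 window", stacklevel=2)
    best = None
    for k in k_values:
        medoid_idx, assign = _pam(D, k)
        sil = float(silhouette_score(D, assign, metric="precomputed"))
        if best is None or sil > best[0] + 1e-12:
            best = (sil, k, medoid_idx, assign)
    sil, k, medoid_idx, assign = best
    within = [D[i, j] for i in range(len(names)) for j in range(i + 1, len(names))
              if assign[i] == assign[j]]
    between = [D[i, j] for i in range(len(names)) for j in range(i + 1, len(names))
               if assign[i] != assign[j]]
    sep = float(np.mean(between) / np.mean(within)) if within else float("inf")
    return ClusterSolution(
        K=k,
        labels={nm: int(c) for nm, c in zip(names, assign)},
        medoids=tuple(names[i] for i in medoid_idx),
        average_silhouette=sil,
        separation_ratio=sep,
    )


def hierarchical_order(profiles: pd.DataFrame):
    """Average-linkage hierarchy of accuracy profiles (Euclidean distances).

    Returns (ordered leaf labels, merge heights, scipy linkage matrix); merge
    heights are non-decreasing, and the leaf order is scipy's deterministic
    dendrogram order.
    """
    if len(profiles) < 2:
        raise ClassificationError("need at least 2 datasets")
    names = list(profiles.index)
    Z = linkage(pdist(profiles.to_numpy(), metric="euclidean"), method="average")
    order = dendrogram(Z, no_plot=True)["leaves"]
    return [names[i] for i in order], Z[:, 2].copy(), Z
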