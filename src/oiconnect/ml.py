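"""Connectivity-feature machine learning: injury classification and
lesion-size regression.

Feature vectors concatenate the upper triangles of the HbO2 and HbR
seed-to-seed Fisher-Z matrices in a canonical seed order (28 pairs per
contrast, 56 features for the default 8-seed atlas).  Classification uses a
soft-margin RBF-kernel SVM with (C, sigma) chosen by grid search on inner
validation folds, evaluated by repeated stratified 10-fold cross-validation.
Regression of the fractional lesion volume uses the Bayesian-regularized
network in :mod:`oiconnect.ann`, with held-out test folds rotated so every
subject is predicted once and metrics pooled over the rotation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .ann import BayesRegNet
from .datatypes import (
    CHROMOPHORES,
    REGION_ORDER,
    ClassifierReport,
    ConnectivityMatrix,
    FeatureVector,
    RegressionReport,
)

__all__ = [
    "canonical_seed_order",
    "build_feature_vector",
    "classification_metrics",
    "default_grid",
    "train_svm",
    "cross_validate_svm",
    "train_ann",
    "evaluate_ann",
    "cross_validate_ann",
]

#: Positive class for all classifier metrics (sensitivity = injured recall).
POSITIVE_LABEL = "injured"
NEGATIVE_LABEL = "control"


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def canonical_seed_order(names) -> list:
    """Stable seed ordering: region (M, C, S, R), then hemisphere (L, R).

    Unknown naming schemes fall back to plain alphabetical order, so the
    feature layout never depends on the order matrices were computed in.
    """
    def key(name: str):
        region, _, hemi = name.partition("_")
        if region in REGION_ORDER and hemi in ("L", "R"):
            return (0, REGION_ORDER.index(region), hemi)
        return (1, name, "")

    return sorted(names, key=key)


def build_feature_vector(
    mats: dict,
    subject_id: str = "",
    label: str | None = None,
    lesion_fraction: float | None = None,
) -> FeatureVector:
    """Concatenate upper-triangle Fisher-Z values of both contrasts.

    ``mats`` maps contrast name to :class:`ConnectivityMatrix`; all matrices
    must share one seed set.  Features are ordered contrast-major
    (HbO2 pairs first), pairs row-major over the canonical seed order, and
    named like ``HbO2:M_L~M_R``.
    """
    contrasts = [c for c in CHROMOPHORES if c in mats] or list(mats)
    seed_sets = {frozenset(mats[c].seed_names) for c in contrasts}
    if len(seed_sets) != 1:
        raise ValueError("connectivity matrices have mismatched seed sets")
    order = canonical_seed_order(list(next(iter(seed_sets))))
    values, names = [], []
    for c in contrasts:
        m: ConnectivityMatrix = mats[c]
        idx = [list(m.seed_names).index(s) for s in order]
        z = m.z[np.ix_(idx, idx)]
        for i in range(len(order)):
            for j in range(i + 1, len(order)):
                values.append(z[i, j])
                names.append(f"{c}:{order[i]}~{order[j]}")
    return FeatureVector(
        values=np.asarray(values),
        names=names,
        subject_id=subject_id,
        label=label,
        lesion_fraction=lesion_fraction,
    )


# ---------------------------------------------------------------------------
# classifier metrics
# ---------------------------------------------------------------------------

def classification_metrics(confusion: np.ndarray) -> dict:
    """Se, Sp, PPV, NPV, Acc from a 2x2 confusion matrix.

    Convention: ``confusion[i, j]`` counts true class i predicted as j with
    index 0 = control (negative) and 1 = injured (positive).  Undefined
    ratios (zero denominator) are returned as NaN.
    """
    c = np.asarray(confusion, dtype=float)
    if c.shape != (2, 2):
        raise ValueError("confusion must be 2x2")
    tn, fp = c[0, 0], c[0, 1]
    fn, tp = c[1, 0], c[1, 1]

    def ratio(num, den):
        return float(num / den) if den > 0 else float("nan")

    return {
        "Se": ratio(tp, tp + fn),
        "Sp": ratio(tn, tn + fp),
        "PPV": ratio(tp, tp + fp),
        "NPV": ratio(tn, tn + fn),
        "Acc": ratio(tp + tn, c.sum()),
    }


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------

def default_grid() -> tuple:
    """Log2-spaced (C, sigma) grid: C in 2^[-5, 15], sigma in 2^[-3, 9]."""
    return (
        tuple(2.0**e for e in range(-5, 16, 2)),
        tuple(2.0**e for e in range(-3, 10, 2)),
    )


@dataclass
class _FittedSVM:
    svc: SVC
    x_mu: np.ndarray
    x_sd: np.ndarray
    C: float
    sigma: float
    grid_scores: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc.predict((np.asarray(X, float) - self.x_mu) / self.x_sd)


def _standardize_fit(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def _labels_to_binary(labels) -> np.ndarray:
    y = np.asarray([1 if l == POSITIVE_LABEL else 0 for l in labels])
    return y


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    grid: tuple | None = None,
    inner_folds: int = 3,
    rng_seed: int = 0,
) -> _FittedSVM:
    """RBF-kernel SVM with (C, sigma) grid search.

    The kernel is exp(-||u - v||^2 / (2 sigma^2)), i.e. gamma = 1/(2 sigma^2).
    Features are z-scored with the training statistics.  Hyperparameters are
    selected by stratified ``inner_folds``-fold validation accuracy over the
    grid (ties resolved toward the first grid entry, so selection is
    deterministic); with a single grid point the search is skipped.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    if min(np.bincount(y.astype(int), minlength=2)) < 2:
        raise ValueError("need at least 2 subjects per class")
    if grid is None:
        grid = default_grid()
    Cs, sigmas = grid
    mu, sd = _standardize_fit(X)

    best = (Cs[0], sigmas[0])
    scores = None
    if len(Cs) * len(sigmas) > 1:
        n_splits = min(inner_folds, int(np.bincount(y.astype(int)).min()))
        skf = StratifiedKFold(n_splits=max(2, n_splits), shuffle=True, random_state=rng_seed % (2**32))
        scores = np.zeros((len(Cs), len(sigmas)))
        for tr, va in skf.split(X, y):
            tmu, tsd = _standardize_fit(X[tr])
            Xtr = (X[tr] - tmu) / tsd
            Xva = (X[va] - tmu) / tsd
            for i, C in enumerate(Cs):
                for j, s in enumerate(sigmas):
                    svc = SVC(C=C, kernel="rbf", gamma=1.0 / (2.0 * s * s))
                    svc.fit(Xtr, y[tr])
                    scores[i, j] += np.mean(svc.predict(Xva) == y[va])
        best_idx = np.unravel_index(np.argmax(scores), scores.shape)
        best = (Cs[best_idx[0]], sigmas[best_idx[1]])

    svc = SVC(C=best[0], kernel="rbf", gamma=1.0 / (2.0 * best[1] ** 2))
    svc.fit((X - mu) / sd, y)
    return _FittedSVM(svc=svc, x_mu=mu, x_sd=sd, C=best[0], sigma=best[1], grid_scores=scores)


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list:
    """Shuffled stratified fold assignment that, unlike sklearn's
    StratifiedKFold, permits more folds than minority-class members (test
    folds may then lack a class, as in small-cohort 10-fold designs)."""
    folds: list = [[] for _ in range(k)]
    start = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[(start + j) % k].append(int(i))
        start += len(idx)
    return [np.array(sorted(f)) for f in folds if f]


def cross_validate_svm(
    features: list,
    k: int = 10,
    repeats: int = 10,
    rng_seed: int = 0,
    grid: tuple | None = None,
    inner_folds: int = 3,
) -> ClassifierReport:
    """Repeated stratified k-fold cross-validation of the injury classifier.

    For every outer training split, hyperparameters are selected on inner
    validation folds of that split only, features are standardized with the
    split's statistics, and the held-out fold is predicted; test subjects
    never influence scaling, selection, or training.  The aggregate confusion
    matrix over all folds and repeats yields the reported Se/Sp/PPV/NPV/Acc;
    per-repeat accuracies are also returned.
    """
    X = np.stack([f.values for f in features])
    y = _labels_to_binary([f.label for f in features])
    if np.unique(y).size < 2:
        raise ValueError("cohort contains a single class")
    n_splits = min(k, len(y))
    confusion = np.zeros((2, 2))
    per_repeat, params = [], []
    all_idx = np.arange(len(y))
    for rep in range(repeats):
        rng = np.random.default_rng(rng_seed + rep)
        rep_conf = np.zeros((2, 2))
        for te in _stratified_folds(y, n_splits, rng):
            tr = np.setdiff1d(all_idx, te)
            if np.unique(y[tr]).size < 2:  # pragma: no cover - stratified guard
                warnings.warn("single-class training split skipped; fold re-randomized")
                continue
            model = train_svm(
                X[tr], y[tr], grid=grid, inner_folds=inner_folds, rng_seed=rng_seed + rep
            )
            pred = model.predict(X[te])
            for yt, yp in zip(y[te], pred):
                rep_conf[int(yt), int(yp)] += 1
            params.append((model.C, model.sigma))
        confusion += rep_conf
        per_repeat.append(float(np.trace(rep_conf) / rep_conf.sum()))
    return ClassifierReport(
        confusion=confusion,
        metrics=classification_metrics(confusion),
        per_repeat_accuracy=per_repeat,
        selected_params=params,
    )


# ---------------------------------------------------------------------------
# ANN regression
# ---------------------------------------------------------------------------

def train_ann(
    X: np.ndarray,
    targets: np.ndarray,
    rng_seed: int = 0,
    n_hidden: int = 20,
    max_epochs: int = 1000,
    mse_goal: float = 1e-5,
) -> BayesRegNet:
    """Train the Bayesian-regularized lesion-size regressor."""
    X = np.asarray(X, dtype=float)
    if len(X) < 5:
        raise ValueError("need at least 5 training subjects")
    net = BayesRegNet(
        n_hidden=n_hidden, max_epochs=max_epochs, mse_goal=mse_goal, rng_seed=rng_seed
    )
    return net.fit(X, np.asarray(targets, dtype=float))


def evaluate_ann(model: BayesRegNet, X_test, y_test) -> RegressionReport:
    """Correlation and RMSEP of predictions on a held-out set.

    RMSEP is reported in the units of the targets.  With zero-variance
    measured targets the correlation is undefined and reported as None.
    """
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test, dtype=float).ravel()
    if y_test.size == 0:
        raise ValueError("test set is empty")
    pred = model.predict(X_test)
    return _regression_report(pred, y_test)


def _regression_report(pred: np.ndarray, y: np.ndarray) -> RegressionReport:
    rmsep = float(np.sqrt(np.mean((pred - y) ** 2)))
    if y.size >= 3 and y.std() > 0 and pred.std() > 0:
        r, p = stats.pearsonr(pred, y)
        r, p = float(r), float(p)
    elif y.std() == 0:
        r, p = None, None
    else:
        r, p = None, None
    return RegressionReport(r=r, rmsep=rmsep, predictions=pred, targets=y, p_value=p)


def cross_validate_ann(
    features: list,
    k: int | None = None,
    rng_seed: int = 0,
    n_hidden: int = 20,
    max_epochs: int = 1000,
    mse_goal: float = 1e-5,
) -> RegressionReport:
    """Rotate held-out test folds so every subject is predicted once.

    ``k`` defaults to leave-one-out for cohorts of up to 13 subjects
    (matching ~15% test folds at the emulated study size) and 10 folds
    otherwise.  Predictions are pooled across the rotation and a single
    r / RMSEP pair is computed on the pooled set.
    """
    X = np.stack([f.values for f in features])
    y = np.asarray([f.lesion_fraction for f in features], dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("all subjects need a lesion_fraction target")
    n = len(y)
    if k is None:
        k = n if n <= 13 else 10
    k = min(k, n)
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    pred = np.empty(n)
    for fold in folds:
        tr = np.setdiff1d(order, fold)
        net = train_ann(
            X[tr], y[tr], rng_seed=rng_seed, n_hidden=n_hidden,
            max_epochs=max_epochs, mse_goal=mse_goal,
        )
        pred[fold] = net.predict(X[fold])
    return _regression_report(pred, y)
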