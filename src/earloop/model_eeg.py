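"""PCA + logistic LASSO classifier of high/low-pleasure EEG epochs.

Pipeline: drop flagged epochs -> PCA (up to 150 components) -> standardize
component scores -> balance classes by subsampling the larger one -> 90/10
stratified split -> 20-fold CV on the training part to pick the L1 weight ->
final fit, confusion/ROC/AUC validation, label-shuffle permutation test, and
back-projection of the coefficients into frequency x derivation space.

The printed loss resembles a squared-error form, but the model is described
as logistic LASSO regression; the implementation minimizes the standard
L1-penalized binomial deviance

    min over (g0, g) of  (1/M) * sum_j logloss_j + lam * ||g||_1
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .eeg_preprocessing import EpochFeatureSet
from .errors import ParameterError, SchemaError, StateError

BANDS = {"theta": (4.0, 7.0), "alpha": (8.0, 13.0), "beta": (14.0, 30.0), "gamma": (31.0, 40.0)}
PC_SD_EPS = 1e-12


@dataclass
class PCScaler:
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, scores: np.ndarray) -> np.ndarray:
        return (scores - self.mean) / np.maximum(self.sd, PC_SD_EPS)


@dataclass
class BalancedTrainingSet:
    scores: np.ndarray  # (m, K) standardized PC scores, classes balanced
    labels: np.ndarray  # (m,) bool
    pca_basis: np.ndarray  # (219, K) loadings (columns = components)
    pca_mean: np.ndarray  # (219,)
    pc_scaler: PCScaler


@dataclass
class EEGClassifier:
    pca_basis: np.ndarray | None = None
    pca_mean: np.ndarray | None = None
    pc_scaler: PCScaler | None = None
    gamma0: float = 0.0
    gamma: np.ndarray | None = None
    lam: float = 0.0
    split_seed: int = 0
    train_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None
    validation: dict | None = None
    perm_p: float | None = None
    fitted: bool = False

    def decode_scores(self, scores_std: np.ndarray) -> np.ndarray:
        """Probability of the high-pleasure class from standardized PC scores."""
        if not self.fitted:
            raise StateError("classifier is not fitted")
        scores_std = np.atleast_2d(scores_std)
        if scores_std.shape[1] != self.gamma.shape[0]:
            raise SchemaError("PC-score width does not match coefficients")
        logit = self.gamma0 + scores_std @ self.gamma
        # clip so the decoded probability stays in the open interval
        return np.clip(expit(logit), 1e-9, 1.0 - 1e-9)

    def decode_features(self, features_std: np.ndarray) -> np.ndarray:
        """Probability from standardized 219-dim spectral features."""
        if self.pca_basis is None:
            raise StateError("classifier lacks a PCA basis")
        features_std = np.atleast_2d(features_std)
        scores = (features_std - self.pca_mean) @ self.pca_basis
        return self.decode_scores(self.pc_scaler.transform(scores))

    def to_dict(self) -> dict:
        return {
            "pca_basis": self.pca_basis.tolist(),
            "pca_mean": self.pca_mean.tolist(),
            "pc_mean": self.pc_scaler.mean.tolist(),
            "pc_sd": self.pc_scaler.sd.tolist(),
            "gamma0": self.gamma0,
            "gamma": self.gamma.tolist(),
            "lam": self.lam,
            "split_seed": self.split_seed,
            "validation": self.validation,
            "perm_p": self.perm_p,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "EEGClassifier":
        return cls(
            pca_basis=np.array(doc["pca_basis"], dtype=float),
            pca_mean=np.array(doc["pca_mean"], dtype=float),
            pc_scaler=PCScaler(
                mean=np.array(doc["pc_mean"], dtype=float),
                sd=np.array(doc["pc_sd"], dtype=float),
            ),
            gamma0=float(doc["gamma0"]),
            gamma=np.array(doc["gamma"], dtype=float),
            lam=float(doc["lam"]),
            split_seed=int(doc["split_seed"]),
            validation=doc.get("validation"),
            perm_p=doc.get("perm_p"),
            fitted=True,
        )


@dataclass
class WeightMap:
    weights: np.ndarray  # (73 bins, 3 derivations)
    band_means: dict[str, float]
    bins: np.ndarray


# ---------------------------------------------------------------------------
# Training-set construction
# ---------------------------------------------------------------------------


def build_training_set(
    featset: EpochFeatureSet, max_pcs: int = 150, seed: int = 0
) -> BalancedTrainingSet:
    """Non-flagged epochs -> standardized, class-balanced PC scores."""
    if featset.labels is None:
        raise ParameterError("feature set carries no class labels")
    keep = ~featset.flags
    X = featset.features[keep]
    y = featset.labels[keep]
    if not y.any() or y.all():
        raise ParameterError("both classes must be present among non-flagged epochs")
    n_comp = min(max_pcs, X.shape[0], X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    basis = pca.components_.T  # (219, K)
    scaler = PCScaler(mean=scores.mean(axis=0), sd=scores.std(axis=0))
    scores_std = scaler.transform(scores)

    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    m = min(len(pos), len(neg))
    pos = rng.choice(pos, size=m, replace=False) if len(pos) > m else pos
    neg = rng.choice(neg, size=m, replace=False) if len(neg) > m else neg
    idx = np.sort(np.concatenate([pos, neg]))
    return BalancedTrainingSet(
        scores=scores_std[idx],
        labels=y[idx],
        pca_basis=basis,
        pca_mean=np.asarray(pca.mean_, dtype=float),
        pc_scaler=scaler,
    )


# ---------------------------------------------------------------------------
# Logistic LASSO fitting
# ---------------------------------------------------------------------------


def _logloss(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _solve_logistic_lasso(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    """Minimize mean binomial deviance + lam * ||gamma||_1 (liblinear)."""
    m = X.shape[0]
    C = 1.0 / max(lam * m, 1e-12)
    model = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, tol=1e-7
    )
    model.fit(X, y.astype(int))
    return float(model.intercept_[0]), np.asarray(model.coef_[0], dtype=float)


def default_logistic_grid(
    X: np.ndarray, y: np.ndarray, n_values: int = 100, min_ratio: float = 1e-4
) -> np.ndarray:
    """Grid descending from the lam that zeroes all coefficients."""
    m = X.shape[0]
    ybar = y.mean()
    lam_max = np.max(np.abs(X.T @ (y - ybar))) / m
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * min_ratio, n_values)


def fit_eeg_classifier(
    balanced: BalancedTrainingSet,
    cv_folds: int = 20,
    lambda_grid: np.ndarray | None = None,
    test_frac: float = 0.1,
    seed: int = 0,
) -> EEGClassifier:
    """90/10 split, CV-selected L1 weight on the training part, final fit.

    The holdout never enters fitting or lambda selection. Splits and CV
    folds are stratified so no fold is single-class.
    """
    X, y = balanced.scores, balanced.labels.astype(float)
    m = X.shape[0]
    if m < 20:
        raise ParameterError(f"need >= 20 balanced epochs, got {m}")
    idx = np.arange(m)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_frac, random_state=seed, stratify=y
    )
    Xtr, ytr = X[train_idx], y[train_idx]
    if lambda_grid is None:
        lambda_grid = default_logistic_grid(Xtr, ytr)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    order = np.argsort(lambda_grid)[::-1]
    lambda_grid = lambda_grid[order]

    if len(lambda_grid) > 1:
        folds = int(min(cv_folds, np.bincount(ytr.astype(int)).min()))
        folds = max(folds, 2)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        cv_err = np.zeros(len(lambda_grid))
        for tr, te in skf.split(Xtr, ytr):
            for i, lam in enumerate(lambda_grid):
                g0, g = _solve_logistic_lasso(Xtr[tr], ytr[tr], lam)
                p = 1.0 / (1.0 + np.exp(-(g0 + Xtr[te] @ g)))
                cv_err[i] += _logloss(ytr[te], p) * len(te)
        cv_err /= len(ytr)
        lam = float(lambda_grid[int(np.argmin(cv_err))])
    else:
        lam = float(lambda_grid[0])

    gamma0, gamma = _solve_logistic_lasso(Xtr, ytr, lam)
    model = EEGClassifier(
        pca_basis=balanced.pca_basis,
        pca_mean=balanced.pca_mean,
        pc_scaler=balanced.pc_scaler,
        gamma0=gamma0,
        gamma=gamma,
        lam=lam,
        split_seed=seed,
        train_idx=train_idx,
        test_idx=test_idx,
        fitted=True,
    )
    model.validation = evaluate_classifier(model, balanced)
    return model


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def auc_trapezoid(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the trapezoid rule on the threshold-swept ROC curve."""
    fpr, tpr, _ = roc_curve(y_true.astype(int), scores)
    return float(np.trapezoid(tpr, fpr))


def confusion_at_half(y_true: np.ndarray, p: np.ndarray) -> dict[str, int]:
    pred = p >= 0.5
    y_true = y_true.astype(bool)
    return {
        "tp": int(np.sum(pred & y_true)),
        "fp": int(np.sum(pred & ~y_true)),
        "fn": int(np.sum(~pred & y_true)),
        "tn": int(np.sum(~pred & ~y_true)),
    }


def evaluate_classifier(model: EEGClassifier, balanced: BalancedTrainingSet) -> dict:
    """Accuracy/AUC/confusion for the stored train and test partitions."""
    if not model.fitted:
        raise StateError("classifier is not fitted")
    if model.test_idx is None or len(model.test_idx) == 0:
        raise StateError("no holdout partition stored")
    out: dict = {}
    for part, idx in (("train", model.train_idx), ("test", model.test_idx)):
        p = model.decode_scores(balanced.scores[idx])
        y = balanced.labels[idx]
        conf = confusion_at_half(y, p)
        acc = (conf["tp"] + conf["tn"]) / len(idx)
        out[f"{part}_acc"] = acc
        out[f"{part}_auc"] = auc_trapezoid(y, p)
        out[f"{part}_confusion"] = conf
    return out


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------


def permutation_test(
    balanced: BalancedTrainingSet,
    model: EEGClassifier,
    n_perm: int = 1000,
    seed: int = 0,
    reselect_lambda: bool = False,
    cv_folds: int = 20,
) -> tuple[float, np.ndarray]:
    """Label-shuffle null distribution of the test AUC.

    Labels are shuffled, the classifier refit on the SAME stored 90/10 split,
    and the test AUC recorded; p = (# permuted AUC > observed) / n_perm
    (strict inequality, as published). By default each permutation refits at
    the observed lambda; ``reselect_lambda=True`` reruns the CV selection too.
    """
    if n_perm < 1:
        raise ParameterError(f"n_perm must be >= 1, got {n_perm}")
    if not model.fitted:
        raise StateError("observed classifier must be fitted first")
    observed = model.validation["test_auc"]
    rng = np.random.default_rng(seed)
    X, y = balanced.scores, balanced.labels.astype(float)
    tr, te = model.train_idx, model.test_idx
    null = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        if yp[tr].min() == yp[tr].max():  # degenerate shuffle: resample
            null[b] = 0.5
            continue
        if reselect_lambda:
            grid = default_logistic_grid(X[tr], yp[tr], n_values=20)
            folds = int(min(cv_folds, np.bincount(yp[tr].astype(int)).min()))
            folds = max(folds, 2)
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            cv_err = np.zeros(len(grid))
            for tr2, te2 in skf.split(X[tr], yp[tr]):
                for i, lam in enumerate(grid):
                    g0, g = _solve_logistic_lasso(X[tr][tr2], yp[tr][tr2], lam)
                    p = 1.0 / (1.0 + np.exp(-(g0 + X[tr][te2] @ g)))
                    cv_err[i] += _logloss(yp[tr][te2], p) * len(te2)
            lam = float(grid[int(np.argmin(cv_err))])
        else:
            lam = model.lam
        g0, g = _solve_logistic_lasso(X[tr], yp[tr], lam)
        scores = g0 + X[te] @ g
        if yp[te].min() == yp[te].max():
            null[b] = 0.5
        else:
            null[b] = auc_trapezoid(yp[te], scores)
    p_value = float(np.sum(null > observed) / n_perm)
    return p_value, null


# ---------------------------------------------------------------------------
# Weight back-projection
# ---------------------------------------------------------------------------


def backproject_weights(
    model: EEGClassifier,
    bins: np.ndarray | None = None,
    convention: str = "multiply",
    band_abs: bool = True,
) -> WeightMap:
    """Map component coefficients back to frequency x derivation space.

    ``convention="multiply"`` rescales each coefficient by its component SD
    before applying the loadings (the published wording);
    ``convention="divide"`` instead divides, which yields the literal linear
    weight of the standardized-feature model. Band summaries average the
    (by default absolute) weights over each band's bins and all derivations.
    """
    if model.pca_basis is None:
        raise StateError("classifier lacks a stored PCA basis")
    if convention == "multiply":
        rescaled = model.gamma * model.pc_scaler.sd
    elif convention == "divide":
        rescaled = model.gamma / np.maximum(model.pc_scaler.sd, PC_SD_EPS)
    else:
        raise ParameterError(f"unknown convention {convention!r}")
    w = model.pca_basis @ rescaled  # (219,)
    n_bins = w.shape[0] // 3
    weights = w.reshape(3, n_bins).T  # (73, 3): columns = left, right, difference
    if bins is None:
        bins = 4.0 + 0.5 * np.arange(n_bins)
    vals = np.abs(weights) if band_abs else weights
    band_means = {}
    for name, (lo, hi) in BANDS.items():
        sel = (bins >= lo) & (bins <= hi)
        band_means[name] = float(vals[sel].mean())
    return WeightMap(weights=weights, band_means=band_means, bins=np.asarray(bins))
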