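"""Proficiency classification: z-score, PCA, component selection, linear SVM.

The protocol mirrors the analysis design: features are z-scored and PCA is
fitted on the whole dataset before cross-validation (the default,
``fold_safe=False``), then a linear soft-margin SVM (C = 1.0) is evaluated
with stratified 10-fold cross-validation and per-fold F1 with "expert" as
the positive class.  Fitting the scaler and PCA on the full data leaks
distributional information across folds; ``fold_safe=True`` refits both
inside each training fold for a leakage-free estimate.

Three feature sets are compared: Basic (48 per-hand aggregates), DBH (16
between-hand aggregates), and their union (64).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import BASIC_COLUMNS, DBH_COLUMNS, FEATURE_NAMES

FEATURE_SETS: dict[str, list[str]] = {
    "basic": BASIC_COLUMNS,
    "dbh": DBH_COLUMNS,
    "basic_plus_dbh": FEATURE_NAMES,
}

POSITIVE_CLASS = "expert"


@dataclass
class ClassificationReport:
    feature_set: str
    mode: str
    n_components: int
    mean_f1: float
    std_f1: float
    fold_f1: list[float] = field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "mode": self.mode,
            "n_components": self.n_components,
            "mean_f1": self.mean_f1,
            "std_f1": self.std_f1,
            "fold_f1": list(self.fold_f1),
            "seed": self.seed,
        }


def zscore_fit_apply(matrix: np.ndarray) -> np.ndarray:
    """Standardize columns to mean 0 and sample SD 1 (ddof=1).

    Zero-variance columns are passed through as zeros with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance column(s) set to zeros")
        sd = np.where(flat, 1.0, sd)
    return (X - mean) / sd


def pca_fit(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal components (rows) and explained-variance ratios.

    Components carry a deterministic sign: the loading of largest
    magnitude is made positive.
    """
    X = np.asarray(matrix, dtype=float)
    pca = PCA()
    pca.fit(X)
    comps = pca.components_.copy()
    for i, c in enumerate(comps):
        if c[np.argmax(np.abs(c))] < 0:
            comps[i] = -c
    return comps, pca.explained_variance_ratio_


def _project(X: np.ndarray, k: int) -> np.ndarray:
    comps, _ = pca_fit(X)
    return (X - X.mean(axis=0)) @ comps[:k].T


def svm_cv(
    X: np.ndarray,
    y,
    folds: int = 10,
    C: float = 1.0,
    seed: int = 0,
    feature_set: str = "",
    mode: str = "",
) -> ClassificationReport:
    """Linear SVM with stratified k-fold CV; per-fold F1 with 'expert'
    positive (falls back to the lexicographically larger label if no
    'expert' label is present, as in toy binary problems)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("binary labels required")
    if len(y) < folds:
        raise ValueError("need at least one sample per fold")
    pos = POSITIVE_CLASS if POSITIVE_CLASS in classes else classes.max()

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for train, test in skf.split(X, y):
        if len(np.unique(y[train])) < 2:
            raise ValueError("a fold lost one of the classes (stratification error)")
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        scores.append(f1_score(y[test], pred, pos_label=pos, zero_division=0))
    scores = np.asarray(scores, dtype=float)
    return ClassificationReport(
        feature_set, mode, X.shape[1],
        float(scores.mean()), float(scores.std(ddof=0)), scores.tolist(), seed,
    )


def select_components(
    ratios: np.ndarray,
    mode: str,
    k: int | None = None,
    scorer=None,
) -> int:
    """Number of principal components to retain.

    cumvar95/cumvar99: smallest k whose cumulative explained-variance
    ratio reaches the threshold.  best: argmax over k of the scorer's
    mean F1 (smallest k on ties).  fixed: the given k.
    """
    ratios = np.asarray(ratios, dtype=float)
    if mode in ("cumvar95", "cumvar99"):
        threshold = 0.95 if mode == "cumvar95" else 0.99
        cum = np.cumsum(ratios)
        idx = np.searchsorted(cum, threshold - 1e-12)
        return int(min(idx + 1, ratios.size))
    if mode == "best":
        if scorer is None:
            raise ValueError("mode 'best' needs a scorer")
        best_k, best_score = 1, -np.inf
        for kk in range(1, ratios.size + 1):
            s = scorer(kk)
            if s > best_score + 1e-12:
                best_k, best_score = kk, s
        return best_k
    if mode == "fixed":
        if k is None:
            raise ValueError("mode 'fixed' needs k")
        return int(k)
    raise ValueError(f"unknown selection mode {mode!r}")


def run_pipeline(
    X: np.ndarray,
    y,
    mode: str,
    k: int | None = None,
    folds: int = 10,
    C: float = 1.0,
    seed: int = 0,
    fold_safe: bool = False,
    feature_set: str = "",
) -> ClassificationReport:
    """z-score -> PCA -> component selection -> linear SVM CV."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if fold_safe:
        return _run_fold_safe(X, y, mode, k, folds, C, seed, feature_set)
    Z = zscore_fit_apply(X)
    comps, ratios = pca_fit(Z)
    scorer = None
    if mode == "best":
        def scorer(kk: int) -> float:
            return svm_cv(_project(Z, kk), y, folds, C, seed).mean_f1
    n_comp = select_components(ratios, mode, k, scorer)
    n_comp = min(n_comp, comps.shape[0])
    proj = (Z - Z.mean(axis=0)) @ comps[:n_comp].T
    report = svm_cv(proj, y, folds, C, seed, feature_set, mode)
    report.n_components = n_comp
    return report


def _run_fold_safe(X, y, mode, k, folds, C, seed, feature_set):
    """Scaler and PCA refitted inside every training fold."""
    if mode == "best":
        raise ValueError("mode 'best' is not supported with fold_safe")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    classes = np.unique(y)
    pos = POSITIVE_CLASS if POSITIVE_CLASS in classes else classes.max()
    scores, n_used = [], 0
    for train, test in skf.split(X, y):
        mean = X[train].mean(axis=0)
        sd = X[train].std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
        Ztr, Zte = (X[train] - mean) / sd, (X[test] - mean) / sd
        comps, ratios = pca_fit(Ztr)
        n_comp = min(select_components(ratios, mode, k), comps.shape[0])
        n_used = n_comp
        center = Ztr.mean(axis=0)
        clf = SVC(kernel="linear", C=C)
        clf.fit((Ztr - center) @ comps[:n_comp].T, y[train])
        pred = clf.predict((Zte - center) @ comps[:n_comp].T)
        scores.append(f1_score(y[test], pred, pos_label=pos, zero_division=0))
    scores = np.asarray(scores, dtype=float)
    return ClassificationReport(
        feature_set, mode + "+fold_safe", n_used,
        float(scores.mean()), float(scores.std(ddof=0)), scores.tolist(), seed,
    )


def run_comparison(
    feature_table: pd.DataFrame,
    modes: list[tuple[str, int | None]] | None = None,
    folds: int = 10,
    C: float = 1.0,
    seed: int = 0,
    fold_safe: bool = False,
) -> list[ClassificationReport]:
    """Evaluate every feature set under every selection mode.

    ``feature_table`` holds one row per performer (the 'all'-excerpts
    aggregate), the 64 feature columns, and a ``group`` column.  Fixed-k
    modes whose k exceeds a set's feature count (k > 16 for DBH-only) are
    skipped, since PCA cannot produce that many components there.
    """
    if modes is None:
        modes = [("cumvar95", None), ("cumvar99", None), ("best", None),
                 ("fixed", 10), ("fixed", 20), ("fixed", 40)]
    y = feature_table["group"].to_numpy()
    reports = []
    for name, cols in FEATURE_SETS.items():
        X = feature_table[cols].to_numpy(dtype=float)
        for mode, k in modes:
            if mode == "fixed" and k is not None and k > len(cols):
                continue
            label = mode if k is None else f"{mode}{k}"
            reports.append(
                run_pipeline(X, y, mode, k, folds, C, seed, fold_safe, name)
            )
            reports[-1].mode = label + ("+fold_safe" if fold_safe else "")
    return reports
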