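"""Linear discriminant classification of notes with balanced cross-validation.

The discriminant functions are the eigenvectors of the ratio of the
between-class to within-class covariance matrices (the MANOVA eigen-problem)
computed on z-scored features, scaled so the within-class variance along
each function is 1. Sequential Wilks'-lambda tests (Bartlett's chi-square
approximation) decide how many functions are significant; classification is
by nearest class centroid in the space of the significant functions.

Cross-validation follows the balanced scheme of the study design: per
iteration and per animal, 19 randomly selected notes train the functions and
1 held-out note is classified; percent correct and its standard error are
accumulated over (by default) 100 random selections, and the pooled
guess-vs-truth counts give the confusion matrix from which percent correct
per class and the mutual information between guesses and truth are derived.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import Generator, default_rng
from scipy import linalg
from scipy.stats import chi2

from .features import FEATURE_COLUMNS

__all__ = [
    "DiscriminantModel",
    "ConfusionMatrix",
    "CrossValidationResult",
    "MutualInformation",
    "zscore_table",
    "balance_notes",
    "fit_lda",
    "predict_lda",
    "cross_validate",
    "chance_level",
    "mutual_information",
]

_RIDGE_SCALE = 1e-6


def zscore_table(
    table: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Centre and normalise feature columns to z-scores.

    Returns (z-scored table, centring means, scaling SDs); the stored
    parameters let test rows be transformed with *training* statistics.
    Raises on zero-variance columns, naming them.
    """
    cols = columns if columns is not None else [c for c in FEATURE_COLUMNS if c in table]
    center = table[cols].mean()
    scale = table[cols].std(ddof=1)
    dead = scale[scale == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance column(s): {dead}")
    out = table.copy()
    out[cols] = (table[cols] - center) / scale
    return out, center, scale


def balance_notes(
    features: pd.DataFrame,
    n_per_animal: int = 20,
    seed: int | Generator = 0,
    group_col: str = "animal_id",
) -> pd.DataFrame:
    """Subsample exactly ``n_per_animal`` notes per animal, without
    replacement. Errors list every animal with too few notes."""
    rng = seed if isinstance(seed, Generator) else default_rng(seed)
    sizes = features.groupby(group_col).size()
    short = sizes[sizes < n_per_animal]
    if len(short):
        raise ValueError(
            "animals with fewer than "
            f"{n_per_animal} notes: {dict(short)}"
        )
    picks = []
    for _, grp in features.groupby(group_col, sort=True):
        picks.append(grp.iloc[rng.choice(len(grp), n_per_animal, replace=False)])
    return pd.concat(picks, ignore_index=True)


# ---------------------------------------------------------------------------
# core eigen-decomposition


def _lda_eig(X: np.ndarray, codes: np.ndarray, k: int):
    """Eigen-solve S_W^-1 S_B; returns (eigenvalues desc, loadings, means).

    Loadings are scaled so each function has unit within-class variance.
    A small ridge stabilises a singular within-class scatter.
    """
    n, p = X.shape
    means = np.stack([X[codes == c].mean(axis=0) for c in range(k)])
    counts = np.bincount(codes, minlength=k).astype(float)
    Xc = X - means[codes]
    S_W = Xc.T @ Xc
    gm = X.mean(axis=0)
    D = means - gm
    S_B = (counts[:, None] * D).T @ D
    try:
        evals, evecs = linalg.eigh(S_B, S_W, check_finite=False)
    except linalg.LinAlgError:
        S_W = S_W + _RIDGE_SCALE * (np.trace(S_W) / p) * np.eye(p)
        evals, evecs = linalg.eigh(S_B, S_W, check_finite=False)
    order = np.argsort(evals)[::-1]
    m = min(k - 1, p)
    evals = np.clip(evals[order][:m], 0.0, None)
    # eigh normalises v' S_W v = I; rescale to unit within-class *variance*
    loadings = evecs[:, order][:, :m] * np.sqrt(max(n - k, 1))
    return evals, loadings, means


def _wilks_pvalues(evals: np.ndarray, n: int, p: int, k: int) -> np.ndarray:
    """Sequential Wilks'-lambda p-values (Bartlett chi-square)."""
    pvals = np.empty(len(evals))
    for s in range(len(evals)):
        lam = float(np.prod(1.0 / (1.0 + evals[s:])))
        stat = -(n - 1 - (p + k) / 2.0) * np.log(max(lam, 1e-300))
        df = (p - s) * (k - 1 - s)
        pvals[s] = chi2.sf(stat, df) if df > 0 else 1.0
    return pvals


@dataclass
class DiscriminantModel:
    classes: list
    loadings: np.ndarray  # (p, m) on z-scored features
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    wilks_p: np.ndarray
    n_significant: int
    centroids: np.ndarray  # (k, m) class centroids in discriminant space
    center: np.ndarray
    scale: np.ndarray
    feature_names: list[str]

    def report(self) -> dict:
        """Loadings / %variance / Wilks p per function, JSON-serialisable."""
        return {
            "classes": list(map(str, self.classes)),
            "n_significant": int(self.n_significant),
            "functions": [
                {
                    "percent_variance": float(self.percent_variance[i]),
                    "wilks_p": float(self.wilks_p[i]),
                    "loadings": {
                        name: float(self.loadings[j, i])
                        for j, name in enumerate(self.feature_names)
                    },
                }
                for i in range(self.loadings.shape[1])
            ],
        }


def fit_lda(
    train: pd.DataFrame,
    labels: str | pd.Series | np.ndarray,
    feature_columns: list[str] | None = None,
    alpha: float = 0.05,
) -> DiscriminantModel:
    """Fit the discriminant functions on (internally z-scored) features.

    ``labels`` is a column name or an array aligned with ``train``. The
    number of significant functions is the length of the initial run of
    sequential Wilks tests with p < alpha.
    """
    cols = feature_columns or [c for c in FEATURE_COLUMNS if c in train]
    y = train[labels].to_numpy() if isinstance(labels, str) else np.asarray(labels)
    X = train[cols].to_numpy(dtype=float)
    classes, codes = np.unique(y, return_inverse=True)
    k = len(classes)
    if k < 2:
        raise ValueError("need >= 2 classes")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    if np.any(scale == 0):
        dead = [cols[i] for i in np.flatnonzero(scale == 0)]
        raise ValueError(f"zero-variance column(s): {dead}")
    Z = (X - center) / scale
    evals, loadings, _ = _lda_eig(Z, codes, k)
    pvals = _wilks_pvalues(evals, len(Z), len(cols), k)
    n_sig = 0
    while n_sig < len(pvals) and pvals[n_sig] < alpha:
        n_sig += 1
    total = evals.sum()
    pct = 100.0 * evals / total if total > 0 else np.zeros_like(evals)
    means_z = np.stack([Z[codes == c].mean(axis=0) for c in range(k)])
    centroids = means_z @ loadings
    return DiscriminantModel(
        classes=list(classes),
        loadings=loadings,
        eigenvalues=evals,
        percent_variance=pct,
        wilks_p=pvals,
        n_significant=n_sig,
        centroids=centroids,
        center=center,
        scale=scale,
        feature_names=cols,
    )


def predict_lda(model: DiscriminantModel, table: pd.DataFrame) -> np.ndarray:
    """Nearest-centroid classification using the significant functions
    (all functions when none is significant); ties break to the lowest
    class index."""
    X = table[model.feature_names].to_numpy(dtype=float)
    Z = (X - model.center) / model.scale
    m = model.n_significant if model.n_significant > 0 else model.loadings.shape[1]
    proj = Z @ model.loadings[:, :m]
    d2 = ((proj[:, None, :] - model.centroids[None, :, :m]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)
    return np.asarray(model.classes)[idx]


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class ConfusionMatrix:
    """Guess-vs-truth counts n(i, j): row i = guessed class, column j = true
    class. The truth marginal p(j) is uniform by construction of the
    balanced test sets."""

    classes: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over the classes")

    @property
    def p_conditional(self) -> np.ndarray:
        """p(guess i | truth j); columns sum to 1."""
        colsum = self.counts.sum(axis=0)
        if np.any(colsum == 0):
            raise ValueError("class with zero test counts")
        return self.counts / colsum

    @property
    def p_joint(self) -> np.ndarray:
        k = len(self.classes)
        return self.p_conditional / k

    @property
    def p_guess(self) -> np.ndarray:
        return self.p_joint.sum(axis=1)

    @property
    def p_truth(self) -> np.ndarray:
        k = len(self.classes)
        return np.full(k, 1.0 / k)

    @property
    def percent_correct(self) -> float:
        return 100.0 * float(np.trace(self.p_joint))

    @property
    def per_class_percent(self) -> np.ndarray:
        return 100.0 * np.diag(self.p_conditional)


@dataclass
class CrossValidationResult:
    percent_correct: float
    standard_error: float
    per_class_percent: np.ndarray
    confusion: ConfusionMatrix
    per_iteration: np.ndarray
    cumulative: np.ndarray
    n_iterations: int
    seed: int | None


def _iteration_split(
    by_animal: list[np.ndarray], n_train: int, n_test: int, rng: Generator
):
    train_idx, test_idx = [], []
    for idx in by_animal:
        pick = rng.permutation(idx)[: n_train + n_test]
        train_idx.append(pick[:n_train])
        test_idx.append(pick[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def _cv_core(
    X: np.ndarray,
    class_codes: np.ndarray,
    k: int,
    by_animal: list[np.ndarray],
    n_train: int,
    n_test: int,
    n_iter: int,
    rng: Generator,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Array-level CV loop; returns (confusion counts, per-iteration pc)."""
    counts = np.zeros((k, k))
    per_iter = np.empty(n_iter)
    for it in range(n_iter):
        tr, te = _iteration_split(by_animal, n_train, n_test, rng)
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance feature in a training split")
        Ztr = (X[tr] - mu) / sd
        Zte = (X[te] - mu) / sd
        ytr, yte = class_codes[tr], class_codes[te]
        evals, loadings, means = _lda_eig(Ztr, ytr, k)
        pvals = _wilks_pvalues(evals, len(Ztr), X.shape[1], k)
        m = 0
        while m < len(pvals) and pvals[m] < alpha:
            m += 1
        if m == 0:
            m = loadings.shape[1]
        A = loadings[:, :m]
        cent = means @ A
        proj = Zte @ A
        d2 = ((proj[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
        pred = np.argmin(d2, axis=1)
        np.add.at(counts, (pred, yte), 1.0)
        per_iter[it] = 100.0 * float(np.mean(pred == yte))
    return counts, per_iter


def cross_validate(
    features: pd.DataFrame,
    labels: str | pd.Series | np.ndarray = "animal_id",
    animal_col: str = "animal_id",
    n_train: int = 19,
    n_test: int = 1,
    n_iter: int = 100,
    seed: int | Generator = 0,
    feature_columns: list[str] | None = None,
    alpha: float = 0.05,
) -> CrossValidationResult:
    """Balanced cross-validated classification.

    Sampling is always per animal (``n_train`` training + ``n_test`` test
    notes each iteration) while ``labels`` defines the classes -- the animal
    itself for identity analyses, or a per-note group label (sex, dominance,
    treatment) for group analyses.
    """
    rng = seed if isinstance(seed, Generator) else default_rng(seed)
    cols = feature_columns or [c for c in FEATURE_COLUMNS if c in features]
    y = features[labels].to_numpy() if isinstance(labels, str) else np.asarray(labels)
    classes, codes = np.unique(y, return_inverse=True)
    animals = features[animal_col].to_numpy()
    by_animal = [np.flatnonzero(animals == a) for a in np.unique(animals)]
    need = n_train + n_test
    short = [i for i, idx in enumerate(by_animal) if len(idx) < need]
    if short:
        bad = np.unique(animals)[short]
        raise ValueError(f"animals with fewer than {need} notes: {list(bad)}")
    X = features[cols].to_numpy(dtype=float)
    counts, per_iter = _cv_core(
        X, codes, len(classes), by_animal, n_train, n_test, n_iter, rng, alpha
    )
    confusion = ConfusionMatrix(list(classes), counts)
    cumulative = np.cumsum(per_iter) / np.arange(1, n_iter + 1)
    se = float(np.std(per_iter, ddof=1) / np.sqrt(n_iter)) if n_iter > 1 else 0.0
    return CrossValidationResult(
        percent_correct=float(np.mean(per_iter)),
        standard_error=se,
        per_class_percent=confusion.per_class_percent,
        confusion=confusion,
        per_iteration=per_iter,
        cumulative=cumulative,
        n_iterations=n_iter,
        seed=None if isinstance(seed, Generator) else int(seed),
    )


def chance_level(classes: int | list) -> float:
    """Percent correct of uniform guessing over k equal-frequency classes."""
    k = classes if isinstance(classes, (int, np.integer)) else len(classes)
    if k < 2:
        raise ValueError("need >= 2 classes")
    return 100.0 / k


# ---------------------------------------------------------------------------
# mutual information


@dataclass
class MutualInformation:
    bits: float
    bits_uncorrected: float
    bias_corrected: bool
    bits_per_second: float | None = None


def mutual_information(
    confusion: ConfusionMatrix | np.ndarray,
    bias_correction: bool | None = None,
    mean_duration_s: float | None = None,
) -> MutualInformation:
    """Mutual information (bits) between classifier guesses and true classes.

    MI = sum_ij p(i,j) log2[p(i,j) / (p(i) p(j))], with p(j) uniform and
    0 log 0 = 0. The optional Miller-Madow correction subtracts the
    small-sample positive bias (#nonzero joint cells - #nonzero guess
    marginals - #classes + 1) / (2 N ln 2); by default it is applied when
    a counts matrix averages fewer than 50 tests per class. Given a mean
    note duration, the information rate in bits/s is MI / duration.
    """
    if isinstance(confusion, ConfusionMatrix):
        cm = confusion
    else:
        counts = np.asarray(confusion, dtype=float)
        cm = ConfusionMatrix(list(range(counts.shape[0])), counts)
    joint = cm.p_joint
    pi = cm.p_guess
    pj = cm.p_truth
    nz = joint > 0
    outer = np.outer(pi, pj)
    mi = float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))
    total = cm.counts.sum()
    k = len(cm.classes)
    if bias_correction is None:
        bias_correction = total > 0 and (total / k) < 50
    corrected = mi
    if bias_correction and total > 0:
        n_joint = int(np.count_nonzero(cm.counts))
        n_rows = int(np.count_nonzero(cm.counts.sum(axis=1)))
        bias = (n_joint - n_rows - k + 1) / (2.0 * total * np.log(2.0))
        corrected = max(mi - bias, 0.0)
    rate = corrected / mean_duration_s if mean_duration_s else None
    return MutualInformation(
        bits=corrected,
        bits_uncorrected=mi,
        bias_corrected=bool(bias_correction),
        bits_per_second=rate,
    )
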