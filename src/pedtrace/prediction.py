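"""Ridge-regression BLUP genomic prediction and the evaluation protocol.

Model: ``y = 1 b + Xc u + e`` with ``u ~ (0, s2u I)``, ``e ~ (0, s2e I)``,
``Xc`` the column-centred design (raw 0/1/2 codes or an AEE matrix).  The
variance ratio ``lambda = s2e / s2u`` is estimated by REML on the spectrum
of ``Xc Xc'`` (thin SVD of ``Xc``) with 1-D optimisation over log-lambda;
marker effects are the BLUPs at the optimum, equal to the closed-form
ridge solution ``(Xc'Xc + lambda I)^-1 Xc'(y - ybar)``.

Evaluation mirrors the standard protocol: a seeded 80/20 split (or k-fold
cross-validation), Pearson correlation between predicted and observed in
the test set as accuracy, and the mean observed phenotype of the top-q
predicted fraction as the selection criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .aee import build_aee_matrix, fit_aee
from .iomodel import (
    GenotypeMatrix,
    HET,
    MISSING_CALL,
    OriginMatrix,
    PhenotypeTable,
)

__all__ = [
    "RidgeModel",
    "ridge_fit",
    "ridge_predict",
    "reml_loglik",
    "EvalReport",
    "evaluate_split",
    "CVResult",
    "cross_validate",
    "marker_heritability",
    "raw_marker_matrix",
    "CompareReport",
    "compare_methods",
]

_LOG_LAMBDA_BOUNDS = (math.log(1e-9), math.log(1e9))


@dataclass
class RidgeModel:
    """Fitted ridge/BLUP model.  ``intercept`` already folds in the column
    centring, so predictions are ``intercept + X_new @ effects``."""

    intercept: float
    effects: np.ndarray
    lambda_: float
    sigma_u2: float | None
    sigma_e2: float | None
    column_ids: list[str] | None = None
    column_centers: np.ndarray = field(default=None)  # type: ignore[assignment]
    y_mean: float = 0.0


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X rows must align with y")
    if y.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if np.allclose(y, y[0]):
        raise ValueError("phenotype has zero variance")
    return X, y


def ridge_fit(
    X: np.ndarray,
    y: np.ndarray,
    lambda_: float | None = None,
    column_ids: list[str] | None = None,
) -> RidgeModel:
    """Fit the mixed model; estimate the variance ratio by REML unless a
    fixed ``lambda_`` is supplied."""
    X, y = _validate_xy(X, y)
    n = y.shape[0]
    centers = X.mean(axis=0)
    Xc = X - centers
    ybar = float(y.mean())
    yc = y - ybar

    # thin SVD; zero singular values carry no signal
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(Xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    r = int((s > tol).sum())
    U, s, Vt = U[:, :r], s[:r], Vt[:r]
    xi = s ** 2
    a = U.T @ yc
    q = float(yc @ yc - a @ a)  # squared norm in the zero-eigenvalue subspace
    q = max(q, 0.0)
    n_zero = (n - 1) - r  # dimensions orthogonal to both 1 and col(Xc)

    sigma_u2: float | None
    sigma_e2: float | None
    if lambda_ is None:
        lambda_ = _reml_ratio(xi, a, q, n, n_zero)
        R = float((a ** 2 / (xi + lambda_)).sum() + (q / lambda_ if n_zero > 0 else 0.0))
        sigma_u2 = R / (n - 1)
        sigma_e2 = lambda_ * sigma_u2
    else:
        if lambda_ <= 0:
            raise ValueError("lambda must be positive")
        sigma_u2 = sigma_e2 = None

    effects = Vt.T @ (s * a / (xi + lambda_))
    intercept = ybar - float(centers @ effects)
    return RidgeModel(
        intercept=intercept,
        effects=effects,
        lambda_=float(lambda_),
        sigma_u2=sigma_u2,
        sigma_e2=sigma_e2,
        column_ids=column_ids,
        column_centers=centers,
        y_mean=ybar,
    )


def _reml_neg_loglik(log_delta: float, xi: np.ndarray, a: np.ndarray, q: float,
                     n: int, n_zero: int) -> float:
    delta = math.exp(log_delta)
    R = float((a ** 2 / (xi + delta)).sum())
    if n_zero > 0:
        R += q / delta
    logdet = float(np.log(xi + delta).sum()) + n_zero * math.log(delta)
    df = n - 1
    ll = 0.5 * (df * math.log(df / (2 * math.pi)) - df - df * math.log(R) - logdet)
    return -ll

def _reml_ratio(xi: np.ndarray, a: np.ndarray, q: float, n: int, n_zero: int) -> float:
    res = minimize_scalar(
        _reml_neg_loglik,
        bounds=_LOG_LAMBDA_BOUNDS,
        args=(xi, a, q, n, n_zero),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(math.exp(res.x))


def reml_loglik(X: np.ndarray, y: np.ndarray, sigma_u2: float, sigma_e2: float) -> float:
    """Restricted log-likelihood at given variance components, evaluated on
    the eigenvalue spectrum of ``Xc Xc'`` (intercept profiled out by the
    centring projection)."""
    X, y = _validate_xy(X, y)
    n = y.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    xi = s ** 2
    a = U.T @ yc
    q = max(float(yc @ yc - a @ a), 0.0)
    n_zero = (n - 1) - len(xi)
    v = sigma_u2 * xi + sigma_e2
    ll = -0.5 * (
        float(np.log(v).sum())
        + n_zero * math.log(sigma_e2)
        + float((a ** 2 / v).sum())
        + (q / sigma_e2 if n_zero > 0 else 0.0)
        + (n - 1) * math.log(2 * math.pi)
    )
    return ll


def ridge_predict(model: RidgeModel, X_new: np.ndarray) -> np.ndarray:
    """GEBVs: ``intercept + X_new @ effects``."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != model.effects.shape[0]:
        raise ValueError("X_new column count does not match the fitted model")
    return model.intercept + X_new @ model.effects


# ---------------------------------------------------------------------------
# Evaluation protocol
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    accuracy: float
    top_q_mean: float
    selection_differential: float
    heritability: float
    n_train: int
    n_test: int


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _top_q_mean(y_obs: np.ndarray, y_pred: np.ndarray, q: float,
                bottom: bool = False) -> float:
    k = max(1, int(math.ceil(q * len(y_obs))))
    order = np.argsort(y_pred, kind="stable")
    chosen = order[:k] if bottom else order[::-1][:k]
    return float(y_obs[chosen].mean())


def evaluate_split(
    X: np.ndarray,
    y: np.ndarray,
    train_fraction: float = 0.8,
    q: float = 0.10,
    seed: int = 0,
) -> EvalReport:
    """Seeded train/test split evaluation.  Accuracy is the Pearson
    correlation between predicted and observed phenotypes in the test set;
    the selection differential compares the top-q predicted lines' observed
    mean with the test-set mean."""
    X, y = _validate_xy(X, y)
    n = len(y)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    train, test = perm[:n_train], perm[n_train:]
    if len(test) == 0 or len(train) < 2:
        raise ValueError("split leaves an empty train or test set")
    model = ridge_fit(X[train], y[train])
    pred = ridge_predict(model, X[test])
    top_mean = _top_q_mean(y[test], pred, q)
    return EvalReport(
        accuracy=_pearson(y[test], pred),
        top_q_mean=top_mean,
        selection_differential=top_mean - float(y[test].mean()),
        heritability=marker_heritability(X[train], y[train]),
        n_train=len(train),
        n_test=len(test),
    )


@dataclass
class CVResult:
    folds: list[EvalReport]
    pooled_accuracy: float
    fold_assignments: np.ndarray


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
    q: float = 0.10,
) -> CVResult:
    """k-fold cross-validation; every line is tested exactly once and the
    pooled accuracy is the correlation over all out-of-fold predictions."""
    X, y = _validate_xy(X, y)
    n = len(y)
    if k < 2 or k > n:
        raise ValueError("need 2 <= k <= n")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        assignments[chunk] = fold
    oof = np.empty(n, dtype=float)
    folds: list[EvalReport] = []
    for fold in range(k):
        test = np.where(assignments == fold)[0]
        train = np.where(assignments != fold)[0]
        model = ridge_fit(X[train], y[train])
        pred = ridge_predict(model, X[test])
        oof[test] = pred
        top_mean = _top_q_mean(y[test], pred, q)
        folds.append(
            EvalReport(
                accuracy=_pearson(y[test], pred),
                top_q_mean=top_mean,
                selection_differential=top_mean - float(y[test].mean()),
                heritability=marker_heritability(X[train], y[train]),
                n_train=len(train),
                n_test=len(test),
            )
        )
    return CVResult(folds=folds, pooled_accuracy=_pearson(y, oof),
                    fold_assignments=assignments)


def marker_heritability(X: np.ndarray, y: np.ndarray) -> float:
    """Marker-based h2: fit REML, then
    ``h2 = s2g / (s2g + s2e)`` with the genomic variance on the phenotype
    scale ``s2g = s2u * mean(diag(Xc Xc'))``."""
    X, y = _validate_xy(X, y)
    model = ridge_fit(X, y)
    Xc = X - X.mean(axis=0)
    mean_diag = float((Xc ** 2).sum()) / X.shape[0]
    s2g = model.sigma_u2 * mean_diag
    h2 = s2g / (s2g + model.sigma_e2) if (s2g + model.sigma_e2) > 0 else 0.0
    return float(min(max(h2, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Method comparison (raw marker codes vs allele-effect matrix)
# ---------------------------------------------------------------------------

def raw_marker_matrix(genotypes: GenotypeMatrix,
                      line_ids: list[str] | None = None) -> np.ndarray:
    """0/1/2 dosage design matrix (het = 1); missing calls are filled with
    the column mean."""
    calls = (genotypes.subset_lines(line_ids).calls if line_ids is not None
             else genotypes.calls)
    X = calls.astype(float)
    missing = calls == MISSING_CALL
    X[missing] = np.nan
    with np.errstate(invalid="ignore"):
        col_means = np.nanmean(X, axis=0)
    col_means = np.nan_to_num(col_means, nan=0.0)
    X[missing] = np.broadcast_to(col_means, X.shape)[missing]
    return X


@dataclass
class CompareReport:
    """Side-by-side evaluation of the raw-marker and AEE arms on an
    identical train/test split."""

    accuracy_raw: float
    accuracy_aee: float
    accuracy_ratio: float
    top_q_mean_raw: float
    top_q_mean_aee: float
    top_q_ratio: float
    bottom_q_mean_raw: float
    bottom_q_mean_aee: float
    test_mean: float
    heritability: float
    n_train: int
    n_test: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def compare_methods(
    origins: OriginMatrix,
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    trait: str,
    env: str,
    seed: int = 0,
    train_fraction: float = 0.8,
    q: float = 0.10,
    mode: str = "split",
    k: int = 5,
) -> CompareReport:
    """Run both prediction arms on identical seeded partitions.

    The AEE table is always fitted on training lines only (held-out lines
    never contribute to mu or alpha), then the numeric matrix is built for
    all lines.  ``mode="split"`` uses one train/test split evaluated on
    the test set; ``mode="cv"`` uses k-fold cross-validation (the
    lower-sampling-bias protocol) with accuracy and selection statistics
    pooled over all out-of-fold predictions.  Both arms always share the
    exact same partition.
    """
    pheno = phenotypes.values_for(trait, env)
    lines = [l for l in origins.line_ids if l in pheno.index and l in genotypes]
    if len(lines) < 5:
        raise ValueError("too few lines that are traced, genotyped and phenotyped")
    y = pheno.loc[lines].to_numpy(float)
    n = len(lines)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)

    X_raw = raw_marker_matrix(genotypes, lines)

    if mode == "split":
        n_train = int(round(train_fraction * n))
        fold_pairs = [(perm[:n_train], perm[n_train:])]
    elif mode == "cv":
        if k < 2 or k > n:
            raise ValueError("need 2 <= k <= n")
        assignments = np.empty(n, dtype=int)
        for fold, chunk in enumerate(np.array_split(perm, k)):
            assignments[chunk] = fold
        fold_pairs = [
            (np.where(assignments != f)[0], np.where(assignments == f)[0])
            for f in range(k)
        ]
    else:
        raise ValueError("mode must be 'split' or 'cv'")

    eval_idx: list[np.ndarray] = []
    preds: dict[str, list[np.ndarray]] = {"raw": [], "aee": []}
    for train, test in fold_pairs:
        train_lines = [lines[i] for i in train]
        table = fit_aee(origins.subset_lines(train_lines), phenotypes, trait, env)
        X_aee = build_aee_matrix(origins.subset_lines(lines), table).values
        for name, X in (("raw", X_raw), ("aee", X_aee)):
            model = ridge_fit(X[train], y[train])
            preds[name].append(ridge_predict(model, X[test]))
        eval_idx.append(test)

    idx = np.concatenate(eval_idx)
    y_test = y[idx]
    pred_raw = np.concatenate(preds["raw"])
    pred_aee = np.concatenate(preds["aee"])

    acc_raw = _pearson(y_test, pred_raw)
    acc_aee = _pearson(y_test, pred_aee)
    top_raw = _top_q_mean(y_test, pred_raw, q)
    top_aee = _top_q_mean(y_test, pred_aee, q)
    train0 = fold_pairs[0][0]
    return CompareReport(
        accuracy_raw=acc_raw,
        accuracy_aee=acc_aee,
        accuracy_ratio=acc_aee / acc_raw if acc_raw != 0 else float("nan"),
        top_q_mean_raw=top_raw,
        top_q_mean_aee=top_aee,
        top_q_ratio=top_aee / top_raw if top_raw != 0 else float("nan"),
        bottom_q_mean_raw=_top_q_mean(y_test, pred_raw, q, bottom=True),
        bottom_q_mean_aee=_top_q_mean(y_test, pred_aee, q, bottom=True),
        test_mean=float(y_test.mean()),
        heritability=marker_heritability(X_raw[train0], y[train0]),
        n_train=len(train0),
        n_test=len(y_test),
    )
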