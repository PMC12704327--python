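"""Principal component decomposition of the eight-score battery.

PCA on the correlation matrix of the (typically absolute-valued) scores,
followed by direct-oblimin rotation with Kaiser normalization of the
retained components, and regression-method subject scores. The rotation is
the standard gradient-projection algorithm for oblique rotations
(quartimin criterion at delta = 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .scoring import SCORE_NAMES

__all__ = [
    "FactorError",
    "FactorModel",
    "standardize",
    "fit_pca",
    "select_components",
    "rotate_oblimin",
    "subject_scores",
    "factor_report",
    "write_factor_report",
    "write_subject_scores",
]


class FactorError(ValueError):
    pass


@dataclass
class FactorModel:
    """Eigenstructure and (optionally rotated) loadings of a score battery.

    ``pattern_loadings`` holds the first ``k`` columns; ``loadings_full``
    always keeps the complete unrotated p x p loading matrix so that
    completeness identities can be checked.
    """

    eigenvalues: np.ndarray  # (p,), descending
    variance_explained_pct: np.ndarray  # (p,), sums to 100
    k: int
    pattern_loadings: np.ndarray  # (p, k)
    factor_correlation: np.ndarray  # (k, k)
    loadings_full: np.ndarray  # (p, p) unrotated
    column_names: tuple[str, ...]
    rotated: bool = False

    def __post_init__(self):
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise FactorError("eigenvalues must be in descending order")
        if abs(self.variance_explained_pct.sum() - 100.0) > 1e-6:
            raise FactorError("variance explained must sum to 100")


def _as_matrix(m) -> tuple[np.ndarray, tuple[str, ...], list]:
    """Accept a DataFrame (with optional patient_id column) or an array."""
    if isinstance(m, pd.DataFrame):
        df = m
        ids = df["patient_id"].tolist() if "patient_id" in df.columns else list(df.index)
        cols = [c for c in df.columns if c != "patient_id"]
        return df[cols].to_numpy(dtype=float), tuple(cols), ids
    arr = np.asarray(m, dtype=float)
    return arr, tuple(f"v{i}" for i in range(arr.shape[1])), list(range(arr.shape[0]))


def standardize(m):
    """Column-standardize to mean 0, sample SD 1 (ddof = 1)."""
    values, cols, ids = _as_matrix(m)
    sd = values.std(axis=0, ddof=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise FactorError(f"constant column(s): {[cols[i] for i in bad]}")
    z = (values - values.mean(axis=0)) / sd
    if isinstance(m, pd.DataFrame):
        out = pd.DataFrame(z, columns=cols)
        if "patient_id" in m.columns:
            out.insert(0, "patient_id", ids)
        return out
    return z


def fit_pca(m) -> FactorModel:
    """Eigen-decompose the correlation matrix of the score battery.

    Unrotated loadings are eigenvectors scaled by sqrt(eigenvalue);
    variance explained per component is 100 * lambda_i / p.
    """
    values, cols, _ = _as_matrix(m)
    n, p = values.shape
    if n <= p:
        raise FactorError(f"need more patients ({n}) than scores ({p})")
    z = standardize(values)
    corr = (z.T @ z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-|entry| element of each eigenvector positive
    for j in range(p):
        i = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] *= -1
    loadings = eigvecs * np.sqrt(eigvals)
    return FactorModel(
        eigenvalues=eigvals,
        variance_explained_pct=100.0 * eigvals / p,
        k=p,
        pattern_loadings=loadings,
        factor_correlation=np.eye(p),
        loadings_full=loadings,
        column_names=cols,
        rotated=False,
    )


def select_components(model: FactorModel, rule: str = "kaiser", k: int | None = None) -> int:
    """Number of components to retain (Kaiser: eigenvalue > 1), or an override."""
    if k is not None:
        if not 1 <= k <= len(model.eigenvalues):
            raise FactorError(f"k override out of range: {k}")
        return int(k)
    if rule != "kaiser":
        raise FactorError(f"unknown selection rule {rule!r}")
    kk = int(np.sum(model.eigenvalues > 1.0))
    if kk == 0:
        raise FactorError("Kaiser rule retains no component; pass an explicit k")
    return kk


# -- direct oblimin via gradient projection ---------------------------------


def _quartimin(L: np.ndarray) -> tuple[float, np.ndarray]:
    """Quartimin criterion (direct oblimin, delta = 0) and its gradient."""
    L2 = L**2
    k = L.shape[1]
    N = np.ones((k, k)) - np.eye(k)
    X = L2 @ N
    return float(np.sum(L2 * X)) / 4.0, L * X


def _gpa_oblique(
    A: np.ndarray, max_iter: int = 1000, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, float]:
    """Gradient-projection minimization of quartimin over oblique rotations.

    Returns (rotated pattern, factor correlation, final criterion).
    """
    k = A.shape[1]
    T = np.eye(k)
    al = 1.0
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin(L)
    G = -((L.T @ Gq) @ Ti).T
    converged = False
    for _ in range(max_iter):
        Gp = G - T @ np.diag(np.sum(T * G, axis=0))
        s = np.linalg.norm(Gp)
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ in range(200):
            X = T - al * Gp
            v = 1.0 / np.sqrt(np.sum(X**2, axis=0))
            Tt = X * v
            Ti = np.linalg.inv(Tt)
            L = A @ Ti.T
            ft, Gq = _quartimin(L)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T = Tt
        f = ft
        G = -((L.T @ Gq) @ np.linalg.inv(T)).T
    if not converged:
        # final check: accept if the projected gradient is already tiny
        Gp = G - T @ np.diag(np.sum(T * G, axis=0))
        if np.linalg.norm(Gp) >= tol * 10:
            raise FactorError(f"oblimin did not converge; criterion = {f:.6g}")
    Phi = T.T @ T
    return L, Phi, f


def rotate_oblimin(
    model: FactorModel, k: int, delta: float = 0.0, kaiser_normalize: bool = True
) -> FactorModel:
    """Direct-oblimin rotation of the first ``k`` unrotated loading columns.

    Rows are Kaiser-normalized before rotation and de-normalized after.
    ``k = 1`` is the identity rotation. Only ``delta = 0`` (quartimin) is
    supported, matching the conventional "oblimin" default.
    """
    if delta != 0.0:
        raise FactorError("only delta = 0 (direct oblimin / quartimin) is supported")
    if k < 1:
        raise FactorError("k must be >= 1")
    A = model.loadings_full[:, :k].copy()
    if k == 1:
        return replace(
            model, k=1, pattern_loadings=A, factor_correlation=np.eye(1), rotated=True
        )
    h = np.sqrt(np.sum(A**2, axis=1))
    if kaiser_normalize:
        if np.any(h == 0):
            raise FactorError("zero-communality row; cannot Kaiser-normalize")
        A_work = A / h[:, None]
    else:
        A_work = A
    L, Phi, _ = _gpa_oblique(A_work)
    if kaiser_normalize:
        L = L * h[:, None]
    # deterministic orientation and ordering: flip each factor so its largest
    # |loading| is positive, order factors by explained sum of squares
    for j in range(k):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] *= -1
            Phi[j, :] *= -1
            Phi[:, j] *= -1
    order = np.argsort(-np.sum(L**2, axis=0), kind="stable")
    L = L[:, order]
    Phi = Phi[np.ix_(order, order)]
    return replace(model, k=k, pattern_loadings=L, factor_correlation=Phi, rotated=True)


def subject_scores(model: FactorModel, m) -> pd.DataFrame:
    """Regression-method component scores from standardized data.

    Weights B = R^-1 (Lambda Phi) with R the sample correlation matrix;
    scores = Z B. For the complete unrotated model (k = p) this reproduces
    the standardized data through scores @ loadings.T.
    """
    values, cols, ids = _as_matrix(m)
    if values.shape[1] != len(model.column_names):
        raise FactorError("score matrix does not match the fitted model dimensions")
    z = standardize(values)
    n = z.shape[0]
    corr = (z.T @ z) / (n - 1)
    structure = model.pattern_loadings @ model.factor_correlation
    weights = np.linalg.solve(corr, structure)
    scores = z @ weights
    out = pd.DataFrame(scores, columns=[f"C{i + 1}" for i in range(model.k)])
    out.insert(0, "patient_id", ids)
    return out


# -- reporting ---------------------------------------------------------------


def factor_report(model: FactorModel) -> dict:
    rotated_ssq = np.sum(model.pattern_loadings**2, axis=0)
    return {
        "n_components": model.k,
        "rotated": model.rotated,
        "eigenvalues": model.eigenvalues.round(6).tolist(),
        "variance_explained_pct": model.variance_explained_pct.round(4).tolist(),
        "variance_explained_top_k_pct": float(model.variance_explained_pct[: model.k].sum()),
        "rotated_sum_of_squares": rotated_ssq.round(6).tolist(),
        "pattern_loadings": {
            name: model.pattern_loadings[i].round(6).tolist()
            for i, name in enumerate(model.column_names)
        },
        "factor_correlation": model.factor_correlation.round(6).tolist(),
    }


def write_factor_report(model: FactorModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(factor_report(model), fh, indent=2)


def write_subject_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index=False)
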