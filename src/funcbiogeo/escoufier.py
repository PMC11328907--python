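"""Escoufier RV-based greedy variable selection.

Reduces a stations × clusters abundance table to an ordered subset of
cluster columns whose joint pattern captures a target fraction of the
full dataset's variance, measured by Escoufier's RV coefficient between
the selected sub-matrix and the full matrix:

    RV(A, B) = tr(S_ab S_ba) / sqrt(tr(S_aa^2) tr(S_bb^2))

with S the cross-covariance blocks of the column-centered matrices.
Greedy forward selection adds, at each step, the column maximizing the
RV with the full matrix; ties break to the lowest column index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import AbundanceMatrix

__all__ = ["EscoufierResult", "rv_coefficient", "escoufier_select"]


@dataclass
class EscoufierResult:
    selected_ids: list[str]
    rv_trajectory: list[float]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.selected_ids) + 1),
                "cluster_id": self.selected_ids,
                "rv": self.rv_trajectory,
            }
        )


def _center(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return X - X.mean(axis=0, keepdims=True)


def rv_coefficient(X_sub: np.ndarray, X_full: np.ndarray, scale: bool = False) -> float:
    """Escoufier's RV between a column subset and the full matrix.

    Columns are centered internally (and optionally scaled to unit SD).
    Returns 0 with a warning when the subset has no variance.
    """
    A = _center(X_sub)
    B = _center(X_full)
    if A.shape[0] != B.shape[0]:
        raise ValueError("matrices must share station rows")
    if scale:
        A = A / np.where(A.std(axis=0) > 0, A.std(axis=0), 1.0)
        B = B / np.where(B.std(axis=0) > 0, B.std(axis=0), 1.0)
    s_ab = A.T @ B
    s_aa = A.T @ A
    s_bb = B.T @ B
    denom = np.sqrt(np.sum(s_aa**2) * np.sum(s_bb**2))
    if denom == 0:
        warnings.warn("zero-variance sub-matrix in RV computation", stacklevel=2)
        return 0.0
    return float(np.sum(s_ab**2) / denom)


def escoufier_select(
    matrix: AbundanceMatrix | pd.DataFrame,
    threshold: float = 0.95,
    max_k: int | None = 50,
    scale: bool = False,
) -> EscoufierResult:
    """Greedy forward selection of columns by RV with the full matrix.

    Stops when RV >= ``threshold`` or ``max_k`` columns are selected.
    Deterministic: RV ties (within 1e-12) break to the lowest column
    index. Raises on a constant matrix (no variance to explain).
    """
    df = matrix.to_frame() if isinstance(matrix, AbundanceMatrix) else matrix
    if df.shape[1] < 2:
        raise ValueError("need at least 2 clusters to select from")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    X = _center(df.to_numpy(dtype=float))
    if scale:
        sd = X.std(axis=0)
        X = X / np.where(sd > 0, sd, 1.0)
    p = X.shape[1]
    C = X.T @ X  # p x p cross-product of centered columns
    if not np.any(np.diag(C) > 0):
        raise ValueError("constant matrix: no variance to explain")

    # RV of subset S against full: ||C[S, :]||_F^2 / sqrt(||C[S, S]||_F^2 * ||C||_F^2)
    row_norms = np.sum(C**2, axis=1)
    full_norm = np.sum(C**2)
    max_k = p if max_k is None else min(max_k, p)

    selected: list[int] = []
    trajectory: list[float] = []
    num = 0.0  # ||C[S, :]||_F^2
    den_sub = 0.0  # ||C[S, S]||_F^2
    available = np.ones(p, dtype=bool)
    while len(selected) < max_k:
        best_rv, best_j, best_num, best_den = -np.inf, -1, 0.0, 0.0
        for j in range(p):
            if not available[j]:
                continue
            num_j = num + row_norms[j]
            cross = C[j, selected] if selected else np.empty(0)
            den_j = den_sub + 2.0 * np.sum(cross**2) + C[j, j] ** 2
            if den_j <= 0:
                continue
            rv_j = num_j / np.sqrt(den_j * full_norm)
            if rv_j > best_rv + 1e-12:
                best_rv, best_j, best_num, best_den = rv_j, j, num_j, den_j
        if best_j < 0:
            break
        selected.append(best_j)
        available[best_j] = False
        num, den_sub = best_num, best_den
        trajectory.append(float(best_rv))
        if best_rv >= threshold:
            break

    ids = [str(df.columns[j]) for j in selected]
    return EscoufierResult(selected_ids=ids, rv_trajectory=trajectory, threshold=threshold)
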