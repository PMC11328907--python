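"""Spatial-block cross-validation, skill metrics and structure tests.

Folds are contiguous blocks of stations ordered by station number: the
cruise trajectory is continuous in space and time, so contiguous id
blocks are spatially and temporally coherent and their held-out
evaluation is not inflated by autocorrelation. Model skill is the
pooled out-of-fold R² and RMSE; conservation of the between-response
correlation structure is tested with a Mantel-style permutation test on
the observed vs predicted response correlation matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mbtr import BoostedEnsemble, MBTRHyperparams, fit_mbtr, predict

__all__ = [
    "FoldSpec",
    "CVReport",
    "make_block_folds",
    "cross_validate",
    "r2_score_pooled",
    "mantel_conservation",
]


@dataclass
class FoldSpec:
    """station_id -> 1-based fold index; folds contiguous in station order."""

    fold_assignments: dict

    @property
    def n_folds(self) -> int:
        return max(self.fold_assignments.values())

    def fold_members(self, k: int) -> list:
        return [s for s, f in self.fold_assignments.items() if f == k]


@dataclass
class CVReport:
    r2: float
    rmse: float
    per_fold_best_rounds: list[int]
    global_best_rounds: int
    r2_per_response_mean: float = np.nan

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "rmse": self.rmse,
            "r2_per_response_mean": self.r2_per_response_mean,
            "per_fold_best_rounds": self.per_fold_best_rounds,
            "global_best_rounds": self.global_best_rounds,
        }


def make_block_folds(station_ids, n_folds: int = 10) -> FoldSpec:
    """Partition stations, sorted by id, into contiguous blocks.

    Block sizes differ by at most one; the ordering contract means a
    permuted input yields identical folds.
    """
    ids = sorted(station_ids)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > len(ids):
        raise ValueError("more folds than stations")
    blocks = np.array_split(np.asarray(ids, dtype=object), n_folds)
    assignments = {}
    for k, block in enumerate(blocks, start=1):
        for s in block:
            assignments[s] = k
    return FoldSpec(fold_assignments=assignments)


def r2_score_pooled(Y_obs: np.ndarray, Y_pred: np.ndarray) -> float:
    """1 - SSE/SST pooled over all responses; SST about per-column means."""
    Y_obs = np.asarray(Y_obs, dtype=float)
    Y_pred = np.asarray(Y_pred, dtype=float)
    sse = np.sum((Y_obs - Y_pred) ** 2)
    sst = np.sum((Y_obs - Y_obs.mean(axis=0, keepdims=True)) ** 2)
    if sst == 0:
        return np.nan
    return float(1.0 - sse / sst)


def _r2_per_response_mean(Y_obs: np.ndarray, Y_pred: np.ndarray) -> float:
    sse = np.sum((Y_obs - Y_pred) ** 2, axis=0)
    sst = np.sum((Y_obs - Y_obs.mean(axis=0, keepdims=True)) ** 2, axis=0)
    ok = sst > 0
    if not ok.any():
        return np.nan
    return float(np.mean(1.0 - sse[ok] / sst[ok]))


def cross_validate(
    X: np.ndarray,
    Y: np.ndarray,
    station_ids,
    folds: FoldSpec,
    hp: MBTRHyperparams = MBTRHyperparams(),
) -> tuple[list[BoostedEnsemble], CVReport]:
    """Fit one ensemble per fold and score pooled out-of-fold predictions.

    Each ensemble trains on the other folds and records its per-round
    loss on the held-out fold; the held-out prediction uses that fold's
    loss-minimizing round count. ``global_best_rounds`` is the round
    count at the minimum held-out loss across all fold runs — the value
    later reused for bootstrap projections.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    ids = list(station_ids)
    fold_of = np.asarray([folds.fold_assignments[s] for s in ids])

    ensembles: list[BoostedEnsemble] = []
    oof_pred = np.full_like(Y, np.nan, dtype=float)
    per_fold_best: list[int] = []
    global_best_loss, global_best_rounds = np.inf, 0
    for k in range(1, folds.n_folds + 1):
        test = fold_of == k
        if (~test).sum() < hp.min_leaf:
            raise ValueError(f"fold {k} leaves fewer training rows than min_leaf")
        ens = fit_mbtr(X[~test], Y[~test], X[test], Y[test], hp)
        ensembles.append(ens)
        best = ens.best_rounds
        per_fold_best.append(best)
        oof_pred[test] = predict(ens, X[test], n_rounds=best)
        fold_min = float(np.min(ens.test_loss))
        if fold_min < global_best_loss:
            global_best_loss, global_best_rounds = fold_min, best

    rmse = float(np.sqrt(np.mean((Y - oof_pred) ** 2)))
    report = CVReport(
        r2=r2_score_pooled(Y, oof_pred),
        rmse=rmse,
        per_fold_best_rounds=per_fold_best,
        global_best_rounds=global_best_rounds,
        r2_per_response_mean=_r2_per_response_mean(Y, oof_pred),
    )
    return ensembles, report


def _offdiag_upper(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def mantel_conservation(
    Y_obs: np.ndarray,
    Y_pred: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel test between observed and predicted response correlation matrices.

    r is the Pearson correlation of the off-diagonal entries of the two
    response-correlation matrices; the one-sided p-value comes from
    jointly permuting the row/column labels of the predicted matrix,
    with the (n_permutations + 1) denominator. Constant response columns
    are excluded with a warning.
    """
    Y_obs = np.asarray(Y_obs, dtype=float)
    Y_pred = np.asarray(Y_pred, dtype=float)
    ok = (Y_obs.std(axis=0) > 0) & (Y_pred.std(axis=0) > 0)
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} constant response column(s)", stacklevel=2)
    Y_obs, Y_pred = Y_obs[:, ok], Y_pred[:, ok]
    d = Y_obs.shape[1]
    if d < 3:
        raise ValueError("need at least 3 (non-constant) response variables")

    C_obs = np.corrcoef(Y_obs, rowvar=False)
    C_pred = np.corrcoef(Y_pred, rowvar=False)
    a = _offdiag_upper(C_obs)

    def corr_with(perm: np.ndarray) -> float:
        b = _offdiag_upper(C_pred[np.ix_(perm, perm)])
        return float(np.corrcoef(a, b)[0, 1])

    identity = np.arange(d)
    r = corr_with(identity)
    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(n_permutations):
        if corr_with(rng.permutation(d)) >= r:
            hits += 1
    p = hits / (n_permutations + 1)
    return r, p
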