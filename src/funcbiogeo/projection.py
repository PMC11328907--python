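"""Bootstrap spatial projection of cluster abundances onto climatology grids.

Each bootstrap round resamples stations with replacement (keeping
feature/response rows paired), refits an MBTR with the validated
hyperparameters at the validated round count, and predicts every
unmasked grid cell. The per-cell mean and coefficient of variation
(SD / mean × 100) across rounds summarize the projection and its
uncertainty. Predictions are relative abundances, so negative model
outputs are clipped to zero before aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from .mbtr import MBTRHyperparams, fit_mbtr, predict

__all__ = ["ProjectionField", "grid_feature_matrix", "bootstrap_project", "fields_to_netcdf"]

MEAN_FLOOR = 1e-6  # below this the CV is undefined and reported missing


@dataclass
class ProjectionField:
    """Per-grid-cell mean prediction and CV (%) for one cluster or MAG."""

    cluster_id: str
    mean: xr.DataArray
    cv: xr.DataArray
    n_boot: int
    reconstructed: bool = False


def grid_feature_matrix(grid: xr.Dataset, feature_names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Extract the unmasked-cell feature matrix for the model's features.

    Returns (cells × features matrix, boolean ocean mask). Raises when
    the grid lacks any training feature, listing the gaps.
    """
    missing = [f for f in feature_names if f not in grid.data_vars]
    if missing:
        raise ValueError(f"grid is missing training features: {missing}")
    mask = grid["mask"].to_numpy() == 1
    cols = [grid[f].to_numpy()[mask] for f in feature_names]
    return np.column_stack(cols), mask


def bootstrap_project(
    X: np.ndarray,
    Y: np.ndarray,
    hp: MBTRHyperparams,
    best_rounds: int,
    grid: xr.Dataset,
    feature_names: list[str],
    cluster_ids: list[str],
    n_boot: int = 100,
    seed: int = 0,
) -> dict[str, ProjectionField]:
    """Bootstrap-refit ensembles and project every cluster onto the grid.

    Round b's resample is seeded from ``(seed, b)``, so results are
    reproducible and independent of execution order. With a single
    round the CV is zero wherever the mean is defined.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if len(cluster_ids) != Y.shape[1]:
        raise ValueError("cluster_ids length must match the response dimension")
    cells, mask = grid_feature_matrix(grid, feature_names)
    hp_proj = MBTRHyperparams(
        **{**hp.__dict__, "max_rounds": best_rounds, "early_stop_patience": None}
    )

    n = X.shape[0]
    preds = np.empty((n_boot, cells.shape[0], Y.shape[1]), dtype=float)
    for b in range(n_boot):
        rng = np.random.default_rng(np.random.SeedSequence([seed, b]))
        idx = rng.integers(0, n, size=n)
        ens = fit_mbtr(X[idx], Y[idx], hp=hp_proj)
        preds[b] = np.clip(predict(ens, cells, n_rounds=ens.n_rounds), 0.0, None)

    mean = preds.mean(axis=0)
    sd = preds.std(axis=0, ddof=1) if n_boot > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > MEAN_FLOOR, 100.0 * sd / mean, np.nan)
    if n_boot == 1:
        cv = np.where(mean > MEAN_FLOOR, 0.0, np.nan)

    fields: dict[str, ProjectionField] = {}
    for j, cid in enumerate(cluster_ids):
        fields[cid] = ProjectionField(
            cluster_id=cid,
            mean=_embed(grid, mask, mean[:, j], f"{cid}_mean"),
            cv=_embed(grid, mask, cv[:, j], f"{cid}_cv"),
            n_boot=n_boot,
        )
    return fields


def _embed(grid: xr.Dataset, mask: np.ndarray, values: np.ndarray, name: str) -> xr.DataArray:
    full = np.full(mask.shape, np.nan)
    full[mask] = values
    return xr.DataArray(full, coords={"lat": grid["lat"], "lon": grid["lon"]},
                        dims=("lat", "lon"), name=name)


def fields_to_netcdf(fields: dict[str, ProjectionField], path) -> None:
    data = {}
    for cid, f in fields.items():
        data[f"{cid}_mean"] = f.mean
        data[f"{cid}_cv"] = f.cv
    ds = xr.Dataset(data)
    ds.attrs["reconstructed"] = ",".join(c for c, f in fields.items() if f.reconstructed)
    ds.to_netcdf(path, engine="scipy")
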