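"""Correspondence analysis and nearest-neighbour projection reconstruction.

Only the variance-selected clusters are modelled directly; the remaining
clusters inherit the projection of their nearest selected neighbour in
correspondence-analysis (CA) space, computed on the observed relative
abundance table of all clusters and restricted to the leading dimensions
that together explain a minimum fraction (default 80%) of the total
inertia. Distances use column principal coordinates, i.e. clusters as
points scaled by their singular values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .projection import ProjectionField

__all__ = ["CAResult", "correspondence_analysis", "map_nonselected", "reconstruct_projections"]

_SV_TOL = 1e-12


@dataclass
class CAResult:
    """Column (cluster) principal coordinates and per-dimension inertia."""

    coordinates: pd.DataFrame  # cluster x dimension
    inertia_fractions: np.ndarray
    n_dims_kept: int

    def kept_coordinates(self) -> pd.DataFrame:
        return self.coordinates.iloc[:, : self.n_dims_kept]


def correspondence_analysis(
    table: pd.DataFrame, variance_min: float = 0.80
) -> CAResult:
    """Standard correspondence analysis of a non-negative table.

    P = N / n; S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}; SVD of S; column
    principal coordinates D_c^{-1/2} V Σ. ``n_dims_kept`` is the
    smallest number of leading dimensions whose cumulative inertia
    reaches ``variance_min``. All-zero columns are dropped with a
    warning; a rank-1 table (zero inertia) raises.
    """
    N = table.to_numpy(dtype=float)
    if (N < 0).any():
        raise ValueError("negative entries are not allowed in a CA table")
    if N.sum() <= 0:
        raise ValueError("grand total must be positive")
    zero_cols = table.columns[N.sum(axis=0) == 0]
    if len(zero_cols):
        warnings.warn(f"dropping {len(zero_cols)} all-zero column(s) from CA", stacklevel=2)
        table = table.drop(columns=zero_cols)
        N = table.to_numpy(dtype=float)
    zero_rows = N.sum(axis=1) == 0
    if zero_rows.any():
        table = table.loc[~zero_rows]
        N = table.to_numpy(dtype=float)

    n = N.sum()
    P = N / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    keep = sv > _SV_TOL
    sv = sv[keep]
    if sv.size == 0:
        raise ValueError("no CA dimensions: rows are proportional (zero inertia)")
    V = Vt[keep].T
    coords = (V * sv) / np.sqrt(c)[:, None]
    inertia = sv**2 / np.sum(sv**2)
    cum = np.cumsum(inertia)
    n_dims = int(np.searchsorted(cum, variance_min - 1e-12) + 1)
    return CAResult(
        coordinates=pd.DataFrame(
            coords, index=table.columns, columns=[f"CA{i+1}" for i in range(sv.size)]
        ),
        inertia_fractions=inertia,
        n_dims_kept=n_dims,
    )


def map_nonselected(
    ca: CAResult, selected_ids, variance_min: float | None = None
) -> pd.DataFrame:
    """Nearest selected neighbour of each non-selected cluster in CA space.

    Euclidean distances over the kept leading dimensions; ties break to
    the selected cluster appearing first in the CA column order. Returns
    a frame (nonselected_id, selected_id, distance, n_dims_kept).
    """
    selected = [s for s in ca.coordinates.index if s in set(selected_ids)]
    if not selected:
        raise ValueError("selected set is empty (or disjoint from the CA clusters)")
    n_dims = ca.n_dims_kept
    if variance_min is not None:
        cum = np.cumsum(ca.inertia_fractions)
        n_dims = int(np.searchsorted(cum, variance_min - 1e-12) + 1)
    coords = ca.coordinates.iloc[:, :n_dims]
    sel = coords.loc[selected].to_numpy()
    rows = []
    for cid in ca.coordinates.index:
        if cid in set(selected):
            continue
        d = np.sqrt(np.sum((sel - coords.loc[cid].to_numpy()) ** 2, axis=1))
        j = int(np.argmin(d))  # argmin keeps the first (lowest-order) tie
        rows.append(
            {
                "nonselected_id": cid,
                "selected_id": selected[j],
                "distance": float(d[j]),
                "n_dims_kept": n_dims,
            }
        )
    return pd.DataFrame(rows, columns=["nonselected_id", "selected_id", "distance", "n_dims_kept"])


def reconstruct_projections(
    mapping: pd.DataFrame, fields: dict[str, ProjectionField]
) -> dict[str, ProjectionField]:
    """Give every mapped non-selected cluster its neighbour's projection.

    The reconstructed field shares the neighbour's mean and CV arrays
    (no copy) and is tagged ``reconstructed``. Idempotent; raises on a
    mapping whose target has no projection.
    """
    out = dict(fields)
    for row in mapping.itertuples(index=False):
        if row.selected_id not in fields:
            raise ValueError(f"mapping target {row.selected_id!r} has no projection field")
        src = fields[row.selected_id]
        out[row.nonselected_id] = replace(
            src, cluster_id=row.nonselected_id, reconstructed=True
        )
    return out
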