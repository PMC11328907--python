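"""Enzyme-level aggregation of cluster projections.

Cluster projections are first standardized to [0, 1] (equally weighted
distribution patterns), then aggregated per enzyme annotation in two
modes: a *standardized* simple mean — the consensus of all member
patterns — and a *weighted* mean using each cluster's total observed
relative abundance across stations as weight — the pattern of the
dominant clusters. The per-cell CV across member patterns measures how
much the members disagree at that location.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import xarray as xr

from .preprocessing import AbundanceMatrix
from .projection import MEAN_FLOOR, ProjectionField

__all__ = [
    "EnzymePattern",
    "standardize_projection",
    "aggregate_standardized",
    "aggregate_weighted",
    "pattern_correlations",
    "default_enzyme_labels",
]


def default_enzyme_labels() -> list[str]:
    """Carbon-fixation / C4-pathway enzyme labels used as aggregation bins."""
    return [
        "RUBISCO",
        "PEPC",
        "PEPCK",
        "MDC-NAD",
        "MDC-NADP",
        "MDH-NAD",
        "MDH-NADP",
        "PEPDK",
        "GOT",
        "GPT-GGAT",
    ]


@dataclass
class EnzymePattern:
    """Aggregated genomic potential in [0, 1] and member CV (%) per cell."""

    enzyme: str
    potential: xr.DataArray
    cv: xr.DataArray
    mode: str
    raw: xr.DataArray | None = None  # pre-rescale aggregate (weighted mode)
    rescaled: bool = False


def standardize_projection(field: ProjectionField) -> ProjectionField:
    """Min-max scale the mean layer to [0, 1] over unmasked cells.

    The CV layer is carried through unchanged. A constant field has no
    pattern to scale and raises.
    """
    vals = field.mean.to_numpy()
    finite = np.isfinite(vals)
    lo, hi = np.nanmin(vals), np.nanmax(vals)
    if not finite.any() or hi - lo <= 0:
        raise ValueError(f"degenerate projection for {field.cluster_id!r}: constant field")
    return replace(field, mean=(field.mean - lo) / (hi - lo))


def _stack(fields: list[ProjectionField]) -> np.ndarray:
    return np.stack([f.mean.to_numpy() for f in fields], axis=0)


def _member_fields(
    fields: dict[str, ProjectionField], emap: dict[str, set[str] | list[str]], enzyme: str
) -> list[ProjectionField]:
    members = sorted(emap[enzyme])
    missing = [m for m in members if m not in fields]
    if missing:
        raise ValueError(f"enzyme {enzyme!r} references clusters without projections: {missing}")
    if not members:
        raise ValueError(f"enzyme {enzyme!r} has no member clusters")
    return [fields[m] for m in members]


def aggregate_standardized(
    fields: dict[str, ProjectionField], emap: dict[str, set[str] | list[str]]
) -> dict[str, EnzymePattern]:
    """Cell-wise unweighted mean of member unit-scaled fields, per enzyme.

    CV = SD across member fields / mean × 100 (sample SD); zero for a
    single member.
    """
    out = {}
    for enzyme in emap:
        members = _member_fields(fields, emap, enzyme)
        stack = _stack(members)
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1) if len(members) > 1 else np.zeros_like(mean)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean > MEAN_FLOOR, 100.0 * sd / mean, np.nan)
        template = members[0].mean
        out[enzyme] = EnzymePattern(
            enzyme=enzyme,
            potential=xr.DataArray(mean, coords=template.coords, dims=template.dims),
            cv=xr.DataArray(cv, coords=template.coords, dims=template.dims),
            mode="standardized",
        )
    return out


def cluster_weights(abundance: AbundanceMatrix | pd.DataFrame) -> pd.Series:
    """Total observed relative abundance of each cluster across stations."""
    df = abundance.to_frame() if isinstance(abundance, AbundanceMatrix) else abundance
    return df.sum(axis=0)


def aggregate_weighted(
    fields: dict[str, ProjectionField],
    abundance: AbundanceMatrix | pd.DataFrame,
    emap: dict[str, set[str] | list[str]],
    rescale: bool = True,
) -> dict[str, EnzymePattern]:
    """Abundance-weighted cell-wise mean of member unit-scaled fields.

    Weights are each member's summed observed relative abundance,
    normalized within the enzyme. The CV uses the unbiased weighted
    variance (reliability weights), so uniform weights reproduce the
    standardized aggregation exactly. The aggregated pattern is
    rescaled to [0, 1] across cells (the raw weighted mean is kept in
    ``raw``).
    """
    w_all = cluster_weights(abundance)
    out = {}
    for enzyme in emap:
        members = _member_fields(fields, emap, enzyme)
        ids = [m.cluster_id for m in members]
        w = w_all.reindex(ids).to_numpy(dtype=float)
        if np.isnan(w).any() or (w < 0).any():
            raise ValueError(f"missing or negative weights for enzyme {enzyme!r}")
        if w.sum() <= 0:
            raise ValueError(f"all-zero weights for enzyme {enzyme!r}")
        w = w / w.sum()
        stack = _stack(members)
        mean = np.tensordot(w, stack, axes=(0, 0))
        denom = 1.0 - np.sum(w**2)
        if denom > 0:
            var = np.tensordot(w, (stack - mean[None]) ** 2, axes=(0, 0)) / denom
            sd = np.sqrt(var)
        else:
            sd = np.zeros_like(mean)  # single effective member
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean > MEAN_FLOOR, 100.0 * sd / mean, np.nan)

        raw = mean.copy()
        rescaled = False
        if rescale:
            lo, hi = np.nanmin(mean), np.nanmax(mean)
            if hi - lo > 0:
                mean = (mean - lo) / (hi - lo)
                rescaled = True
        template = members[0].mean
        coords, dims = template.coords, template.dims
        out[enzyme] = EnzymePattern(
            enzyme=enzyme,
            potential=xr.DataArray(mean, coords=coords, dims=dims),
            cv=xr.DataArray(cv, coords=coords, dims=dims),
            mode="weighted",
            raw=xr.DataArray(raw, coords=coords, dims=dims),
            rescaled=rescaled,
        )
    return out


def pattern_correlations(patterns: dict[str, EnzymePattern] | dict[str, xr.DataArray]) -> pd.DataFrame:
    """Pairwise Pearson correlation of patterns over common unmasked cells."""
    names = sorted(patterns)
    if len(names) < 2:
        raise ValueError("need at least 2 patterns")
    arrays = {
        k: (v.potential if isinstance(v, EnzymePattern) else v).to_numpy().ravel()
        for k, v in patterns.items()
    }
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            x, y = arrays[a], arrays[b]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                r = np.nan
            else:
                r = float(np.corrcoef(x[ok], y[ok])[0, 1])
            out.loc[a, b] = out.loc[b, a] = r
    return out


def patterns_to_netcdf(patterns: dict[str, EnzymePattern], path) -> None:
    data = {}
    for name, p in patterns.items():
        data[f"{name}_potential"] = p.potential
        data[f"{name}_cv"] = p.cv
    ds = xr.Dataset(data)
    modes = {p.mode for p in patterns.values()}
    ds.attrs["mode"] = ",".join(sorted(modes))
    ds.attrs["rescaled"] = ",".join(name for name, p in patterns.items() if p.rescaled)
    ds.to_netcdf(path, engine="scipy")
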