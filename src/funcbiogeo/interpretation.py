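"""Model interpretation: importances, partial dependence, pattern groups.

Variable importance accumulates each split's loss gain onto its feature
(split counts scaled by gain) and normalizes to percent. Partial
dependence is the marginal mean prediction over a grid of one feature
with all other features held at their observed values. MAG-level
projections are grouped by Ward hierarchical clustering of their cell
vectors and groups correlated against enzyme patterns; the taxonomic
composition of a set of clusters is weighted by observed relative
abundance and summarized with the Shannon index (natural log).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .aggregation import EnzymePattern, pattern_correlations
from .mbtr import BoostedEnsemble, predict
from .preprocessing import AbundanceMatrix
from .projection import ProjectionField

__all__ = [
    "ImportanceReport",
    "TaxonomicProfile",
    "variable_importance",
    "partial_dependence",
    "cluster_mag_patterns",
    "correlate_groups_with_enzymes",
    "taxonomic_composition",
]


@dataclass
class ImportanceReport:
    """Per-feature split-gain importance, in percent (sums to 100)."""

    importance: pd.Series

    def __post_init__(self) -> None:
        total = self.importance.sum()
        if not np.isclose(total, 100.0, atol=1e-6):
            raise ValueError(f"importances must sum to 100, got {total}")

    def top_feature(self) -> str:
        return str(self.importance.idxmax())


@dataclass
class TaxonomicProfile:
    """Class proportions (sum to 1) and Shannon diversity H = -sum p ln p."""

    proportions: pd.Series
    shannon: float


def variable_importance(
    ensembles: BoostedEnsemble | list[BoostedEnsemble],
    feature_names: list[str] | None = None,
) -> ImportanceReport:
    """Split-gain importance, averaged over ensembles after normalization."""
    if isinstance(ensembles, BoostedEnsemble):
        ensembles = [ensembles]
    if not ensembles:
        raise ValueError("need at least one fitted ensemble")
    if feature_names is None:
        feature_names = ensembles[0].feature_names
    n_feat = ensembles[0].n_features or (len(feature_names) if feature_names else 0)
    if not n_feat:
        raise ValueError("cannot infer the number of features")
    if feature_names is None:
        feature_names = [f"feature_{i}" for i in range(n_feat)]

    per_ensemble = []
    for ens in ensembles:
        gains = np.zeros(n_feat)
        for tree in ens.trees:
            for node in tree.walk():
                if not node.is_leaf:
                    gains[node.split_feature] += node.split_gain
        total = gains.sum()
        if total <= 0:
            raise ValueError("ensemble has zero total split gain")
        per_ensemble.append(100.0 * gains / total)
    mean = np.mean(per_ensemble, axis=0)
    mean = 100.0 * mean / mean.sum()
    return ImportanceReport(pd.Series(mean, index=feature_names))


def partial_dependence(
    ensemble: BoostedEnsemble,
    feature: int,
    n_grid: int,
    X_ref: np.ndarray,
    n_rounds: int | None = None,
) -> pd.DataFrame:
    """Marginal response of each target to one feature.

    For each of ``n_grid`` evenly spaced values over the feature's
    observed range, the value is substituted into every reference row,
    predictions are averaged over rows, and one curve per response
    dimension is returned (index: grid value).
    """
    X_ref = np.asarray(X_ref, dtype=float)
    if not 0 <= feature < X_ref.shape[1]:
        raise ValueError("feature index out of range")
    col = X_ref[:, feature]
    lo, hi = col.min(), col.max()
    if hi - lo <= 0:
        raise ValueError("constant feature: no range for partial dependence")
    grid = np.linspace(lo, hi, n_grid) if n_grid > 1 else np.array([0.5 * (lo + hi)])
    curves = []
    for v in grid:
        Xv = X_ref.copy()
        Xv[:, feature] = v
        curves.append(predict(ensemble, Xv, n_rounds=n_rounds).mean(axis=0))
    names = ensemble.response_names or [f"response_{j}" for j in range(len(curves[0]))]
    return pd.DataFrame(curves, index=pd.Index(grid, name="grid_value"), columns=names)


def _field_vectors(fields: dict[str, ProjectionField]) -> tuple[list[str], np.ndarray]:
    names = sorted(fields)
    mats = []
    common = None
    for n in names:
        v = fields[n].mean.to_numpy().ravel()
        ok = np.isfinite(v)
        common = ok if common is None else (common & ok)
        mats.append(v)
    M = np.stack([m[common] for m in mats], axis=0)
    return names, M


def cluster_mag_patterns(mag_fields: dict[str, ProjectionField], k: int) -> pd.Series:
    """Ward hierarchical clustering of MAG-level projection patterns.

    Flattened unmasked cell vectors, Ward criterion on Euclidean
    distances, cut at ``k`` groups. Returns MAG id -> group (1..k).
    """
    if len(mag_fields) < 2:
        raise ValueError("need at least 2 MAG fields")
    if k > len(mag_fields):
        raise ValueError("k exceeds the number of MAGs")
    names, M = _field_vectors(mag_fields)
    Z = linkage(M, method="ward")
    groups = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(groups, index=names, name="group")


def correlate_groups_with_enzymes(
    group_mean_fields: dict[str, "np.ndarray | object"],
    enzyme_patterns: dict[str, EnzymePattern],
) -> pd.DataFrame:
    """Pearson r over unmasked cells for every (group, enzyme) pair."""
    combined = {f"group:{g}": v for g, v in group_mean_fields.items()}
    combined.update({f"enzyme:{e}": p for e, p in enzyme_patterns.items()})
    full = pattern_correlations(combined)
    g_names = sorted(group_mean_fields)
    e_names = sorted(enzyme_patterns)
    return full.loc[[f"group:{g}" for g in g_names], [f"enzyme:{e}" for e in e_names]].set_axis(
        g_names, axis=0
    ).set_axis(e_names, axis=1)


def shannon_index(proportions: np.ndarray) -> float:
    p = np.asarray(proportions, dtype=float)
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def taxonomic_composition(
    cluster_set,
    abundance: AbundanceMatrix | pd.DataFrame,
    taxonomy: dict[str, dict | "pd.Series"],
) -> TaxonomicProfile:
    """Abundance-weighted taxonomic class composition of a cluster set.

    Each cluster's summed observed relative abundance is distributed
    over its member classes proportionally to the class multiset, then
    pooled and normalized; Shannon uses the natural log.
    """
    clusters = sorted(cluster_set)
    if not clusters:
        raise ValueError("empty cluster set")
    df = abundance.to_frame() if isinstance(abundance, AbundanceMatrix) else abundance
    weights = df.sum(axis=0)
    pooled: dict[str, float] = {}
    for c in clusters:
        if c not in taxonomy:
            raise ValueError(f"cluster {c!r} has no taxonomy")
        classes = taxonomy[c]
        counts = pd.Series(dict(classes), dtype=float)
        if counts.sum() <= 0:
            raise ValueError(f"cluster {c!r} has an empty class multiset")
        w = float(weights.get(c, 0.0))
        frac = counts / counts.sum()
        for cls, f in frac.items():
            pooled[cls] = pooled.get(cls, 0.0) + w * f
    props = pd.Series(pooled, dtype=float)
    total = props.sum()
    if total <= 0:
        raise ValueError("zero total abundance over the cluster set")
    props = props / total
    return TaxonomicProfile(proportions=props.sort_index(), shannon=shannon_index(props.to_numpy()))
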