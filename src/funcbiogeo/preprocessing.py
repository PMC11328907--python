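"""Protein cluster construction, selection filters and count normalization.

Clusters are connected components of a sequence similarity network (SSN):
pairwise protein alignments filtered at minimum identity and coverage,
self-hits removed. Downstream filters keep clusters whose annotated
members are exclusively target enzymes and that are detected at a
minimum number of stations; counts are normalized by gene coding length
and per-station sequencing effort, then converted to relative abundances
summing to 1 per station over the selected clusters.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Cluster",
    "AbundanceMatrix",
    "read_edge_list",
    "build_clusters_from_edges",
    "attach_gene_metadata",
    "select_exclusive_clusters",
    "counts_to_cluster_table",
    "filter_min_stations",
    "normalize_counts",
    "compare_fractions",
]


@dataclass
class Cluster:
    """A protein functional cluster (SSN connected component or singleton)."""

    cluster_id: str
    member_genes: set[str]
    annotations: set[str] = field(default_factory=set)
    taxa: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if not self.member_genes:
            raise ValueError("a cluster needs at least one member gene")


@dataclass
class AbundanceMatrix:
    """Stations × clusters relative abundances; every row sums to 1."""

    values: np.ndarray
    station_ids: list
    cluster_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("negative entries in abundance matrix")
        rowsum = self.values.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-9):
            raise ValueError("abundance rows must sum to 1 within 1e-9")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.station_ids, columns=self.cluster_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AbundanceMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), [str(c) for c in df.columns])

    def to_tsv(self, path) -> None:
        self.to_frame().rename_axis("station_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "AbundanceMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))


def read_edge_list(path) -> pd.DataFrame:
    """Read a similarity edge list TSV (qseqid, sseqid, pident, qcovhsp)."""
    df = pd.read_csv(path, sep="\t")
    expected = {"qseqid", "sseqid", "pident", "qcovhsp"}
    if not expected <= set(df.columns):
        # headerless protein-search output: assume the 4-column dialect
        df = pd.read_csv(path, sep="\t", header=None, names=["qseqid", "sseqid", "pident", "qcovhsp"])
    return df


def build_clusters_from_edges(
    edges: pd.DataFrame,
    all_genes: set[str],
    identity_min: float = 80.0,
    coverage_min: float = 80.0,
) -> list[Cluster]:
    """Connected components of the filtered similarity graph.

    Removes self-hits and edges below either the identity or the coverage
    threshold (percent scale); genes left without any surviving edge
    become singleton clusters. Cluster ids are assigned in order of each
    component's lexicographically smallest member, so the labelling is
    deterministic.
    """
    if not (0 <= identity_min <= 100 and 0 <= coverage_min <= 100):
        raise ValueError("thresholds must lie in [0, 100]")
    referenced = set(edges["qseqid"]) | set(edges["sseqid"])
    unknown = referenced - set(all_genes)
    if unknown:
        raise ValueError(f"edges reference genes absent from all_genes: {sorted(unknown)[:5]}")

    keep = (
        (edges["qseqid"] != edges["sseqid"])
        & (edges["pident"] >= identity_min)
        & (edges["qcovhsp"] >= coverage_min)
    )
    g = nx.Graph()
    g.add_nodes_from(all_genes)
    g.add_edges_from(edges.loc[keep, ["qseqid", "sseqid"]].itertuples(index=False, name=None))

    components = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    return [
        Cluster(cluster_id=f"PFC{i:04d}", member_genes=set(members))
        for i, members in enumerate(components, start=1)
    ]


def attach_gene_metadata(clusters: list[Cluster], genes: pd.DataFrame) -> list[Cluster]:
    """Fill cluster annotations and taxa from a gene metadata table.

    Expects columns gene_id, annotation (empty string = unannotated) and
    tax_class. Mutates and returns ``clusters``.
    """
    meta = genes.set_index("gene_id")
    for cl in clusters:
        members = sorted(cl.member_genes & set(meta.index))
        ann = set(meta.loc[members, "annotation"]) - {""} if members else set()
        cl.annotations = {a for a in ann if isinstance(a, str)}
        if "tax_class" in meta.columns and members:
            cl.taxa = Counter(meta.loc[members, "tax_class"])
    return clusters


def select_exclusive_clusters(
    clusters: list[Cluster],
    target_annotations: set[str],
    genes: pd.DataFrame | None = None,
) -> list[Cluster]:
    """Keep clusters whose annotated members carry only target annotations.

    Members without any annotation are neutral; clusters with zero
    annotated members are dropped (nothing ties them to the targets).
    When ``genes`` is given, exclusivity is checked per member gene;
    otherwise the cluster's pooled annotation set is used.
    """
    if not target_annotations:
        raise ValueError("target_annotations must be non-empty")
    kept = []
    if genes is not None:
        ann = genes.set_index("gene_id")["annotation"]
    for cl in clusters:
        if genes is not None:
            member_ann = [
                a for a in ann.reindex(sorted(cl.member_genes)).dropna() if a != ""
            ]
            annotations = set(member_ann)
        else:
            annotations = cl.annotations
        if not annotations:
            continue
        if annotations <= target_annotations:
            kept.append(cl)
    return kept


def counts_to_cluster_table(counts: pd.DataFrame, cluster_map: pd.Series) -> pd.DataFrame:
    """Sum a station × gene count table into a station × cluster table."""
    common = counts.columns.intersection(cluster_map.index)
    return counts[common].T.groupby(cluster_map.loc[common]).sum().T


def filter_min_stations(matrix: pd.DataFrame, min_stations: int = 10) -> pd.DataFrame:
    """Drop columns detected (count > 0) at fewer than ``min_stations`` stations."""
    if min_stations < 1:
        raise ValueError("min_stations must be >= 1")
    detected = (matrix > 0).sum(axis=0)
    survivors = detected.index[detected >= min_stations]
    if len(survivors) == 0:
        raise ValueError(f"no clusters survive the >= {min_stations}-station detection filter")
    return matrix[survivors]


def normalize_counts(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    cluster_map: pd.Series,
    selected_clusters: list[str] | None = None,
) -> tuple[AbundanceMatrix, dict[str, pd.DataFrame]]:
    """Length- and depth-normalize counts, then form cluster relative abundances.

    Per gene: count / coding length. Per station: divide by the total raw
    reads of that station over *all* genes (sequencing effort, including
    genes outside the selected clusters). Gene values are summed within
    clusters and each station row is finally renormalized over the
    selected clusters to sum to 1. Stations with zero reads across the
    selected clusters are excluded with a warning.

    Returns the :class:`AbundanceMatrix` and the intermediate matrices
    (``rate`` = length-normalized, ``normalized`` = after depth division,
    ``cluster`` = per-cluster before row renormalization).
    """
    lengths = gene_lengths.reindex(counts.columns)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive coding length")
    station_totals = counts.sum(axis=1)
    if (station_totals <= 0).any():
        raise ValueError("every station needs a positive total read count")

    rate = counts / lengths
    normalized = rate.div(station_totals, axis=0)
    cluster_table = counts_to_cluster_table(normalized, cluster_map)
    if selected_clusters is not None:
        missing = set(selected_clusters) - set(cluster_table.columns)
        if missing:
            raise ValueError(f"selected clusters absent from counts: {sorted(missing)[:5]}")
        cluster_table = cluster_table[list(selected_clusters)]

    rowsum = cluster_table.sum(axis=1)
    dead = rowsum.index[rowsum <= 0]
    if len(dead):
        warnings.warn(
            f"excluding {len(dead)} station(s) with zero reads over selected clusters: "
            f"{list(dead)[:5]}",
            stacklevel=2,
        )
        cluster_table = cluster_table.drop(index=dead)
        rowsum = rowsum.drop(index=dead)
    rel = cluster_table.div(rowsum, axis=0)
    intermediates = {"rate": rate, "normalized": normalized, "cluster": cluster_table}
    return AbundanceMatrix.from_frame(rel), intermediates


def compare_fractions(counts_A: pd.DataFrame, counts_B: pd.DataFrame) -> dict:
    """Compare two size-fraction count tables over their shared stations.

    Reports the percentage of clusters detected in B that are also
    detected in A, the percentage of B's reads those shared clusters
    carry, Pearson/Spearman correlations of per-cluster total reads at
    shared stations, and a chi-square test comparing the two per-cluster
    count distributions.
    """
    shared = counts_A.index.intersection(counts_B.index)
    if len(shared) < 2:
        raise ValueError("need at least 2 shared stations")
    A = counts_A.loc[shared]
    B = counts_B.loc[shared]

    det_A = set(A.columns[(A > 0).any(axis=0)])
    det_B = set(B.columns[(B > 0).any(axis=0)])
    both = det_A & det_B
    pct_detected = 100.0 * len(both) / len(det_B) if det_B else np.nan
    reads_B = B.sum().sum()
    pct_reads = 100.0 * B[sorted(both)].sum().sum() / reads_B if reads_B > 0 else np.nan

    clusters = sorted(set(A.columns) | set(B.columns))
    ta = A.reindex(columns=clusters, fill_value=0).sum(axis=0).to_numpy(dtype=float)
    tb = B.reindex(columns=clusters, fill_value=0).sum(axis=0).to_numpy(dtype=float)
    pearson = stats.pearsonr(ta, tb)
    spearman = stats.spearmanr(ta, tb)

    table = np.vstack([ta, tb])
    nonzero = table.sum(axis=0) > 0
    chi2, p, dof, expected = stats.chi2_contingency(table[:, nonzero], correction=False)
    if (expected < 5).any():
        warnings.warn("chi-square expected counts < 5; test may be unreliable", stacklevel=2)

    return {
        "pct_B_clusters_detected_in_A": pct_detected,
        "pct_B_reads_in_shared_clusters": pct_reads,
        "pearson_r": float(pearson.statistic),
        "pearson_p": float(pearson.pvalue),
        "spearman_r": float(spearman.statistic),
        "spearman_p": float(spearman.pvalue),
        "chi2": float(chi2),
        "chi2_p": float(p),
        "chi2_dof": int(dof),
        "n_shared_stations": int(len(shared)),
    }
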