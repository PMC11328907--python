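import numpy as np
import pandas as pd
import pytest

from funcbiogeo.preprocessing import (
    AbundanceMatrix,
    Cluster,
    attach_gene_metadata,
    build_clusters_from_edges,
    compare_fractions,
    counts_to_cluster_table,
    filter_min_stations,
    normalize_counts,
    select_exclusive_clusters,
)

from _oracles import chi_square_direct, union_find_components


def edges_frame(rows):
    return pd.DataFrame(rows, columns=["qseqid", "sseqid", "pident", "qcovhsp"])


class TestBuildClusters:
    def test_threshold_filters_weak_edge(self):
        edges = edges_frame([("A", "B", 85.0, 90.0), ("B", "C", 70.0, 90.0)])
        clusters = build_clusters_from_edges(edges, {"A", "B", "C"}, 80, 80)
        parts = {frozenset(c.member_genes) for c in clusters}
        assert parts == {frozenset({"A", "B"}), frozenset({"C"})}

    def test_self_hit_yields_singleton(self):
        edges = edges_frame([("A", "A", 100.0, 100.0)])
        clusters = build_clusters_from_edges(edges, {"A"}, 80, 80)
        assert [c.member_genes for c in clusters] == [{"A"}]

    def test_unknown_gene_rejected(self):
        edges = edges_frame([("A", "Z", 90.0, 90.0)])
        with pytest.raises(ValueError, match="absent"):
            build_clusters_from_edges(edges, {"A"}, 80, 80)

    def test_random_graph_matches_union_find_oracle(self, rng):
        genes = [f"g{i}" for i in range(30)]
        rows = []
        for _ in range(60):
            a, b = rng.choice(genes, size=2, replace=False)
            rows.append((a, b, float(rng.uniform(50, 100)), float(rng.uniform(50, 100))))
        edges = edges_frame(rows)
        clusters = build_clusters_from_edges(edges, set(genes), 80, 80)
        kept = [
            (r.qseqid, r.sseqid)
            for r in edges.itertuples(index=False)
            if r.qseqid != r.sseqid and r.pident >= 80 and r.qcovhsp >= 80
        ]
        expected = union_find_components(genes, kept)
        assert {frozenset(c.member_genes) for c in clusters} == expected

    def test_partition_property(self, rng):
        genes = {f"g{i}" for i in range(20)}
        rows = [
            (f"g{rng.integers(20)}", f"g{rng.integers(20)}", 90.0, 90.0) for _ in range(30)
        ]
        clusters = build_clusters_from_edges(edges_frame(rows), genes, 80, 80)
        seen = [g for c in clusters for g in c.member_genes]
        assert sorted(seen) == sorted(genes)


class TestExclusivity:
    def test_target_only_cluster_kept(self):
        cl = Cluster("c1", {"a"}, annotations={"PEPC"})
        assert select_exclusive_clusters([cl], {"PEPC", "RUBISCO"}) == [cl]

    def test_mixed_annotation_dropped(self):
        cl = Cluster("c1", {"a", "b"}, annotations={"PEPC", "other-pathway"})
        assert select_exclusive_clusters([cl], {"PEPC", "RUBISCO"}) == []

    def test_unannotated_members_neutral_but_fully_unannotated_dropped(self):
        kept = Cluster("c1", {"a", "b"}, annotations={"RUBISCO"})
        empty = Cluster("c2", {"c"}, annotations=set())
        result = select_exclusive_clusters([kept, empty], {"RUBISCO"})
        assert result == [kept]

    def test_known_nonexclusive_fraction_survives(self, env_specs):
        from funcbiogeo.synthetic import generate_community
        from funcbiogeo.pipeline import generate_edge_list

        genes, truth = generate_community(
            5, 10, 3, seed=2, env_specs=env_specs, fraction_nonexclusive=0.3
        )
        edges = generate_edge_list(truth, seed=2)
        clusters = build_clusters_from_edges(edges, set(genes["gene_id"]))
        attach_gene_metadata(clusters, genes)
        targets = {e for v in truth.enzyme_labels.values() for e in v} - {"other_pathway"}
        assert len(select_exclusive_clusters(clusters, targets)) == 7

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            select_exclusive_clusters([], set())


class TestMinStations:
    def test_nine_of_ten_removed(self):
        counts = pd.DataFrame(
            {"keep": np.ones(12, dtype=int), "drop": [1] * 9 + [0] * 3}
        )
        out = filter_min_stations(counts, 10)
        assert list(out.columns) == ["keep"]

    def test_min_one_keeps_everything_detected(self, small_counts):
        assert filter_min_stations(small_counts, 1).shape == small_counts.shape

    def test_toy_table_matches_enumeration(self):
        counts = pd.DataFrame(
            [[1, 0, 2, 0], [3, 1, 0, 0], [0, 2, 0, 0], [1, 0, 0, 0], [2, 0, 0, 1]],
            columns=list("abcd"),
        )
        detected = {"a": 4, "b": 2, "c": 1, "d": 1}
        for m in (1, 2, 4):
            out = filter_min_stations(counts, m)
            assert set(out.columns) == {c for c, n in detected.items() if n >= m}

    def test_no_survivors_is_explicit_error(self):
        counts = pd.DataFrame({"a": [1, 0], "b": [0, 1]})
        with pytest.raises(ValueError, match="no clusters survive"):
            filter_min_stations(counts, 2)


class TestNormalize:
    def test_length_weighting_hand_example(self):
        counts = pd.DataFrame({"g1": [10], "g2": [10]}, index=["s1"])
        lengths = pd.Series({"g1": 100.0, "g2": 200.0})
        cmap = pd.Series({"g1": "c1", "g2": "c2"})
        ab, _ = normalize_counts(counts, lengths, cmap)
        np.testing.assert_allclose(ab.values[0], [2 / 3, 1 / 3])

    def test_rows_sum_to_one(self, small_counts, small_community):
        _, truth = small_community
        ab, _ = normalize_counts(small_counts, truth.gene_lengths, truth.gene_assignments)
        assert np.allclose(ab.values.sum(axis=1), 1.0, atol=1e-9)

    def test_scale_invariance_of_station_row(self, small_counts, small_community):
        _, truth = small_community
        ab1, _ = normalize_counts(small_counts, truth.gene_lengths, truth.gene_assignments)
        doubled = small_counts.copy()
        doubled.iloc[0] = doubled.iloc[0] * 2
        ab2, _ = normalize_counts(doubled, truth.gene_lengths, truth.gene_assignments)
        np.testing.assert_allclose(ab1.values[0], ab2.values[0], atol=1e-12)

    def test_zero_selected_station_excluded_with_warning(self):
        counts = pd.DataFrame({"g1": [5, 0], "g2": [0, 7]}, index=["s1", "s2"])
        lengths = pd.Series({"g1": 100.0, "g2": 100.0})
        cmap = pd.Series({"g1": "c1", "g2": "c2"})
        with pytest.warns(UserWarning, match="zero reads"):
            ab, _ = normalize_counts(counts, lengths, cmap, selected_clusters=["c1"])
        assert ab.station_ids == ["s1"]

    def test_station_reordering_commutes(self, small_counts, small_community):
        _, truth = small_community
        ab1, _ = normalize_counts(small_counts, truth.gene_lengths, truth.gene_assignments)
        shuffled = small_counts.sample(frac=1.0, random_state=0)
        ab2, _ = normalize_counts(shuffled, truth.gene_lengths, truth.gene_assignments)
        pd.testing.assert_frame_equal(
            ab1.to_frame().sort_index(), ab2.to_frame().sort_index()
        )


class TestAbundanceMatrix:
    def test_row_sum_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            AbundanceMatrix(np.array([[0.5, 0.4]]), ["s1"], ["a", "b"])

    def test_tsv_round_trip(self, toy_abundance, tmp_path):
        m = AbundanceMatrix.from_frame(toy_abundance)
        path = tmp_path / "ab.tsv"
        m.to_tsv(path)
        back = AbundanceMatrix.from_tsv(path)
        np.testing.assert_allclose(m.values, back.values)
        assert back.cluster_ids == m.cluster_ids


class TestCompareFractions:
    def test_identical_tables(self):
        counts = pd.DataFrame(
            {"a": [3, 1, 4], "b": [0, 2, 2], "c": [5, 5, 0]}, index=["s1", "s2", "s3"]
        )
        rep = compare_fractions(counts, counts)
        assert rep["pct_B_clusters_detected_in_A"] == 100.0
        assert rep["pct_B_reads_in_shared_clusters"] == 100.0
        assert rep["pearson_r"] == pytest.approx(1.0)
        assert rep["spearman_r"] == pytest.approx(1.0)

    def test_independent_tables_uncorrelated(self, rng):
        n = 200
        idx = [f"s{i}" for i in range(25)]
        cols = [f"c{j}" for j in range(n)]
        A = pd.DataFrame(rng.poisson(5, size=(25, n)), index=idx, columns=cols)
        B = pd.DataFrame(rng.poisson(5, size=(25, n)), index=idx, columns=cols)
        rep = compare_fractions(A, B)
        assert abs(rep["pearson_r"]) < 0.2

    def test_chi_square_matches_textbook_formula(self):
        A = pd.DataFrame({"a": [10, 5], "b": [20, 5], "c": [5, 5]}, index=["s1", "s2"])
        B = pd.DataFrame({"a": [8, 2], "b": [12, 18], "c": [10, 10]}, index=["s1", "s2"])
        rep = compare_fractions(A, B)
        table = np.vstack([A.sum(axis=0).to_numpy(), B.sum(axis=0).to_numpy()])
        assert rep["chi2"] == pytest.approx(chi_square_direct(table), abs=1e-10)

    def test_requires_shared_stations(self):
        A = pd.DataFrame({"a": [1]}, index=["s1"])
        B = pd.DataFrame({"a": [1]}, index=["s2"])
        with pytest.raises(ValueError, match="shared stations"):
            compare_fractions(A, B)


def test_counts_to_cluster_table_sums_members():
    counts = pd.DataFrame({"g1": [1, 2], "g2": [3, 4], "g3": [5, 6]})
    cmap = pd.Series({"g1": "c1", "g2": "c1", "g3": "c2"})
    table = counts_to_cluster_table(counts, cmap)
    np.testing.assert_array_equal(table["c1"].to_numpy(), [4, 6])
    np.testing.assert_array_equal(table["c2"].to_numpy(), [5, 6])
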