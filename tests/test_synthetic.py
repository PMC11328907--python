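import numpy as np
import pandas as pd
import pytest

from funcbiogeo import synthetic
from funcbiogeo.synthetic import (
    EnvVariableSpec,
    SyntheticTruth,
    expected_relative_abundance,
    generate_community,
    generate_env_grid,
    generate_stations,
    simulate_reads,
)


def _ocean(grid, layer):
    return grid[layer].to_numpy()[grid["mask"].to_numpy() == 1]


class TestEnvGrid:
    def test_uniform_zero_noise_equals_midpoint(self):
        spec = EnvVariableSpec("x", (10.0, 20.0), "uniform", 0.0, (0.0, 1.0))
        grid = generate_env_grid([spec], 10.0, seed=0)
        assert np.allclose(_ocean(grid, "x_mean"), 15.0)

    def test_gradient_zero_noise_monotone_in_abs_latitude(self):
        spec = EnvVariableSpec("t", (0.0, 30.0), "gradient", 0.0, (0.0, 1.0))
        grid = generate_env_grid([spec], 10.0, seed=0)
        col = grid["t_mean"].to_numpy()[:, 0]
        lat = grid["lat"].to_numpy()
        north = lat > 0
        order = np.argsort(lat[north])
        assert np.all(np.diff(col[north][order]) < 0)  # cooling away from the equator

    def test_same_seed_bit_identical(self, env_specs):
        a = generate_env_grid(env_specs, 10.0, seed=5)
        b = generate_env_grid(env_specs, 10.0, seed=5)
        for v in a.data_vars:
            np.testing.assert_array_equal(a[v].to_numpy(), b[v].to_numpy())

    def test_empty_specs_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            generate_env_grid([], 10.0, seed=0)

    def test_resolution_must_divide(self, env_specs):
        with pytest.raises(ValueError, match="divide 180"):
            generate_env_grid(env_specs, 7.0, seed=0)

    def test_netcdf_round_trip(self, small_grid, tmp_path):
        path = tmp_path / "grid.nc"
        synthetic.grid_to_netcdf(small_grid, path)
        back = synthetic.grid_from_netcdf(path)
        np.testing.assert_allclose(
            small_grid["temperature_mean"].to_numpy(), back["temperature_mean"].to_numpy()
        )
        assert back.attrs["variables"] == small_grid.attrs["variables"]


class TestStations:
    def test_count_and_ordering(self, small_grid):
        st = generate_stations(small_grid, 130, seed=1)
        assert len(st) == 130
        assert list(st["station_id"]) == list(range(1, 131))

    def test_env_vector_matches_grid_cell(self, small_grid, small_stations):
        lat = small_grid["lat"].to_numpy()
        lon = small_grid["lon"].to_numpy()
        layer = small_grid["temperature_mean"].to_numpy()
        for row in small_stations.itertuples(index=False):
            i = int(np.argmin(np.abs(lat - row.lat)))
            j = int(np.argmin(np.abs(lon - row.lon)))
            assert layer[i, j] == row.temperature_mean

    def test_consecutive_steps_bounded(self, small_grid):
        st = generate_stations(small_grid, 40, seed=3, max_step_deg=20.0)
        dlat = np.abs(np.diff(st["lat"].to_numpy()))
        dlon = np.abs(np.diff(st["lon"].to_numpy()))
        dlon = np.minimum(dlon, 360.0 - dlon)  # wrap
        assert dlat.max() <= 20.0 + 1e-9
        assert dlon.max() <= 20.0 + 1e-9

    def test_too_many_stations_rejected(self, small_grid):
        n_ocean = int((small_grid["mask"].to_numpy() == 1).sum())
        with pytest.raises(ValueError, match="ocean cells"):
            generate_stations(small_grid, n_ocean + 1, seed=0)

    def test_deterministic(self, small_grid):
        a = generate_stations(small_grid, 25, seed=9)
        b = generate_stations(small_grid, 25, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestCommunity:
    def test_nonexclusive_fraction_exact(self, env_specs):
        _, truth = generate_community(
            5, 10, 3, seed=0, env_specs=env_specs, fraction_nonexclusive=0.3
        )
        n_nonexcl = sum("other_pathway" in v for v in truth.enzyme_labels.values())
        assert n_nonexcl == 3

    def test_gene_partition(self, small_community):
        genes, truth = small_community
        assert genes["gene_id"].is_unique
        assert set(truth.gene_assignments.index) == set(genes["gene_id"])
        assert set(truth.gene_assignments) == set(truth.cluster_ids)

    def test_mag_class_labels(self, env_specs):
        genes, truth = generate_community(5, 10, 3, seed=1, env_specs=env_specs)
        assert truth.taxon_labels.nunique() == 5

    def test_zero_counts_rejected(self, env_specs):
        with pytest.raises(ValueError):
            generate_community(0, 10, 3, seed=0, env_specs=env_specs)

    def test_breadth_floor_enforced(self, small_community):
        _, truth = small_community
        bad = truth.niche_breadths.copy()
        bad.iloc[0, 0] = 0.0
        with pytest.raises(ValueError, match="breadths"):
            SyntheticTruth(
                niche_optima=truth.niche_optima,
                niche_breadths=bad,
                cluster_base_abundance=truth.cluster_base_abundance,
                gene_assignments=truth.gene_assignments,
                taxon_labels=truth.taxon_labels,
                enzyme_labels=truth.enzyme_labels,
                gene_lengths=truth.gene_lengths,
            )

    def test_truth_json_round_trip(self, small_community):
        _, truth = small_community
        back = SyntheticTruth.from_json(truth.to_json())
        pd.testing.assert_frame_equal(truth.niche_optima, back.niche_optima)
        assert truth.enzyme_labels == back.enzyme_labels
        pd.testing.assert_series_equal(
            truth.archetype_labels, back.archetype_labels, check_names=False
        )


def _single_variable_truth(optima, breadths, base, n_genes_per_cluster=1, lengths=None):
    cluster_ids = [f"K{i}" for i in range(len(optima))]
    genes, assignments, glen = [], {}, {}
    g = 0
    for ci, c in enumerate(cluster_ids):
        for _ in range(n_genes_per_cluster):
            gid = f"g{g}"
            assignments[gid] = c
            glen[gid] = 1000.0 if lengths is None else lengths[g]
            g += 1
    return SyntheticTruth(
        niche_optima=pd.DataFrame({"env": optima}, index=cluster_ids),
        niche_breadths=pd.DataFrame({"env": breadths}, index=cluster_ids),
        cluster_base_abundance=pd.Series(base, index=cluster_ids),
        gene_assignments=pd.Series(assignments),
        taxon_labels=pd.Series({"M1": "class_a"}),
        enzyme_labels={c: {"E1"} for c in cluster_ids},
        gene_lengths=pd.Series(glen),
        abundance_noise_sd=0.0,
    )


def _stations_frame(env_values):
    return pd.DataFrame(
        {
            "station_id": np.arange(1, len(env_values) + 1),
            "lat": 0.0,
            "lon": 0.0,
            "env_mean": env_values,
            "env_sd": 0.0,
        }
    )


class TestSimulateReads:
    def test_single_gene_gets_full_depth(self):
        truth = _single_variable_truth([0.0], [1.0], [1.0])
        st = _stations_frame([0.0, 1.0, -2.0])
        counts = simulate_reads(st, truth, depth_per_station=500, seed=0)
        assert (counts.to_numpy() == 500).all()

    def test_depth_conserved_per_station(self, small_stations, small_community):
        _, truth = small_community
        counts = simulate_reads(small_stations, truth, depth_per_station=7_000, seed=2)
        assert (counts.sum(axis=1) == 7_000).all()

    def test_deterministic(self, small_stations, small_community):
        _, truth = small_community
        a = simulate_reads(small_stations, truth, 5_000, seed=11)
        b = simulate_reads(small_stations, truth, 5_000, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_non_finite_env_rejected(self, small_community):
        _, truth = small_community
        st = pd.DataFrame(
            {"station_id": [1, 2], "lat": 0.0, "lon": 0.0}
            | {f"{v}_mean": [np.nan, 1.0] for v in truth.variable_names}
            | {f"{v}_sd": [0.0, 0.0] for v in truth.variable_names}
        )
        with pytest.raises(ValueError, match="non-finite"):
            simulate_reads(st, truth, 100, seed=0)

    def test_dominant_cluster_follows_nearer_optimum(self):
        """With two disjoint narrow niches the cluster whose optimum is
        nearer the station's environment dominates, averaged over
        replicate draws."""
        truth = _single_variable_truth([-1.0, 1.0], [0.3, 0.3], [1.0, 1.0])
        st = _stations_frame([-0.8, 0.9])
        totals = np.zeros((2, 2))
        for rep in range(200):
            counts = simulate_reads(st, truth, 200, seed=rep)
            totals += counts.to_numpy()
        assert totals[0, 0] > totals[0, 1]  # station near -1 dominated by K0
        assert totals[1, 1] > totals[1, 0]

    def test_empirical_mean_matches_analytic_within_3se(self):
        """Relative abundance from the Gaussian response formula matches
        the multinomial mean over 500 replicates."""
        truth = _single_variable_truth([-0.5, 0.2, 1.0], [0.6, 0.8, 0.5], [1.0, 2.0, 0.7])
        st = _stations_frame([0.0])
        env = pd.DataFrame({"env": [0.0]}, index=[1])
        expected = expected_relative_abundance(env, truth).to_numpy()[0]
        depth = 2_000
        reps = 500
        draws = np.zeros((reps, 3))
        for rep in range(reps):
            draws[rep] = simulate_reads(st, truth, depth, seed=rep).to_numpy()[0] / depth
        se = draws.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(draws.mean(axis=0) - expected) <= 3 * se + 1e-12)
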