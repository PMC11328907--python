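"""Synthetic ocean metagenomics data with known niche structure.

Generates the four inputs the projection pipeline consumes — gridded
environmental climatologies, a cruise-like station trajectory, a
MAG/gene/cluster community, and per-station read counts — together with
the ground truth (niche optima, breadths, base abundances) needed for
parameter-recovery tests.

The generative model is deliberately simple and fully documented in
``docs/methods.md``: each protein cluster responds to the environment
through a product of independent Gaussian niche responses, station-level
expected cluster signals are perturbed by lognormal noise, and realized
read counts are drawn from a single multinomial per station at fixed
sequencing depth, with gene-level expectations proportional to
cluster signal times gene coding length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "EnvVariableSpec",
    "SyntheticTruth",
    "generate_env_grid",
    "generate_stations",
    "generate_community",
    "simulate_reads",
    "expected_cluster_signal",
    "expected_relative_abundance",
    "grid_to_netcdf",
    "grid_from_netcdf",
]

_BREADTH_FLOOR = 1e-6

_SHAPES = ("gradient", "bell", "uniform")


@dataclass(frozen=True)
class EnvVariableSpec:
    """One synthetic environmental climatology variable.

    Parameters
    ----------
    name:
        Variable label; grid layers are named ``<name>_mean`` and
        ``<name>_sd``.
    mean_range:
        (min, max) of the yearly-mean layer, in variable units.
    latitudinal_shape:
        ``gradient`` (monotone in \\|latitude\\|, e.g. temperature),
        ``bell`` (peaked at the equator) or ``uniform``.
    noise_sd:
        SD of the iid cell-level noise added to both layers, same units.
    seasonality_range:
        (min, max) of the yearly-SD (seasonality) layer; seasonality
        increases with \\|latitude\\| within this range.
    structure_amplitude:
        Amplitude, as a fraction of the mean range, of a smooth seeded
        lat-lon random field added to the mean layer — the regional
        (non-latitudinal) structure real climatologies have. Zero by
        default, so purely latitudinal constructions stay exact.
    """

    name: str
    mean_range: tuple[float, float]
    latitudinal_shape: str = "gradient"
    noise_sd: float = 0.0
    seasonality_range: tuple[float, float] = (0.0, 1.0)
    structure_amplitude: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.mean_range
        if not lo < hi:
            raise ValueError(f"mean_range must satisfy min < max, got {self.mean_range}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.latitudinal_shape not in _SHAPES:
            raise ValueError(
                f"latitudinal_shape must be one of {_SHAPES}, got {self.latitudinal_shape!r}"
            )


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated community.

    ``niche_optima`` and ``niche_breadths`` are cluster × variable frames
    in variable units; breadths are strictly positive. ``enzyme_labels``
    maps each cluster to its functional annotation set; clusters flagged
    non-exclusive additionally carry the ``"other_pathway"`` label.
    """

    niche_optima: pd.DataFrame
    niche_breadths: pd.DataFrame
    cluster_base_abundance: pd.Series
    gene_assignments: pd.Series  # gene_id -> cluster_id
    taxon_labels: pd.Series  # mag_id -> taxonomic class
    enzyme_labels: dict[str, set[str]]
    gene_lengths: pd.Series = field(default_factory=pd.Series)
    abundance_noise_sd: float = 0.10
    archetype_labels: pd.Series = field(default_factory=pd.Series)  # cluster -> archetype

    def __post_init__(self) -> None:
        if (self.niche_breadths.to_numpy() < _BREADTH_FLOOR).any():
            raise ValueError(f"niche breadths must be >= {_BREADTH_FLOOR}")
        if (self.cluster_base_abundance.to_numpy() <= 0).any():
            raise ValueError("cluster base abundances must be strictly positive")
        counts = self.gene_assignments.value_counts()
        missing = set(self.niche_optima.index) - set(counts.index)
        if missing:
            raise ValueError(f"clusters without genes: {sorted(missing)}")

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.niche_optima.index)

    @property
    def variable_names(self) -> list[str]:
        return list(self.niche_optima.columns)

    def to_json(self) -> str:
        return json.dumps(
            {
                "niche_optima": self.niche_optima.to_dict(orient="index"),
                "niche_breadths": self.niche_breadths.to_dict(orient="index"),
                "cluster_base_abundance": self.cluster_base_abundance.to_dict(),
                "gene_assignments": self.gene_assignments.to_dict(),
                "taxon_labels": self.taxon_labels.to_dict(),
                "enzyme_labels": {k: sorted(v) for k, v in self.enzyme_labels.items()},
                "gene_lengths": self.gene_lengths.to_dict(),
                "abundance_noise_sd": self.abundance_noise_sd,
                "archetype_labels": self.archetype_labels.to_dict(),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            niche_optima=pd.DataFrame.from_dict(d["niche_optima"], orient="index"),
            niche_breadths=pd.DataFrame.from_dict(d["niche_breadths"], orient="index"),
            cluster_base_abundance=pd.Series(d["cluster_base_abundance"]),
            gene_assignments=pd.Series(d["gene_assignments"]),
            taxon_labels=pd.Series(d["taxon_labels"]),
            enzyme_labels={k: set(v) for k, v in d["enzyme_labels"].items()},
            gene_lengths=pd.Series(d["gene_lengths"]),
            abundance_noise_sd=d.get("abundance_noise_sd", 0.10),
            archetype_labels=pd.Series(d.get("archetype_labels", {}), dtype=object),
        )


def _latitudinal_base(spec: EnvVariableSpec, lat: np.ndarray) -> np.ndarray:
    lo, hi = spec.mean_range
    frac = np.abs(lat) / 90.0
    if spec.latitudinal_shape == "uniform":
        return np.full_like(lat, 0.5 * (lo + hi))
    if spec.latitudinal_shape == "gradient":
        # warm at the equator, cold at the poles: strictly monotone in |lat|
        return hi - (hi - lo) * frac
    # bell centred on the equator
    return lo + (hi - lo) * np.exp(-((lat / 30.0) ** 2))


def generate_env_grid(
    specs: list[EnvVariableSpec],
    grid_resolution: float = 4.0,
    seed: int = 0,
    land_lat: float = 72.0,
) -> xr.Dataset:
    """Build a gridded climatology with a synthetic land/ocean mask.

    One ``<var>_mean`` and one ``<var>_sd`` layer per variable, plus a
    ``mask`` layer (1 = ocean, 0 = land; polar caps beyond ``land_lat``
    are land). Deterministic for a fixed seed.
    """
    if not specs:
        raise ValueError("at least one EnvVariableSpec is required")
    if 180.0 % grid_resolution != 0:
        raise ValueError(f"grid_resolution must divide 180 evenly, got {grid_resolution}")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate variable names in specs")

    rng = np.random.default_rng(seed)
    lat = np.arange(-90 + grid_resolution / 2, 90, grid_resolution)
    lon = np.arange(-180 + grid_resolution / 2, 180, grid_resolution)
    lat2d = np.repeat(lat[:, None], lon.size, axis=1)

    mask = (np.abs(lat2d) <= land_lat).astype(np.int8)

    lon2d = np.repeat(lon[None, :], lat.size, axis=0)
    data = {}
    for spec in specs:
        base = _latitudinal_base(spec, lat2d)
        if spec.structure_amplitude > 0:
            base = base + _smooth_field(rng, lat2d, lon2d) * (
                spec.structure_amplitude * (spec.mean_range[1] - spec.mean_range[0])
            )
        mean_layer = base + rng.normal(0.0, spec.noise_sd, size=base.shape)
        smin, smax = spec.seasonality_range
        sd_base = smin + (smax - smin) * np.abs(lat2d) / 90.0
        sd_layer = sd_base + rng.normal(0.0, spec.noise_sd, size=base.shape)
        sd_layer = np.maximum(sd_layer, 0.0)
        data[f"{spec.name}_mean"] = (("lat", "lon"), mean_layer)
        data[f"{spec.name}_sd"] = (("lat", "lon"), sd_layer)
    data["mask"] = (("lat", "lon"), mask)

    grid = xr.Dataset(data, coords={"lat": lat, "lon": lon})
    grid.attrs["variables"] = names
    grid.attrs["resolution_deg"] = grid_resolution
    return grid


def grid_to_netcdf(grid: xr.Dataset, path) -> None:
    g = grid.copy()
    # NetCDF3 global attrs must be scalar strings; the name "variables"
    # collides with the scipy backend's internals, hence the rename
    g.attrs = dict(grid.attrs)
    g.attrs["env_variables"] = ",".join(grid.attrs.get("variables", []))
    g.attrs.pop("variables", None)
    g.to_netcdf(path, engine="scipy")


def grid_from_netcdf(path) -> xr.Dataset:
    g = xr.open_dataset(path, engine="scipy").load()
    if isinstance(g.attrs.get("env_variables"), str):
        g.attrs["variables"] = g.attrs.pop("env_variables").split(",")
    return g


def _smooth_field(rng: np.random.Generator, lat2d: np.ndarray, lon2d: np.ndarray) -> np.ndarray:
    """Smooth random field of unit scale: a few low-frequency sinusoids."""
    field2d = np.zeros_like(lat2d)
    for _ in range(4):
        f_lat = rng.integers(1, 4)
        f_lon = rng.integers(1, 4)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.3, 1.0)
        field2d += amp * np.sin(
            2 * np.pi * (f_lat * lat2d / 180.0 + f_lon * lon2d / 360.0) + phase
        )
    return field2d / 2.0


def _ocean_cells(grid: xr.Dataset) -> np.ndarray:
    return np.argwhere(grid["mask"].to_numpy() == 1)


def generate_stations(
    grid: xr.Dataset,
    n_stations: int = 130,
    seed: int = 0,
    max_step_deg: float = 16.0,
) -> pd.DataFrame:
    """Place stations along a spatially autocorrelated random-walk path.

    Stations occupy distinct ocean cells; consecutive stations are within
    ``max_step_deg`` in both latitude and longitude (longitude wraps), so
    contiguous blocks of station ids are spatially coherent — the property
    block cross-validation relies on. The walk drifts persistently in
    longitude (an expedition-like transect that can circumnavigate)
    while wandering freely in latitude. ``station_id`` is 1-based path
    order.
    """
    if n_stations < 2:
        raise ValueError("n_stations must be >= 2")
    ocean = _ocean_cells(grid)
    if len(ocean) < n_stations:
        raise ValueError(f"grid has {len(ocean)} ocean cells < {n_stations} stations")

    res = float(grid.attrs.get("resolution_deg", abs(float(grid.lat[1] - grid.lat[0]))))
    step_cells = max(1, int(max_step_deg / res))
    nlat = grid.sizes["lat"]
    nlon = grid.sizes["lon"]
    mask = grid["mask"].to_numpy() == 1

    rng = np.random.default_rng(seed)
    drift = int(rng.choice([-1, 1]))  # persistent east/west heading
    start = ocean[rng.integers(len(ocean))]
    path = [tuple(start)]
    visited = {tuple(start)}
    while len(path) < n_stations:
        i, j = path[-1]
        candidates = []
        for di in range(-step_cells, step_cells + 1):
            ii = i + di
            if not 0 <= ii < nlat:
                continue
            for dj in range(1, step_cells + 1):
                jj = (j + drift * dj) % nlon
                if mask[ii, jj] and (ii, jj) not in visited:
                    candidates.append((ii, jj))
        if not candidates:
            # allow sideways/backwards moves when the heading is blocked
            for di in range(-step_cells, step_cells + 1):
                ii = i + di
                if not 0 <= ii < nlat:
                    continue
                for dj in range(-step_cells, step_cells + 1):
                    if di == 0 and dj == 0:
                        continue
                    jj = (j + dj) % nlon
                    if mask[ii, jj] and (ii, jj) not in visited:
                        candidates.append((ii, jj))
        if not candidates:
            # dead end: restart from the unvisited ocean cell nearest the path end
            remaining = [tuple(c) for c in ocean if tuple(c) not in visited]
            remaining.sort(key=lambda c: (abs(c[0] - i) + min(abs(c[1] - j), nlon - abs(c[1] - j))))
            candidates = remaining[:1]
        nxt = candidates[rng.integers(len(candidates))]
        path.append(nxt)
        visited.add(nxt)

    lat = grid["lat"].to_numpy()
    lon = grid["lon"].to_numpy()
    rows = []
    layer_names = [v for v in grid.data_vars if v != "mask"]
    layers = {v: grid[v].to_numpy() for v in layer_names}
    for order, (i, j) in enumerate(path, start=1):
        row = {"station_id": order, "lat": lat[i], "lon": lon[j]}
        for v in layer_names:
            row[v] = layers[v][i, j]
        rows.append(row)
    stations = pd.DataFrame(rows)
    if not np.isfinite(stations[layer_names].to_numpy()).all():
        raise ValueError("non-finite environmental values at stations")
    return stations


def generate_community(
    n_mags: int = 30,
    n_clusters: int = 40,
    n_enzymes: int = 5,
    seed: int = 0,
    env_specs: list[EnvVariableSpec] | None = None,
    fraction_nonexclusive: float = 0.3,
    genes_per_cluster: tuple[int, int] = (2, 6),
    gene_length_range: tuple[int, int] = (300, 3000),
    annotated_fraction: float = 0.7,
    dominant_variable: str | None = None,
    abundance_noise_sd: float = 0.10,
    n_archetypes: int = 8,
    optimum_jitter_frac: float = 0.04,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a MAG/gene/cluster community with Gaussian niche truth.

    Returns gene metadata (gene_id, mag_id, length, annotation, tax_class,
    cluster_id) and the :class:`SyntheticTruth`. Each cluster carries one
    enzyme annotation; ``round(fraction_nonexclusive * n_clusters)``
    clusters additionally annotate one member with ``"other_pathway"`` to
    exercise the exclusivity filter downstream.

    Clusters are jittered copies of ``n_archetypes`` archetypal niches:
    archetype optima are uniform within each variable's mean range and
    each cluster perturbs them by ``optimum_jitter_frac`` of the range.
    This redundancy (many clusters, few independent spatial patterns)
    is the structure variance-based cluster selection and CA
    nearest-neighbour reconstruction rely on. One *dominant* variable
    (default: the first spec) gets narrow niche breadths so it drives
    the abundance patterns; the others get broad ones.
    """
    if min(n_mags, n_clusters, n_enzymes) < 1:
        raise ValueError("n_mags, n_clusters and n_enzymes must be >= 1")
    if not n_clusters >= n_enzymes:
        raise ValueError("need n_clusters >= n_enzymes")
    if env_specs is None:
        env_specs = default_env_specs()
    n_archetypes = min(n_archetypes, n_clusters)
    rng = np.random.default_rng(seed)

    cluster_ids = [f"PFC{i:04d}" for i in range(1, n_clusters + 1)]
    mag_ids = [f"MAG{i:03d}" for i in range(1, n_mags + 1)]
    enzymes = [f"ENZ{i:02d}" for i in range(1, n_enzymes + 1)]
    taxon_labels = pd.Series(
        {m: f"class_{i:03d}" for i, m in enumerate(mag_ids, start=1)}, name="tax_class"
    )

    var_names = [s.name for s in env_specs]
    if dominant_variable is None:
        dominant_variable = var_names[0]
    if dominant_variable not in var_names:
        raise ValueError(f"dominant_variable {dominant_variable!r} not among variables")

    # every archetype used at least once, then random fill
    arch_assign = list(range(n_archetypes)) + list(
        rng.integers(n_archetypes, size=n_clusters - n_archetypes)
    )
    rng.shuffle(arch_assign)
    archetype_labels = pd.Series(
        [f"ARCH{a + 1:02d}" for a in arch_assign], index=cluster_ids, dtype=object
    )

    # each archetype is *driven* by one variable (narrow breadth there,
    # broad elsewhere), so archetype patterns are quasi-independent; the
    # dominant variable drives half of them and hence the dataset
    n_dom = max(1, int(np.ceil(0.6 * n_archetypes)))
    others = [v for v in var_names if v != dominant_variable]
    drivers = [dominant_variable] * n_dom + [
        others[i % len(others)] for i in range(n_archetypes - n_dom)
    ] if others else [dominant_variable] * n_archetypes
    driver_of = {a: drivers[a] for a in range(n_archetypes)}

    optima = {}
    breadths = {}
    for s in env_specs:
        lo, hi = s.mean_range
        width = hi - lo
        driven = np.array([driver_of[a] == s.name for a in range(n_archetypes)])
        # stratified optima over the variable's range for the archetypes
        # it drives (distinct, comparably sized niche bands); uniform for
        # the rest
        arch_opt = rng.uniform(lo, hi, size=n_archetypes)
        n_driven = int(driven.sum())
        if n_driven:
            quantiles = (np.arange(n_driven) + 0.5) / n_driven
            arch_opt[driven] = lo + width * rng.permutation(quantiles)
        arch_frac = rng.uniform(0.60, 0.90, size=n_archetypes)
        if s.name == dominant_variable:
            arch_frac[driven] = rng.uniform(0.15, 0.25, size=n_driven)
        else:
            arch_frac[driven] = rng.uniform(0.30, 0.45, size=n_driven)
        jitter = rng.normal(0.0, optimum_jitter_frac * width, size=n_clusters)
        optima[s.name] = arch_opt[arch_assign] + jitter
        breadths[s.name] = arch_frac[arch_assign] * width * rng.uniform(
            0.9, 1.1, size=n_clusters
        )
    niche_optima = pd.DataFrame(optima, index=cluster_ids)[var_names]
    niche_breadths = pd.DataFrame(breadths, index=cluster_ids)[var_names]
    base = pd.Series(rng.lognormal(0.0, 0.25, size=n_clusters), index=cluster_ids)

    # enzyme labels: every enzyme used at least once, then random fill
    assignment = list(enzymes) + list(rng.choice(enzymes, size=n_clusters - n_enzymes))
    rng.shuffle(assignment)
    enzyme_labels = {c: {e} for c, e in zip(cluster_ids, assignment)}
    n_nonexcl = int(round(fraction_nonexclusive * n_clusters))
    nonexclusive = list(rng.choice(cluster_ids, size=n_nonexcl, replace=False))
    for c in nonexclusive:
        enzyme_labels[c] = enzyme_labels[c] | {"other_pathway"}

    rows = []
    gene_counter = 0
    for c in cluster_ids:
        n_genes = int(rng.integers(genes_per_cluster[0], genes_per_cluster[1] + 1))
        member_enzyme = sorted(enzyme_labels[c] - {"other_pathway"})[0]
        annotated = rng.random(n_genes) < annotated_fraction
        if not annotated.any():
            annotated[0] = True  # every cluster keeps >=1 annotated member
        extra_idx = int(rng.integers(n_genes)) if c in nonexclusive else -1
        for g in range(n_genes):
            gene_counter += 1
            if g == extra_idx:
                annotation = "other_pathway"
            elif annotated[g]:
                annotation = member_enzyme
            else:
                annotation = ""
            rows.append(
                {
                    "gene_id": f"G{gene_counter:06d}",
                    "mag_id": mag_ids[int(rng.integers(n_mags))],
                    "length": int(rng.integers(gene_length_range[0], gene_length_range[1] + 1)),
                    "annotation": annotation,
                    "cluster_id": c,
                }
            )
    genes = pd.DataFrame(rows)
    genes["tax_class"] = genes["mag_id"].map(taxon_labels)

    truth = SyntheticTruth(
        niche_optima=niche_optima,
        niche_breadths=niche_breadths,
        cluster_base_abundance=base,
        gene_assignments=genes.set_index("gene_id")["cluster_id"],
        taxon_labels=taxon_labels,
        enzyme_labels=enzyme_labels,
        gene_lengths=genes.set_index("gene_id")["length"].astype(float),
        abundance_noise_sd=abundance_noise_sd,
        archetype_labels=archetype_labels,
    )
    return genes, truth


def default_env_specs() -> list[EnvVariableSpec]:
    """Default climatology variables used by the synthetic study.

    Temperature-like gradient variable (the dominant niche axis by
    default), nutrient-like reversed gradients, and irradiance-like bell
    shapes — four variables, hence eight model features once the mean and
    seasonality layers are both used.
    """
    return [
        EnvVariableSpec("temperature", (-2.0, 30.0), "gradient", 0.5, (0.5, 6.0), 0.15),
        EnvVariableSpec("nitrate", (0.0, 30.0), "bell", 0.5, (0.2, 4.0), 0.35),
        EnvVariableSpec("irradiance", (20.0, 220.0), "gradient", 4.0, (5.0, 60.0), 0.25),
        EnvVariableSpec("salinity", (31.0, 38.0), "uniform", 0.3, (0.1, 1.5), 0.35),
    ]


def expected_cluster_signal(
    env_means: pd.DataFrame | pd.Series, truth: SyntheticTruth
) -> pd.DataFrame:
    """Analytic (noise-free) cluster signal at given environmental means.

    signal_c = base_c * prod_v exp(-(env_v - opt_cv)^2 / (2 breadth_cv^2))
    """
    if isinstance(env_means, pd.Series):
        env_means = env_means.to_frame().T
    env = env_means[truth.variable_names].to_numpy(dtype=float)  # n x V
    opt = truth.niche_optima.to_numpy(dtype=float)  # C x V
    brd = truth.niche_breadths.to_numpy(dtype=float)
    z = (env[:, None, :] - opt[None, :, :]) / brd[None, :, :]
    logresp = -0.5 * np.sum(z**2, axis=2)
    sig = truth.cluster_base_abundance.to_numpy()[None, :] * np.exp(logresp)
    return pd.DataFrame(sig, index=env_means.index, columns=truth.cluster_ids)


def expected_relative_abundance(
    env_means: pd.DataFrame | pd.Series, truth: SyntheticTruth
) -> pd.DataFrame:
    sig = expected_cluster_signal(env_means, truth)
    return sig.div(sig.sum(axis=1), axis=0)


def _station_env_means(stations: pd.DataFrame, truth: SyntheticTruth) -> pd.DataFrame:
    cols = {}
    for v in truth.variable_names:
        col = f"{v}_mean"
        if col not in stations.columns:
            raise ValueError(f"stations table lacks column {col!r}")
        cols[v] = stations[col].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=stations["station_id"].to_numpy())


def simulate_reads(
    stations: pd.DataFrame,
    truth: SyntheticTruth,
    depth_per_station: int = 100_000,
    seed: int = 0,
    overdispersion: float = 0.0,
) -> pd.DataFrame:
    """Draw raw read counts (station × gene) at fixed sequencing depth.

    Gene expectations are cluster signal × gene length; each station's
    counts are one multinomial draw at ``depth_per_station``, so column
    sums per station equal the depth exactly. Station-level lognormal
    noise (``truth.abundance_noise_sd``) perturbs cluster signals before
    the draw; ``overdispersion`` > 0 switches the draw to a
    Dirichlet-multinomial with that precision-inverse.
    """
    if depth_per_station <= 0:
        raise ValueError("depth_per_station must be > 0")
    env = _station_env_means(stations, truth)
    if not np.isfinite(env.to_numpy()).all():
        raise ValueError("station env_vector contains non-finite values")
    rng = np.random.default_rng(seed)

    signal = expected_cluster_signal(env, truth).to_numpy()  # n x C
    if truth.abundance_noise_sd > 0:
        signal = signal * rng.lognormal(0.0, truth.abundance_noise_sd, size=signal.shape)

    genes = truth.gene_assignments.index.to_numpy()
    lengths = truth.gene_lengths.loc[genes].to_numpy(dtype=float)
    cluster_idx = pd.Index(truth.cluster_ids).get_indexer(truth.gene_assignments.to_numpy())

    counts = np.zeros((len(env), len(genes)), dtype=np.int64)
    for s in range(len(env)):
        w = signal[s, cluster_idx] * lengths
        total = w.sum()
        if total <= 0:
            raise ValueError("degenerate zero signal at a station")
        p = w / total
        if overdispersion > 0:
            p = rng.dirichlet(p / overdispersion)
        counts[s] = rng.multinomial(depth_per_station, p)
    return pd.DataFrame(counts, index=env.index.rename("station_id"), columns=genes)
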