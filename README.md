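# funcbiogeo

Projecting the ocean biogeography of **genomic functional potential**:
given the relative abundances of protein functional clusters (PFCs —
connected components of a protein sequence-similarity network) across
the stations of an oceanographic survey, and gridded environmental
climatologies, `funcbiogeo` models abundance as a joint function of the
environment, maps it globally with bootstrap uncertainty, and
aggregates the cluster-level maps into enzyme-level patterns of
genomic potential. It is written for microbial ecologists and
biogeographers working with metagenome-assembled genomes (MAGs) and
gene-level read counts.

## What it computes

The core regressor is a **multivariate boosted tree** (MBTR): gradient
boosting in which every tree has vector-valued leaves, fitted jointly
to all response clusters under squared-error loss,

    F_r(x) = ȳ + η · Σ_{i≤r} T_i(x),      T_i fitted to Y − F_{i−1}(X),

with each split chosen to maximize the joint sum-of-squares reduction
over all responses. Sharing splits across correlated clusters both
regularizes the small-sample fit and conserves the between-cluster
correlation structure, which is verified with a Mantel permutation test
on the observed vs predicted response-correlation matrices.

Around the regressor, the package implements the full pipeline:

* **preprocessing** — SSN clustering (80%/80% identity/coverage,
  self-hits removed), annotation-exclusivity and ≥10-station detection
  filters, gene-length and sequencing-effort normalization to
  per-station relative abundances (each station row sums to 1);
* **escoufier_selection** — greedy RV-coefficient reduction of the
  response set to the clusters carrying ≥95% of the dataset variance;
* **model_validation** — 10-fold spatial-block cross-validation
  (contiguous station blocks), pooled out-of-fold R²/RMSE, Mantel test;
* **spatial_projection** — station-level bootstrap refits projected
  onto the climatology grid; per-cell mean and coefficient of
  variation;
* **cluster_reconstruction** — correspondence analysis of the full
  abundance table; each non-modeled cluster inherits the projection of
  its nearest selected neighbour in CA space (≥80% inertia dimensions);
* **enzyme_aggregation** — standardized (equal-weight) and
  abundance-weighted enzyme-level patterns with member CV, and
  inter-pattern spatial correlations;
* **interpretation** — split-gain variable importance, partial
  dependence, Ward clustering of MAG-level patterns, abundance-weighted
  taxonomic composition with Shannon diversity;
* **synthetic** — a fully seeded generator (climatology grids,
  expedition-like station trajectory, archetype-structured communities,
  multinomial read counts) with stored ground truth, so every stage is
  testable against known niches at desk scale.

See `docs/methods.md` for the model details, generator assumptions and
numerical choices.

## Worked example

Run the end-to-end synthetic study — 130 stations, 4 climatology
variables (8 features: yearly mean + yearly SD each), 40 clusters with
Gaussian niches, depth 10⁵ reads/station, 20 bootstrap rounds:

```python
from funcbiogeo.pipeline import PipelineConfig, run_synthetic_pipeline

result = run_synthetic_pipeline(seed=1, config=PipelineConfig(n_boot=20, abundance_noise_sd=0.05))
d = result.diagnostics
print(f"clusters: {d['n_clusters_surviving']} surviving, {d['n_selected']} modeled "
      f"(RV captured = {d['final_rv']:.3f})")
print(f"held-out skill: R2 = {d['oof_r2']:.3f}, RMSE = {d['oof_rmse']:.4f}")
print(f"correlation structure: Mantel r = {d['mantel_r']:.3f} (p = {d['mantel_p']:.3f})")
print(f"top feature: {d['top_feature']} ({d['top_feature_importance_pct']:.1f}% importance)")
print(f"projection vs analytic niche surfaces: mean Pearson r = {d['projection_truth_r_mean']:.3f}")
print(f"fields: {d['n_fields_total']} total, {d['n_fields_reconstructed']} reconstructed by CA neighbour")
```

prints (about a minute on one CPU):

```
clusters: 28 surviving, 8 modeled (RV captured = 0.993)
held-out skill: R2 = 0.731, RMSE = 0.0118
correlation structure: Mantel r = 0.926 (p = 0.001)
top feature: temperature_mean (56.6% importance)
projection vs analytic niche surfaces: mean Pearson r = 0.863
fields: 28 total, 20 reconstructed by CA neighbour
```

Reading the numbers: of 40 simulated clusters, 28 pass the exclusivity
and detection filters; 8 are selected for modeling and capture 99.3%
of the dataset variance by Escoufier's RV. The block cross-validated
model explains 73% of the held-out abundance variance (RMSE on the 0–1
relative-abundance scale), keeps the between-cluster correlation
structure (Mantel r = 0.93, permutation p = 0.001), and correctly
identifies the generator's dominant niche axis (temperature mean) as
the most important feature. Bootstrap-projected cluster maps correlate
at r = 0.86 with the analytic niche surfaces computed from the stored
truth, and the 20 non-modeled clusters receive their CA
nearest-neighbour's projection.

A command-line entry point wraps the same stages
(`funcbiogeo simulate | preprocess | select | fit | evaluate | project
| interpret`); run `funcbiogeo --help`.

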