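# Methods

`funcbiogeo` projects the biogeography of genomic functional potential:
it models the relative abundance of protein functional clusters (PFCs)
— connected components of a protein sequence-similarity network, assumed
functionally homogeneous — as a joint function of environmental
climatologies, and extrapolates the fitted response onto a global grid
with bootstrap uncertainty. This note documents the statistical model,
the synthetic data generator the package is validated on, and the
numerical and design choices a user should know about.

## From reads to relative abundances

Protein clusters are built from a pairwise similarity edge list by
removing self-hits and edges under 80% identity or 80% coverage and
taking connected components of the surviving graph; genes without any
surviving edge become singleton clusters. Two selection filters follow:

* **annotation exclusivity** — a cluster is kept only when every
  *annotated* member carries target annotations exclusively (members
  with no annotation are neutral; clusters with no annotated member are
  dropped, since nothing ties them to the target enzymes);
* **detection prevalence** — clusters detected (raw count > 0) at fewer
  than 10 stations are dropped. Detection uses raw counts, before any
  normalization; the order (filter on raw detection, then normalize) is
  a deliberate choice, since prevalence is a property of the raw data.

Counts are divided by gene coding length and by the station's total raw
reads over *all* genes (sequencing-effort normalization includes genes
outside the selected clusters), summed within clusters, and finally
each station row is renormalized over the selected clusters to sum
to 1. The final matrix is therefore compositional: values are shares of
the selected-cluster pool, not absolute abundances. Both intermediate
matrices are returned for inspection.

## Variance-based cluster reduction

To keep the number of response variables commensurate with ~130
stations, an ordered subset of clusters is chosen by Escoufier's
method: greedy forward selection maximizing the RV coefficient

    RV(A, B) = tr(S_AB S_BA) / sqrt(tr(S_AA^2) tr(S_BB^2))

between the selected sub-matrix and the full matrix (columns centered;
scaling optional and off by default, since relative abundances share a
scale). Ties in RV gain break to the lowest column index, making the
selection deterministic. The implementation evaluates RV incrementally
from the p×p cross-product matrix, so each greedy step is O(p·k).

Two practical observations, verified empirically and worth flagging:

* On compositional data dominated by a strong environmental gradient,
  a *single* cluster pattern can already reach RV ≈ 0.9, so a pure
  "stop at 95%" rule may select only 1–3 clusters — too few for
  multivariate modeling. The pipeline therefore selects a **fixed
  number** of clusters (default: one fifth of the candidates, 8 of 40
  in the synthetic study) and *verifies* that the captured RV exceeds
  0.95, rather than using 0.95 as the stopping rule. Both knobs
  (`threshold`, `max_k`) are exposed.
* The greedy RV trajectory is non-decreasing on generic data but can
  dip slightly on strongly compositional matrices; the trajectory is
  reported so this is visible.

## Multivariate boosted tree regression (MBTR)

The regressor is gradient boosting in which each tree predicts the full
response vector jointly: one split partition is chosen for all
responses at once by maximizing the joint squared-error reduction

    gain = ||Σ_L r||²/n_L + ||Σ_R r||²/n_R − ||Σ r||²/n

(vector norms over response dimensions). Under squared-error loss the
hessian of the loss is the identity, so the general hessian-weighted
leaf solution collapses to the mean residual vector of the leaf's
samples; the code is written against the general interface but only the
squared-error loss ships. Sharing splits across correlated responses is
the mechanism by which the model conserves the between-response
correlation structure, which is tested explicitly (see below).

Defaults mirror the validated configuration: learning rate 5·10⁻³,
minimum 30 observations per terminal leaf, 10 candidate quantiles per
split. Choices the configuration leaves open, fixed here:

* **maximum depth 6** — with min_leaf 30 and ~120 training rows the
  admissibility constraint binds first, so depth is a safety cap;
* **candidate thresholds** are the interior evenly spaced empirical
  quantiles (i/(q+1), i = 1..q), recomputed per node (richer splits at
  depth); a flag switches to global quantiles;
* **determinism** — no subsampling anywhere; split ties break to the
  lowest feature index then the lowest threshold;
* **stopping** — the ensemble is grown until the held-out loss stops
  improving (patience 50, cap 1000 rounds). A fixed small round budget
  (e.g. 200) demonstrably underfits at this learning rate: fold test
  losses are still decreasing at round 200.

## Validation

Cross-validation uses 10 contiguous blocks of stations ordered by
station number. The cruise trajectory is continuous in space and time,
so contiguous blocks are spatially/temporally coherent and held-out
skill is not inflated by autocorrelation. Reported skill is the pooled
out-of-fold R² (1 − SSE/SST over all responses and stations, SST about
per-column means — so predicting the column means scores exactly 0) and
RMSE on the 0–1 relative-abundance scale; the per-response mean R² is
also reported. The boosting-round count reused downstream is the one at
the minimum held-out loss across all fold runs.

Conservation of the correlation structure is tested by a Mantel-style
permutation test: Pearson correlation between the off-diagonal entries
of the observed and predicted response-correlation matrices, with a
one-sided p-value from jointly permuting row/column labels of one
matrix ((n_perm + 1) denominator, 999 permutations by default).

## Spatial projection and reconstruction

Projections bootstrap the stations: each round resamples station rows
with replacement (X–Y pairing preserved), refits an ensemble with the
validated hyperparameters and round count, and predicts every unmasked
grid cell; negative predictions are clipped to zero (the responses are
relative abundances; the regressor is unconstrained). The per-cell mean
and coefficient of variation (sample SD / mean × 100) across rounds
form the projection and its uncertainty; where the mean is below 10⁻⁶
the CV is reported missing rather than exploding. Per-round seeds
derive from (master seed, round index), so results are independent of
execution order. Cell predictions are *not* renormalized to the
simplex across clusters: standardization happens downstream, and the
sum-over-clusters of projected means is only approximately 1.

Non-selected clusters inherit the projection of their nearest selected
neighbour in correspondence-analysis space: CA of the observed
relative abundance table of all clusters, distances in the leading
column-principal coordinates that cumulatively explain ≥ 80% of the
inertia, ties to the first selected cluster in column order. Column
principal coordinates (clusters as points, scaled by singular values)
are the documented choice; reconstruction copies the neighbour's mean
and CV fields by reference and tags them `reconstructed`.

## Enzyme aggregation

Cluster projections are min–max standardized to [0, 1] over ocean
cells, then aggregated per enzyme annotation in two modes: the
**standardized** pattern is the plain mean of member patterns (each
cluster counts equally — the consensus pattern), the **weighted**
pattern weights members by their total observed relative abundance
across stations (dominant clusters set the pattern). The weighted CV
uses the unbiased reliability-weight variance, so uniform weights
reproduce the standardized aggregation exactly; the weighted pattern is
rescaled to [0, 1] after aggregation (flagged in the output metadata,
with the raw weighted mean kept) so both modes share a display scale.
The enzyme-level CV measures disagreement *among member cluster
patterns*; bootstrap CV remains a cluster-level quantity and is not
folded in.

## Interpretation

Variable importance accumulates each split's loss gain onto its
feature (i.e., split counts scaled by gain), normalizes to percent per
ensemble and averages across ensembles. Partial dependence substitutes
a grid of values of one feature into every reference row and averages
predictions, at the validated truncation round. MAG-level patterns are
grouped by Ward hierarchical clustering (scipy's `ward` on Euclidean
cell vectors, equivalent to R's `ward.D2` on Euclidean distances) and
correlated against enzyme patterns on unit-scaled fields. Taxonomic
composition weights each cluster's class multiset by its summed
observed relative abundance; the Shannon index uses the natural log
(the ecology convention; the base is configurable nowhere on purpose —
report ln-based H).

## The synthetic study

No generative model for the real data exists, so the package ships a
generator whose structure mirrors what the pipeline assumes, with known
truth for recovery tests. All of the following are stand-ins, chosen
once and documented:

* **Climatologies** — four variables (temperature-like gradient,
  nutrient-like equatorial bell, irradiance gradient, salinity) on a
  1°–10° grid (4° in the shipped study): a latitudinal base shape, a
  smooth seeded lat–lon "regional" field (a few low-frequency
  sinusoids; amplitude a per-variable fraction of the range — without
  it the environmental space is effectively one-dimensional and every
  niche pattern collinear), iid cell noise, plus a yearly-SD layer
  increasing with |latitude|. Land is the polar caps (|lat| > 72°).
* **Trajectory** — a random walk over ocean cells with a persistent
  longitudinal drift (expedition-like; it can circumnavigate) and a
  16° step bound. Contiguous station ids are therefore spatially
  coherent, which is what block cross-validation assumes, and the walk
  samples the environmental space broadly enough that the projection
  grid is mostly inside the sampled envelope.
* **Community** — 40 clusters as jittered copies of 8 niche
  *archetypes*. Each archetype is driven by one variable (narrow
  Gaussian breadth, 15–25% of the range for the dominant driver,
  30–45% for others) and responds broadly (60–90%) to the rest; the
  dominant variable (temperature by default) drives 60% of archetypes,
  so it is genuinely the dominant generating feature. Optima of driven
  archetypes are stratified across the variable's range. Cluster base
  abundances are lognormal (σ = 0.25); 2–6 genes per cluster with
  lengths uniform in 300–3000 nt; 30% of clusters carry a non-target
  annotation on one member to exercise the exclusivity filter.
* **Reads** — expected cluster signal at a station is
  base × Π_v exp(−(env_v − opt_v)²/(2·breadth_v²)), perturbed by
  station-level lognormal noise (σ = 0.10 by default, 0.05 in the
  low-noise recovery runs), gene expectations proportional to signal ×
  length, and one multinomial draw per station at fixed depth (10⁵) —
  so per-station depth is conserved exactly and the relative-abundance
  target is exact in expectation. Dirichlet-multinomial overdispersion
  is available behind a switch, off by default.

What the generator does **not** emulate: sequencing error, mapping
ambiguity, assembly artifacts, depth variation between stations,
taxon–gene copy-number variation, and temporal variability. Passing
recovery tests therefore demonstrates the pipeline's correctness and
its statistical behaviour under its own assumptions, not performance on
real metagenomes.

## Problem sizes and numerical choices

The shipped end-to-end study uses 130 stations, 40 clusters, 8 model
features, depth 10⁵, a 4° grid (~2700 ocean cells), 10 folds, 20
bootstrap rounds and 999 Mantel permutations; it completes in about a
minute on one CPU. Numerical tolerances: abundance rows sum to 1 within
1e-9; RV/CA oracle agreement is exact to 1e-12/1e-10; split-gain ties
use a 1e-15 guard; CA singular values below 1e-12 are treated as null
dimensions; CV is undefined (missing) below a 1e-6 mean floor.

## Known limitations

* Projection skill degrades outside the environmental envelope sampled
  by the stations (trees extrapolate as constants); the recovery
  correlation with the analytic niche surface is high (~0.9) inside
  the envelope and low far outside it. A formal area-of-applicability
  mask is not implemented.
* The fixed-size Escoufier selection may leave some archetypes without
  a selected representative; clusters of an uncovered archetype are
  then reconstructed from the nearest covered pattern, which bounds
  in-pipeline archetype recovery below 100% even at low noise.
* With ~130 stations and min_leaf 30, individual trees are coarse
  (3–4 leaves); the model relies on many boosting rounds for
  smoothness, and the learning rate/round interplay matters more than
  usual.
* NetCDF output uses the NetCDF3 (scipy engine) format.
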