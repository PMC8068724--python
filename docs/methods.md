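# Methods

## Scope

`richconn` implements a complete rich-club analysis of structural brain
connectomes: network construction from weighted connectivity matrices,
global and nodal graph metrics with matched-random-network normalization,
rich-club quantification and rich/feeder/local edge decomposition,
covariate-adjusted permutation inference including the network-based
statistic (NBS), mapping of differential edges onto depression-related
circuits, and SVM classification of groups from network features. Because
clinical diffusion-MRI cohorts of this kind are rarely deposited, the
package ships a synthetic-cohort generator that plants every structure the
pipeline is meant to detect, so each stage can be validated against known
ground truth. Tractography, registration, and atlas construction are out of
scope: the pipeline starts from per-subject N x N connectivity matrices.

## Network construction

Connectivity matrices are symmetric, nonnegative, zero-diagonal, and read
from delimited text. Asymmetries up to 1e-6 are repaired by averaging with
the transpose; anything larger is rejected as a directed input.

*Streamline filter.* Entries with streamline count <= 3 are zeroed (strict
inequality: a count of exactly 3 is removed). This suppresses spurious
single-fiber connections from deterministic tractography.

*Sparsity thresholding.* Sparsity is the retained-edge fraction of the
N(N-1)/2 possible edges. Binarization keeps the E = round(s * N(N-1)/2)
strongest-weight edges; ties at the cut rank are broken by ascending
(i, j) node-pair order so results are bit-reproducible. Group analyses run
over the sweep s = 0.05 ... 0.20 in steps of 0.01 (16 levels); graphs along
the sweep are nested by construction, and binarization is idempotent.
A validation warning (not an error) fires when the mean degree at the
minimum sparsity does not exceed ln(N), the usual estimability floor for
sparse-graph metrics; the criterion's original formulation is ambiguous
about its units, so it is deliberately not enforced as a hard constraint.

*Curve integration.* Metrics measured along the sweep are summarized by the
trapezoidal area under the metric-vs-sparsity curve. A plain Riemann sum
(value x step), used by some connectome toolboxes for "AUC" metrics, is
available via `integrate_curve(..., method="sum")`.

## Graph metrics

All metrics are computed on binary undirected graphs; distances are hop
counts.

- **Dc** — degree.
- **Ne** — nodal efficiency: mean of 1/d(i, j) over j != i; unreachable
  nodes contribute 0, so isolated nodes have Ne = 0.
- **Bc** — betweenness centrality, unnormalized (raw shortest-path counts,
  ties split evenly). Normalization by (N-1)(N-2)/2 is a presentation
  choice left to the caller.
- **C** — mean local clustering coefficient.
- **L** — characteristic path length over *connected* pairs only; this
  keeps L finite on graphs with isolated fragments (the alternative,
  harmonic means, is already captured by the efficiency metrics).
- **Eg / Eloc** — global efficiency and its neighborhood-subgraph average.
- **Q** — modularity Σ_c (e_cc − a_c²) of a partition found by
  deterministic greedy agglomeration (exhaustive search is used only as a
  test oracle; a partition worse than the trivial single community is never
  returned).
- **gamma, lambda, sigma** — C/C_rand, L/L_rand, and their ratio
  (small-worldness), with C_rand and L_rand averaged over degree-preserving
  rewired surrogates (below). Subject networks are expected to satisfy
  sigma > 1.1 at the densest threshold; `small_world_check` reports
  violations without dropping subjects.
- **Hemispheric asymmetry** — (X_L − X_R)/(X_L + X_R) of per-hemisphere
  metric sums; positive values mean leftward asymmetry; a zero denominator
  yields NaN with a warning.

## Rich-club organization

Phi(k) is the edge density among nodes of degree strictly greater than k;
it is undefined (NaN) when fewer than two nodes qualify. Normalization uses
Maslov–Sneppen double-edge swaps: each surrogate starts from the observed
graph and applies 10E swap attempts, each rejected if it would create a
self-loop or multi-edge, which preserves every node's degree exactly.
Phi_norm(k) = Phi(k) / mean of Phi over the surrogate ensemble, and the
permutation p at each k is the add-one estimator
(1 + #{Phi_rand >= Phi}) / (1 + n_random), never exactly zero. The
significant regime is the longest contiguous k-run with Phi_norm > 1 and
p < 0.05. Note that p has a resolution floor of 1/(n_random + 1): at least
20 surrogates are needed before any level can reach p < 0.05.

*Group-average network.* An edge enters the group-representative graph when
present in at least 80% of subjects (boundary inclusive); the occurrence
threshold is configurable.

*Hub identification.* Hubs are nodes whose degree on the group-average
network exceeds a threshold k\*. With `k_star="auto"`, k\* is placed at the
degree level with the widest gap in the degree sequence *within* the
significant Phi_norm regime. The naive alternative — k\* = the regime's
smallest k — systematically under-thresholds: a genuine core's excess
density also inflates Phi_norm at degree levels well below the hub range,
so the regime's lower edge sits among mid-degree peripheral nodes. The
degree-gap rule exploits the fact that a real core separates from the
periphery in the degree sequence; when no gap wider than 1 exists the rule
falls back to the regime's smallest k. A mean + SD degree rule is available
as `rule="mean_sd"`. When several groups are analyzed, hub sets are
computed per group and intersected ("common hubs").

*Edge classes.* Given a hub set, every edge is exactly one of rich
(hub-hub), feeder (hub-nonhub), or local (nonhub-nonhub); the three classes
partition the edge set and their count proportions sum to 1. Class
strengths sum the subject's raw pre-binarization weights over the class
edges surviving each sparsity level, then integrate across the sweep.

## Inference

*Permutation tests.* Group comparisons of scalar metrics residualize the
metric on an intercept plus nuisance covariates (age, sex as 0/1,
education) by OLS, then permute group labels on the residuals
(residualize-then-permute); the Freedman–Lane scheme (permute reduced-model
residuals, reconstruct, re-residualize) is available via
`perm_test(..., scheme="freedman_lane")` and agrees closely on fixed
designs. Two groups: statistic = difference of group
means, two-sided; three or more: one-way F, upper tail. P-values use the
add-one estimator and are invariant to affine rescaling of the metric.
Covariates are never permuted. Node-level families are controlled by
Bonferroni: significant iff p < alpha/N_nodes, strict (0.05/90 ≈ 5.6e-4 at
default settings).

*Partial correlation.* Pearson correlation of OLS residuals of both
variables on the covariates (age, sex, education, gray-matter volume for
symptom-score analyses), tested against t with n − n_cov − 2 degrees of
freedom.

*NBS.* Per-edge two-sample pooled-variance t statistics on
covariate-residualized edge weights; the supra-threshold graph at an
uncorrected edge p (default 0.01, two-sided) is decomposed into connected
components; component size is the edge count (extent statistic; an
intensity statistic — summed supra-threshold excess sum(|t| − t_crit) — is
available via `statistic="intensity"`). The
family-wise p of each observed component is the add-one fraction of label
permutations whose *largest* component is at least as large. The
permutation loop is fully vectorized (t maps for hundreds of permutations
per matrix multiply; component labeling by union-find on the few
supra-threshold edges), so 10,000 permutations on a 90-node cohort run in
seconds. Defaults follow the protocol values (edge p = 0.01, 10,000
permutations); the component-forming p and iteration count are exposed for
sensitivity analyses.

## Circuits

Six depression-related circuits (default mode network, salience, negative
affect, positive affect, attention, cognitive control) are named region
sets over the parcellation; sets may overlap. The bundled default
configuration transcribes the published circuit descriptions onto AAL-90
labels and is deliberately approximate — supply a YAML mapping for a
specific cohort. Differential edges are assigned to a circuit when both
endpoints belong to it (default) or when any endpoint does; edges matching
no circuit are labeled unassigned. Assignment is deterministic and
invariant to edge order.

## Classification

Pairwise (one-vs-one) RBF-SVM with three preprocessing steps fit strictly
inside every leave-one-out training fold: a two-sample t-test filter
(keep features with p < 0.05; if nothing survives, the single best |t|
feature), min-max scaling to [0, 1] with training-fold extrema (test values
clipped), then the SVM. ROC/AUC are computed from the continuous per-fold
decision values; sensitivity/specificity are recalls of the positive/
negative class. Accuracy significance is a label-permutation p with the
add-one estimator, re-running the entire per-fold pipeline on every
permuted label vector.

Hyperparameters: C = 1 and gamma = "scale" (1/(n_features · Var)). The
LibSVM-default gamma = 1/n_features is available but not default: with
hundreds of near-collinear min-max-scaled edge features it collapses the
RBF kernel toward a constant, at which point leave-one-out's class-
imbalance bias dominates and decisions anti-order (observed accuracy near
0 on strongly separable data). Two leave-one-out artifacts are worth
knowing when reading null results: (1) at small n, the held-out subject's
class is always one sample short in training, biasing null accuracy and
AUC *below* chance ("anti-learning"); (2) permutation-null AUCs have high
per-run variance. Both shrink with sample size; null calibration checks in
the test suite therefore run at the emulated study's scale (~40 per
group).

Leakage is guarded twice: a structural test asserts the filter and scaler
see exactly n−1 rows in every fold, and a behavioral canary shows that on
pure-noise data the per-fold pipeline stays at chance AUC while a
deliberately leaky variant (feature selection on all subjects including
each held-out one, exposed as the clearly-labeled `global_tfilter=True`
compatibility mode) inflates AUC far above it.

## Synthetic cohorts

The generator emulates the targeted study design: 90-node AAL-style
connectomes in three groups (CN/MDDNSI/MDDSI, default sizes 50/58/69), a
planted rich club of 11 hub regions (bilateral putamen, precuneus,
thalamus, insula, caudate, plus left anterior cingulate), and group
effects concentrated on feeder and local connections.

Template: each node pair is present with probability `base_density`
(default 0.30), except hub-hub pairs boosted to
min(0.95, base_density × hub_core_boost) — an excess density *beyond what
the degree sequence implies*, which is exactly what degree-preserving
normalization detects. Weights are log-normal (sigma 0.5) around a median
streamline count of 40, multiplied by hub_core_boost^0.75 per hub endpoint
so hub edges survive thresholding and hubs end up as the top-degree nodes.
With hub_core_boost = 1 the construction is exchangeable across nodes (no
rich club); with hub_fraction = 0 there are no hubs.

Per subject: template weights × per-edge-class group multiplier (defaults:
MDDNSI feeder ×0.85 / local ×0.90; MDDSI feeder ×0.75 / local ×0.85; CN
reference) × elementwise log-normal noise (sigma 0.30, matching the
right-skewed positive dispersion of streamline counts), plus a 2% Bernoulli
presence flip that creates the subject-level topology variation assumed by
the 80% occurrence rule (toggled-on edges draw a half-strength template
weight). Covariates (age ~ N(40, 11) clipped to 18–75, sex ~ Bernoulli(½),
education ~ N(12, 3), gray-matter volume ~ N(600, 50)) are independent of
group by default so covariate adjustment is testable under the null; a
`confound_strength` knob injects a group-age confound for testing.
Symptom scores follow HAMD = intercept + group offset − 40 × (mean nodal
efficiency of two designated hubs) + N(0, 3), clipped at 0, giving
partial-correlation recovery a known negative sign; HAMA is a scaled
version and SI-severity is drawn only for the MDDSI group.

What the generator does **not** emulate: spatial embedding and distance-
dependent connectivity, hemispheric topology, and local clustering
structure — synthetic subject networks are ER-like outside the planted
core, so their small-worldness sigma hovers near 1 rather than the > 1.1
typical of real connectomes. Passing tests therefore demonstrate that the
pipeline recovers planted rich-club, edge-class, and group-difference
structure under realistic noise; they do not certify behavior on the
spatial and clustered organization of real tractography data.

## Reproducibility and problem sizes

Every stochastic step (rewiring, permutations, the generator, label
shuffles) takes an explicit seed; the pipeline derives stage seeds from the
single run seed and records the full configuration in
`run_manifest.json`, so identical config + seed gives byte-identical
outputs. Test-suite and acceptance-script runs use desk-scale problem
sizes chosen once — e.g. 30–60 subjects per cohort, 30–100 matched random
networks, 500–2000 permutations, 200–500 calibration simulations — while
the library defaults keep the protocol values (1000 random networks,
10,000 permutations). The analysis drivers under `analysis/` state their
own sizes in `study_config.py`.

## Known limitations

- Binary-graph analysis only: weighted path-length and weighted rich-club
  variants are out of scope.
- The default circuit configuration is an approximate transcription of
  published circuit descriptions onto AAL-90 labels, not a validated mask
  set.
- The modularity maximizer is greedy; it matches exhaustive search on
  small benchmarks but carries no optimality guarantee.
- Permutation inference assumes exchangeability of residualized values
  across subjects.
- LOOCV metrics at small n carry the biases described above; interpret
  single-run AUCs with their permutation p, not in isolation.
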