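# Methods

`symptomnet` implements a complete symptom-network analysis for two
co-occurring psychological constructs measured by ordinal
questionnaires: fear of cancer recurrence (FCRI, 42 items scored 0–4 in
7 dimensions, item 13 reverse-keyed) and pain catastrophizing (PCS, 13
items scored 0–4).  The analytic unit is a respondents × nodes table of
20 nodes — the 7 FCRI dimension scores (F1–F7, community 1) and the 13
PCS items (P1–P13, community 2).  Because the motivating study's
questionnaire data are not public, the package ships a synthetic-data
generator with known network truth; all quantitative validation is
parameter recovery and statistical calibration against that truth.

## Measurement layer

Reverse-keyed items are transformed as v' = max + min − v before
summation (an involution).  Reliability is Cronbach's α in the raw
covariance form α = k/(k−1)·(1 − Σ s²ᵢ / s²_total).  Missing data are
handled only by listwise deletion, mirroring the exclusion of
incomplete questionnaires; imputation is deliberately not offered.
The design-stage sample-size rule counts model parameters: p thresholds
plus p(p−1)/2 pairwise parameters, inflated by 1/(1−attrition); for
p = 20 and 20% attrition this gives 210 and 263 cases.  The FCRI
dimension-to-item layout is an editable default (contiguous blocks:
8/9/4/6/3/3/9 items) since published sources do not fix it uniquely;
dimension scores enter the network as raw sums (a `--standardize`-style
option is unnecessary because partial correlations are scale-free once
the input is a correlation matrix).

## Synthetic generator

`GeneratorSpec` plants a block precision matrix: two communities (7 and
13 nodes), each within-community pair receiving an edge with
probability `within_density` (default 0.2) and partial correlation
drawn from `weight_range` (default 0.15–0.3, positive), plus
`n_bridge_edges` (default 2) cross-community bridges.  Positive
definiteness is enforced by uniformly shrinking all off-diagonals until
the smallest eigenvalue exceeds 0.01; the recorded truth stores the
*realized* partial correlations after shrinkage.  Latent data are drawn
from the implied Gaussian (rescaled to unit variances) and discretized
at per-node cut points; the default cuts (−0.25, 0.55, 1.15, 1.75)
give right-skewed 5-category marginals (≈ 0.40/0.29/0.17/0.09/0.04),
as typical of symptom ratings.  Default n = 346 matches the motivating
study's analytic sample.  Edge strengths were fixed once at a level a
psychometric network would call moderate; much denser or stronger
truths produce correlation chains that violate the lasso's
irrepresentability conditions, in which case *no* path-based estimator
can recover the support and recovery benchmarks become meaningless.
The generator emulates cross-sectional ordinal data from a single
Gaussian copula; it does not emulate longitudinal dependence,
demographic covariate structure, response styles, or item-level
measurement error in the dimension scores — recovery results therefore
speak to estimator correctness, not to robustness against those
features of real data.

A single-chain Gibbs sampler provides binary data from arbitrary Ising
models (conditional logit τᵢ + Σⱼ βᵢⱼ xⱼ) for testing the intervention
machinery against exactly enumerable 2-node distributions.

## Correlations

Ordinal inputs use two-step polychoric estimation: thresholds from the
inverse-normal CDF of marginal cumulative proportions, then the
correlation by bounded scalar maximization (tolerance 1e−6) of the
bivariate-normal contingency likelihood.  Rectangle probabilities come
from a vectorized Gauss–Legendre implementation of the bivariate normal
CDF (Drezner–Wesolowsky/Genz scheme; unit-tested against scipy to
5e−7), which makes bootstrap-scale polychoric matrices affordable
(~0.3 s for 190 pairs at n ≈ 350).  Method `auto` picks polychoric when
every column is integer with ≤ 7 levels, Pearson otherwise.  Indefinite
matrices are smoothed by eigenvalue clipping at zero with a
unit-diagonal rescale.  Estimates at the ±0.999 bound are clamped with
a warning.

The redundancy screen ("goldbricker") flags a pair with |r| ≥ 0.50
when fewer than 25% of third nodes distinguish the two items at
p < 0.05 in a dependent-correlation test (the back-transformed-average
Fisher-z variant for overlapping correlations).  The thresholds are
package conventions, configurable, not study-reported values.

## Network estimation

The Gaussian graphical model is estimated by graphical lasso — an
in-package blockwise coordinate-descent solver for
max log det K − tr(SK) − λ Σ_{i≠j}|K_ij| (off-diagonal penalty only;
verified against scikit-learn's solver and against a derivative-free
optimizer of the objective).  The λ path has 100 log-spaced points from
λ_max = max|off-diag S| down to 0.01·λ_max, warm-started.  Model
selection minimizes EBIC = −2ℓ + E·log n + 4·E·γ·log p with γ = 0.5 by
default.

A deliberate design choice: by default the likelihood ℓ entering EBIC
is that of the **support-constrained MLE** ("refit"; computed by
iterative proportional scaling) rather than the penalized estimate, and
the selected model's weights are the refit partial correlations
−K_ij/√(K_ii·K_jj).  With the penalized likelihood the criterion keeps
improving as λ shrinks purely because shrinkage bias decreases, which
systematically over-selects edges (on 20-node synthetic truths with
~20 edges it chooses 50–60); the refit convention restores the
intended complexity trade-off and recovers planted supports with
F1 ≥ 0.9 at n = 2000.  `refit=False` reproduces the
penalized-likelihood convention common in R implementations.

## Centrality

Strength Σⱼ|wᵢⱼ|; expected influence Σⱼ wᵢⱼ; shortest-path metrics use
edge length 1/|w|; betweenness counts unordered pairs excluding
endpoints with fractional credit for ties; closeness is the
unnormalized inverse total distance (matching the small printed
magnitudes such as 0.030 in this literature), computed within a node's
component with isolates reported as 0 and flagged.  Bridge strength and
bridge expected influence restrict the sums to edges leaving the node's
community and require ≥ 2 communities.

## Stability and comparison

Edge accuracy: nonparametric bootstrap (resample respondents,
re-estimate correlation + EBIC-glasso per replicate), percentile 95%
intervals.  Centrality stability: case-dropping bootstrap; CS
coefficient = the largest drop proportion q (grid 0.05–0.75) at which
the Spearman correlation between subsample and full-sample centralities
is ≥ 0.7 in ≥ 95% of subsamples; constant subsample centralities (empty
networks) count as failures.  Spearman is the default because only the
ordering is interpreted; Pearson is available.

The network comparison test pools both groups and re-splits at the
original sizes K times (default 1000), re-estimating both networks per
permutation.  Global statistic S = |difference in global strength|
(signed, "expected influence" variant by default, matching how the
global test is usually reported for these data; unsigned by flag);
structure statistic M = max |edge difference|; per-edge and per-node
centrality tests reuse the same draws, edge p-values Holm-corrected;
all p-values use the add-one convention and so are never 0.

## Bayesian network

Variables are treated as continuous Gaussian (standard for ordinal
dimension/item scores in this setting).  The decomposable score is the
Gaussian BIC, per node ℓᵢ − (|parents| + 2)/2 · log n (coefficients +
intercept + variance), higher is better; search is greedy
add/delete/reverse hill climbing with seeded random restarts (default
10; restart 0 from the empty graph, others from sparse random DAGs).
Model averaging runs B = 200 bootstrap resamples; an edge is retained
when it appears in ≥ 50% of resamples (presence rule, a package
convention) *and* its majority direction holds in ≥ 75% of its
appearances (the directionality rule).  Cycles in the averaged graph —
rare — are broken by dropping the lowest-presence edge, logged.
Reported per-edge strength is the deviance-scale change from removing
the edge on the full data (negative = the edge improves fit, i.e.
inclusion lowers the lower-is-better BIC), and the reported network
"BIC" is the higher-is-better score (log-likelihood minus penalty), the
sign convention used by the common structure-learning packages whose
output this mirrors.  Complexity summaries: MBS = mean Markov-blanket
size (parents ∪ children ∪ co-parents), BF = mean out-degree;
"parent nodes" are roots with at least one child.

## Ising interventions

Responses are dichotomized at > 0.  The Ising model is estimated by
eLasso: per-node L1 logistic regressions over a 50-point λ path
(λ_max = max|Z'(y−ȳ)|/n down to 0.01·λ_max), with the intercept-only
model included as a path candidate and effectively unpenalized
intercepts; per-node selection by EBIC = −2ℓ + k·log n + 2γk·log(p−1)
with γ = 0.25 (eLasso convention).  The two directed estimates of each
coupling are combined by the AND rule by default (both nonzero,
averaged; conservative), OR available.  Nodewise predictability is
normalized classification accuracy (accuracy − majority)/(1 −
majority), floored at 0.

Interventions perturb one node's threshold by ± 2 standard deviations
of the fitted threshold vector (amplify raises activation probability),
then Gibbs-sample n_sim = 10,000 responses (1,000 burn-in) from
baseline and perturbed models with a shared random stream (common
random numbers: a zero perturbation reproduces the baseline exactly).
ΔScore is the change in mean total symptom count; targets are ranked by
ΔScore under amplification (aggravation) and attenuation (alleviation).
"Relative influence" is reported as ΔScore / Σ|ΔScore| within a
direction, and an optional seed-replicate consistency check reports the
fraction of replicates agreeing on the rank-1 target; both are
reconstructions of commonly displayed summaries whose exact estimators
are not standardized, and are labelled as such in the API.  Clinical
relevance cut-offs for ΔScore are exposed as user-configurable report
thresholds, not hard-coded logic.

## Pipeline

`pipeline.run_all` executes scoring (item-level input) → redundancy
screen → per-community networks → combined network → centrality →
stability → group comparison → Bayesian network → Ising interventions,
writing per-stage artifacts and a JSON report.  One global seed
deterministically derives stage seeds by fixed offsets
(bootstrap +101, CS +202, NCT +303, BN +404, Ising +505); every
randomized stage echoes its effective B/K/n_sim.  Analysis drivers
under `analysis/` present the same stages as a narrative sequence.

## Problem sizes used in validation

Oracle-equivalence checks run on 3-node problems against brute-force
optimization, exhaustive DAG enumeration (25 graphs) and 2-D likelihood
grid search.  Recovery checks use the default 20-node design at
n = 2000 (single run for edge F1; 50 replicate truths for bridge
ranking, judged top-3 within each node's community) and a 2-node Ising
model at n = 5000.  Calibration checks use 150 null replicates of a
6-node comparison (n = 300/group, K = 100, Pearson inputs) for the
comparison test's type-I error, and 20 ten-node pure-noise cohorts
(n = 300, B = 25 per drop level) for the CS coefficient's null
behaviour.  Bootstrap-heavy defaults (B = 1000) are reduced in tests
and drivers; the reductions are always stated at the call site.

## Known limitations

- Polychoric estimation is pairwise two-step, not full-information ML;
  smoothing can perturb individual entries when the matrix is
  indefinite.
- The refit EBIC default departs from the penalized-likelihood
  convention of common R implementations (documented above); set
  `refit=False` for strict parity.
- The Bayesian network treats ordinal scores as Gaussian; with 5-level
  items this is an approximation, and bootstrap presence/direction
  frequencies inherit it.
- The NCT assumes exchangeability under the null; covariate-driven
  group differences in marginal distributions will inflate rejections.
- eLasso coupling estimates are averaged directed logistic
  coefficients; under severe separation they are capped, with a
  warning, rather than re-estimated by exact methods.
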