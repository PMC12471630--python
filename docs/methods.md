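# Methods

This note documents the models and procedures the package implements, the
defaults that matter, the numerical choices, and what the synthetic-data
tests do and do not demonstrate about real data.

## The synthetic study

The generator emulates a 2×2×2 water (W) × nitrogen (N) × phosphorus (P)
addition field experiment in a karst shrubland: 8 treatments
(C, W, N, P, WN, WP, NP, WNP) × 5 blocks = 40 samples.

**Soil-property table.** Each variable is drawn
Normal(baseline mean × Π active-factor multipliers, SD), truncated at zero.
Baselines are the bundled control-treatment means
(`data/soil_treatment_means.csv`); SDs are the published standard errors
scaled by √5 (n = 5 blocks). Three documented single-factor responses are
planted as multiplicative effects on the mean: W → soil water content
×1.0758, N → nitrate ×1.5766, P → C:N ×1.1609. Truncation rather than
resampling is used for negative draws; at the table's coefficients of
variation the truncation probability is negligible, so the induced bias is
immaterial.

**OTU counts.** A Gaussian copula with log-normal marginals: latent
log-abundances are `μ_taxon + σ·z`, where `z` is multivariate normal with
correlation equal to the planted basis-correlation matrix, `μ_taxon ~
Normal(0, 1.5²)` spreads mean abundances across taxa (heavy right tail, as
in amplicon data), and `σ = 1.0` is the across-sample log-scale SD. With
this construction the Pearson correlation of latent log-abundances equals
the planted value exactly — the quantity SparCC estimates. Abundances are
closed to fractions and counts drawn multinomially at a log-normal library
size (mean 2×10⁴ reads, CV 0.3). The sequencing depth of the original study
is not published; these depth settings are conventional amplicon values and
are configurable. Default dimensions are 210 taxa (150 labelled "bacteria",
60 "fungi"; labels are metadata only — correlations are estimated jointly,
matching a multitrophic network), with 40 planted disjoint pairs, |ρ| ∈
[0.7, 0.9], 80% positive. Ten taxa per factor (drawn outside the planted
pairs, so treatment effects never confound correlation recovery) respond
2-fold to each active factor; this creates presence/absence variation
between per-sample sub-networks.

**What the generator does not emulate:** phylogenetic correlation structure,
overdispersion beyond the log-normal (no zero-inflation mechanism other
than sampling), taxon-specific depth biases, and block-level spatial
autocorrelation. Passing recovery tests therefore show estimator
correctness under a compositional log-normal world, not performance
guarantees on arbitrary real communities.

## SparCC

Given filtered counts (taxa with total abundance strictly > 400 across all
samples; strictness follows the usual "greater than" reading, and the
filter scope is configurable), each of R = 20 Dirichlet resamples draws
per-sample fractions from Dirichlet(counts + 1) (posterior under a uniform
prior), forms the variation matrix t_ij = Var[log(x_i/x_j)] (unbiased, n−1
denominator), and solves the basis system

    Σ_{j≠i} t_ij = (D−2) ω_i + Σ_j ω_j      (M ω = t_row, M = (D−2)I + 11ᵀ)

derived from t_ij = ω_i + ω_j − 2ρ_ij√(ω_iω_j) under the sparsity
approximation Σ ρ ≈ 0. Up to E = 10 exclusion iterations then remove the
strongest not-yet-excluded pair if |ρ| > 0.1 and re-solve; an excluded pair
(i, j) drops t_ij from rows i and j of the system, which removes one ω_i
and one ω_j term — M_ii, M_jj **and** M_ij, M_ji each decrement by 1. The
off-diagonal decrement follows directly from the row-sum derivation (and
matches the reference SparCC implementations); omitting it would leave a
stale coupling between excluded partners. Correlations are reported for
*all* pairs from the final variances: ρ_ij = (ω_i + ω_j − t_ij)/(2√(ω_iω_j)),
clipped to [−1, 1]; negative variance solutions are floored at 10⁻⁶. Taxa
involved in ≥ D−3 excluded pairs are dropped from that resample's solve
(NaN, with a warning) to keep the system well posed. The final estimate is
the element-wise median over resamples — robust to occasional degenerate
solves; with R = 1 the single resample is returned unchanged.

R = 20, E = 10, and the 0.1 threshold are the standard SparCC/FastSpar
conventions; the study-anchored values are the 400 filter, the 0.6
correlation threshold, p < 0.01, and B = 100 bootstraps.

Dirichlet draws are seeded per (seed, sample-id), making estimates exactly
invariant to sample reordering. Taxon reordering changes which draw lands
on which taxon, so invariance there is distributional, not bitwise; at
depth 2×10⁴ the resampling noise on the median is small (≲0.1 on any entry).

**Pseudo p-values.** Each of B = 100 bootstrap replicates permutes every
taxon's counts independently across samples — destroying association while
preserving marginals — and re-estimates ρ with a reduced R = 5.
p_ij = (1 + #{|ρ_b| ≥ |ρ_obs|})/(1 + B), so min p = 1/101. Consequence,
documented prominently: at the 0.01 significance level with B = 100, an
edge qualifies only when its observed |ρ| beats **all** 100 replicates.
Threshold comparisons: |ρ| ≥ 0.6 inclusive, p < 0.01 strict (both
configurable; the boundary conventions are package choices, not claims
about the original analysis).

## Networks and topology

Edges carry the correlation as weight and its sign; per-sample sub-networks
are induced subgraphs on taxa with count > 0 (a `min_count` option exists
for sensitivity analysis), retaining isolated nodes — which therefore enter
the density and average-degree denominators. Both the full node count and
the non-isolated count are reported.

Modularity is unweighted Newman Q over a partition from
Clauset–Newman–Moore greedy agglomeration (deterministic; communities
ordered by lowest node label; isolated nodes become singletons). *Relative
modularity* — reported by field studies but rarely defined — is taken as
RM = (Q_obs − Q̄_null)/Q̄_null with Q̄_null the mean modularity of detected
communities on 100 Erdős–Rényi G(N, E) graphs matched on nodes and edges.
Definition and replicate count are config-exposed. On ER inputs RM is
centred on 0 (self-consistency); RM is NaN with a warning if the null mean
is zero, and for edgeless sub-networks.

## Stability

**Natural connectivity** λ̄ = ln((1/N) Σ_i e^{λ_i}) over the unweighted
adjacency spectrum (signs and weights ignored — the measure is defined
spectrally for simple graphs), computed with a log-sum-exp and restricted
to the non-isolated block (isolated nodes contribute e⁰ = 1 each), which is
exact and keeps sequential-removal curves cheap. Exactly 0 for edgeless
graphs.

**Robustness** removes round(fN) nodes per fraction f on a 0→0.95 grid
(step 0.05) and counts the proportion of the original N that survive *and*
retain at least one edge — the secondary-extinction convention behind
"species remaining" curves (a flag disables it). **Vulnerability** removes
nodes one at a time and tracks λ̄ after each removal. Removal order is
uniform random (default) or degree-targeted (hubs first, dynamic degree,
ties to the lowest node index; deterministic, so replicates collapse to 1).
Scalars for ANOVA: the robustness AUC (mean over the fraction grid) and the
intact network's λ̄.

## Treatment statistics

Shannon H = −Σ p_i ln p_i (nats). The factorial ANOVA is an OLS fit of
y ~ W*N*P (type-II sums of squares; sequential and partial coincide on the
balanced design, which is asserted). A Shapiro–Wilk gate on full-model
residuals (α = 0.05) triggers the ln(x+1) transform when normality fails;
the flag is recorded. Block is available as an additive fixed term but off
by default — the three-way analysis as usually reported lists only W, N, P
and their interactions; both variants are one flag apart. A constant
response is reported as F = 0, p = 1 for every term rather than 0/0.

Fisher's LSD uses pooled-MSE pairwise t tests on the residual df. Compact
letters are the maximal cliques of the "not significantly different" graph,
ordered by descending group mean — this satisfies the display contract
exactly (two groups share a letter iff their pairwise p ≥ α) and is
deterministic.

Marginal percent change of factor F for variable v is
100 × (mean over +F samples − mean over −F samples)/(−F mean); on a
balanced design this equals the average of the four +F treatment means
against the four −F means, which is how the bundled published table
reproduces the reported +7.58% (SWC, W), +57.66% (NO₃⁻, N) and +16.09%
(C:N, P) to within printed rounding.

The Mantel test correlates upper-triangle distances (Spearman default),
with a one-sided permutation p over joint row/column permutations of the
second matrix (999 permutations, add-one rule). Constant distance vectors
(e.g. a zero-variance environmental variable) carry no rank information and
return NaN rather than an arbitrary value.

## Pipeline determinism and problem sizes

Stage seeds derive from the master seed by SHA-256 hashing of
(seed, stage), so stages never share or shift each other's random streams;
all numeric output uses fixed `%.10g` formatting. Two runs from one master
seed are byte-identical (checksums recorded in `manifest.json`).

Default per-run Monte-Carlo sizes are chosen so a full default run (40
samples, 210 taxa, B = 100) completes in about a minute on one CPU while
keeping Monte-Carlo error well below the treatment signal of interest:
100 ER replicates per relative-modularity null, 50 robustness replicates
and 10 vulnerability replicates per network (41 networks: global + 40
sub-networks). The validation suite uses the emulated study scale for
estimator checks (D = 50, n = 40, 10 seeds) and reduced dimensions
(D = 80, B = 100, 5 seeds × 3 density levels) for the
complexity→stability ranking, which concerns ordering rather than absolute
values.

## Known limitations

- Pseudo p-values are granular (multiples of 1/101 at B = 100); tests near
  the 0.01 boundary are all-or-nothing, as discussed above.
- Relative modularity uses one specific (ER-matched, greedy-detection)
  null; degree-preserving nulls would give different absolute RM values.
- The per-treatment pooled-network variant of the stability analysis is
  supported by pooling sample tables upstream, but the default is
  per-sample curves; single-curve-per-treatment figures in field studies
  may correspond to either convention.
- SparCC assumes sparse true correlation; dense planted structures (many
  correlated pairs among few taxa) bias basis variances and attenuate
  estimates.
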