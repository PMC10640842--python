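# Methods

## Scope and data model

The unit of analysis is the *plot network*: the season-aggregated weighted
bipartite matrix of one 4 m² experimental plot, rows = plant species with at
least one visit, columns = insect species with at least one specimen,
entries = visit counts. Season aggregation is by summation over sampling
events — the only operator consistent with treating total specimen counts as
network weights. Plants that bloomed but received no visits are excluded
from the matrix but retained in the plot metadata (`plants_bloomed`),
because the connectance denominator is defined over bloomed plants, not
visited plants. Species labels are exact case-sensitive strings; taxonomic
cleaning is assumed upstream.

## Structural metrics

**Connectance.** `C = L / (P · I)` with `L` = realized links, `P` = bloomed
plant species in the plot, `I` = the experiment-wide insect species pool
(a parameter: pass the study-wide observed richness, or the pool size of a
simulation). This "experiment-wide" variant lets plots be compared against
a common interaction space; it is bounded by (0, 1].

**Degrees.** Unweighted degree `L/S` and weighted degree `N_v/S`, where `S`
counts the species actually present in the network. These are per-species
averages of link count and visit count respectively.

**NODF.** For every pair of rows (and of columns) with strictly decreasing
fill, the paired term is 100 × (shared presences) / (fill of the sparser);
equal-fill pairs contribute 0. NODF is the mean over all row pairs and
column pairs. The implementation is vectorized over the pair matrices and is
exact (no sampling).

**max-NODF and NODFc.** Raw NODF depends strongly on matrix size and fill,
so nestedness is normalized by the maximum NODF attainable at the same
dimensions (m, n) and link count L:

    NODFc = (NODF / max_NODF) / (C_fill · ln √(mn)),   C_fill = L/(mn).

The fill constant and the natural-log geometric-mean size constant follow
the established size-correction convention for this statistic. The search
for max-NODF is exhaustive for mn ≤ 12; otherwise a greedy construction
(maximally nested minimal cover, then additions on the staircase frontier;
for budgets below m+n−1 a minimal row/column cover with additions anywhere)
is refined by first-improvement single-link relocations, capped at 10,000
evaluated moves. The heuristic is deterministic, and equals exhaustive
enumeration on every feasible (m, n, L) up to 3×4 (verified in tests).
Results are cached by (m, n, L), which matters in the null-model stage where
many draws share dimensions. When max-NODF is 0 (permutation-matrix fills)
the observed NODF is necessarily 0 and the ratio is defined as 0.

**Modularity.** Barber's weighted bipartite modularity
`Q = (1/F) Σ (A_ij − k_i d_j/F) δ(g_i, g_j)` is maximized by label
propagation: rows and columns alternately adopt the module label that
maximizes their exact Barber contribution (each sweep is monotone in Q),
followed by agglomerative merging of module pairs with positive merge gain,
repeated from 20 seeded restarts by default. Ties in Q break toward fewer
modules. The single-module partition (Q = 0) is always admissible, so the
reported optimum is never negative. Q for a *given* partition is exact
(`barber_q`); only the combinatorial search is heuristic, which is why a
seed policy is part of the interface.

## Null models

Null ensembles hold row and column sums fixed (species totals are treated
as given; only the allocation of individual visits is randomized) using
Patefield's conditional algorithm, i.e. tables follow the Fisher–Yates
(multiple hypergeometric) distribution — the classic `r2dtable` null. Each
draw is scored with the same six metrics as the observed network
(connectance, both degrees, NODF, NODFc, modularity), and observed values
are standardized as z-scores. Two consequences of fixed margins are handled
explicitly:

- weighted degree (`N_v/S`) is completely determined by the margins, so its
  null distribution is degenerate; such metrics are reported as
  *not standardizable* (missing), never as ±∞;
- modularity on each draw uses a fresh optimizer seed derived from the
  ensemble's master seed, and fewer restarts than observed networks
  (default 4 vs 20) since the z-score aggregates over hundreds of draws.

The treatment-level departure rule flags a metric when mean(z) ± sd(z)
across that treatment's plots excludes zero. The z-score treatment models
(below) use treatment as the only fixed effect — floral display is a
plot-level covariate of the raw metric, not of its null standardization.

## Diversity

Pooled per-treatment abundance vectors feed Hill numbers
`qD = (Σ pᵢ^q)^(1/(1−q))` (q = 0 richness, q = 1 the Shannon limit, q = 2
inverse Simpson), the singleton/doubleton coverage estimator
`Ĉ = 1 − (f₁/n)·[(n−1)f₁/((n−1)f₁ + 2f₂)]`, and interpolated rarefaction:
q = 0 uses the exact hypergeometric formula, q ≥ 1 the Hill number of the
expected abundance-frequency counts of a size-m subsample. Extrapolation
beyond the observed sample size and bootstrap confidence bands are out of
scope; the quantitative claim the pipeline supports is the coverage value.

## Treatment inference

Each network metric is modelled with a Gaussian linear mixed model fitted by
REML (`statsmodels` MixedLM behind the module surface): fixed effects are
treatment (reference level C) and the mean-centered log floral display,
random intercept per block. Abundance-like responses are log-transformed;
"GLMM" here means a Gaussian LMM on transformed responses — the reported
t statistics and log-scale effect sizes are inconsistent with count-family
link functions, and this choice is made deliberately and documented. The
treatment × display interaction is fitted first and dropped unless some
interaction contrast has p < 0.05. Centering the display covariate makes
treatment contrasts interpretable as differences at the average display
when an interaction is retained. p-values use a residual-df t
approximation (not Satterthwaite/Kenward–Roger); contrast estimates are
unaffected, p-values may differ in the third decimal for block designs of
this size. Constant responses short-circuit to zero effects with R²m = 0.

Nakagawa's R² uses the variance of the fixed-effect linear predictor:
R²m = σ²_f/(σ²_f+σ²_α+σ²_ε) and R²c = (σ²_f+σ²_α)/(σ²_f+σ²_α+σ²_ε).

Per-species foraging breadth (plant species visited per plot, zero for
plots a species skipped) is compared across treatments with Kruskal–Wallis
(tie-corrected) plus Dunn-type pairwise contrasts against the control:
mean rank differences with normal-approximation two-sided p-values,
Bonferroni-multiplied by the family size (default 10, the number of most
abundant species tested). Pearson correlations across metrics are reported
pairwise with a p < 0.05 significance flag.

## Synthetic experiment generator

The generator emulates the study design, not insect behaviour: 8 blocks ×
{C, F, H, HF}, 7 plants with a fixed attractiveness profile, a 90-species
insect pool with log-normal activity aᵢ (σ_log = 0.8), log-normal floral
display per plot (mean log 9.2, σ_log 0.5, mm² scale) *independent of
treatment* — the treatments changed floral chemistry, not display size, and
a distribution test in the suite enforces this. Visitation is two-stage:

1. **Inclusion.** Species i forages in a plot with probability
   πᵢ = aᵢ/(aᵢ + c) (half-saturation c = 2.0); fertilizer multiplies the
   inclusion odds by ρ_F = 1.5. The realized number of included species
   concentrates at Σπᵢ (stochastic rounding) with species drawn without
   replacement ∝ πᵢ: fixed-effort field surveys have sub-binomial richness
   noise, and fully independent Bernoulli inclusion would make the plot
   richness far noisier than the precision real block designs of this size
   achieve.
2. **Counts.** Each included species deposits negative-binomial visits on
   each bloomed plant with mean ∝ activity × plant attractiveness ×
   (display/display mean)^β × exp(−δ_H·[herbicide]), β = 1, size θ = 15,
   baseline rate 0.24. Links with zero counts vanish, so richness responds
   mildly to anything that scales counts.

δ_H = 0.33 is the herbicide log-abundance decrement; ρ_F is set so
fertilizer adds ≈ +4.7 realized species per plot. With the defaults a
season yields ≈ 1,900 specimens over 32 plots with ≈ 80–90 visitor species,
and the mixed-model stage recovers a significantly negative C–H abundance
contrast and a significantly positive C–F richness contrast in ≥ 80% of
seeded replicates, with both contrasts centered on zero (type-I rate ≈ 5%)
when δ_H = 0 and ρ_F = 1. What the generator does *not* emulate: phenology
and within-season dynamics, site covariates beyond the block intercept,
insect population feedbacks, and identity-level visitation structure
(plants differ only in attractiveness). Passing tests therefore demonstrate
that the pipeline recovers design-level effects of the planted kind — not
that any particular field system behaves like the generator.

Dose arithmetic: seasonal total = Σ_months conc(mg/L) × 10 L × 4
applications / 4 m², mg→g. Four applications per month is the rate implied
by a weekly schedule and is the only value consistent with the printed
seasonal totals.

## Pipeline and reproducibility

`run_all` derives each stage's seeds from the config seed, so a run is
deterministic end to end (byte-identical CSVs; the JSON manifest records
the config digest, input source, and counts). Degenerate inputs are
explicit errors (empty plot networks, all-zero matrices, undefined
connectance at zero bloomed plants) rather than NaNs. Null ensembles
default to 500 draws per network for study-scale analyses; the acceptance
script uses 100 draws and 2 optimizer restarts per draw, which keeps the
full recomputation to a few minutes on one CPU while leaving z-score
estimates stable to well under the reported precision.

## Known limitations

- The max-NODF search is heuristic above mn = 12; it is exact on everything
  enumerable we test, but a certified global optimum is not guaranteed for
  large sparse matrices.
- Mixed-model p-values use a residual-df approximation; for 31–32
  observations in 8 blocks these are close to, but not identical with,
  Satterthwaite-corrected values.
- The weighted-degree z-score is structurally degenerate under fixed-margin
  nulls and is reported missing; pipelines built on tools that report a
  nonzero value are computing a different network-level quantity.
- Diversity extrapolation beyond the sample and bootstrap intervals are not
  implemented.
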