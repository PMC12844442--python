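# Methods

This note documents the models implemented in `microscale`, the parameter
choices that matter, what the synthetic generator does and does not emulate,
and the numerical conventions.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Data model and preprocessing

Communities are samples × taxa integer count matrices (`OtuTable`); sample
metadata (`SampleFrame`) describes a nested quadrat design: replicate plots
per group, quadrats at levels k = 0, 1, … whose side doubles per level
(side0 · 2^k, area = (side0 · 2^k)² m²), sharing an origin so each quadrat
nests inside the next.  With side0 = 0.5 m and 13 levels the design spans
0.25 m² to 2048 × 2048 m².

* **Rarefaction** draws an exact multivariate hypergeometric subsample (no
  replacement) to a fixed depth; samples below the depth are dropped with a
  warning, not padded.  Depth is a plain parameter.
* **Taxon filtering** keeps taxa whose share of the grand total is
  ≥ `min_rel_abund` (default 0.001) *and* whose prevalence is
  ≥ `min_prevalence` (default 0.2).  Prevalence is computed over whatever
  sample set is handed in, so per-group or per-area filtering is achieved by
  subsetting first.  The abundance criterion uses the grand-total share
  rather than a per-sample mean share — the common convention for a
  "relative abundance below 0.1%" rule.

## Taxa–area relationship (TAR)

For each plot, samples at levels ≤ k are pooled (cumulative nesting) and the
richness of the pooled count vector recorded against the level-k area.  Two
models are fitted to each group's pooled points:

* logarithmic `S = c + z·log_b A` by closed-form OLS (default base b = 10;
  `z` scales with the base choice, so the base is always reported with it);
* power `S = c·A^z` by Levenberg–Marquardt on the original scale,
  initialised from log–log OLS with deterministic jittered restarts.

R² is computed on the original richness scale for both, making the models
directly comparable.  Replicate plots contribute separate points to one
pooled fit per group by default (a per-plot mode would fit each plot and
compare slopes; pooling uses all the information and mirrors how nested
designs are usually summarised).  Slope differences between groups are
tested by permutation: pooled (area, S) points are randomly reassigned to
the two groups preserving sizes, refitted, and the two-sided p-value is
(1 + #{|Δz_perm| ≥ |Δz_obs|}) / (n_perm + 1).  For the logarithmic model the
permutation slopes are computed in closed form for all permutations at once.
A plot-level permutation unit is available for nested dependence.

## Co-occurrence networks and the node–area relationship (NAR)

Pairwise Spearman correlations use average-rank ties; two-sided p-values
come from the t-approximation t = r·√((n−2)/(1−r²)) (p = 0 at |r| = 1
exactly; constant taxa are flagged and recorded as r = 0, p = 1).  Edges
require |r| strictly above `r_thresh` (default 0.80) and p below `p_thresh`
(default 0.05, uncorrected as is conventional for this construction;
Benjamini–Hochberg correction is available and can only remove edges).
Nodes are taxa with at least one edge.

The NAR rebuilds the network per nested level from the cumulative sample
set (all samples at levels ≤ k across the group's plots), re-applying the
abundance/prevalence filter to each level's sample set; a per-level
(disjoint) mode is available.  Levels with fewer than `min_samples` samples
are skipped with a warning.

**Choosing `min_samples`.** The default (8) only guards against degenerate
correlation estimates.  At the fixed threshold |r| > 0.8, however, the null
exceedance probability per taxon pair is roughly 2Φ(−0.8·√(n−3)) under the
Fisher approximation — about 10⁻³ at n = 12 — so a table with several
hundred filtered taxa (10⁴–10⁵ pairs) accumulates dozens of spurious nodes
at small n that vanish by n ≈ 20.  For species-rich tables we therefore
recommend `min_samples` ≳ 20–24; the worked example uses 24.  This
small-sample edge inflation is itself the mechanism that makes a
never-cohering community's node–area curve decline with area.

**Tipping point.** A single line and a continuous two-piece linear model in
(log10 area, node count) are fitted, the breakpoint searched over interior
observed levels by an SSE grid.  The curve is classified `unimodal` when the
segmented model improves SSE by ≥ 10% and the slopes flip from positive to
negative; otherwise `monotonic-increasing`/`-decreasing` by the sign of the
single-line slope (a perfectly flat line counts as decreasing).  The 10%
margin keeps noise on an essentially monotonic curve from being declared a
tipping point.

## Neutral community model (NCM)

At Sloan's stationarity a taxon with metacommunity frequency p has local
relative abundance q ~ Beta(Nm·p, Nm·(1−p)).  The classic fit predicts the
occurrence frequency as the Beta tail above a detection limit d = 1/N (one
read at depth N): F̂ = 1 − I_d(Nm·p, Nm·(1−p)).  Because presence in count
data is "at least one of N reads", detection is really a beta-binomial
event, and the exact prediction is

    F̂ = 1 − B(Nm·p, Nm·(1−p) + N) / B(Nm·p, Nm·(1−p)).

The Beta-tail approximation systematically overestimates `m`: on data
simulated exactly from the stationary model (N = 2000, S = 500, 100
samples) it inflates m̂ by 20–48% across m ∈ {0.05…0.6}, while the exact
form recovers m within a few percent (both measured by the test suite).
`fit_ncm` therefore defaults to `detection="exact"`; the classic
`detection="beta-tail"` (with configurable d) is retained for comparability
with the standard R implementations.  Nm is located by a 60-point log-spaced
grid search refined with bounded scalar minimisation; R² = 1 − SSres/SStot
on the observed frequencies; the 95% band uses Wilson binomial intervals at
the sample count, partitioning taxa as above/within/below.  A uniform
per-sample depth is required (rarefy first), and m = Nm/N.

## Normalised stochasticity ratio (NST)

Per group, observed pairwise dissimilarities D_ij (Bray–Curtis by default;
Jaccard available) are compared with their mean E_ij over null communities
that fix each sample's richness and total, draw occupancy proportional to
regional occurrence frequency, and assign abundances multinomially
proportional to regional relative abundances.  Selection strength per pair
is C_ij = (D−E)/(D_max−E) if D > E (D_max = 1) else (E−D)/E; stochasticity
is ST_ij = 1 − C_ij, and NST is the mean ST over pairs, clipped to [0, 1].
The reported standard error is over pairwise ST values — the resampling
unit is the pair, which understates uncertainty relative to a sample-level
bootstrap and is reported as such.  Pairs with E = 0 are excluded and
counted.  The default 1000 null draws keep the Monte-Carlo error in E well
below the D−E contrasts of interest; scaled-down runs (e.g. 200) are used
where many replicates are needed.

This normalisation is deliberately the simplest member of the
stochasticity-ratio family; published variants add further weighting and
pairing conventions.  The estimator here is validated behaviourally: data
generated by the null model itself score high; Sloan-neutral fixtures score
> 0.5; strongly niche-filtered fixtures score < 0.5.

## Niche breadth

Levins breadth per taxon, B_i = 1/Σ_j P_ij², with P_ij the share of taxon
i's total found in sample j; B ranges from 1 (one sample) to the number of
samples (even spread).  The community value is the unweighted mean over taxa
with nonzero totals (the "B_com" convention); an abundance-weighted mean is
also reported since rare taxa otherwise dominate.

## Diversity, heterogeneity, Mantel

Alpha diversity: richness, Shannon–Wiener (natural log) and Gini–Simpson
1 − Σq².  Beta diversity: Bray–Curtis on counts.  Environmental
heterogeneity: variables z-scored over all samples (sample sd, ddof = 1;
constant variables dropped with a warning), then within-group pairwise
distances — Euclidean by default, Bray–Curtis on the standardised values as
an option, since both conventions are in circulation; the group mean is the
heterogeneity summary.  Mantel tests correlate lower triangles (Pearson
default, Spearman optional), permuting rows/columns of the second matrix
jointly, one-tailed "greater" by default with 999 permutations — the
defaults of the common R implementation; per-variable environmental
distances are |z_i − z_j|.

## Synthetic generator

The generator emulates the *statistical* structure of a nested amplicon
survey, not any real taxonomic composition:

* **Metacommunity**: lognormal species-abundance distribution (σ the
  evenness knob), normalised.
* **Neutral regime**: per sample, q ~ Beta(N·m·p, N·m·(1−p)) per taxon,
  rows renormalised, counts multinomial at depth N — exactly the stationary
  distribution the NCM fit assumes, enabling sharp parameter-recovery
  tests.  (m = 0 is rejected; the Beta degenerates.)
* **Niche regime**: a smooth environmental field E(x, y) — linear gradient
  plus Gaussian bumps, standardised to unit variance and scaled by
  `env_range` — is sampled at quadrat coordinates; taxon i with optimum E_i
  contributes expected share ∝ p_i·exp(−niche_strength·(E−E_i)²).  The
  written environment table carries the filtering axis and two pure-noise
  variables.
* **Guilds**: each guild's member taxa (consecutive blocks of the most
  abundant taxa, so count noise stays small) share a multiplicative factor
  exp(loading · g(x, y)) where g is a unit sine field of the *within-plot*
  coordinates with wavelength `field_scale`.  An i.i.d. per-sample factor
  would induce the same correlation at every scale; a smooth spatial factor
  means samples within a small extent see nearly the same factor value (no
  correlation to detect) while sample sets spanning ~ a wavelength see it
  vary, so within-guild correlation *emerges with sampled extent* — the
  mechanism behind a rising node–area curve.  Because the field depends on
  within-plot position it repeats identically across replicate plots, so
  pooling plots strengthens rather than dilutes the signal.  For samples at
  levels ≥ `collapse_level` the factor is redrawn independently per member
  taxon (variance-matched), destroying the correlation at large scales and
  creating the designed tipping point; `collapse_level = 0` yields guilds
  that never cohere.  Counts are redrawn multinomially at each sample's
  original depth, so totals are conserved.

`nar_guild_fixture` freezes the canonical node–area study conditions: nine
levels (0.25 m² to 16384 m²), three plots, two corner samples per level,
N = 4000 reads, m = 0.9 (a weakly noisy neutral base so the guild factor
dominates), 100 taxa with σ = 0.8 (members abundant enough that multinomial
noise is small), ten guilds of six with loading 2.0 and wavelength
max_side/8 — under which within-guild Spearman r crosses the 0.8 threshold
around mid levels and saturates near 0.9.

What the generator does **not** emulate: real taxonomies and their
phylogenetic structure, sequencing error and compositional artefacts beyond
multinomial sampling, temporal variation, and spatial autocorrelation of
the neutral noise itself.  Passing tests therefore demonstrate estimator
correctness and calibration under the stated generative models, not
performance guarantees on any particular field dataset.

## Problem sizes and determinism

Simulated fixtures use 36–162 samples and 100–2000 taxa; permutation tests
use 999 permutations (500 replicates for calibration checks), and NST uses
200–1000 null draws depending on how many replicates a check needs.  These
sizes make every analysis exact enough to verify the properties of interest
while keeping any single run in seconds to a couple of minutes.

Every stochastic step takes an explicit seed; the pipeline derives and logs
a sub-seed per stage from the master seed, and identical configs reproduce
all outputs byte for byte (the manifest records versions, config, seeds and
warnings, never timestamps).

## Known limitations

* The NST normalisation is the simple pairwise form described above; it is
  not numerically interchangeable with the weighted published variants,
  although it preserves the 0.5 interpretation boundary in our calibrations.
* The Spearman p-value uses the t-approximation, adequate at n ≥ ~10; at
  smaller n combined with hundreds of taxa, threshold exceedance is noise-
  dominated whatever the p-value — hence the `min_samples` guidance above.
* The breakpoint model is two-piece linear in log area; smooth unimodal
  curves are classified correctly but their curvature is not modelled.
* `compare_slopes` permutes richness points (or plots); it does not model
  the dependence induced by cumulative pooling within a plot, which is why
  the plot-level unit is offered.
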