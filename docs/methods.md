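# Methods

This note documents the statistical machinery the package implements, the
choices made where the underlying procedures are conventionally
underspecified, and what the synthetic-data generator does and does not
emulate.

## Study design assumed by the pipeline

Samples sit on a continuous-cropping-year (CCY) gradient with seven levels
(1, 2, 5, 10, 15, 20, 25 years) and four replicates each. Samples with
2–10 years form the *short-term* class, ≥15 years the *long-term* class;
first-year samples belong to neither class. Group contrasts (networks,
per-class neutral-model fits, βNTI groupings) use only the two duration
classes; gradient regressions use all 28 samples. Abundance tables are
taxon × sample counts (or relative abundances); the orientation is fixed,
taxa as rows.

## Diversity

*Chao1* uses the bias-corrected estimator S_obs + F₁(F₁−1)/(2(F₂+1)) with
F₁/F₂ the singleton/doubleton counts, so it is defined when F₂ = 0 and
always ≥ S_obs. *Shannon* entropy is −Σ pᵢ ln pᵢ in natural log. Both are
computed on raw counts without rarefaction by default; rarefaction depth, if
any, is the caller's responsibility and is recorded in output.

*Bray–Curtis* is 1 − 2Σ min(xₐᵢ, x_bᵢ)/(Σ xₐᵢ + Σ x_bᵢ); on counts it
equals the relative-abundance version whenever sample totals are equal.
*PCoA* is classical scaling: Gower double-centering of −½D², symmetric
eigendecomposition, coordinates eigvec·√λ over positive eigenvalues.
Negative eigenvalues (possible for non-Euclidean dissimilarities) are
dropped from the explained-variance denominator and their total magnitude is
reported (`negative_eigenvalue_mass`) so the correction is visible. The
ordination distance is Bray–Curtis by default; nothing in the pipeline
depends on that choice.

Group testing combines one-way ANOVA across CCY groups, a pooled-variance
two-sample t-test between duration classes, and Fisher's LSD (pairwise
t-tests sharing the ANOVA error variance) with an insert-and-absorb compact
letter display. Constant inputs take a degenerate path (p = 1, equal
letters) rather than erroring. Trend fits are ordinary least squares; the
linear model reports Pearson's r and its two-sided p, the quadratic model
(for unimodal phylum-style trends) reports the regression F-test p. Trend
fits on "dominant" taxa use the top N (default 10) by grand-mean relative
abundance.

## Co-occurrence networks

Taxa are filtered to mean relative abundance > 0.1% across the group's
samples (a "cumulative abundance" floor; a strict sum-across-samples
variant is available via `mode="sum"`). Pearson correlations are computed
on relative abundances across samples (≥4 samples required); two-sided
p-values come from the t distribution with n−2 df. The full upper triangle
is Benjamini–Hochberg adjusted, and an edge requires |r| ≥ 0.7 **and**
q < 0.05 (strict inequality; pairs at exactly q = 0.05 are excluded).
Zero-variance taxa have undefined correlations and can form no edges.
Isolated nodes are retained by default so node counts are comparable across
thresholds.

Modularity is computed from Louvain communities on |r| weights with a fixed
seed and resolution 1.0; Louvain is a heuristic, so agreement with other
tools (e.g. Gephi) is approximate by nature. Average path length is averaged
over connected pairs only, with the number of components reported alongside
— conventions differ between tools and this one is stated rather than
guessed. Correlating relative abundances carries the usual compositional
caveat (closure can induce spurious negative correlation); the package
deliberately implements the simple Pearson pipeline rather than
compositional alternatives (SparCC etc.), which are out of scope.

## Natural connectivity and attack curves

Natural connectivity of an adjacency matrix with eigenvalues {λᵢ} is
λ̄ = ln((1/N) Σ exp(λᵢ)), computed with log-sum-exp so large spectra cannot
overflow. It is 0 exactly for edgeless graphs and strictly increasing in n
for complete graphs. The thresholded graph is binarized first (the spectral
definition is for adjacency matrices); an |r|-weighted variant exists behind
a flag. Attack curves remove one node per step — under `highest_degree` the
*current* maximum-degree node (adaptive re-ranking), ties broken
lexicographically by node id for determinism — recomputing λ̄ on the
remaining N nodes each step, until ⌈max_frac·N⌉ nodes are gone (capped at
N−1; default max_frac = 0.8). Percent-of-initial values are undefined for
edgeless starting graphs and flagged degenerate rather than erroring.
Curves are compared with a two-sided Wilcoxon signed-rank test on
pct-of-initial values aligned by linear interpolation onto the union of the
two fraction-removed grids; identical curves return p = 1 with an explicit
note, and short series (<5 shared points) fall back to the exact test with
a warning note.

## Sloan neutral community model

With community size N (arithmetic mean of sample read totals — a single
size must summarize unequal depths), detection limit d = 1/N, and
metacommunity abundance p (grand-mean relative abundance), the model
predicts occupancy Freq(p) = 1 − BetaCDF(d; Nm·p, Nm·(1−p)). The migration
probability m is estimated by bounded scalar least squares on untransformed
frequencies, m ∈ (10⁻⁶, 1); R² = 1 − SSE/SST may be negative when the model
fits worse than the mean. Bootstrap (taxa resampled with replacement,
default 1,000 iterations) yields percentile CIs for m, Nm and R² — the "fit
statistics". The three-fraction partition (above/within/below) compares
observed occupancy to a 95% band around the predicted frequency; the default
band is the Wilson score interval for a proportion estimated from n_samples
presence/absence trials, matching the canonical Sloan-model scripts, with a
bootstrap percentile band of the fitted curve available via
`band="bootstrap"`.

**Known limitation — detection bias.** The generative twin
(`simulate_neutral_table`) draws per-sample abundance x ~ Beta(Nm·p,
Nm·(1−p)) and reads ~ Binomial(N, x), so real detection is soft:
P(detect) = 1 − (1−x)^N. The fitted model assumes the hard threshold
x > d. Taxa near the detection limit are therefore occupied more often than
the model predicts, and the least-squares fit compensates by inflating Nm —
by roughly 10–30% when many taxa populate the transition zone (worst around
Nm ≈ 10³ at N = 10⁴), and negligibly when occupancies are saturated.
Refitting with the exact beta-binomial detection probability removes the
bias (≤3%), and the canonical R implementation (nlsLM on `pbeta`)
reproduces our estimates to three significant figures, confirming this is a
property of the standard estimator, not of this implementation. The same
softness lowers the within-band fraction on neutral data to ≈75–80% rather
than the nominal 95%.

## βMNTD, βNTI and assembly processes

Abundance-weighted β-mean nearest taxon distance between samples a and b is

    βMNTD = ½ [ Σᵢ f_ia · min_{j∈b} d(i,j) + Σⱼ f_jb · min_{i∈a} d(j,i) ]

with f the within-sample relative abundances over present taxa and d the
patristic distance; shared taxa contribute distance 0, and the measure is
symmetric and invariant to rescaling a sample's counts. βNTI standardizes
the observed βMNTD against a null distribution from shuffling the taxa
across the phylogeny's tips (abundances fixed; 999 randomizations by
default, one seeded generator). Pairs are classified heterogeneous selection
(βNTI > +2), homogeneous selection (< −2) or stochastic; pairs with a
degenerate null (sd = 0 — e.g. star trees, or two samples containing
exactly the same taxon set, where every shuffle preserves all zero
nearest-taxon distances) are flagged `unclassified` rather than forced into
a class. Group summaries report process percentages over classified pairs
within-short, within-long, and between classes; first-year samples are
excluded from all three groupings.

Two statistical points shape how the null model should be validated.
First, within one dataset all sample pairs share a single realized
assignment of taxa to tips, so their βNTI values are strongly correlated:
a single dataset's exceedance rate is not an estimate of the type-I rate.
Calibration is therefore checked across independent replicate simulations
(each with its own tree and neutral table), where the aggregate
|βNTI| > 2 rate is ≈5%. Second, selection power is non-monotone at the
extremes of niche width σ: as σ shrinks the mean between-environment βNTI
first rises, but below σ ≈ 0.25 (traits standardized to unit sd)
communities collapse onto few clades and the null sd inflates, while at
σ ≳ 1.5 communities overlap completely and pairs degenerate. The power
property is asserted on the monotone range σ ∈ (1.0, 0.75, 0.5).

## Synthetic-data generator

`simulate_tree` draws Kingman-coalescent trees (uniform pair merges,
exponential internode times), giving ultrametric bifurcating phylogenies.
`brownian_traits` evolves a niche optimum along the tree (variance ∝ branch
length) and standardizes it to zero mean, unit sd, so niche widths and
environments share a scale. `make_niche_model` maps CCY linearly onto an
environment in (−1, 1) — the simplest strictly monotone gradient.
`simulate_selection_table` filters taxa through a Gaussian kernel
exp(−(trait−env)²/2σ²), applies multiplicative lognormal noise
(default sd 0.3) and draws multinomial reads.

`simulate_ccy_dataset` mirrors the full design: 28 samples; one set of 8
taxa whose summed relative abundance rises linearly 10% → 30% across
1 → 25 years and one mirrored declining set (the opposing dominant-genus
trends); Zipf-like within-set shares with lognormal noise (per-taxon sd
0.05, per-set sd 0.05); a neutral Sloan background (Nm = 1000, lognormal
metacommunity) for the remaining 104 taxa; multinomial sampling at 20,000
reads so columns sum exactly to depth. The shared set-level trends make
within-set pairs strongly positively and between-set pairs negatively
correlated, giving the co-occurrence networks signed structure to detect.
The noise scales are chosen for test power: they produce strong, detectable
gradients and network signal at n = 12 samples per class, which real soil
data will usually not match.

The generator emulates the *statistical* structure each stage assumes —
monotone abundance trends, neutral occupancy–abundance coupling,
phylogenetically conserved niches under a monotone environment. It does not
emulate sequencing error, chimeras, compositional artifacts, taxonomic
mis-annotation, spatial autocorrelation between replicate plots, or joint
selection-plus-neutral dynamics in a single community. Passing tests
therefore demonstrate that the estimators recover known structure under
their own modelling assumptions, not that those assumptions hold in field
data.

## Determinism and problem sizes

Every stochastic step (tree simulation, abundance draws, null
randomizations, bootstraps, Louvain, random attacks) derives from one seed
via spawned child sequences; pipeline reruns with the same config are
byte-identical, and the seed is recorded in `summary.json`. Defaults used
by the orchestrated pipeline — 199 βNTI nulls and 200 bootstrap iterations
— keep an end-to-end run under a minute on one core; the acceptance script
raises these to the conventional 999 nulls and 1,000 bootstrap iterations.
Library defaults elsewhere follow the field's conventions (999 nulls, 1,000
bootstraps, |r| ≥ 0.7, q < 0.05, 0.1% floor, 80% node removal).
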