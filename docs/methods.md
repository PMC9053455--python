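# Methods

This note documents the models, conventions and design choices behind
`paregions`: what each stage computes, which knobs matter, what the
synthetic generator does and does not emulate, and the numerical decisions
a maintainer would need to know.

## Guideline scoring

Weekly minutes of vigorous activity, moderate activity and walking are
collapsed into moderate-equivalent minutes (MEM), weighting vigorous
minutes ×2 and walking minutes ×0.5 relative to moderate minutes. The four
categories partition respondents exhaustively:

| category | rule |
|---|---|
| non-active | vigorous = moderate = walking = 0 exactly |
| below-healthy | active but MEM < 150 |
| healthy | 150 ≤ MEM < 300 |
| extra-healthy | MEM ≥ 300 |

Conventions fixed here: *meeting the guidelines* is inclusive at 150 and at
300 ("below 150" / "300 or more" force the half-open bins [150, 300) and
[300, ∞)); walking counts as physical activity, so a walking-only
respondent is below-healthy, not non-active; the working-age filter 18–64
is closed on both ends. Regional rates are plain unweighted percentages of
the eligible (in-age) respondents — no survey post-stratification weights
are applied, since the estimand is the simple regional share. Classification
is monotone: increasing any minute field can only move a respondent toward
a more active category.

## Taxonomy

**Inputs.** The four raw percentage rates per region, unstandardized: all
four live on the same 0–100 scale, so standardizing would only reweight
them arbitrarily.

**Hierarchical stage.** Agglomeration is implemented with the
Lance–Williams recurrence for single, complete, average and Ward linkage.
Ward is restricted to squared Euclidean dissimilarities and its recorded
merge height is the increase in total within-cluster sum of squares
(ΔESS = |A||B|/(|A|+|B|) · ‖c_A − c_B‖²; d²/2 when two singletons merge);
the other linkages record the plain cluster dissimilarity. All ties break
toward the lowest cluster index, and profiles are ordered by region id
before clustering, so the stage is deterministic and invariant to input row
permutations.

**Choosing k.** Each candidate k in 2…6 is scored by the mean pairwise
adjusted Rand index of its cut partitions across the exploration battery
(default: Ward/squared-Euclidean, complete and average linkage under
Euclidean and Manhattan distances; single linkage is supported but excluded
from the default battery because of chaining). Agreement alone cannot pick
k: on well-separated data the *coarser* cuts of the same tree also agree
perfectly across methods, so every robust k (mean ARI ≥ 0.8 by default) is
kept and the recommendation among them maximizes the relative merge-height
jump in the Ward dendrogram — the standard elbow, measuring how much more
expensive it is to go below k clusters than it was to reach them. If no k
is robust the stage refuses to recommend and requires an explicit override.

**K-means refinement.** Lloyd's algorithm starts from the Ward partition's
centroids, with no random restarts; assignment ties break toward the lowest
centroid index, an empty cluster is reseeded to the point farthest from its
assigned centroid (logged), and iteration stops when assignments are stable
or after `max_iter = 300` (convergence is typically reached in under 20
iterations at a few hundred regions). Inertia is non-increasing across
iterations and never exceeds the seeding inertia.

**Labels.** With k = 4, each semantic label (unhealthy / below-healthy /
healthy / extra-healthy) is tied to one rate, and labels are assigned by
maximizing the sum of the chosen centroid components over one-to-one
assignments (Hungarian algorithm), so tied argmaxes still yield a
bijection.

## Cluster profiling

Per indicator: cluster means with largest/smallest flags; a Shapiro–Wilk
normality screen *within each cluster*, excluding the indicator from the
testing battery if normality is rejected at α in any cluster (clusters of
size < 3 or constant samples are untestable — the indicator stays in, with
a warning); Levene's variance-homogeneity test with group-mean centering
(mean-centering is what distinguishes Levene's statistic from the
median-centered variant); then either the classical one-way ANOVA
(homoscedastic case) or the Brown–Forsythe robust test of equal means

F* = Σ nᵢ(x̄ᵢ − x̄)² / Σ (1 − nᵢ/N) sᵢ²,

with Satterthwaite denominator degrees of freedom; for two groups F* equals
the squared Welch t statistic. Note the Brown–Forsythe *means* test is a
different procedure from the Brown–Forsythe (median-centered) *variance*
test; the battery uses the means test, switched in whenever Levene rejects
at 5%.

Post hoc comparisons: pooled-variance pairwise t tests with Bonferroni
adjustment (p·m capped at 1) when variances are homogeneous; otherwise
Tamhane's T2, i.e. pairwise Welch t statistics with the Šidák-type
conservative bound 1 − (1 − p)^m. Šidák-adjusted p never exceeds
Bonferroni-adjusted p, and both never fall below the raw p.

Degenerate paths are explicit: zero within-group variance gives F = 0
(p = 1) under equal means and F = ∞ (p = 0) under unequal ones, and
identical absolute deviations short-circuit Levene to (0, 1).

## Multinomial logit

Baseline-category parameterization with the unhealthy cluster as baseline:
β_baseline ≡ 0 and ln(P_j/P_baseline) = x'β_j for each other category.
Because the four sector-employment shares and the three population-age
shares each sum to 100, one member of each set (agriculture; population
over 64) is dropped as the reference — remaining sector coefficients are
interpreted against agriculture, population coefficients against the
over-64 share. Predictors enter on their raw scales so odds ratios are per
unit of the indicator (GDP per capita then prints OR 1.000 per unit — a
scale artifact kept as is, not rescaled).

**Optimization.** Full Newton–Raphson on the observed information with
step-halving on any likelihood decrease; convergence when the maximum
absolute score component is below 1e-8 or the relative log-likelihood
change is below 1e-10 with terminal gradient below 1e-6. Internally the
predictors are standardized for conditioning and the estimates and
covariance are mapped back to the raw scale exactly. The intercept-only
log-likelihood has the closed form Σ n_j log(n_j/n).

**Numerical choices.** The Wald covariance inverts the observed
information through an eigendecomposition with an eigenvalue floor
(1e-10 × the largest eigenvalue): under quasi-separation the information
has near-zero — occasionally round-off-negative — eigenvalues, and a naive
pseudo-inverse turns those into enormous *negative* variances. Flooring
yields a positive-semidefinite covariance with honestly huge variances
along weakly identified directions. Separation itself is flagged when any
standardized coefficient exceeds 15 in magnitude (an odds shift of e¹⁵ per
SD has no finite-sample interpretation); rank-deficient designs fail with
the collinear set named.

**Diagnostics.** LR test against the intercept-only model with
(J−1)·p degrees of freedom (36 for 4 categories and 12 predictors);
Cox–Snell R² = 1 − exp((2/n)(ℓ₀ − ℓ)) and Nagelkerke's rescaling by its
ceiling 1 − exp((2/n)ℓ₀) (always ≥ Cox–Snell); hit ratio of
argmax-probability prediction against the maximum chance criterion
1.25 × the largest category share; tolerance = 1 − R²_aux and
VIF = 1/tolerance from auxiliary least-squares fits; Wald confidence bounds
exp(b ± z·SE) with z = Φ⁻¹(0.975) = 1.959964 and two-sided significance
stars at 1/5/10%.

**IIA.** The Hausman–McFadden test refits the model with one non-baseline
category's observations removed and compares the common coefficients:
H = d'(V_r − V_f)⁻d, χ² with df = the number of common coefficients. The
covariance difference is frequently not positive definite in finite
samples; such runs use a generalized inverse over the non-negative
eigenspace (df = its rank) and are flagged *inconclusive* rather than
trusted. One test per non-baseline category is reported. Under IIA-true
simulated data the rejection rate among positive-definite runs sits near
the nominal 5% (validated in `analysis/06_validation_studies.py`).

## Synthetic data generator

The generator emulates a guideline-scored activity survey over regions with
a regional covariate table, under four region archetypes ordered from most
to least active.

**Microdata.** Each archetype has a probability mix over the four activity
categories (pairwise L1 distance ≥ 0.6 between default mixes, so the
archetypes are recoverable at desk scale). An individual is generated by
sampling a target category from the mix, then drawing weekly minutes from
that category's minute model — a zero-inflated log-normal per activity type
(probability of exactly zero, median, log-scale sigma), non-negative and
right-skewed like self-reported activity data — and resampling until the
scoring rule reproduces the target category. The mix is therefore realized
*by construction*; a mis-specified minute model fails loudly after 1000
attempts per individual, naming the category. Ages are uniform on 15–75 so
the 18–64 filter always has work to do.

**Covariates.** Indicator values are drawn independently (given archetype)
from normals with archetype-specific means; sector and population share
groups are then clipped at zero and renormalized to close to exactly 100,
and bounded indicators are clipped to their ranges. The default archetype
means encode the orderings the pipeline should rediscover (GDP per capita,
economic-activity rate, services share and social-network use decreasing
toward the unhealthy archetype; agriculture, industry and poverty risk
increasing; density and the age shares deliberately non-monotone). The
default within-archetype SDs are derived from the study conditions by
variance decomposition — the overall regional SD of each indicator with the
between-archetype variance of the four archetype means removed — so the
archetypes overlap heavily in covariate space and the regression faces a
realistically noisy problem (hit ratios around 60%, not a separable toy).

**Defaults.** 50 regions per archetype × 100 respondents per region
(≈ 200 regions, 20 000 respondents — the scale of a multi-country survey
wave divided across regions); one global integer seed, with per-stream
seeds derived deterministically from it.

**What the generator does not emulate.** Survey answer scales
(days-per-week × duration bands) — minutes are drawn directly; survey
weights; spatial autocorrelation between neighboring regions; covariate
correlation beyond compositional closure. Passing the recovery tests
therefore shows the pipeline is correct and well-calibrated under known
structure, not that any real survey meets these assumptions.

## Validation studies and problem sizes

`paregions.validation` runs the Monte-Carlo studies used by the test suite
and the acceptance script, at sizes chosen to keep each study's binomial
error well inside its acceptance band: type-I error of the LR test (2000
replications, n = 500, three categories, two null predictors), Levene
(2000 replications, 4 × 50 normals) and Brown–Forsythe (2000 replications,
variance ratio 16 with group sizes 10 vs 100, where classical ANOVA is
miscalibrated); Hausman–McFadden rejection under IIA-true data (500
replications at n = 2000, scored over positive-definite runs only); and the
end-to-end recovery study (50 seeds at the default scale), which scores
partition recovery (ARI ≥ 0.9), label accuracy, and sign recovery of the
non-null generative covariate effects. "Non-null" is defined once, at the
population level: coefficients of a fit to a very large covariate-only draw
(5000 regions per archetype), standardized by predictor SD, with magnitude
≥ 0.5; a sign is recovered when the fitted coefficient matches it in the
majority of the 50 replicate fits.

## Known limitations

- The k-selection rule (ARI robustness screen + Ward elbow) is one
  reasonable formalization of "several methods agree on a robust solution";
  other defensible rules exist, which is why the recommendation can always
  be overridden.
- The Hausman–McFadden test is fragile by construction; most runs at a few
  hundred regions are inconclusive, and the package reports them as such
  rather than forcing a verdict.
- Tamhane's T2 is implemented as Welch pairwise tests with the Šidák-type
  bound — the procedure's defining construction — not via its original
  studentized-maximum-modulus tables.
- Regional rates are unweighted respondent shares; with very few
  respondents in a region the rates are coarse (a region with three
  respondents can only have rates in thirds), which real survey data shares.
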