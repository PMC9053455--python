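# paregions

Regional physical-activity taxonomy and socioeconomic characterization.

Public-health surveillance compares *regions*, not just countries, by the
share of their working-age population meeting the WHO physical-activity
guidelines. This package implements that comparison as a reproducible
pipeline for epidemiologists and regional-health analysts:

1. **Guideline scoring** — each survey respondent's weekly minutes of
   vigorous activity, moderate activity and walking are collapsed into
   moderate-equivalent minutes, `MEM = 2·vigorous + moderate + 0.5·walking`,
   and binned into four categories: *non-active* (no activity at all),
   *below-healthy* (`0 < MEM < 150`), *healthy* (`150 ≤ MEM < 300`, meets
   the guidelines) and *extra-healthy* (`MEM ≥ 300`, additional health
   benefits). Only respondents aged 18–64 enter the regional rates.
2. **Regional profiles** — per region, the percentage of eligible
   respondents in each category (four rates summing to 100).
3. **Taxonomy** — hierarchical clustering of the rate profiles under
   several linkage rules and distance measures; the number of clusters is
   chosen by cross-method agreement (mean pairwise adjusted Rand index)
   combined with the Ward-dendrogram elbow; the Ward/squared-Euclidean
   centroids then seed a deterministic K-means refinement, and the four
   clusters are labeled *extra-healthy / healthy / below-healthy /
   unhealthy* by an optimal one-to-one assignment on the centroids.
4. **Profiling** — per-cluster means of 14 regional socioeconomic
   indicators, Shapiro–Wilk normality screening, Levene's variance test,
   one-way ANOVA or the Brown–Forsythe robust means test, and Bonferroni or
   Tamhane-T2 pairwise comparisons.
5. **Regression** — a baseline-category multinomial logit
   `P(Y=j) = exp(x'β_j) / (1 + Σ_g exp(x'β_g))` of cluster membership on the
   indicators (unhealthy cluster as baseline; agriculture and the over-64
   population share dropped as compositional references), fitted by
   Newton–Raphson maximum likelihood, with Wald odds ratios and confidence
   bounds, the likelihood-ratio model test, Cox–Snell and Nagelkerke
   pseudo-R², the classification hit ratio against the maximum chance
   criterion (1.25 × largest category share), tolerance/VIF collinearity
   screening and Hausman–McFadden tests of the independence of irrelevant
   alternatives.

A synthetic-data module generates survey microdata and covariates from four
region *archetypes* with known class mixes and indicator means, so the whole
pipeline is validated by recovery of the generating structure. See
`docs/methods.md` for the model details and design choices.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic data (200 regions × 100 respondents, seed 1) and write their
tables under `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_score_regions.py
python analysis/03_cluster_taxonomy.py
python analysis/04_profile_clusters.py
python analysis/05_mlr_model.py
python analysis/06_validation_studies.py
```

Step 3 prints the k-selection report and the labeled taxonomy:

```
 k  mean_ari  height_jump
 2     0.703        2.124
 3     1.000        1.528
 4     1.000       20.724
 5     0.891        1.124
 6     0.828        1.037
recommended k = 4; used k = 4; K-means converged in 2 iterations, inertia 15196.2
labeled centroids (activity rates, %):
               rate_non_active  rate_below_healthy  rate_healthy  rate_extra_healthy
extra-healthy              3.1                12.5          19.3                65.1
healthy                    7.9                21.9          45.2                24.9
below-healthy             12.2                47.8          21.7                18.2
unhealthy                 39.6                28.6          11.6                20.3
recovery of the generating archetypes: ARI = 0.987, label accuracy = 0.995
```

Four cluster counts agree perfectly across linkage methods (mean ARI 1.0)
and sit just before a twenty-fold jump in Ward merge cost, so k = 4 is both
robust and well separated; the refined clusters recover the generating
archetypes almost exactly. Step 5 then reports

```
model fit: LR chi2(36) = 226.80, p = 1.58e-29; Cox-Snell R2 = 0.678, Nagelkerke R2 = 0.723
classification: hit ratio 62.5% vs maximum chance criterion 31.9% -> practically significant: True
multicollinearity: max VIF 2.39 (no concern below 10)
```

i.e. the 12 indicators explain cluster membership far beyond chance (36
degrees of freedom = 3 contrasts × 12 predictors), with services share,
tertiary education and poverty risk carrying most of the signal, and the
GDP-per-capita odds ratio printing as 1.000 per unit — a scale artifact of
a per-inhabitant indicator, reproduced as such. The Hausman–McFadden runs
come back inconclusive (non-positive-definite covariance differences), a
known behaviour of that test at this sample size.

The equivalent one-shot run is `paregions run-all --seed 1 --out results/run`
(a CLI with `simulate`, `classify`, `aggregate`, `cluster`, `profile`,
`mlr` and `run-all` subcommands wraps the library).

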