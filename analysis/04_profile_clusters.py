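#!/usr/bin/env python
"""Step 4 — socioeconomic profiling of the clusters.

Computes per-cluster indicator means (with largest/smallest flags), screens
univariate normality per cluster, tests variance homogeneity, runs the
one-way ANOVA or the Brown-Forsythe robust means test per indicator, and
summarizes the Bonferroni / Tamhane-T2 pairwise comparisons.
"""

from pathlib import Path

import pandas as pd

from paregions.pipeline import read_covariates
from paregions.profiling import anova_battery, anova_table, cluster_means_table, standardized_means_matrix
from paregions.taxonomy import ClusterSolution

ROOT = Path(__file__).resolve().parents[1] / "results"


def load_solution() -> ClusterSolution:
    import numpy as np

    assign = pd.read_csv(ROOT / "cluster_assignments.csv")
    labels = {int(c): str(l) for c, l in
              assign[["cluster_index", "cluster_label"]].drop_duplicates()
              .itertuples(index=False)}
    return ClusterSolution(
        assignments=dict(zip(assign["region_id"].astype(str),
                             assign["cluster_index"].astype(int))),
        centroids=np.zeros((len(labels), 4)), k=len(labels), inertia=0.0,
        seed_centroids=np.zeros((len(labels), 4)), n_iter=0, labels=labels,
    )


def main() -> None:
    cov = read_covariates(ROOT / "data" / "covariates.csv")
    sol = load_solution()

    means = cluster_means_table(cov, sol)
    means.to_csv(ROOT / "cluster_means.csv")
    print("cluster means (largest / smallest flagged):")
    print(means.round(2).to_string())

    results = anova_battery(cov, sol)
    table = anova_table(results)
    table.to_csv(ROOT / "anova.csv", index=False)
    included = table[table["included"]]
    excluded = table[~table["included"]]
    print(f"\nANOVA battery: {len(included)} indicators tested, "
          f"{len(excluded)} excluded by the normality screen "
          f"({', '.join(excluded['indicator'])})")
    cols = ["indicator", "F", "p_value", "robust_used", "posthoc"]
    print(included[cols].round(4).to_string(index=False))

    z = standardized_means_matrix(cov, sol)
    z.to_csv(ROOT / "standardized_cluster_means.csv")

    sig = included[included["p_value"] < 0.05]
    unhealthy_pairs = sig["posthoc"].str.contains("unhealthy").sum()
    print(f"\n{len(sig)} indicators differ across clusters at the 5% level; "
          f"the unhealthy cluster appears in the post hoc summary of "
          f"{unhealthy_pairs} of them")


if __name__ == "__main__":
    main()
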