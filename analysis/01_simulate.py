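#!/usr/bin/env python
"""Step 1 — generate the synthetic study data.

Draws the default four-archetype synthetic dataset (200 regions, 100 survey
respondents each): individual weekly activity minutes plus the 14 regional
socioeconomic indicators.  Writes microdata, covariates and the true
region-archetype map under results/data/.
"""

from pathlib import Path

from paregions.pipeline import write_covariates, write_microdata
from paregions.synthetic import (
    SimulationConfig,
    default_archetypes,
    generate_covariates,
    generate_microdata,
)

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(rng_seed=SEED)
    archetypes = default_archetypes()
    micro = generate_microdata(config, archetypes)
    cov = generate_covariates(config, archetypes)

    write_microdata(micro, OUT / "microdata.csv")
    write_covariates(cov, OUT / "covariates.csv")
    micro[["region_id", "archetype"]].drop_duplicates().to_csv(
        OUT / "region_archetypes.csv", index=False
    )

    n_regions = micro["region_id"].nunique()
    print(f"seed {SEED}: {len(micro)} respondents in {n_regions} regions "
          f"({len(archetypes)} archetypes x {config.n_regions_per_archetype} regions "
          f"x {config.n_individuals_per_region} respondents)")
    print(f"wrote microdata.csv, covariates.csv, region_archetypes.csv -> {OUT}")


if __name__ == "__main__":
    main()
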