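"""Synthetic survey microdata and regional covariates with known structure.

The generator emulates the two data sources the pipeline consumes:

* individual-level survey microdata (weekly vigorous / moderate / walking
  minutes plus age and region), drawn so that each region realizes a known
  *archetype* mix over the four activity categories, and
* a region-level socioeconomic indicator table whose per-archetype means
  follow a fixed ordering pattern (richer, more service-oriented, more
  educated regions are the more active ones).

Because the archetype of every region is known, the whole pipeline can be
validated by partition recovery (adjusted Rand index against the generating
archetypes) and by the signs of the covariate effects.

Individuals are generated by rejection: a target category is sampled from the
archetype's class mix, minutes are drawn from that category's zero-inflated
log-normal minute model, and the draw is kept only if the scoring rule maps
it back to the target category.  The generative class mix is therefore
realized by construction, not approximately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .scoring import (
    CLASS_LABELS,
    DEFAULT_THRESHOLDS,
    MICRODATA_COLUMNS,
    classify_minutes,
)

logger = logging.getLogger(__name__)


class SimulationError(RuntimeError):
    """Raised when a simulation configuration cannot be realized."""


#: the 14 regional indicators, in canonical column order
COVARIATE_NAMES = [
    "gdp_pc",
    "unemployment",
    "density",
    "econ_activity",
    "agriculture",
    "industry",
    "construction",
    "services",
    "pop_lt15",
    "pop_15_64",
    "pop_gt64",
    "tertiary",
    "social_users",
    "poverty_social_risk",
]

#: compositional groups closed to 100%
SECTOR_SHARES = ["agriculture", "industry", "construction", "services"]
POPULATION_SHARES = ["pop_lt15", "pop_15_64", "pop_gt64"]

#: indicators bounded in [0, 100]
_PERCENTAGE_VARS = set(
    SECTOR_SHARES
    + POPULATION_SHARES
    + ["unemployment", "econ_activity", "tertiary", "social_users", "poverty_social_risk"]
)

ARCHETYPE_NAMES = ["extra-healthy", "healthy", "below-healthy", "unhealthy"]


@dataclass(frozen=True)
class MinuteDistribution:
    """Zero-inflated log-normal model for one activity type's weekly minutes.

    With probability ``p_zero`` the value is exactly 0; otherwise it is
    ``median * exp(sigma * Z)`` rounded to whole minutes.
    """

    p_zero: float
    median: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_zero <= 1.0:
            raise ValueError(f"p_zero must lie in [0, 1], got {self.p_zero}")
        if self.median < 0 or self.sigma < 0:
            raise ValueError("median and sigma must be non-negative")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        zero = rng.random(n) < self.p_zero
        vals = np.round(self.median * np.exp(self.sigma * rng.standard_normal(n)))
        return np.where(zero, 0.0, vals)


#: per-class minute models (vigorous, moderate, walking)
DEFAULT_MINUTE_DISTRIBUTIONS: Dict[str, Dict[str, MinuteDistribution]] = {
    "non_active": {
        "vigorous": MinuteDistribution(1.0, 0.0, 0.0),
        "moderate": MinuteDistribution(1.0, 0.0, 0.0),
        "walking": MinuteDistribution(1.0, 0.0, 0.0),
    },
    "below_healthy": {
        "vigorous": MinuteDistribution(0.75, 20.0, 0.8),
        "moderate": MinuteDistribution(0.35, 40.0, 0.7),
        "walking": MinuteDistribution(0.25, 60.0, 0.7),
    },
    "healthy": {
        "vigorous": MinuteDistribution(0.55, 35.0, 0.6),
        "moderate": MinuteDistribution(0.15, 130.0, 0.5),
        "walking": MinuteDistribution(0.15, 90.0, 0.6),
    },
    "extra_healthy": {
        "vigorous": MinuteDistribution(0.35, 70.0, 0.6),
        "moderate": MinuteDistribution(0.10, 280.0, 0.5),
        "walking": MinuteDistribution(0.10, 150.0, 0.6),
    },
}


@dataclass(frozen=True)
class ArchetypeSpec:
    """A region archetype: class mix plus covariate means and spreads."""

    name: str
    class_mix: Tuple[float, float, float, float]
    covariate_means: Dict[str, float]
    covariate_sds: Dict[str, float]

    def __post_init__(self) -> None:
        mix = np.asarray(self.class_mix, dtype=float)
        if mix.shape != (4,):
            raise ValueError("class_mix must have four entries")
        if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"class_mix must be non-negative and sum to 1, got {self.class_mix}"
            )
        missing = set(COVARIATE_NAMES) - set(self.covariate_means)
        if missing:
            raise ValueError(f"covariate_means missing indicators: {sorted(missing)}")
        for k in COVARIATE_NAMES:
            if self.covariate_sds.get(k, 0.0) < 0:
                raise ValueError(f"covariate_sds[{k!r}] must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for one synthetic draw.  One global seed drives every stream."""

    n_regions_per_archetype: int = 50
    n_individuals_per_region: int = 100
    rng_seed: int = 0
    age_range: Tuple[int, int] = (15, 75)
    resample_cap: int = 1000
    minute_distributions: Dict[str, Dict[str, MinuteDistribution]] = field(
        default_factory=lambda: DEFAULT_MINUTE_DISTRIBUTIONS
    )

    def __post_init__(self) -> None:
        if self.n_regions_per_archetype < 1 or self.n_individuals_per_region < 1:
            raise ValueError("counts must be >= 1")
        if self.resample_cap < 1:
            raise ValueError("resample_cap must be >= 1")
        lo, hi = self.age_range
        if lo > hi:
            raise ValueError(f"invalid age_range {self.age_range}")


# ---------------------------------------------------------------------------
# default archetypes
# ---------------------------------------------------------------------------

# class mixes over (non_active, below_healthy, healthy, extra_healthy);
# pairwise L1 distance >= 0.6 so the archetypes are recoverable at desk scale
_DEFAULT_MIXES = {
    "extra-healthy": (0.03, 0.12, 0.20, 0.65),
    "healthy": (0.08, 0.22, 0.45, 0.25),
    "below-healthy": (0.12, 0.48, 0.22, 0.18),
    "unhealthy": (0.40, 0.28, 0.12, 0.20),
}

# per-archetype indicator means; the orderings across archetypes (GDP, services,
# social-network use decreasing toward the unhealthy archetype; agriculture,
# industry and poverty risk increasing) encode the pattern the pipeline is
# expected to rediscover
_DEFAULT_MEANS = {
    "extra-healthy": {
        "gdp_pc": 31532.88, "unemployment": 6.07, "density": 336.29,
        "econ_activity": 76.29, "agriculture": 2.96, "industry": 16.35,
        "construction": 6.77, "services": 74.23, "pop_lt15": 15.68,
        "pop_15_64": 64.58, "pop_gt64": 19.74, "tertiary": 33.29,
        "social_users": 59.27, "poverty_social_risk": 19.40,
    },
    "healthy": {
        "gdp_pc": 27774.19, "unemployment": 9.20, "density": 156.01,
        "econ_activity": 73.99, "agriculture": 4.73, "industry": 17.09,
        "construction": 6.73, "services": 71.45, "pop_lt15": 15.40,
        "pop_15_64": 64.59, "pop_gt64": 20.03, "tertiary": 34.13,
        "social_users": 56.35, "poverty_social_risk": 20.32,
    },
    "below-healthy": {
        "gdp_pc": 26862.28, "unemployment": 8.94, "density": 548.61,
        "econ_activity": 70.93, "agriculture": 6.38, "industry": 17.72,
        "construction": 6.67, "services": 69.22, "pop_lt15": 16.09,
        "pop_15_64": 65.18, "pop_gt64": 18.73, "tertiary": 31.42,
        "social_users": 53.61, "poverty_social_risk": 24.52,
    },
    "unhealthy": {
        "gdp_pc": 21908.57, "unemployment": 8.92, "density": 175.59,
        "econ_activity": 70.76, "agriculture": 10.97, "industry": 19.68,
        "construction": 7.12, "services": 62.23, "pop_lt15": 14.84,
        "pop_15_64": 65.51, "pop_gt64": 19.66, "tertiary": 24.99,
        "social_users": 51.14, "poverty_social_risk": 26.49,
    },
}

# within-archetype spreads, derived from the study conditions: the overall
# regional SD of each indicator with the between-archetype variance of the
# four archetype means (size-weighted 73/31/57/35) removed.  Archetypes
# overlap heavily in covariate space, so the regression stage faces a noisy
# problem of the realistic difficulty rather than a separable toy one.
_DEFAULT_SDS = {
    "gdp_pc": 10542.0, "unemployment": 5.15, "density": 834.0,
    "econ_activity": 4.51, "agriculture": 6.20, "industry": 7.49,
    "construction": 1.54, "services": 10.43, "pop_lt15": 1.92,
    "pop_15_64": 2.43, "pop_gt64": 2.89, "tertiary": 8.66,
    "social_users": 10.51, "poverty_social_risk": 7.69,
}


def default_archetypes() -> List[ArchetypeSpec]:
    """The four default region archetypes, ordered most to least active."""
    return [
        ArchetypeSpec(
            name=name,
            class_mix=_DEFAULT_MIXES[name],
            covariate_means=dict(_DEFAULT_MEANS[name]),
            covariate_sds=dict(_DEFAULT_SDS),
        )
        for name in ARCHETYPE_NAMES
    ]


# ---------------------------------------------------------------------------
# microdata
# ---------------------------------------------------------------------------

def region_ids(config: SimulationConfig, archetypes: Sequence[ArchetypeSpec]) -> pd.DataFrame:
    """Deterministic region-id table: ``region_id, archetype``."""
    rows = []
    idx = 1
    for arch in archetypes:
        for _ in range(config.n_regions_per_archetype):
            rows.append((f"R{idx:04d}", arch.name))
            idx += 1
    return pd.DataFrame(rows, columns=["region_id", "archetype"])


def _sample_class_minutes(
    rng: np.random.Generator,
    models: Dict[str, MinuteDistribution],
    target_code: int,
    n: int,
    cap: int,
    class_label: str,
) -> np.ndarray:
    """Draw ``n`` (vigorous, moderate, walking) rows that score as ``target_code``.

    Rejection sampling in vectorized rounds; every slot gets at most ``cap``
    attempts before the configuration is declared non-realizable.
    """
    out = np.empty((n, 3), dtype=float)
    pending = np.arange(n)
    for _attempt in range(cap):
        m = len(pending)
        draw = np.column_stack(
            [
                models["vigorous"].sample(rng, m),
                models["moderate"].sample(rng, m),
                models["walking"].sample(rng, m),
            ]
        )
        codes = np.atleast_1d(
            classify_minutes(draw[:, 0], draw[:, 1], draw[:, 2], DEFAULT_THRESHOLDS)
        )
        ok = codes == target_code
        out[pending[ok]] = draw[ok]
        pending = pending[~ok]
        if len(pending) == 0:
            return out
    raise SimulationError(
        f"minute distribution for class {class_label!r} failed to realize the "
        f"target class within {cap} attempts per individual"
    )


def generate_microdata(
    config: SimulationConfig, archetypes: Sequence[ArchetypeSpec]
) -> pd.DataFrame:
    """Generate survey microdata; returns the microdata frame plus an
    ``archetype`` column tagging each region's generating archetype.
    """
    if len(archetypes) == 0:
        raise ValueError("at least one archetype is required")
    rng = np.random.default_rng(_stream_seed(config.rng_seed, "microdata"))
    regions = region_ids(config, archetypes)
    arch_by_name = {a.name: a for a in archetypes}
    lo, hi = config.age_range
    n = config.n_individuals_per_region

    frames = []
    for region_id, arch_name in regions.itertuples(index=False):
        arch = arch_by_name[arch_name]
        mix = np.asarray(arch.class_mix, dtype=float)
        targets = rng.choice(4, size=n, p=mix / mix.sum())
        minutes = np.empty((n, 3), dtype=float)
        for code in range(4):
            slots = np.flatnonzero(targets == code)
            if len(slots) == 0:
                continue
            label = CLASS_LABELS[code]
            models = config.minute_distributions[label]
            minutes[slots] = _sample_class_minutes(
                rng, models, code, len(slots), config.resample_cap, label
            )
        ages = rng.integers(lo, hi + 1, size=n)
        frames.append(
            pd.DataFrame(
                {
                    "respondent_id": [f"{region_id}-{i + 1:05d}" for i in range(n)],
                    "region_id": region_id,
                    "age": ages,
                    "vigorous_min": minutes[:, 0],
                    "moderate_min": minutes[:, 1],
                    "walking_min": minutes[:, 2],
                    "archetype": arch_name,
                    "target_class": np.asarray(CLASS_LABELS, dtype=object)[targets],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def _validate_compositional_means(arch: ArchetypeSpec, slack: float = 0.5) -> None:
    for group, names in (("sector shares", SECTOR_SHARES), ("population shares", POPULATION_SHARES)):
        total = sum(arch.covariate_means[k] for k in names)
        if abs(total - 100.0) > slack:
            raise SimulationError(
                f"archetype {arch.name!r}: {group} means sum to {total:.3f}, "
                f"expected 100 +/- {slack}"
            )
        for k in names:
            if not 0.0 <= arch.covariate_means[k] <= 100.0:
                raise SimulationError(
                    f"archetype {arch.name!r}: mean of {k!r} outside [0, 100]"
                )


def _close_group(values: np.ndarray) -> np.ndarray:
    """Clip at zero and renormalize rows to sum exactly 100."""
    v = np.clip(values, 0.0, None)
    totals = v.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise SimulationError("compositional group collapsed to all-zero shares")
    return 100.0 * v / totals


def generate_covariates(
    config: SimulationConfig, archetypes: Sequence[ArchetypeSpec]
) -> pd.DataFrame:
    """Generate the regional indicator table (one row per region).

    Indicators are drawn independently (given archetype) from normals with the
    archetype's means/SDs; compositional groups are then clipped at zero and
    renormalized to close exactly to 100, and bounded indicators are clipped
    to their valid ranges.
    """
    if len(archetypes) == 0:
        raise ValueError("at least one archetype is required")
    for arch in archetypes:
        _validate_compositional_means(arch)
    rng = np.random.default_rng(_stream_seed(config.rng_seed, "covariates"))
    regions = region_ids(config, archetypes)
    arch_by_name = {a.name: a for a in archetypes}

    n_r = config.n_regions_per_archetype
    rows = []
    for arch in archetypes:
        means = np.array([arch.covariate_means[k] for k in COVARIATE_NAMES])
        sds = np.array([arch.covariate_sds.get(k, 0.0) for k in COVARIATE_NAMES])
        draws = means + sds * rng.standard_normal((n_r, len(COVARIATE_NAMES)))
        block = pd.DataFrame(draws, columns=COVARIATE_NAMES)
        # exact closure of the two compositional groups
        block[SECTOR_SHARES] = _close_group(block[SECTOR_SHARES].to_numpy())
        block[POPULATION_SHARES] = _close_group(block[POPULATION_SHARES].to_numpy())
        for k in COVARIATE_NAMES:
            if k in _PERCENTAGE_VARS:
                block[k] = block[k].clip(0.0, 100.0)
        block["gdp_pc"] = block["gdp_pc"].clip(lower=1.0)
        block["density"] = block["density"].clip(lower=1.0)
        block["archetype"] = arch.name
        rows.append(block)
    out = pd.concat(rows, ignore_index=True)
    out.insert(0, "region_id", regions["region_id"].to_numpy())
    # region order in `regions` is archetype-blocked, matching `rows`
    assert (out["archetype"].to_numpy() == regions["archetype"].to_numpy()).all()
    return out


def _stream_seed(seed: int, label: str) -> np.random.SeedSequence:
    """Derive a per-stream seed deterministically from the one global seed."""
    return np.random.SeedSequence(entropy=seed, spawn_key=(hash_label(label),))


def hash_label(label: str) -> int:
    # stable small hash (Python's hash() is salted per process)
    h = 0
    for ch in label:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h
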