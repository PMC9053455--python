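"""End-to-end orchestration: file I/O, configuration, reports.

A run is fully determined by a :class:`RunConfig` (read from YAML) and its
seed: simulate (or load) microdata and covariates, classify and aggregate to
regional activity-rate profiles, build the cluster taxonomy, profile the
clusters on the socioeconomic indicators, and fit the cluster-membership
regression.  Every intermediate table is written as CSV next to a
human-readable report, and every sample-size reduction (age filter, dropped
regions) is logged so the audit trail from raw respondents to final model is
reconstructible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .scoring import (
    DEFAULT_AGE_RANGE,
    DEFAULT_THRESHOLDS,
    MICRODATA_COLUMNS,
    PROFILE_RATE_COLUMNS,
    classify_frame,
    filter_working_age,
    regionalize,
)
from .synthetic import (
    COVARIATE_NAMES,
    POPULATION_SHARES,
    SECTOR_SHARES,
    SimulationConfig,
    default_archetypes,
    generate_covariates,
    generate_microdata,
)
from .taxonomy import DEFAULT_K_RANGE, DEFAULT_RUNS, ClusterSolution, build_taxonomy
from .profiling import anova_battery, anova_table, cluster_means_table
from .mlr import mlr_analysis

logger = logging.getLogger(__name__)

#: slack allowed on real-data compositional closure (percentage points)
CLOSURE_SLACK = 0.5


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


# ---------------------------------------------------------------------------
# CSV I/O with validation
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PipelineError(f"{path}: missing column(s) {missing}")


def read_microdata(path) -> pd.DataFrame:
    """Read and validate the microdata CSV.

    Malformed rows (non-numeric, negative or non-finite minutes, negative
    age) are rejected with their 1-based data line numbers.
    """
    df = pd.read_csv(path)
    _require_columns(df, MICRODATA_COLUMNS, path)
    bad_lines: List[int] = []
    for col in ("age", "vigorous_min", "moderate_min", "walking_min"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals) | (vals < 0)
        bad_lines.extend((df.index[bad] + 2).tolist())  # +2: header + 1-based
        df[col] = vals
    if bad_lines:
        raise PipelineError(
            f"{path}: invalid value(s) at line(s) {sorted(set(bad_lines))[:20]}"
        )
    df["region_id"] = df["region_id"].astype(str)
    return df


def write_microdata(df: pd.DataFrame, path) -> None:
    df[MICRODATA_COLUMNS].to_csv(path, index=False)


def read_covariates(path, closure_slack: float = CLOSURE_SLACK) -> pd.DataFrame:
    """Read and validate the regional covariates CSV.

    Sector and population shares must each close to 100 within
    ``closure_slack`` percentage points and lie inside [0, 100].
    """
    df = pd.read_csv(path)
    _require_columns(df, ["region_id", *COVARIATE_NAMES], path)
    bad: Dict[int, str] = {}
    for col in COVARIATE_NAMES:
        vals = pd.to_numeric(df[col], errors="coerce")
        for idx in df.index[~np.isfinite(vals)]:
            bad.setdefault(idx + 2, f"non-numeric {col}")
        df[col] = vals
    for name, group in (("sector", SECTOR_SHARES), ("population", POPULATION_SHARES)):
        total = df[group].sum(axis=1)
        off = np.abs(total - 100.0) > closure_slack
        for idx in df.index[off & np.isfinite(total)]:
            bad.setdefault(idx + 2, f"{name} shares sum to {total[idx]:.3f}")
        in_range = ((df[group] >= 0) & (df[group] <= 100)).all(axis=1)
        for idx in df.index[~in_range]:
            bad.setdefault(idx + 2, f"{name} share outside [0, 100]")
    if bad:
        detail = "; ".join(f"line {k}: {v}" for k, v in sorted(bad.items())[:10])
        raise PipelineError(f"{path}: invalid row(s): {detail}")
    df["region_id"] = df["region_id"].astype(str)
    return df


def write_covariates(df: pd.DataFrame, path) -> None:
    cols = ["region_id", *COVARIATE_NAMES]
    if "archetype" in df.columns:
        cols = cols + ["archetype"]
    df[cols].to_csv(path, index=False)


def read_profiles(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["region_id", *PROFILE_RATE_COLUMNS, "n_eligible"], path)
    df["region_id"] = df["region_id"].astype(str)
    return df


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

def descriptive_stats(table: pd.DataFrame, columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-variable minimum, maximum, mean, median and SD (n-1 denominator)."""
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    if len(table) < 2:
        raise ValueError("need at least two rows for descriptive statistics")
    sub = table[list(columns)]
    return pd.DataFrame(
        {
            "variable": list(columns),
            "minimum": sub.min().to_numpy(),
            "maximum": sub.max().to_numpy(),
            "mean": sub.mean().to_numpy(),
            "median": sub.median().to_numpy(),
            "sd": sub.std(ddof=1).to_numpy(),
        }
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything that determines a run; precedence CLI > file > defaults."""

    rng_seed: int = 0
    microdata_path: Optional[str] = None
    covariates_path: Optional[str] = None
    simulate: bool = True
    n_regions_per_archetype: int = 50
    n_individuals_per_region: int = 100
    thresholds: Tuple[float, float] = DEFAULT_THRESHOLDS
    age_range: Tuple[int, int] = DEFAULT_AGE_RANGE
    taxonomy_runs: Tuple[Tuple[str, str], ...] = DEFAULT_RUNS
    k_range: Tuple[int, ...] = DEFAULT_K_RANGE
    k_override: Optional[int] = None
    robustness_threshold: float = 0.8
    profiling_alpha: float = 0.05
    mlr_baseline: str = "unhealthy"
    mlr_drop_references: Tuple[str, str] = ("agriculture", "pop_gt64")
    ci_level: float = 0.95

    @classmethod
    def from_dict(cls, raw: Dict) -> "RunConfig":
        kwargs: Dict = {}
        flat = dict(raw)
        for block in ("simulation", "scoring", "taxonomy", "profiling", "mlr"):
            flat.update(raw.get(block, {}) or {})
            flat.pop(block, None)
        rename = {
            "runs": "taxonomy_runs",
            "alpha": "profiling_alpha",
            "baseline": "mlr_baseline",
            "drop_references": "mlr_drop_references",
        }
        valid = {f.name for f in dataclasses.fields(cls)}
        for key, value in flat.items():
            key = rename.get(key, key)
            if key not in valid:
                raise PipelineError(f"unknown config key {key!r}")
            kwargs[key] = value
        cfg = cls(**kwargs)
        if cfg.taxonomy_runs is not None:
            cfg.taxonomy_runs = tuple((str(l), str(d)) for l, d in cfg.taxonomy_runs)
        cfg.thresholds = tuple(cfg.thresholds)  # type: ignore[assignment]
        cfg.age_range = tuple(cfg.age_range)  # type: ignore[assignment]
        cfg.k_range = tuple(cfg.k_range)  # type: ignore[assignment]
        if not cfg.simulate and (cfg.microdata_path is None or cfg.covariates_path is None):
            raise PipelineError("non-simulation runs need microdata_path and covariates_path")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    config: RunConfig
    descriptive: pd.DataFrame
    sample_counts: Dict[str, int]
    agreement: pd.DataFrame
    cluster_sizes: Dict[str, int]
    centroids: pd.DataFrame
    anova: pd.DataFrame
    means_table: pd.DataFrame
    wald_table: Optional[pd.DataFrame]
    mlr_summary: Optional[Dict[str, float]]
    provenance: Dict[str, str]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.descriptive.to_csv(out / "descriptive_stats.csv", index=False)
        self.agreement.to_csv(out / "k_agreement.csv", index=False)
        self.centroids.to_csv(out / "centroids.csv")
        self.anova.to_csv(out / "anova.csv", index=False)
        self.means_table.to_csv(out / "cluster_means.csv")
        if self.wald_table is not None:
            self.wald_table.to_csv(out / "mlr_coefficients.csv", index=False)
        summary = {
            "sample_counts": self.sample_counts,
            "cluster_sizes": self.cluster_sizes,
            "mlr": self.mlr_summary,
            "provenance": self.provenance,
        }
        (out / "report.json").write_text(json.dumps(summary, indent=2, default=str))
        (out / "report.txt").write_text(self.render_text())

    def render_text(self) -> str:
        lines = [
            "Regional physical-activity taxonomy run",
            f"  config digest: {self.provenance['config_digest']}, seed {self.config.rng_seed}",
            f"  respondents: {self.sample_counts}",
            f"  cluster sizes: {self.cluster_sizes}",
            "",
            "Cluster centroids (activity rates, %):",
            self.centroids.round(2).to_string(),
            "",
            "ANOVA battery:",
            self.anova.round(4).to_string(index=False),
        ]
        if self.mlr_summary:
            lines += ["", "Cluster-membership model:",
                      json.dumps(self.mlr_summary, indent=2, default=str)]
        return "\n".join(lines) + "\n"


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_all(config: RunConfig, out_dir=None) -> RunReport:
    """Execute simulate/load -> classify -> aggregate -> cluster -> profile
    -> regression, writing artifacts when ``out_dir`` is given."""
    microdata, covariates = _stage("input")(_load_inputs)(config)
    classified = _stage("classify")(classify_frame)(microdata, config.thresholds)
    eligible, (n_before, n_after) = _stage("age-filter")(filter_working_age)(
        classified, config.age_range
    )
    profiles = _stage("aggregate")(regionalize)(eligible, config.thresholds)
    tax = _stage("cluster")(build_taxonomy)(
        profiles,
        runs=config.taxonomy_runs,
        k_range=config.k_range,
        k_override=config.k_override,
        robustness_threshold=config.robustness_threshold,
    )
    solution = tax.solution

    means = _stage("profile")(cluster_means_table)(covariates, solution)
    battery = _stage("profile")(anova_battery)(covariates, solution, config.profiling_alpha)
    anova = anova_table(battery, config.profiling_alpha)

    wald = None
    mlr_summary = None
    if solution.labels is not None:
        analysis = _stage("mlr")(mlr_analysis)(
            covariates, solution,
            baseline=config.mlr_baseline,
            drop_references=config.mlr_drop_references,
            level=config.ci_level,
        )
        wald = analysis.wald_table
        d = analysis.diagnostics
        mlr_summary = {
            "lr_chi2": d.lr_chi2, "lr_df": d.lr_df, "lr_p": d.lr_p,
            "cox_snell_r2": d.cox_snell_r2, "nagelkerke_r2": d.nagelkerke_r2,
            "hit_ratio": d.hit_ratio, "max_chance": d.max_chance,
            "practical_significance": d.practical_significance,
            "max_vif": float(d.collinearity["vif"].max()),
            "iia": [
                {"omitted": t.omitted_category, "H": t.statistic, "df": t.df,
                 "p": t.p_value, "valid": t.valid}
                for t in d.iia_tests
            ],
        }
    else:
        logger.warning("clusters are unlabeled (k != 4); regression stage skipped")

    merged = profiles.merge(covariates, on="region_id")
    descriptive = descriptive_stats(merged, PROFILE_RATE_COLUMNS + COVARIATE_NAMES)

    sizes: Dict[str, int] = {}
    for rid, ci in solution.assignments.items():
        name = solution.labels[ci] if solution.labels else f"C{ci + 1}"
        sizes[name] = sizes.get(name, 0) + 1

    centroids = pd.DataFrame(
        solution.centroids,
        columns=PROFILE_RATE_COLUMNS,
        index=[solution.labels[i] if solution.labels else f"C{i + 1}"
               for i in range(solution.k)],
    )

    report = RunReport(
        config=config,
        descriptive=descriptive,
        sample_counts={
            "respondents": n_before,
            "working_age": n_after,
            "regions": len(profiles),
        },
        agreement=tax.agreement,
        cluster_sizes=dict(sorted(sizes.items())),
        centroids=centroids,
        anova=anova,
        means_table=means,
        wald_table=wald,
        mlr_summary=mlr_summary,
        provenance={
            "config_digest": config.digest(),
            "seed": str(config.rng_seed),
            "package_version": __version__,
        },
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_microdata(microdata, out / "microdata.csv")
        write_covariates(covariates, out / "covariates.csv")
        profiles.to_csv(out / "regional_profiles.csv", index=False)
        solution.assignment_frame().to_csv(out / "cluster_assignments.csv", index=False)
        report.write(out)
    return report


def _load_inputs(config: RunConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    if config.simulate:
        sim = SimulationConfig(
            n_regions_per_archetype=config.n_regions_per_archetype,
            n_individuals_per_region=config.n_individuals_per_region,
            rng_seed=config.rng_seed,
        )
        arch = default_archetypes()
        micro = generate_microdata(sim, arch)
        cov = generate_covariates(sim, arch)
        return micro, cov
    micro = read_microdata(config.microdata_path)
    cov = read_covariates(config.covariates_path)
    return micro, cov
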