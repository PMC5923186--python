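"""End-to-end orchestration: simulate -> preprocess -> fit -> report.

A :class:`RunConfig` (round-trippable through YAML) drives the whole
analysis.  Every run writes the resolved configuration, the seed, the
package version, and a manifest with a SHA-256 checksum per artifact, so
repeated runs with the same configuration are verifiably identical.

The single global seed is expanded through numpy ``SeedSequence`` spawn
keys into per-stage substreams, so individual stages can be re-run
standalone with unchanged results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import InvalidSpecError, SchemaError
from .model import (
    BDLIMSpec,
    METHYLATION_ADJUSTMENT,
    PATTERNS,
    SPIROMETRY_ADJUSTMENT,
    build_covariate_design,
    compare_patterns,
    compute_dic,
    fit_bdlim,
)
from .methylation import effect_table, sex_stratified_table
from .preprocess import add_methylation_summary, compute_lung_zscores
from .synthetic import TruthSpec, generate_cohort
from .windows import plot_lag_curves, window_report

#: outcomes the lag models understand: spirometry z-scores and raw %5mC
LAG_MODEL_OUTCOMES = ("z_fev1", "z_fvc", "z_fev1_fvc", "z_fef2575", "gstp1_mean")

EXPOSURE_PREFIX = "pm25_wk"


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    out_dir: str
    seed: int = 0
    cohort_path: str | None = None      # CSV cohort table; None -> simulate
    exposure_path: str | None = None    # CSV weekly exposure matrix
    simulation: dict = field(default_factory=dict)  # TruthSpec overrides
    outcomes: tuple = ("z_fev1",)
    patterns: tuple = tuple(PATTERNS)
    weight_df: int = 4
    credible_level: float = 0.95
    mcmc: dict = field(default_factory=dict)        # BDLIMSpec overrides
    run_methylation_models: bool = True

    def validate(self) -> None:
        unknown = [o for o in self.outcomes if o not in LAG_MODEL_OUTCOMES]
        if unknown:
            raise SchemaError(
                f"unknown outcomes {unknown}; valid: {LAG_MODEL_OUTCOMES}",
                missing=unknown,
            )
        bad = [p for p in self.patterns if p not in PATTERNS]
        if bad:
            raise InvalidSpecError(f"unknown patterns {bad}")
        if not (0.5 < self.credible_level < 1.0):
            raise InvalidSpecError("credible_level must be in (0.5, 1)")
        if (self.cohort_path is None) != (self.exposure_path is None):
            raise InvalidSpecError(
                "cohort_path and exposure_path must be given together"
            )

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["outcomes"] = list(self.outcomes)
        d["patterns"] = list(self.patterns)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("outcomes", "patterns"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _stage_seed(base: int, stage: str) -> int:
    key = int.from_bytes(stage.encode(), "little") % (2**31)
    return int(np.random.SeedSequence((base, key)).generate_state(1)[0] % (2**31))


def exposure_columns(df: pd.DataFrame) -> list[str]:
    return sorted(c for c in df.columns if c.startswith(EXPOSURE_PREFIX))


def _load_inputs(config: RunConfig):
    if config.cohort_path is not None:
        cohort = pd.read_csv(config.cohort_path, index_col="child_id")
        exposures = pd.read_csv(config.exposure_path, index_col="child_id")
        missing = [
            c
            for c in ("sex", "maternal_age", "maternal_education", "child_age", "height")
            if c not in cohort.columns
        ]
        if missing:
            raise SchemaError(f"cohort table missing columns {missing}", missing=missing)
        return cohort, exposures, None
    sim_kwargs = dict(config.simulation)
    sim_kwargs.setdefault("seed", _stage_seed(config.seed, "simulate"))
    spec = TruthSpec(**sim_kwargs)
    cohort, exposures = generate_cohort(spec)
    return cohort, exposures, spec


def _adjustment_for(outcome: str):
    return METHYLATION_ADJUSTMENT if outcome == "gstp1_mean" else SPIROMETRY_ADJUSTMENT


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; return the artifact manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort, exposures, truth = _load_inputs(config)

    # full-term analysis sample
    if "gestational_age" in cohort.columns:
        keep = cohort["gestational_age"] >= 37
        cohort = cohort.loc[keep]
        exposures = exposures.loc[cohort.index]

    panel = compute_lung_zscores(cohort)
    cohort = pd.concat([cohort, panel.zscores], axis=1)
    cohort = add_methylation_summary(cohort)

    artifacts = {}

    def save_df(name, df, index=True):
        path = out / name
        df.to_csv(path, index=index)
        artifacts[name] = path

    save_df("cohort.csv", cohort)
    save_df("exposures.csv", exposures)
    save_df("zscore_coefficients.csv", panel.coefficient_table())
    if truth is not None:
        (out / "truth_spec.json").write_text(json.dumps(truth.to_dict(), indent=1))
        artifacts["truth_spec.json"] = out / "truth_spec.json"

    X = exposures[exposure_columns(exposures)]
    group = cohort["sex"].to_numpy()
    mcmc_kwargs = dict(config.mcmc)
    summary = {}

    for outcome in config.outcomes:
        Z = build_covariate_design(cohort, _adjustment_for(outcome))
        y = cohort[outcome].to_numpy(dtype=float)
        fits = {}
        for pattern in config.patterns:
            spec = BDLIMSpec(
                pattern=pattern,
                weight_df=config.weight_df,
                seed=_stage_seed(config.seed, f"fit:{outcome}:{pattern}"),
                **mcmc_kwargs,
            )
            fit = fit_bdlim(y, X, Z, group if pattern != "n" else None, spec)
            compute_dic(fit)
            fits[pattern] = fit
        comparison = compare_patterns(fits)
        save_df(f"patterns_{outcome}.csv", comparison, index=False)
        best = comparison.loc[comparison["best"], "pattern"].iloc[0]
        report = window_report(fits[best], level=config.credible_level)
        save_df(f"lag_curve_{outcome}.csv", report.to_table(), index=False)
        save_df(f"cumulative_effects_{outcome}.csv", report.ce_table(), index=False)
        fig = plot_lag_curves(report, outcome_label=outcome)
        fig_path = out / f"lag_curve_{outcome}.svg"
        fig.savefig(fig_path, metadata={"Date": None})
        artifacts[fig_path.name] = fig_path
        import matplotlib.pyplot as plt

        plt.close(fig)
        summary[outcome] = {
            "best_pattern": best,
            "windows": {str(g): report.windows[g] for g in report.groups},
            "cumulative_effects": {str(g): list(report.ce[g]) for g in report.groups},
        }

    if config.run_methylation_models:
        z_outcomes = [o for o in LAG_MODEL_OUTCOMES if o.startswith("z_")]
        save_df(
            "methylation_models.csv",
            effect_table(cohort, z_outcomes),
            index=False,
        )
        save_df(
            "methylation_by_sex.csv",
            sex_stratified_table(cohort, z_outcomes),
            index=False,
        )

    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    artifacts["summary.json"] = out / "summary.json"
    config.to_yaml(out / "config.yaml")
    artifacts["config.yaml"] = out / "config.yaml"

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "artifacts": {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in sorted(artifacts.items())
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
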