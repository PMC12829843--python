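"""End-to-end orchestration: ingest/simulate -> lags -> summaries ->
models -> trends, with a YAML configuration and a run manifest.

Every stage writes plain-text outputs (CSV/JSON) into the configured
output directory; two runs with the same configuration and seed produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnostics import simulate_residuals
from .lags import (cumulative_within, is_evenly_distributed, lag_table,
                   seasonality_matrix)
from .mixed import (ModelSpec, build_model_frame, collinearity_screen,
                    compare_null, fit_lmm, null_spec, wald_anova)
from .records import (ExclusionLog, covariate_frame, filter_window,
                      read_records, write_records)
from .summaries import summary_table
from .synth import GeneratorConfig, generate
from .trends import TREND_VARIABLES, fit_trend, loess_smooth, yearly_series

log = logging.getLogger("taxalag")


@dataclass
class PipelineConfig:
    """Plain-text configuration; every analysis constant that the method
    fixes silently (365.25 d/y, 30-day gap, 10% trim, 1.4826 MAD scale,
    1.96 CI multiplier, 0.70 collinearity threshold) surfaces here with
    its method-matching default."""

    input_path: str | None = None
    input_format: str | None = None  # csv / xlsx / None = infer
    column_map: dict = field(default_factory=dict)
    simulate: bool = False
    seed: int = 0
    first_year: int = 2000
    last_year: int = 2023
    gap_days: int = 30
    trim: float = 0.10
    mad_scale: float = 1.4826
    moment_type: int = 3
    collinearity_threshold: float = 0.70
    evenness_min_fraction: float = 0.40
    cumulative_thresholds: list = field(
        default_factory=lambda: [5, 10, 15, 20, 25, 50, 75, 100, 125])
    fit_models: bool = True
    fit_regional_models: bool = True
    n_sim_residuals: int = 250
    fit_trends: bool = True
    trend_variables: list = field(
        default_factory=lambda: list(TREND_VARIABLES))
    loess_span: float = 0.75
    output_dir: str = "taxalag_output"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        payload = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_inputs(config: PipelineConfig):
    """Records + exclusion log, from file or the synthetic generator."""
    exclusions = ExclusionLog()
    if config.simulate or config.input_path is None:
        gen = GeneratorConfig(seed=config.seed,
                              first_year=config.first_year,
                              last_year=config.last_year)
        records, truth = generate(gen)
    else:
        records, exclusions = read_records(
            config.input_path, fmt=config.input_format,
            column_map=config.column_map or None)
        truth = None
    records, window_log = filter_window(records, config.first_year,
                                        config.last_year)
    exclusions.extend(window_log)
    return records, exclusions, truth


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        records, exclusions, truth = load_inputs(config)
        log.info("ingest: %d species retained, %d excluded",
                 len(records), len(exclusions))
        write_records(records, out / "records.csv")
        exclusions.write_csv(out / "exclusions.csv")
        if truth is not None:
            truth.to_csv(out / "truth.csv", index=False)

        stage = "lags"
        lag_df = lag_table(records, config.gap_days)
        lag_df.to_csv(out / "lag_table.csv", index=False)
        fractions = cumulative_within(
            lag_df["overall_y"], config.cumulative_thresholds)
        _write_json(out / "cumulative_within.json", {
            "thresholds_y": list(config.cumulative_thresholds),
            "fraction_described": fractions,
        })

        stage = "summaries"
        table1 = summary_table(lag_df, "region", config.trim,
                               config.mad_scale, config.moment_type)
        table1.to_csv(out / "summary_table.csv", index=False)
        table1.round(2).to_csv(out / "summary_table_2dp.csv", index=False)

        stage = "seasonality"
        regions = sorted({r.region for r in records})
        season_long = []
        evenness = {}
        for scope in ["global"] + regions:
            m = seasonality_matrix(
                records, None if scope == "global" else scope)
            season_long.append(m.to_long())
            even, ratios = is_evenly_distributed(
                m, config.evenness_min_fraction)
            evenness[scope] = {
                "evenly_distributed": even,
                "month_to_peak_ratios": [float(v) for v in ratios],
                "total_events": m.total(),
            }
        pd.concat(season_long, ignore_index=True).to_csv(
            out / "seasonality.csv", index=False)
        _write_json(out / "seasonality_evenness.json", evenness)

        model_results = {}
        if config.fit_models:
            stage = "models"
            model_results = fit_models(records, lag_df, config)
            _write_json(out / "models.json", model_results)

        trend_results = {}
        if config.fit_trends:
            stage = "trends"
            trend_results, trend_tables = run_trends(records, lag_df, config)
            trend_tables.to_csv(out / "trend_series.csv", index=False)
            _write_json(out / "trend_fits.json", trend_results)

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "config_digest": config.digest(),
            "seed": config.seed,
            "n_species_retained": len(records),
            "n_species_excluded": len(exclusions),
            "n_unique_collection_dates": int(lag_df["n_unique_dates"].sum()),
            "n_models": len(model_results),
            "n_trend_fits": len(trend_results),
            "elapsed_s": round(time.time() - t0, 2),
        }
        config.to_yaml(out / "config.yaml")
        _write_json(out / "manifest.json", manifest)
        return manifest
    except Exception as exc:
        (out / "FAILED_STAGE.txt").write_text(f"{stage}: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def fit_models(records, lag_df, config: PipelineConfig) -> dict:
    """Global + regional mixed models with collinearity screen, Wald
    Type-II tests, null-model comparison and residual diagnostics."""
    cov = covariate_frame(records)
    frame = build_model_frame(cov, lag_df)
    numeric = ["n_authors", "n_types", "n_species_in_paper", "n_trips",
               "genus_richness"]
    offending = collinearity_screen(frame, config.collinearity_threshold,
                                    numeric)
    results = {"collinearity": {
        "threshold": config.collinearity_threshold,
        "offending_pairs": [
            {"a": a, "b": b, "r": r} for a, b, r in offending],
    }}
    scopes = [("global", frame, ModelSpec())]
    if config.fit_regional_models:
        for region in sorted(frame["region"].unique()):
            sub = frame[frame["region"] == region].reset_index(drop=True)
            scopes.append((region, sub, ModelSpec().for_region(region)))
    for name, df, spec in scopes:
        fixed = []
        for c in spec.fixed:
            if df[c].nunique() < 2:
                log.warning("%s: dropping constant covariate %r", name, c)
            else:
                fixed.append(c)
        spec = dataclasses.replace(spec, fixed=tuple(fixed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lmm(df, spec)
            nfit = fit_lmm(df, null_spec(spec))
            block = fit.to_dict()
            if fit.converged:
                block["anova"] = wald_anova(fit).to_dict(orient="records")
                block["null_comparison"] = compare_null(fit, nfit)
                block["residual_diagnostics"] = simulate_residuals(
                    fit, config.n_sim_residuals, seed=config.seed).to_dict()
        results[name] = block
    return results


def run_trends(records, lag_df, config: PipelineConfig):
    """Trend fits for every (scope, variable); returns fit dicts and the
    long table of yearly series with LOESS smooths."""
    regions = sorted({r.region for r in records})
    fits = {}
    tables = []
    for scope in ["global"] + regions:
        for var in config.trend_variables:
            series = yearly_series(records, lag_df, var, scope)
            tab = series.data.copy()
            tab.insert(0, "variable", var)
            tab.insert(0, "scope", scope)
            if len(series) >= 4:
                tab["loess"] = loess_smooth(series, config.loess_span)
            else:
                tab["loess"] = np.nan
            tables.append(tab)
            if len(series) >= 3:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fits[f"{scope}:{var}"] = fit_trend(series).to_dict()
    return fits, pd.concat(tables, ignore_index=True)


def configure_logging(verbose: bool = False, quiet: bool = False) -> None:
    level = logging.WARNING if quiet else (
        logging.DEBUG if verbose else logging.INFO)
    logging.basicConfig(stream=sys.stderr, level=level,
                        format="%(asctime)s %(name)s %(levelname)s "
                               "%(message)s")
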