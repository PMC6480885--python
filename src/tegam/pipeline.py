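"""Orchestration: simulate or load data, fit Models I-IV, report effects.

A run produces, under ``output_dir``:

* ``comparison_table.csv`` — per-model, per-pollutant and combined excess
  risks with 95% CIs (the model-comparison table layout);
* ``fit_log_model_<M>.txt`` — iteration history, selected smoothing
  parameters, edf, dispersion and GCV per model;
* ``model_iv_surface_<pollutant>.csv`` / ``model_iv_curve_<pollutant>.csv``
  — RR grids for the tensor model;
* ``report.json`` — machine-readable results with a config hash and seed
  for provenance.

Outputs carry no timestamps, so reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .data import DailyDataset, POLLUTANTS
from .design import BuiltDesign, ModelSpec, build_model
from .effects import (
    EffectEstimate,
    combined_rr_single_sum,
    exposure_response_curve,
    profile_contrast,
    rr_surface,
)
from .gam import FitResult, GCVConfig, gcv_select
from .synthetic import SimulationConfig, simulate_dataset

__all__ = ["RunConfig", "ModelOutcome", "ComparisonReport", "run", "run_stratified", "run_lag_sensitivity", "fit_model"]

MODELS = ("I", "II", "III", "IV")


@dataclass
class RunConfig:
    input: str = "simulate"  # path to a CSV, or "simulate"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    models: tuple[str, ...] = MODELS
    pollutant_lag: int = 3
    sensitivity_lags: tuple[int, ...] = (2, 3)  # windows: lag 0-1 and lag 0-2
    strata: str | None = None
    output_dir: str = "tegam_output"
    seed: int = 0
    tensor_dims: tuple[int, int, int] = (5, 5, 5)
    df_time_per_year: float = 7.0
    df_met: int = 3
    gcv: GCVConfig = field(default_factory=GCVConfig)
    cov_type: str = "sandwich"
    surfaces: bool = True

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("at least one model must be requested")

    def model_spec(self, model: str, pollutant: str | None = None, lag: int | None = None) -> ModelSpec:
        return ModelSpec(
            model=model,
            pollutant=pollutant,
            pollutant_lag=self.pollutant_lag if lag is None else lag,
            df_time_per_year=self.df_time_per_year,
            df_met=self.df_met,
            tensor_dims=self.tensor_dims,
        )

    def canonical_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, tuple):
                return list(obj)
            if callable(obj):
                return getattr(obj, "__name__", "callable")
            return obj

        # output_dir is disk layout, not part of the scientific configuration
        return {
            f.name: enc(getattr(self, f.name))
            for f in dataclasses.fields(self)
            if f.name != "output_dir"
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.canonical_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "gcv" in d and isinstance(d["gcv"], dict):
            d["gcv"] = GCVConfig(**d["gcv"])
        for key in ("models", "sensitivity_lags", "tensor_dims"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ModelOutcome:
    model: str
    fits: dict[str, FitResult]          # Model I: one per pollutant; else {"all": fit}
    builds: dict[str, BuiltDesign]
    per_pollutant: dict[str, EffectEstimate]
    combined: EffectEstimate
    error: str | None = None

    @property
    def primary_fit(self) -> FitResult:
        return next(iter(self.fits.values()))


@dataclass
class ComparisonReport:
    config_hash: str
    seed: int
    outcomes: dict[str, ModelOutcome]
    failures: dict[str, str] = field(default_factory=dict)
    dropped_days: dict[str, int] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for model, out in self.outcomes.items():
            for pol in POLLUTANTS:
                if pol in out.per_pollutant:
                    est = out.per_pollutant[pol]
                    rows.append(_effect_row(model, pol, est))
            rows.append(_effect_row(model, "combined", out.combined))
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "version": __version__,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "failures": self.failures,
            "dropped_days": self.dropped_days,
            "effects": self.table().to_dict(orient="records"),
            "diagnostics": {
                model: {
                    name: {
                        "edf": fit.edf,
                        "dispersion": fit.dispersion,
                        "gcv": fit.gcv,
                        "lambdas": np.asarray(fit.lambdas).tolist(),
                        "converged": fit.converged,
                    }
                    for name, fit in out.fits.items()
                }
                for model, out in self.outcomes.items()
            },
        }


def _effect_row(model: str, label: str, est: EffectEstimate) -> dict:
    er_lo, er_hi = est.er_ci
    return {
        "model": model,
        "pollutant": label,
        "rr": est.rr,
        "er_percent": est.er_percent,
        "er_ci_low": er_lo,
        "er_ci_high": er_hi,
        "se_log_rr": est.se_log_rr,
        "from_levels": json.dumps(est.contrast[0], sort_keys=True),
        "to_levels": json.dumps(est.contrast[1], sort_keys=True),
    }


def _iqr_profiles(built: BuiltDesign) -> tuple[dict, dict]:
    ref = {p: built.quantile(p, 0.25) for p in POLLUTANTS if p in built.lagged}
    to = {p: built.quantile(p, 0.75) for p in ref}
    return ref, to


def fit_model(
    data: DailyDataset, config: RunConfig, model: str, lag: int | None = None
) -> ModelOutcome:
    """Build, fit and summarize one of Models I-IV on a dataset."""
    fits: dict[str, FitResult] = {}
    builds: dict[str, BuiltDesign] = {}
    if model == "I":
        for pol in POLLUTANTS:
            built = build_model(data, config.model_spec("I", pollutant=pol, lag=lag))
            _, fit = gcv_select(built.design, config.gcv, cov_type=config.cov_type)
            fits[pol], builds[pol] = fit, built
        per_pollutant = {}
        increments = {}
        for pol in POLLUTANTS:
            built = builds[pol]
            ref, to = _iqr_profiles(built)
            from_p = {q: ref[q] for q in POLLUTANTS}
            to_p = dict(from_p)
            to_p[pol] = to[pol]
            per_pollutant[pol] = profile_contrast(fits[pol], built, from_p, to_p, label=pol)
            increments[pol] = built.increments[pol]
        combined = combined_rr_single_sum(fits, increments)
        return ModelOutcome(model, fits, builds, per_pollutant, combined)

    built = build_model(data, config.model_spec(model, lag=lag))
    _, fit = gcv_select(built.design, config.gcv, cov_type=config.cov_type)
    fits["all"], builds["all"] = fit, built
    ref, to = _iqr_profiles(built)
    per_pollutant = {}
    for pol in POLLUTANTS:
        to_p = dict(ref)
        to_p[pol] = to[pol]
        per_pollutant[pol] = profile_contrast(fit, built, ref, to_p, label=pol)
    combined = profile_contrast(fit, built, ref, to, label="combined")
    return ModelOutcome(model, fits, builds, per_pollutant, combined)


def _load_data(config: RunConfig) -> DailyDataset:
    if config.input == "simulate":
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        return simulate_dataset(sim)
    return DailyDataset.from_csv(config.input)


def run(config: RunConfig, data: DailyDataset | None = None) -> ComparisonReport:
    """Full pipeline: data, all requested models, artifacts on disk."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if data is None:
        data = _load_data(config)

    outcomes: dict[str, ModelOutcome] = {}
    failures: dict[str, str] = {}
    dropped: dict[str, int] = {}
    for model in config.models:
        try:
            outcome = fit_model(data, config, model)
            outcomes[model] = outcome
            dropped[model] = max(len(b.dropped_days) for b in outcome.builds.values())
            for name, fit in outcome.fits.items():
                log_path = out_dir / f"fit_log_model_{model}{'' if name == 'all' else '_' + name}.txt"
                lines = [
                    f"model {model} ({name})",
                    f"lambdas: {np.asarray(fit.lambdas).tolist()}",
                    f"edf: {fit.edf:.6g}",
                    f"dispersion: {fit.dispersion:.6g}",
                    f"gcv: {fit.gcv:.6g}",
                    f"converged: {fit.converged} in {fit.iterations} iterations",
                ] + fit.log
                log_path.write_text("\n".join(lines) + "\n")
        except Exception as exc:  # graceful degradation per model
            failures[model] = f"{type(exc).__name__}: {exc}"

    report = ComparisonReport(
        config_hash=config.config_hash(),
        seed=config.seed,
        outcomes=outcomes,
        failures=failures,
        dropped_days=dropped,
    )
    report.table().to_csv(out_dir / "comparison_table.csv", index=False, float_format="%.10g")
    (out_dir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True, default=str) + "\n"
    )

    if config.surfaces and "IV" in outcomes:
        out4 = outcomes["IV"]
        fit, built = out4.fits["all"], out4.builds["all"]
        for pol in POLLUTANTS:
            surf = rr_surface(fit, built, fixed_pollutant=pol, grid_resolution=15)
            surf.to_csv(out_dir / f"model_iv_surface_{pol}.csv")
            curve = exposure_response_curve(fit, built, pol, n_points=40)
            curve.to_csv(out_dir / f"model_iv_curve_{pol}.csv", index=False, float_format="%.10g")
    return report


def run_stratified(
    config: RunConfig, strata_datasets: Mapping[str, DailyDataset]
) -> dict[str, ComparisonReport]:
    """Independent full pipeline per stratum (strata fit 'respectively').

    Strata with fewer than 365 days of counts are skipped with a warning
    entry rather than an error.
    """
    reports: dict[str, ComparisonReport] = {}
    for name, data in strata_datasets.items():
        n_counts = int(data.frame["deaths"].notna().sum())
        if n_counts < 365:
            sub = dataclasses.replace(config, output_dir=str(Path(config.output_dir) / name))
            Path(sub.output_dir).mkdir(parents=True, exist_ok=True)
            (Path(sub.output_dir) / "skipped.txt").write_text(
                f"stratum {name} skipped: only {n_counts} days with counts (< 365)\n"
            )
            continue
        sub = dataclasses.replace(config, output_dir=str(Path(config.output_dir) / name))
        reports[name] = run(sub, data=data)
    return reports


def split_by_stratum(frames: pd.DataFrame, stratum_col: str) -> dict[str, DailyDataset]:
    """Split a long table with a stratum column into per-stratum datasets."""
    if stratum_col not in frames.columns:
        raise KeyError(f"stratum column {stratum_col!r} not found")
    out = {}
    for name, g in frames.groupby(stratum_col, sort=True):
        out[str(name)] = DailyDataset(frame=g.drop(columns=[stratum_col]).reset_index(drop=True))
    return out


def run_lag_sensitivity(config: RunConfig, data: DailyDataset | None = None) -> dict[int, ComparisonReport]:
    """Refit the full model set per moving-average window (lag 0-1, 0-2, ...)."""
    if not config.sensitivity_lags:
        raise ValueError("sensitivity_lags must be non-empty")
    if data is None:
        data = _load_data(config)
    reports: dict[int, ComparisonReport] = {}
    for window in config.sensitivity_lags:
        sub = dataclasses.replace(
            config,
            pollutant_lag=window,
            output_dir=str(Path(config.output_dir) / f"lag0_{window - 1}"),
            surfaces=False,
        )
        reports[window] = run(sub, data=data)
    return reports
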