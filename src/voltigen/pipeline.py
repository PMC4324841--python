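"""End-to-end study orchestration.

Runs the full factorial study — every location × GCM model × emission
scenario × period cell — by generating (or ingesting) replicate weather,
pushing each replicate through the degree-day engine, and assembling the
study-shaped outputs: per-replicate predictions, per-cell mean ± SE
summaries, t-tests of future cells against baseline, percent change in
generation time, and the ANOVA variance partition.

Per-model climates are not published at daily resolution, so each GCM
model is represented by a fixed multiplicative scale on the scenario
warming offset (warm models CNR/ECH/CSI above 1, cool models BCC/MIR/INM
below); the ensemble model AVG is, by default, the day-wise average of
the six model weather series, computed before degree-day accumulation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .datasets import load_annual_mean_projections
from .degree_days import (
    GDDParams,
    GenerationPrediction,
    SeasonWindow,
    accumulate_generations,
    generation_time,
    summarize_cell,
)
from .stats_analysis import (
    VariancePartition,
    anova_partition,
    percent_change_gt,
    table_deltas,
    two_sample_t_equal_var,
)
from .synthetic_weather import (
    PERIOD_YEARS,
    SCENARIOS,
    LocationClimate,
    ReplicateSet,
    ScenarioOffset,
    child_seed,
    generate_replicate_set,
)
from .weather_io import WeatherSeries

__all__ = [
    "GCM_MODELS",
    "ENSEMBLE_MODEL",
    "MODEL_DELTA_SCALE",
    "StudyConfig",
    "StudyResult",
    "default_config",
    "run_study",
    "ensemble_average",
]

log = logging.getLogger(__name__)

#: The six GCM model codes plus the ensemble average.
GCM_MODELS = ("BCC", "CNR", "CSI", "ECH", "INM", "MIR")
ENSEMBLE_MODEL = "AVG"

#: Multiplicative scale each model applies to the scenario warming offset.
#: Warm models (CNR, ECH, CSI) sit above 1, cool ones below; baseline
#: offsets are zero, so all models coincide at baseline by construction.
MODEL_DELTA_SCALE = {
    "BCC": 0.88,
    "CNR": 1.12,
    "CSI": 1.08,
    "ECH": 1.10,
    "INM": 0.95,
    "MIR": 0.92,
}

PERIODS = tuple(PERIOD_YEARS)  # ("BL", "NF", "DF", "VDF")


@dataclass(frozen=True)
class StudyConfig:
    """Full configuration of one factorial study run."""

    locations: tuple[LocationClimate, ...]
    models: tuple[str, ...] = GCM_MODELS + (ENSEMBLE_MODEL,)
    scenarios: tuple[str, ...] = SCENARIOS
    periods: tuple[str, ...] = PERIODS
    gdd: GDDParams = GDDParams()
    window: SeasonWindow = SeasonWindow()
    n_replicates: int = 20
    seed: int = 1
    year_length: int = 365
    #: Baseline replicates are generated with this noise sd; the default 0
    #: yields identical replicates and hence SE exactly 0.00, matching the
    #: published baseline convention.
    baseline_noise_sd: float = 0.0
    gt_definition: str = "window"
    #: "weather": ensemble = day-wise mean of the six model series;
    #: "predictions": ensemble = mean of the six models' predictions.
    ensemble_mode: str = "weather"
    include_baseline_in_partition: bool = False
    integer_generations: bool = False
    model_delta_scale: Mapping[str, float] = field(
        default_factory=lambda: dict(MODEL_DELTA_SCALE)
    )

    def __post_init__(self) -> None:
        if not self.locations:
            raise ValueError("at least one location is required")
        for m in self.models:
            if m != ENSEMBLE_MODEL and m not in GCM_MODELS:
                raise ValueError(f"unknown model code {m!r}")
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ValueError(f"unknown scenario {s!r}")
        for p in self.periods:
            if p not in PERIOD_YEARS:
                raise ValueError(f"unknown period {p!r}")
        if self.ensemble_mode not in ("weather", "predictions"):
            raise ValueError("ensemble_mode must be 'weather' or 'predictions'")
        if self.gt_definition not in ("window", "boundary"):
            raise ValueError("gt_definition must be 'window' or 'boundary'")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def n_cells(self) -> int:
        return len(self.locations) * len(self.models) * len(self.scenarios) * len(self.periods)

    # --- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "locations": [asdict(c) for c in self.locations],
            "models": list(self.models),
            "scenarios": list(self.scenarios),
            "periods": list(self.periods),
            "gdd": asdict(self.gdd),
            "window": asdict(self.window),
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "year_length": self.year_length,
            "baseline_noise_sd": self.baseline_noise_sd,
            "gt_definition": self.gt_definition,
            "ensemble_mode": self.ensemble_mode,
            "include_baseline_in_partition": self.include_baseline_in_partition,
            "integer_generations": self.integer_generations,
            "model_delta_scale": dict(self.model_delta_scale),
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        d = dict(d)
        d["locations"] = tuple(LocationClimate(**c) for c in d["locations"])
        d["gdd"] = GDDParams(**d.get("gdd", {}))
        d["window"] = SeasonWindow(**d.get("window", {}))
        for key in ("models", "scenarios", "periods"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def default_config(seed: int = 1, n_replicates: int = 20, **overrides) -> StudyConfig:
    """The study's default configuration.

    Six locations whose baseline annual means come from the packaged
    projection table, seven models (six GCMs + ensemble), three
    scenarios, four periods, 20 replicates per cell.
    """
    table = load_annual_mean_projections()
    base = table[table["scenario"] == "BL"].pivot(
        index="location", columns="variable", values="value"
    )
    locations = tuple(
        LocationClimate(
            name=loc,
            baseline_tmax_mean=float(base.loc[loc, "tmax"]),
            baseline_tmin_mean=float(base.loc[loc, "tmin"]),
        )
        for loc in base.index
    )
    return StudyConfig(locations=locations, seed=seed, n_replicates=n_replicates, **overrides)


def ensemble_average(model_sets: Mapping[str, ReplicateSet]) -> ReplicateSet:
    """Day-wise average of the six GCM models' weather, per replicate index.

    All six model codes must be present; averaging preserves Tmax >= Tmin,
    is idempotent on identical inputs, and is performed *before* degree-day
    accumulation (the capped degree-day map is concave, so averaging order
    matters near the upper cut-off).

    Raises
    ------
    KeyError
        Naming any missing model.
    """
    missing = [m for m in GCM_MODELS if m not in model_sets]
    if missing:
        raise KeyError("ensemble needs all six models; missing: " + ", ".join(missing))
    sets = [model_sets[m] for m in GCM_MODELS]
    n_rep = sets[0].n_replicates
    for m, rs in zip(GCM_MODELS, sets):
        if rs.n_replicates != n_rep:
            raise ValueError(f"model {m} has {rs.n_replicates} replicates, expected {n_rep}")
    reps: list[WeatherSeries] = []
    for r in range(n_rep):
        tmax = np.mean([rs.replicates[r].tmax for rs in sets], axis=0)
        tmin = np.mean([rs.replicates[r].tmin for rs in sets], axis=0)
        ref = sets[0].replicates[r]
        df = pd.DataFrame({"tmax": tmax, "tmin": tmin}, index=ref.dates)
        reps.append(WeatherSeries(data=df, station_id=ref.station_id))
    cell = dict(sets[0].cell)
    cell["model"] = ENSEMBLE_MODEL
    return ReplicateSet(cell=cell, replicates=reps, seed=sets[0].seed)


@dataclass
class StudyResult:
    """Outputs of one study run.

    ``predictions`` has one row per (location, model, scenario, period,
    replicate); ``cell_summaries`` one row per cell; ``ttests`` compares
    each future ensemble cell against its baseline; ``gt_percent_change``
    is the model × scenario × period percent shortening of generation
    time; ``partitions`` maps response name to its variance partition.
    """

    config: StudyConfig
    predictions: pd.DataFrame
    cell_summaries: pd.DataFrame
    ttests: pd.DataFrame
    gt_percent_change: pd.DataFrame
    partitions: dict[str, VariancePartition]
    manifest: dict
    failures: list[dict] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.predictions.to_csv(out / "predictions.csv", index=False)
        self.cell_summaries.to_csv(out / "cell_summaries.csv", index=False)
        self.ttests.to_csv(out / "ttests.csv", index=False)
        self.gt_percent_change.to_csv(out / "gt_percent_change.csv", index=False)
        parts = []
        for response, vp in self.partitions.items():
            t = vp.table.copy()
            t.insert(0, "response", response)
            parts.append(t)
        pd.concat(parts, ignore_index=True).to_csv(out / "variance_partition.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return out


def _scenario_deltas(config: StudyConfig) -> pd.DataFrame:
    """Location × scenario × period warming offsets from the packaged table."""
    deltas = table_deltas(load_annual_mean_projections()).deltas
    wide = deltas.pivot_table(
        index=["location", "scenario", "period"], columns="variable", values="delta"
    ).reset_index()
    wide["period"] = wide["period"].map({v: k for k, v in PERIOD_YEARS.items()})
    return wide.set_index(["location", "scenario", "period"])


def _predict_replicates(
    rs: ReplicateSet, config: StudyConfig
) -> list[GenerationPrediction]:
    preds = []
    for series in rs.replicates:
        p = accumulate_generations(
            series, config.window, config.gdd, integer_generations=config.integer_generations
        )
        if config.gt_definition != "window":
            p.generation_time = generation_time(p, config.window, config.gt_definition)
        preds.append(p)
    return preds


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> StudyResult:
    """Run every configured cell and assemble the study outputs.

    Deterministic under a fixed seed: per-cell seeds are derived from
    ``config.seed`` and the cell's factor indices, so adding or removing
    cells does not perturb the remaining ones.  Cell failures are
    recorded in the manifest and the run continues.
    """
    delta_lookup = _scenario_deltas(config)
    loc_index = {c.name: i for i, c in enumerate(config.locations)}

    rows: list[dict] = []
    summary_rows: list[dict] = []
    failures: list[dict] = []
    manifest_cells: list[dict] = []

    preds_by_cell: dict[tuple[str, str, str, str], list[GenerationPrediction]] = {}

    for climate in config.locations:
        li = loc_index[climate.name]
        for si, scen in enumerate(config.scenarios):
            for pi, per in enumerate(config.periods):
                try:
                    if per == "BL":
                        dtx = dtn = 0.0
                    else:
                        d = delta_lookup.loc[(climate.name, scen, per)]
                        dtx, dtn = float(d["tmax"]), float(d["tmin"])
                    cell_climate = (
                        replace(climate, daily_noise_sd=config.baseline_noise_sd)
                        if per == "BL"
                        else climate
                    )
                    model_sets: dict[str, ReplicateSet] = {}
                    for mi, model in enumerate(GCM_MODELS):
                        scale = float(config.model_delta_scale.get(model, 1.0))
                        offset = ScenarioOffset(
                            scenario=scen if per != "BL" else "BL",
                            period=per,
                            delta_tmax=dtx * scale,
                            delta_tmin=dtn * scale,
                        )
                        cell_seed = child_seed(config.seed, li, mi, si, pi)
                        model_sets[model] = generate_replicate_set(
                            cell_climate,
                            offset,
                            n_replicates=config.n_replicates,
                            seed=cell_seed,
                            year_length=config.year_length,
                            cell={
                                "location": climate.name,
                                "model": model,
                                "scenario": scen,
                                "period": per,
                            },
                        )

                    for model in config.models:
                        if model == ENSEMBLE_MODEL:
                            continue
                        preds = _predict_replicates(model_sets[model], config)
                        preds_by_cell[(climate.name, model, scen, per)] = preds
                        manifest_cells.append(
                            {
                                "location": climate.name,
                                "model": model,
                                "scenario": scen,
                                "period": per,
                                "source": "generated",
                                "seed": model_sets[model].seed,
                            }
                        )

                    if ENSEMBLE_MODEL in config.models:
                        if config.ensemble_mode == "weather":
                            avg_rs = ensemble_average(model_sets)
                            preds = _predict_replicates(avg_rs, config)
                        else:
                            per_model = [
                                preds_by_cell.get((climate.name, m, scen, per))
                                or _predict_replicates(model_sets[m], config)
                                for m in GCM_MODELS
                            ]
                            preds = []
                            for r in range(config.n_replicates):
                                n_avg = float(np.mean([pm[r].n_generations for pm in per_model]))
                                tdd_avg = float(np.mean([pm[r].tdd for pm in per_model]))
                                gt = config.window.n_days / n_avg if n_avg > 0 else None
                                preds.append(
                                    GenerationPrediction(
                                        n_generations=n_avg,
                                        generation_time=gt,
                                        tdd=tdd_avg,
                                        mean_gdd=None,
                                        boundary_days=(),
                                        window=config.window,
                                        params=config.gdd,
                                    )
                                )
                        preds_by_cell[(climate.name, ENSEMBLE_MODEL, scen, per)] = preds
                        manifest_cells.append(
                            {
                                "location": climate.name,
                                "model": ENSEMBLE_MODEL,
                                "scenario": scen,
                                "period": per,
                                "source": config.ensemble_mode,
                                "seed": config.seed,
                            }
                        )
                except Exception as exc:  # record and continue with other cells
                    log.error("cell (%s, %s, %s) failed: %s", climate.name, scen, per, exc)
                    failures.append(
                        {"location": climate.name, "scenario": scen, "period": per, "error": str(exc)}
                    )

    for (loc, model, scen, per), preds in preds_by_cell.items():
        for r, p in enumerate(preds):
            rows.append(
                {
                    "location": loc,
                    "model": model,
                    "scenario": scen,
                    "period": per,
                    "replicate": r,
                    "n_generations": p.n_generations,
                    "generation_time": p.generation_time,
                    "tdd": p.tdd,
                    "mean_gdd": p.mean_gdd,
                }
            )
        s = summarize_cell(preds)
        summary_rows.append(
            {
                "location": loc,
                "model": model,
                "scenario": scen,
                "period": per,
                "mean_n": s.mean_n,
                "se_n": s.se_n,
                "mean_gt": s.mean_gt,
                "se_gt": s.se_gt,
                "n_replicates": s.n_replicates,
            }
        )

    predictions = pd.DataFrame(rows).sort_values(
        ["location", "model", "scenario", "period", "replicate"], kind="mergesort"
    ).reset_index(drop=True)
    cell_summaries = pd.DataFrame(summary_rows).sort_values(
        ["location", "model", "scenario", "period"], kind="mergesort"
    ).reset_index(drop=True)

    ttests = _baseline_ttests(predictions, config)
    gt_pc = _gt_percent_change(cell_summaries, config)
    partitions = _partitions(predictions, config)

    log.info(
        "study complete: %d cells (%d locations x %d models x %d scenarios x %d periods), %d failures",
        config.n_cells,
        len(config.locations),
        len(config.models),
        len(config.scenarios),
        len(config.periods),
        len(failures),
    )
    manifest = {
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "package_version": __version__,
        "n_cells": config.n_cells,
        "n_prediction_rows": len(predictions),
        "failures": failures,
        "cells": manifest_cells,
    }
    result = StudyResult(
        config=config,
        predictions=predictions,
        cell_summaries=cell_summaries,
        ttests=ttests,
        gt_percent_change=gt_pc,
        partitions=partitions,
        manifest=manifest,
        failures=failures,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


def _baseline_ttests(predictions: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Equal-variance t-tests of each future ensemble cell vs its baseline."""
    model = ENSEMBLE_MODEL if ENSEMBLE_MODEL in config.models else config.models[0]
    sub = predictions[predictions["model"] == model]
    rows = []
    for (loc, scen), grp in sub.groupby(["location", "scenario"], observed=True):
        bl = grp[grp["period"] == "BL"]
        if bl.empty:
            continue
        for per in config.periods:
            if per == "BL":
                continue
            fut = grp[grp["period"] == per]
            if fut.empty:
                continue
            for response in ("n_generations", "generation_time"):
                res = two_sample_t_equal_var(
                    fut[response].to_numpy(), bl[response].to_numpy()
                )
                rows.append(
                    {
                        "location": loc,
                        "model": model,
                        "scenario": scen,
                        "period": per,
                        "response": response,
                        "t": res.statistic,
                        "df": res.df,
                        "pvalue": res.pvalue,
                        "significant_p01": res.significant_at_01,
                        "degenerate": res.degenerate or "",
                    }
                )
    return pd.DataFrame(rows)


def _gt_percent_change(cell_summaries: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Percent GT shortening vs baseline, per model × scenario × period."""
    rows = []
    for (model, scen), grp in cell_summaries.groupby(["model", "scenario"], observed=True):
        bl = grp[grp["period"] == "BL"].set_index("location")["mean_gt"]
        for per in config.periods:
            if per == "BL":
                continue
            fut = grp[grp["period"] == per].set_index("location")["mean_gt"]
            common = bl.index.intersection(fut.index)
            if len(common) == 0:
                continue
            pcs = [percent_change_gt(fut[loc], bl[loc]) for loc in common]
            rows.append(
                {
                    "model": model,
                    "scenario": scen,
                    "period": per,
                    "pct_change_gt": float(np.mean(pcs)),
                    "n_locations": len(common),
                }
            )
    return pd.DataFrame(rows)


def _partitions(predictions: pd.DataFrame, config: StudyConfig) -> dict[str, VariancePartition]:
    data = predictions
    if not config.include_baseline_in_partition:
        data = data[data["period"] != "BL"]
    sources = [
        s
        for s, col in (
            ("location", "location"),
            ("period", "period"),
            ("model", "model"),
            ("scenario", "scenario"),
        )
        if data[col].nunique() >= 2
    ]
    out: dict[str, VariancePartition] = {}
    if len(sources) < 2:
        return out
    interactions = (
        [("location", "period")] if {"location", "period"}.issubset(sources) else []
    )
    for response in ("n_generations", "generation_time"):
        try:
            out[response] = anova_partition(
                data, response, sources=sources, interactions=interactions
            )
        except ValueError as exc:
            log.warning("variance partition for %s skipped: %s", response, exc)
    return out
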