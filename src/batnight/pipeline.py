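"""End-to-end pipeline: inputs -> night table -> fitted GAM -> calibration -> reports.

One :class:`PipelineConfig` (loadable from YAML) determines a run
completely; :func:`run_pipeline` writes a fixed artifact bundle to an
output directory:

    night_table.csv         one row per (location, night) with all covariates
    model.json              fitted coefficients, smoothing parameters, alpha
    calibration_report.csv  one row per alpha grid value, winner marked
    effect_curves.csv       per-term probability curves with 95% bands
    diagnostics.csv         randomized quantile residuals + approximate Wald table
    manifest.json           seeds, versions, row counts, config echo

All randomness (simulation, residual randomization, contrast Monte
Carlo) is seeded from the config, so replaying a manifest reproduces the
bundle byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import calibration as cal
from . import covariates as cov
from . import gam
from . import ingest
from . import synthetic as syn

logger = logging.getLogger("batnight")

ARTIFACTS = ("night_table.csv", "model.json", "calibration_report.csv",
             "effect_curves.csv", "diagnostics.csv", "manifest.json")


@dataclass
class PipelineConfig:
    """Everything a run needs.  Paths may be None when simulating."""

    detections_path: str | None = None
    weather_path: str | None = None
    platforms_path: str | None = None
    stations_path: str | None = None
    periods_path: str | None = None
    simulate: bool = True                       # no paths: generate a scenario
    species: str = "Pnat"
    season_window: tuple[int, int] = cov.SEASON_WINDOW
    migration_dir: float = cov.MIGRATION_DIR
    crosswind_flip: bool = True
    alpha_grid: tuple[float, float, float] = (0.0, 2.0, 0.025)  # min, max, step
    selection_rule: str = "youden_then_loss"
    threshold: float = 0.5
    lambda_grid: tuple[float, ...] = gam.DEFAULT_LAMBDA_GRID
    effect_terms: tuple[str, ...] = ("night_in_year", "lunar_phase",
                                     "tailwind", "crosswind")
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.season_window
        if not (1 <= lo <= hi <= 366):
            raise ValueError("season window must lie within [1, 366]")
        if self.alpha_grid[2] <= 0:
            raise ValueError("alpha grid step must be positive")

    @property
    def alpha_values(self) -> tuple[float, ...]:
        lo, hi, step = self.alpha_grid
        return tuple(np.round(np.arange(lo, hi + step / 2, step), 6))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("season_window", "alpha_grid", "lambda_grid", "effect_terms"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def summarize_detections(records: pd.DataFrame,
                         positive_minutes: pd.DataFrame | None = None) -> dict:
    """Recording totals, feeding-buzz share, and per-location counts.

    Percentages are rounded to one decimal, half away from zero.
    """
    if positive_minutes is None:
        positive_minutes = ingest.to_positive_minutes(records) if len(records) \
            else pd.DataFrame(columns=["location_id", "minute"])
    n = len(records)
    buzz = int(records["feeding_buzz"].sum()) if n else 0
    per_loc = (records.groupby("location_id").size().to_dict() if n else {})
    buzz_locs = (records.loc[records["feeding_buzz"], "location_id"].nunique()
                 if n else 0)
    return {
        "n_recordings": n,
        "n_feeding_buzzes": buzz,
        "feeding_buzz_pct": round_half_away(100.0 * buzz / n, 1) if n else 0.0,
        "n_positive_minutes": len(positive_minutes),
        "recordings_per_location": per_loc,
        "n_locations_with_feeding_buzz": int(buzz_locs),
    }


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention used for reported percentages)."""
    factor = 10 ** ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def positive_night_share(table: pd.DataFrame) -> dict:
    n = len(table)
    pos = int(table["y"].sum())
    return {"n_nights": n, "n_positive_nights": pos,
            "positive_night_pct": round_half_away(100.0 * pos / n, 1) if n else 0.0}


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def prepare_night_table(config: PipelineConfig):
    """Ingest (or simulate) the inputs and build the night table."""
    if config.simulate:
        scenario = syn.simulate_scenario(
            syn.ScenarioConfig(seed=config.seed),
            season_window=config.season_window,
            migration_dir=config.migration_dir,
            crosswind_flip=config.crosswind_flip)
        return scenario.night_table, scenario
    detections = ingest.read_detections(config.detections_path,
                                        species_filter=config.species)
    weather = ingest.read_weather(config.weather_path)
    platforms = ingest.read_stations(config.platforms_path)
    stations = ingest.read_stations(config.stations_path)
    periods = ingest.read_periods(config.periods_path)
    minutes = ingest.to_positive_minutes(detections)
    weather_series = {}
    for r in platforms.itertuples():
        loc_periods = periods.loc[periods["location_id"] == r.station_id]
        hours = _hours(loc_periods)
        weather_series[r.station_id] = ingest.impute_weather(
            (r.lon, r.lat), stations, weather, hours)
    table = cov.build_night_table(minutes, weather_series, periods, platforms,
                                  season_window=config.season_window,
                                  migration_dir=config.migration_dir,
                                  crosswind_flip=config.crosswind_flip)
    return table, None


def _hours(loc_periods: pd.DataFrame) -> pd.DatetimeIndex:
    pieces = []
    for r in loc_periods.itertuples():
        start = pd.Timestamp(r.start_date, tz="UTC") \
            + pd.Timedelta(hours=ingest.NIGHT_START_HOUR)
        end = pd.Timestamp(r.end_date, tz="UTC") \
            + pd.Timedelta(hours=ingest.NIGHT_START_HOUR + 23)
        pieces.append(pd.date_range(start, end, freq="h"))
    idx = pieces[0]
    for piece in pieces[1:]:
        idx = idx.union(piece)
    return idx


def run_pipeline(config: PipelineConfig, out_dir, overwrite: bool = False) -> dict:
    """Run every stage and write the artifact bundle.

    Returns a summary dict (the manifest).  Existing output directories
    are refused unless ``overwrite`` is set.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "pipeline.log")

    stage = "prepare"
    try:
        table, scenario = prepare_night_table(config)
        logger.info("night table: %d rows, %d positive", len(table),
                    int(table["y"].sum()))
        table.to_csv(out / "night_table.csv", index=False)

        stage = "fit"
        design = gam.assemble_design(table)
        lam = gam.select_lambda(design, config.lambda_grid)
        model = gam.fit_pirls(design, lam)
        logger.info("fit: deviance %.2f, edf %.2f", model.deviance, model.edf)

        stage = "calibrate"
        result = cal.evaluate_model(model, table, grid=config.alpha_values,
                                    threshold=config.threshold,
                                    rule=config.selection_rule)
        result.table.to_csv(out / "calibration_report.csv", index=False)
        model.to_json(out / "model.json")

        stage = "report"
        curves = []
        for term in config.effect_terms:
            block = gam._find_block(model, term)
            lo, hi = block.training_range() if block.spec.kind != "cyclic_cubic" \
                else block.payload["range"]
            grid = np.linspace(lo, hi, 101)
            curve = gam.effect_curve(model, term, grid)
            curve = curve.rename(columns={block.spec.covariates[0]: "value"})
            curve.insert(0, "term", term)
            curves.append(curve)
        pd.concat(curves, ignore_index=True).to_csv(out / "effect_curves.csv",
                                                    index=False)

        complete = model.complete_cases(table)
        resid = gam.dunn_smyth_residuals(model, complete, rng_seed=config.seed)
        diag = complete[["location_id", "night_start_date", "y"]].copy()
        diag["fitted_probability"] = gam.predict_probability(model, complete)
        diag["dunn_smyth_residual"] = resid
        diag.to_csv(out / "diagnostics.csv", index=False)

        final = result.selected
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config": _jsonable(asdict(config)),
            "n_nights": len(table),
            "n_positive_nights": int(table["y"].sum()),
            "alpha": model.alpha,
            "sensitivity": final.sensitivity,
            "specificity": final.specificity,
            "zero_one_loss": final.zero_one_loss,
            "deviance": model.deviance,
            "edf": model.edf,
            "artifacts": list(ARTIFACTS),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _setup_logging(log_path) -> None:
    logger.setLevel(logging.INFO)
    have_file = any(isinstance(h, logging.FileHandler)
                    and getattr(h, "baseFilename", None) == str(log_path)
                    for h in logger.handlers)
    if not have_file:
        logger.addHandler(logging.FileHandler(log_path))
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler) for h in logger.handlers):
        logger.addHandler(logging.StreamHandler(sys.stderr))
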