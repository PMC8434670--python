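"""Readers and writers for the file-based interfaces.

CSV dialect: comma-separated, ISO-8601 timestamps, dot decimal separator,
header row required.  Floats are written with 12 significant digits so a
write/read round trip reproduces values to better than 1e-9 relative.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .simulate import ScenarioConfig, SimulationResult
from .types import BatchConfig, LevelSeries, SensorReading

__all__ = [
    "read_level_series",
    "write_level_series",
    "read_batch_config",
    "write_batch_config",
    "read_scenario",
    "write_scenario_outputs",
    "write_outputs",
]

FLOAT_FMT = "%.12g"


def read_level_series(path: Path | str, format: Optional[str] = None) -> LevelSeries:
    """Read silo level readings from ``readings.csv`` or its JSON equivalent.

    Rows whose level cell is empty or unparseable become ``missing``
    readings; duplicate timestamps are rejected with an error naming the
    offending timestamp.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        df = pd.read_csv(path, dtype={"level_fraction": object})
    elif fmt == "json":
        df = pd.DataFrame(json.loads(path.read_text(encoding="utf-8")))
    else:
        raise ValueError(f"unknown format {format!r}")
    if not {"timestamp", "level_fraction"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns 'timestamp' and 'level_fraction'")
    ts = pd.to_datetime(df["timestamp"], utc=True).dt.tz_localize(None)
    levels = pd.to_numeric(df["level_fraction"], errors="coerce")
    order = np.argsort(ts.values, kind="stable")
    readings = []
    for i in order:
        lvl = levels.iloc[i]
        if pd.isna(lvl):
            readings.append(SensorReading(timestamp=ts.iloc[i].to_pydatetime(), quality_flag="missing"))
        else:
            readings.append(SensorReading(timestamp=ts.iloc[i].to_pydatetime(), level_fraction=float(lvl)))
    return LevelSeries(readings=readings)


def write_level_series(series: LevelSeries, path: Path | str) -> None:
    df = series.to_frame()
    df["timestamp"] = pd.DatetimeIndex(df["timestamp"]).strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_batch_config(path: Path | str) -> BatchConfig:
    """Load ``batch.yaml`` (or .json): the farmer-declared batch record."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return BatchConfig(**data)


def write_batch_config(config: BatchConfig, path: Path | str) -> None:
    data = config.model_dump(mode="json")
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


def read_scenario(path: Path | str) -> ScenarioConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return ScenarioConfig(**(data or {}))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "isoformat"):
        return obj.isoformat()
    return obj


def write_scenario_outputs(sim: SimulationResult, outdir: Path | str) -> dict[str, Path]:
    """Write the simulator's readings.csv + batch.yaml + truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "readings": outdir / "readings.csv",
        "batch": outdir / "batch.yaml",
        "truth": outdir / "truth.json",
    }
    write_level_series(sim.series, paths["readings"])
    write_batch_config(sim.batch, paths["batch"])
    truth = {k: _jsonable(v) for k, v in asdict(sim.truth).items()}
    paths["truth"].write_text(json.dumps(truth, indent=1) + "\n", encoding="utf-8")
    return paths


def write_outputs(result, outdir: Path | str) -> dict[str, Path]:
    """Write the pipeline's cleaned_weight.csv, weekly_intake.csv,
    distribution.csv, alerts.json and summary.json."""
    from .alerts import write_alerts  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cleaned_weight": outdir / "cleaned_weight.csv",
        "weekly_intake": outdir / "weekly_intake.csv",
        "distribution": outdir / "distribution.csv",
        "alerts": outdir / "alerts.json",
        "summary": outdir / "summary.json",
    }
    cw = result.silo.cleaned.to_frame()[["timestamp", "weight_kg"]]
    cw["timestamp"] = pd.DatetimeIndex(cw["timestamp"]).strftime("%Y-%m-%dT%H:%M:%S")
    cw.to_csv(paths["cleaned_weight"], index=False, float_format=FLOAT_FMT)

    wi = result.intake.to_frame()
    wi = wi[["week", "afi_sensor_kg", "afi_theory_kg", "deviation", "afi_linear_kg", "n_present"]]
    wi.to_csv(paths["weekly_intake"], index=False, float_format=FLOAT_FMT)

    if result.distribution is not None:
        result.distribution.to_frame().to_csv(paths["distribution"], index=False, float_format=FLOAT_FMT)
    else:
        pd.DataFrame(columns=["bin_low_kg", "bin_high_kg", "expected_count"]).to_csv(
            paths["distribution"], index=False
        )

    write_alerts(result.alerts, paths["alerts"])
    paths["summary"].write_text(json.dumps(_jsonable(result.summary), indent=2) + "\n", encoding="utf-8")
    return paths
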