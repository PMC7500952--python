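"""Configuration schema and tabular I/O.

Run configuration is YAML or JSON validated against a pydantic schema
(unknown keys rejected, violations reported with key paths).  Trace and
division tables are tidy CSV; every run directory written by the CLI
carries the effective configuration, the seed, and the package version.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

logger = logging.getLogger("ifngate")

TRACE_COLUMNS = ["cell_id", "time_h", "channel", "value"]
DIVISION_COLUMNS = ["cell_id", "division_time_h"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelConfig(_Strict):
    k1: float = Field(ge=0)
    k2: float = Field(gt=0)
    k3: float = Field(gt=0)
    k4: float = Field(ge=0)
    k5: float = Field(ge=0)
    tau: float = Field(default=8.0, ge=0)


class ProgramConfig(_Strict):
    """Either explicit intervals or one of the named builders."""

    intervals: list[tuple[float, float]] | None = None
    pretreatment: dict | None = None  # {pre_h, break_h, second_h}
    pulses: dict | None = None        # {n, on_h, off_h}

    @model_validator(mode="after")
    def _one_of(self):
        given = [x is not None for x in (self.intervals, self.pretreatment, self.pulses)]
        if sum(given) != 1:
            raise ValueError(
                "specify exactly one of intervals / pretreatment / pulses"
            )
        return self


class GatingConfig(_Strict):
    mode: str = "fixed_delay"
    tau: float = Field(default=8.0, ge=0)
    cycle_length: float = Field(default=21.82, gt=0)
    window: float = Field(default=7.3, ge=0)
    onset_phase: float = Field(default=0.0, ge=0)


class VariantConfig(_Strict):
    positive_feedback: bool = True
    negative_feedback: bool = True
    usp18_knockdown: bool = False
    grouping: str = "gated"


class NoiseConfigSchema(_Strict):
    sigma_irf9: float = Field(default=250.0, ge=0)
    sigma_usp18: float = Field(default=1000.0, ge=0)
    convention: str = "paper_euler"


class CohortConfigSchema(_Strict):
    n_cells: int = Field(default=400, ge=1)
    dt: float = Field(default=0.001, gt=0)
    pre_durations: list[float] = [2.0, 10.0, 24.0]
    break_h: float = Field(default=8.0, ge=0)
    second_h: float = Field(default=10.0, ge=0)
    horizon_h: float = Field(default=34.0, gt=0)
    cycle_length: float = Field(default=21.82, gt=0)
    window: float = Field(default=7.3, ge=0)


class GeneratorConfigSchema(_Strict):
    n_cells: int = Field(default=200, ge=1)
    cycle_mean: float = Field(default=21.82, gt=0)
    cycle_sd: float = Field(default=2.0, gt=0)
    window: float = Field(default=7.3, ge=0)
    act_mean: float = Field(default=7.9, gt=0)
    act_cv: float = Field(default=0.556, gt=0)
    usp18_jitter_sd: float = Field(default=0.5, ge=0)
    noise_sd: float = Field(default=20.0, ge=0)
    t_end: float = Field(default=45.0, gt=0)


class FitConfigSchema(_Strict):
    tau_grid: list[float] = [float(t) for t in range(1, 21)]
    n_starts: int = Field(default=10, ge=1)
    dt: float = Field(default=0.005, gt=0)
    trace_weight: float = Field(default=1.0, gt=0)
    endpoint_weight: float = Field(default=10.0, gt=0)


class AnalysisConfigSchema(_Strict):
    smooth_window: int = Field(default=5, ge=3)
    threshold_sd: float = Field(default=3.0, ge=0)
    persistence: int = Field(default=3, ge=1)
    delay_threshold: float = Field(default=10.0, ge=0)
    onset: float = 0.0


class RunConfig(_Strict):
    """Top-level run configuration; sub-blocks are optional and default
    to the package's study conditions."""

    model: ModelConfig | None = None
    program: ProgramConfig | None = None
    gating: GatingConfig = GatingConfig()
    variant: VariantConfig = VariantConfig()
    noise: NoiseConfigSchema = NoiseConfigSchema()
    cohort: CohortConfigSchema = CohortConfigSchema()
    generator: GeneratorConfigSchema = GeneratorConfigSchema()
    fit: FitConfigSchema = FitConfigSchema()
    analysis: AnalysisConfigSchema = AnalysisConfigSchema()
    seed: int = 0
    t_end: float = Field(default=48.0, gt=0)
    dt: float = Field(default=0.001, gt=0)


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return RunConfig.model_validate(raw or {})
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ValueError(f"invalid configuration in {path}: {locs}") from exc


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)


def read_traces(path) -> pd.DataFrame:
    """Read a tidy trace CSV (cell_id, time_h, channel, value); rejects
    duplicate (cell, channel, time) rows, sorts per cell/channel."""
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=["cell_id", "channel", "time_h"], keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: duplicate (cell, channel, time) rows at lines {lines}")
    sorted_df = df.sort_values(["cell_id", "channel", "time_h"], kind="mergesort")
    if not sorted_df.index.equals(df.index):
        logger.warning("%s: rows were not sorted; sorting", path)
    return sorted_df.reset_index(drop=True)


def write_traces(df: pd.DataFrame, path) -> None:
    df[TRACE_COLUMNS].to_csv(path, index=False)


def read_divisions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in DIVISION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df.sort_values(["cell_id", "division_time_h"]).reset_index(drop=True)


def write_divisions(df: pd.DataFrame, path) -> None:
    df[DIVISION_COLUMNS].to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2)


def write_provenance(out_dir, config: RunConfig, seed: int) -> None:
    """Record the effective configuration, seed, and package version."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_config(config, out_dir / "config.yaml")
    write_json(
        {"seed": seed, "ifngate_version": __version__},
        out_dir / "provenance.json",
    )
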