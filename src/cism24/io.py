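"""Dataset readers/writers and pipeline configuration.

The analytic CSV schema is the package's interchange format: one row per
subject with the five part columns (``mvpa, lpa, st, nsst, slp``, minutes),
``phq9_total``, optionally ``severity``, and covariate columns.  Everything
the CLI writes re-parses under these readers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._reference import DAY_MINUTES, PARTS

logger = logging.getLogger(__name__)

__all__ = [
    "PART_COLUMNS",
    "PipelineConfig",
    "load_config",
    "read_analytic_dataset",
    "write_analytic_dataset",
]

#: Part columns in the CSV schema (any order is accepted on read).
PART_COLUMNS = PARTS


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for the command-line pipeline."""

    part_order: tuple[str, ...] = PARTS
    total: float = DAY_MINUTES
    zero_floor: float = 1.0
    covariates: tuple[str, ...] = ()
    deltas: tuple[float, ...] = (10.0, 20.0, 30.0)
    curve_min: float = -60.0
    curve_max: float = 60.0
    curve_step: float = 5.0
    confidence: float = 0.95
    seed: int = 0
    n: int = 6666
    noise_sd: float = 5.0
    pivot_coefficients: dict[str, float] | None = None
    baseline_minutes: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if sorted(self.part_order) != sorted(PARTS):
            raise ValueError(
                f"part_order must be a permutation of {PARTS}, got {self.part_order}"
            )
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")
        if any(d <= 0 for d in self.deltas):
            raise ValueError("deltas must be positive")
        if self.curve_step <= 0:
            raise ValueError("curve_step must be positive")
        if self.zero_floor <= 0:
            raise ValueError("zero_floor must be positive")


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Read a YAML or JSON config file; keyword overrides win."""
    data: dict = {}
    if path is not None:
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = (
            json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        ) or {}
    data.update(overrides)
    for key in ("part_order", "covariates", "deltas"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return PipelineConfig(**data)


def read_analytic_dataset(
    path: str | Path,
    covariates: Sequence[str] = (),
    outcome: str = "phq9_total",
) -> tuple[pd.DataFrame, dict]:
    """Read and validate an analytic CSV.

    Rows with missing fields, non-positive part values, or a non-finite
    outcome are dropped and logged with their row number.  (The outcome is
    not clipped to the 0-27 questionnaire range: synthetic cohorts carry
    continuous scores.)  Returns the clean frame and a report dict with
    ``n_read`` and ``n_dropped``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = list(PART_COLUMNS) + [outcome] + list(covariates)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name} is missing required columns: {missing}")
    n_read = len(df)
    if n_read == 0:
        logger.warning("%s contains a header but no rows", path.name)
        return df, {"n_read": 0, "n_dropped": 0}

    parts = df[list(PART_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    outcome_vals = pd.to_numeric(df[outcome], errors="coerce")
    ok = (
        parts.notna().all(axis=1)
        & (parts > 0).all(axis=1)
        & outcome_vals.notna()
        & np.isfinite(outcome_vals)
        & df[list(covariates)].notna().all(axis=1)
    )
    for idx in df.index[~ok]:
        logger.info("dropping row %d: failed validation", idx)
    clean = df[ok].reset_index(drop=True)
    report = {"n_read": n_read, "n_dropped": int((~ok).sum())}
    if report["n_dropped"]:
        logger.warning("dropped %d of %d rows", report["n_dropped"], n_read)
    return clean, report


def write_analytic_dataset(df: pd.DataFrame, path: str | Path) -> None:
    """Write the analytic schema as UTF-8 CSV with a header row."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
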