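"""File I/O: packaged fixtures, cohort CSV round-trips, and run configs.

Cohort CSV schema: ``id``, one column per risk factor, optionally
``area_stratum`` and ``weight``, and ``status_s2`` .. ``status_s5``.
Missing factor values are empty cells, read back as NaN (never sentinel
strings).  Configs are YAML (preferred) or JSON.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort_simulator import STATUSES, CohortTable, RiskFactorSpec

__all__ = [
    "load_table1_marginals",
    "load_table2_coefficients",
    "load_baseline_config",
    "baseline_specs_from_config",
    "load_population_series",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_config",
]


def _data_path(name: str):
    return resources.files("cohortdrift.data").joinpath(name)


def load_table1_marginals() -> pd.DataFrame:
    """Per-survey attrition-status marginals (proportions of initial cohort)."""
    with resources.as_file(_data_path("table1_marginals.csv")) as p:
        return pd.read_csv(p)


def load_table2_coefficients() -> pd.DataFrame:
    """Long table of attrition odds ratios and 95% CIs per
    (factor, category, outcome) versus the respondent outcome."""
    with resources.as_file(_data_path("table2_coefficients.csv")) as p:
        return pd.read_csv(p)


def load_baseline_config() -> dict:
    """Raw baseline configuration (factor specs, missingness, strata,
    Survey-5 marginal targets)."""
    with resources.as_file(_data_path("baseline_specs.yaml")) as p:
        with open(p) as fh:
            return yaml.safe_load(fh)


def baseline_specs_from_config(config: dict) -> list[RiskFactorSpec]:
    specs = []
    for entry in config["factors"]:
        cats = entry["categories"]
        specs.append(
            RiskFactorSpec(
                name=entry["name"],
                categories=tuple(cats),
                baseline_probs=tuple(cats.values()),
                reference=entry["reference"],
                scale=entry.get("scale", "nominal"),
            )
        )
    return specs


def load_population_series() -> pd.DataFrame:
    """External and cohort prevalence series at calendar time points."""
    with resources.as_file(_data_path("population_series.csv")) as p:
        return pd.read_csv(p, dtype={"time": str})


def write_cohort_csv(cohort: CohortTable, path) -> None:
    cohort.data.to_csv(path, index=False)


def read_cohort_csv(path, factors: Sequence[str] | None = None) -> CohortTable:
    """Read a cohort CSV, validating schema and status vocabulary.

    ``factors`` defaults to every column that is not id/weight/stratum/status.
    Unknown status labels are rejected with their line numbers and values.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=object)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty input file") from None
    if df.empty:
        raise ValueError(f"{path}: no records")
    if "id" not in df.columns:
        raise ValueError(f"{path}: schema mismatch, required column 'id' not found")
    status_cols = [c for c in CohortTable.STATUS_COLUMNS if c in df.columns]
    problems = []
    for col in status_cols:
        bad = df[col].notna() & ~df[col].isin(STATUSES)
        for idx in df.index[bad]:
            problems.append(f"line {idx + 2}: {col}={df.loc[idx, col]!r}")
    if problems:
        shown = "; ".join(problems[:10])
        raise ValueError(
            f"{path}: unknown status labels (allowed: {', '.join(STATUSES)}): {shown}"
        )
    if "weight" in df.columns:
        df["weight"] = pd.to_numeric(df["weight"])
    df["id"] = pd.to_numeric(df["id"])
    if factors is None:
        reserved = {"id", "weight", "area_stratum", *CohortTable.STATUS_COLUMNS}
        factors = [c for c in df.columns if c not in reserved]
    cohort = CohortTable(df, list(factors))
    cohort.validate()
    return cohort


def read_config(path) -> dict:
    """YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
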