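"""Tabular data model shared by every stage of the pipeline.

Two flat CSV tables describe a habitat-patch network and its monitoring
record:

``patches.csv``
    One row per patch: planar coordinates in meters (a projected CRS is
    assumed upstream; at the ~35 km extent of a typical study window,
    planar Euclidean distance is adequate), patch area in m², pooled
    host-plant percent cover on the 0-100 scale, a three-level grazing
    regime, mean and SD of annual solar irradiance (Wh/m²), a flag saying
    whether the patch is part of the annual monitoring, and a fallback
    abundance used for connectivity sums when it is not.

``surveys.csv``
    One row per patch × year × generation: the adult count recorded on a
    transect walk, plus a flag marking occasions outside the patch's
    survey window.

Both tables are carried in memory as :class:`pandas.DataFrame` with the
exact column names of the CSV dialect, so round-tripping is trivial.
Validation is strict and reports every offending row, not just the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

GRAZING_LEVELS = ("never", "sometimes", "always")
GENERATIONS = ("spring", "summer")
#: order of generations within a year: the spring flight precedes the summer one
GENERATION_ORDER = {"spring": 0, "summer": 1}

PATCH_COLUMNS = [
    "patch_id",
    "x_m",
    "y_m",
    "area_m2",
    "host_density_pct",
    "grazing",
    "irr_mean_whm2",
    "irr_sd_whm2",
    "surveyed",
    "fallback_abundance",
]

SURVEY_COLUMNS = ["patch_id", "year", "generation", "count", "surveyed"]


class ValidationError(ValueError):
    """Input table violates the data model; carries row-level diagnostics."""

    def __init__(self, problems: Iterable[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid input table:\n  " + "\n  ".join(self.problems)
        )


@dataclass
class AnalysisConfig:
    """Settings of the statistical pipeline.

    Parameters
    ----------
    alpha
        Per-meter decay rate of the negative-exponential dispersal kernel;
        1/alpha is the mean movement distance. The default 0.0034 m⁻¹
        corresponds to a 295 m mean movement distance.
    abundance_offset
        Small constant added to mean abundance before log-transforming so
        that patch-generations with zero mean can enter the Gaussian model.
    confidence_mass
        Cumulative Akaike weight defining the confidence set of models used
        for averaging.
    averaging_mode
        ``"full"`` substitutes 0 for a coefficient in models lacking the
        term (shrinkage toward zero); ``"conditional"`` averages only over
        models containing it.
    log_transform_area
        If True, use log10(area) instead of raw area as the predictor.
    fallback_generation_scale
        Optional mapping generation -> multiplier applied to the fallback
        abundance of unmonitored patches when computing connectivity. Off
        (None) by default: the fallback is a single rough estimate, not
        generation-resolved.
    """

    alpha: float = 0.0034
    abundance_offset: float = 0.1
    confidence_mass: float = 0.95
    averaging_mode: str = "full"
    log_transform_area: bool = False
    fallback_generation_scale: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValidationError([f"alpha must be >= 0, got {self.alpha}"])
        if not (0 < self.confidence_mass <= 1):
            raise ValidationError(
                [f"confidence_mass must be in (0, 1], got {self.confidence_mass}"]
            )
        if self.averaging_mode not in ("full", "conditional"):
            raise ValidationError(
                [f"averaging_mode must be 'full' or 'conditional', got {self.averaging_mode!r}"]
            )


def _as_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False,
    }
    out = series.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = series[out.isna()].unique()
        raise ValidationError([f"unparseable boolean value(s): {list(bad)}"])
    return out.astype(bool)


def validate_patches(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a patch table; raise on any violation."""
    problems: list[str] = []
    missing = [c for c in PATCH_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError([f"patches table missing column(s): {missing}"])
    df = df.loc[:, PATCH_COLUMNS].copy()
    df["patch_id"] = df["patch_id"].astype(str)
    df["surveyed"] = _as_bool(df["surveyed"])

    dup = df["patch_id"][df["patch_id"].duplicated()].unique()
    if len(dup):
        problems.append(f"duplicate patch_id(s): {sorted(dup)}")
    for idx, row in df.iterrows():
        if not row["area_m2"] > 0:
            problems.append(f"row {idx} (patch {row['patch_id']}): area_m2 must be > 0, got {row['area_m2']}")
        if not (0 <= row["host_density_pct"] <= 100):
            problems.append(f"row {idx} (patch {row['patch_id']}): host_density_pct outside [0, 100]: {row['host_density_pct']}")
        if row["grazing"] not in GRAZING_LEVELS:
            problems.append(f"row {idx} (patch {row['patch_id']}): unknown grazing level {row['grazing']!r} (field 'grazing')")
        if row["irr_mean_whm2"] < 0 or row["irr_sd_whm2"] < 0:
            problems.append(f"row {idx} (patch {row['patch_id']}): irradiance columns must be >= 0")
        if row["fallback_abundance"] < 0:
            problems.append(f"row {idx} (patch {row['patch_id']}): fallback_abundance must be >= 0")
    if problems:
        raise ValidationError(problems)
    return df.reset_index(drop=True)


def validate_surveys(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a survey table and sort it chronologically.

    The chronology is a total order: year ascending, spring before summer
    within a year, patch id as the final tiebreak.
    """
    problems: list[str] = []
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError([f"surveys table missing column(s): {missing}"])
    df = df.loc[:, SURVEY_COLUMNS].copy()
    df["patch_id"] = df["patch_id"].astype(str)
    df["surveyed"] = _as_bool(df["surveyed"])
    df["year"] = df["year"].astype(int)

    bad_gen = ~df["generation"].isin(GENERATIONS)
    for idx in df.index[bad_gen]:
        problems.append(f"row {idx}: unknown generation {df.at[idx, 'generation']!r}")
    bad_count = df["count"] < 0
    for idx in df.index[bad_count]:
        problems.append(f"row {idx} (patch {df.at[idx, 'patch_id']}): negative count {df.at[idx, 'count']}")
    key = df[["patch_id", "year", "generation"]]
    dups = key[key.duplicated()]
    for _, row in dups.iterrows():
        problems.append(
            f"duplicate survey key (patch_id={row['patch_id']}, year={row['year']}, generation={row['generation']})"
        )
    if problems:
        raise ValidationError(problems)
    df["count"] = df["count"].astype(int)
    return sort_surveys(df)


def sort_surveys(df: pd.DataFrame) -> pd.DataFrame:
    order = df["generation"].map(GENERATION_ORDER)
    return (
        df.assign(_g=order)
        .sort_values(["year", "_g", "patch_id"], kind="mergesort")
        .drop(columns="_g")
        .reset_index(drop=True)
    )


def read_patches(path: str | Path) -> pd.DataFrame:
    return validate_patches(pd.read_csv(path))


def read_surveys(path: str | Path) -> pd.DataFrame:
    return validate_surveys(pd.read_csv(path))


def write_patches(df: pd.DataFrame, path: str | Path) -> None:
    validate_patches(df).to_csv(path, index=False)


def write_surveys(df: pd.DataFrame, path: str | Path) -> None:
    validate_surveys(df).to_csv(path, index=False)
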