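import numpy as np
import pandas as pd
import pytest

from patchmeta import (AnalysisConfig, DynamicsConfig, LandscapeConfig,
                       generate_landscape, simulate_dataset)


@pytest.fixture(scope="session")
def study_landscape() -> pd.DataFrame:
    """Default-size landscape: 50 surveyed + 25 network patches."""
    return generate_landscape(LandscapeConfig(seed=11))


@pytest.fixture(scope="session")
def study_dataset():
    """One full synthetic study: landscape + 12-year two-generation surveys."""
    return simulate_dataset(LandscapeConfig(seed=11), DynamicsConfig(seed=11))


@pytest.fixture()
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture()
def toy_patches() -> pd.DataFrame:
    """Four hand-written patches, one unsurveyed with a fallback abundance."""
    return pd.DataFrame({
        "patch_id": ["a", "b", "c", "d"],
        "x_m": [0.0, 295.0, 0.0, 1000.0],
        "y_m": [0.0, 0.0, 400.0, 1000.0],
        "area_m2": [1000.0, 2000.0, 1500.0, 500.0],
        "host_density_pct": [2.0, 0.0, 10.0, 5.0],
        "grazing": ["never", "sometimes", "always", "never"],
        "irr_mean_whm2": [8.0e5, 8.1e5, 7.9e5, 8.0e5],
        "irr_sd_whm2": [4.0e4, 5.0e4, 3.0e4, 4.5e4],
        "surveyed": [True, True, True, False],
        "fallback_abundance": [0, 0, 0, 3],
    })


@pytest.fixture()
def toy_surveys() -> pd.DataFrame:
    """Hand-written two-year survey table for the toy patches."""
    rows = []
    for pid, counts in {
        "a": {(1, "spring"): 2, (1, "summer"): 0, (2, "spring"): 3, (2, "summer"): 4},
        "b": {(1, "spring"): 10, (1, "summer"): 7, (2, "spring"): 4, (2, "summer"): 8},
        "c": {(1, "spring"): 0, (1, "summer"): 0, (2, "spring"): 0, (2, "summer"): 0},
    }.items():
        for (year, gen), count in counts.items():
            rows.append({"patch_id": pid, "year": year, "generation": gen,
                         "count": count, "surveyed": True})
    return pd.DataFrame(rows)
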