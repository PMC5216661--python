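"""Synthetic habitat networks and multi-year, two-generation survey data.

The generator emulates a 12-year monitoring campaign of a bivoltine
butterfly in a fragmented network of dry-grassland patches near its
northern range margin: ~50 monitored patches plus ~25 unmonitored network
patches scattered over a 35 × 35 km window, two flight periods per year
for the first 8 years and summer-only monitoring afterwards, unequal
per-patch survey durations, and covariates calibrated to the field
summaries of such a system (log-normal patch areas with mean ~15,756 m²,
zero-inflated host-plant cover with mean ~3.61%, grazing split 7/19/24
over never/sometimes/always, solar irradiance ~807,542 ± 48,325 Wh/m²).

Dynamics are generated from *known standardized coefficients*, so every
downstream stage — connectivity, response construction, multimodel
inference — can be validated by parameter recovery:

* occupancy of a patch in a year is Bernoulli with logit equal to the
  standardized linear predictor ``X · beta_occ``; the draw is shared by
  the two generations of that year (one local population flies in both
  flight periods), so a vacant two-generation year yields two mutually
  consecutive zero counts and the conservative false-absence rule
  downstream recovers the simulated state;
* counts on an occupied occasion are Poisson-lognormal: Poisson with rate
  ``exp(X · beta_abund + eps) × summer multiplier``, eps ~ N(0,
  overdispersion_sd) per occasion — field counts of butterflies are
  overdispersed, and overdispersion_sd = 0 recovers a pure Poisson;
* the connectivity covariate is computed from a first-pass simulation
  that ignores connectivity (a documented two-pass scheme rather than a
  fixed-point iteration), then dynamics are redrawn including the
  connectivity terms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from . import connectivity as conn_mod
from .inference import ALL_COLUMNS, standardize
from .io import (GRAZING_LEVELS, ValidationError, validate_patches,
                 validate_surveys, write_patches, write_surveys)

#: per-patch survey durations of the emulated design: 34 patches monitored
#: all 12 years, eight for 11, six for 9, one for 8 and one for 7 years
SURVEY_DURATION_BREAKDOWN = {12: 34, 11: 8, 9: 6, 8: 1, 7: 1}

#: occupancy breakdown of the emulated system: patches occupied in every
#: year, never occupied, and occupied intermittently
OCCUPANCY_BREAKDOWN = {"always_occupied": 9, "never_occupied": 9,
                       "intermittent": 32}


def total_patches_in_design(breakdown: dict[int, int] = SURVEY_DURATION_BREAKDOWN) -> int:
    """Total monitored patches implied by a survey-duration breakdown."""
    return int(sum(breakdown.values()))


def ever_occupied_patches_in_design(
        breakdown: dict[str, int] = OCCUPANCY_BREAKDOWN) -> int:
    """Patches recorded as occupied at least once, from the occupancy breakdown."""
    return int(breakdown["always_occupied"] + breakdown["intermittent"])


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    s2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - s2 / 2.0, math.sqrt(s2)


def host_lognormal_params(mean: float = 3.61, sd: float = 5.63,
                          zero_prob: float = 0.15,
                          upper: float = 40.0) -> tuple[float, float]:
    """(mu, sigma) of the positive part of the zero-inflated host-cover mixture.

    sigma comes from moment-matching the untruncated mixture to the target
    mean and SD; mu is then adjusted numerically so that the mean of the
    [0, upper]-truncated positive part still matches, keeping the overall
    mixture mean on target despite the truncation.
    """
    m_pos = mean / (1.0 - zero_prob)
    var_pos = (sd ** 2 + mean ** 2) / (1.0 - zero_prob) - m_pos ** 2
    sigma = math.sqrt(math.log(1.0 + var_pos / m_pos ** 2))

    def truncated_mean(mu: float) -> float:
        a = (math.log(upper) - mu) / sigma
        return math.exp(mu + sigma ** 2 / 2) * norm.cdf(a - sigma) / norm.cdf(a)

    mu = brentq(lambda m: truncated_mean(m) - m_pos, -10.0, 10.0)
    return mu, sigma


_AREA_MU, _AREA_SIGMA = lognormal_params_from_moments(15756.0, 24882.0)
_HOST_MU, _HOST_SIGMA = host_lognormal_params()


@dataclass
class LandscapeConfig:
    """Static landscape: patch positions, areas and quality covariates."""
    n_surveyed: int = 50
    n_unsurveyed: int = 25
    window_side: float = 35_000.0
    core_side: float = 10_000.0
    n_clusters: int = 12
    cluster_sd: float = 400.0
    min_edge_separation: float = 50.0
    area_log_mean: float = _AREA_MU
    area_log_sd: float = _AREA_SIGMA
    host_zero_prob: float = 0.15
    host_log_mean: float = _HOST_MU
    host_log_sd: float = _HOST_SIGMA
    host_upper_pct: float = 40.0
    grazing_probs: tuple[float, float, float] = (7 / 50, 19 / 50, 24 / 50)
    irr_mean_center: float = 807_542.0
    irr_mean_spread: float = 48_325.0
    irr_sd_center: float = 47_678.0
    irr_sd_spread: float = 31_754.0
    fallback_mean: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.grazing_probs) - 1.0) > 1e-9 or min(self.grazing_probs) < 0:
            raise ValidationError(
                [f"grazing_probs must be a probability vector, got {self.grazing_probs}"])
        if self.n_surveyed < 2:
            raise ValidationError(["n_surveyed must be >= 2"])
        for name in ("area_log_sd", "host_log_sd", "irr_mean_spread",
                     "irr_sd_spread", "host_zero_prob"):
            if getattr(self, name) < 0:
                raise ValidationError([f"{name} must be >= 0"])


def _default_beta_occ() -> dict[str, float]:
    # dominant standardized effects of the emulated system: host-plant
    # density, patch area, and a negative connectivity x host interaction
    # (the rescue effect weakens the host-density dependence of
    # well-connected patches)
    return {"intercept": 0.0, "host_density": 0.85, "area": 0.6,
            "connectivity:host_density": -0.7}


def _default_beta_abund() -> dict[str, float]:
    # Poisson log-rate effects are smaller than the patch-level log-mean
    # effects of the emulated system because part of the observed abundance
    # response operates through occupancy; with this baseline the realized
    # per-patch mean abundances land on the field summaries (~6 spring,
    # ~16 summer among ever-occupied patches)
    return {"intercept": math.log(5.0), "host_density": 0.45, "area": 0.3,
            "connectivity:host_density": -0.35}


@dataclass
class DynamicsConfig:
    """Occupancy/count dynamics generated from known standardized effects."""
    years: int = 12
    both_generations_through_year: int = 8
    beta_occ: dict[str, float] = field(default_factory=_default_beta_occ)
    beta_abund: dict[str, float] = field(default_factory=_default_beta_abund)
    summer_abundance_multiplier: float = 16.16 / 6.13
    overdispersion_sd: float = 0.5
    alpha: float = 0.0034
    survey_duration_scheme: dict[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValidationError(["years must be >= 1"])
        if self.summer_abundance_multiplier <= 0:
            raise ValidationError(["summer_abundance_multiplier must be > 0"])
        if self.overdispersion_sd < 0:
            raise ValidationError(["overdispersion_sd must be >= 0"])
        for name, beta in (("beta_occ", self.beta_occ),
                           ("beta_abund", self.beta_abund)):
            unknown = set(beta) - set(ALL_COLUMNS)
            if unknown:
                raise ValidationError(
                    [f"{name} refers to unknown term(s) {sorted(unknown)}; "
                     f"allowed: {list(ALL_COLUMNS)}"])


def scaled_landscape_config(n_surveyed: int, n_unsurveyed: int = 25,
                            seed: int = 0, **overrides) -> LandscapeConfig:
    """Landscape config for a larger replica of the default study system.

    Scaling the survey to ``n_surveyed`` patches keeps the local spatial
    structure of the default calibration fixed — the same patches-per-
    cluster ratio and within-cluster scatter — by growing the number of
    patch complexes and the core area proportionally to ``n_surveyed``.
    The per-patch distributions of covariates and of the connectivity
    index therefore stay at their calibrated study-size values at any n.
    """
    base = LandscapeConfig()
    factor = n_surveyed / base.n_surveyed
    kwargs = dict(
        n_surveyed=n_surveyed,
        n_unsurveyed=n_unsurveyed,
        n_clusters=max(1, round(base.n_clusters * factor)),
        core_side=min(base.core_side * math.sqrt(factor), base.window_side),
        seed=seed,
    )
    kwargs.update(overrides)
    return LandscapeConfig(**kwargs)


def durations_from_breakdown(breakdown: dict[int, int], n: int) -> list[int]:
    """Per-patch survey durations for ``n`` patches, scaled from a breakdown.

    Counts are scaled proportionally with largest-remainder rounding, so
    the default breakdown reproduces itself exactly at its own total.
    """
    total = sum(breakdown.values())
    items = sorted(breakdown.items(), reverse=True)
    raw = [(d, c * n / total) for d, c in items]
    counts = {d: int(math.floor(x)) for d, x in raw}
    short = n - sum(counts.values())
    for d, x in sorted(raw, key=lambda t: t[1] - math.floor(t[1]), reverse=True):
        if short == 0:
            break
        counts[d] += 1
        short -= 1
    out: list[int] = []
    for d, c in sorted(counts.items(), reverse=True):
        out.extend([d] * c)
    return out[:n]


def generate_landscape(config: LandscapeConfig) -> pd.DataFrame:
    """Draw a patch table; deterministic given ``config.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = config.n_surveyed + config.n_unsurveyed
    area = rng.lognormal(config.area_log_mean, config.area_log_sd, n)

    # Monitored patches form local complexes (dry-grassland patches cluster
    # around villages and eskers) inside a core area of the window; the
    # extra network patches span the species' whole distribution. A Thomas
    # cluster process — cluster centers uniform in the core, patches
    # Gaussian-scattered around them — reproduces both the mean and the SD
    # of the field system's connectivity index (roughly 4.5 ± 8 spring and
    # 12 ± 19 summer with the calibrated abundances), which a uniform
    # placement cannot do simultaneously.
    #
    # Patches are discrete entities: two patches count as separate only when
    # their edges are >= 50 m apart, so centroid separations are bounded
    # below by the sum of the (circular-equivalent) radii plus 50 m.
    # Placement is sequential rejection sampling against that constraint.
    lo = (config.window_side - min(config.core_side, config.window_side)) / 2.0
    hi = lo + min(config.core_side, config.window_side)
    centers = rng.uniform(lo, hi, (max(config.n_clusters, 1), 2))
    assignment = rng.integers(0, len(centers), config.n_surveyed)
    radius = np.sqrt(area / np.pi)
    x = np.empty(n)
    y = np.empty(n)
    for i in range(n):
        for _ in range(1000):
            if i < config.n_surveyed:
                xi, yi = centers[assignment[i]] + rng.normal(0.0, config.cluster_sd, 2)
            else:
                xi, yi = rng.uniform(0.0, config.window_side, 2)
            d = np.hypot(x[:i] - xi, y[:i] - yi)
            if np.all(d >= radius[:i] + radius[i] + config.min_edge_separation):
                break
        x[i], y[i] = xi, yi

    host = np.zeros(n)
    positive = rng.random(n) >= config.host_zero_prob
    idx = np.flatnonzero(positive)
    while len(idx):
        draw = rng.lognormal(config.host_log_mean, config.host_log_sd, len(idx))
        ok = draw <= config.host_upper_pct
        host[idx[ok]] = draw[ok]
        idx = idx[~ok]

    grazing = rng.choice(GRAZING_LEVELS, size=n, p=list(config.grazing_probs))

    def trunc_normal(center, spread, size):
        out = np.full(size, -1.0)
        bad = np.flatnonzero(out < 0)
        while len(bad):
            out[bad] = rng.normal(center, spread, len(bad))
            bad = np.flatnonzero(out < 0)
        return out

    irr_mean = trunc_normal(config.irr_mean_center, config.irr_mean_spread, n)
    irr_sd = trunc_normal(config.irr_sd_center, config.irr_sd_spread, n)

    surveyed = np.arange(n) < config.n_surveyed
    fallback = np.where(surveyed, 0, rng.poisson(config.fallback_mean, n))

    width = len(str(n))
    patches = pd.DataFrame({
        "patch_id": [f"p{i + 1:0{width}d}" for i in range(n)],
        "x_m": x, "y_m": y, "area_m2": area,
        "host_density_pct": host, "grazing": grazing,
        "irr_mean_whm2": irr_mean, "irr_sd_whm2": irr_sd,
        "surveyed": surveyed, "fallback_abundance": fallback,
    })
    return validate_patches(patches)


def _covariate_design(patches: pd.DataFrame,
                      conn_std: np.ndarray | None) -> np.ndarray:
    """Standardized generator design (rows = surveyed patches, ALL_COLUMNS).

    ``conn_std`` is an already-standardized connectivity column, or None
    for the connectivity-free first pass (column and its interactions 0).
    """
    n = len(patches)
    cols = {}
    cols["intercept"] = np.ones(n)
    cols["area"], *_ = standardize(patches["area_m2"], "area")
    cols["host_density"], *_ = standardize(patches["host_density_pct"], "host_density")
    cols["irr_mean"], *_ = standardize(patches["irr_mean_whm2"], "irr_mean")
    cols["irr_sd"], *_ = standardize(patches["irr_sd_whm2"], "irr_sd")
    cols["grazing_sometimes"] = (patches["grazing"] == "sometimes").to_numpy(float)
    cols["grazing_always"] = (patches["grazing"] == "always").to_numpy(float)
    cols["connectivity"] = np.zeros(n) if conn_std is None else conn_std
    for partner in ("grazing_sometimes", "grazing_always", "host_density",
                    "irr_mean", "irr_sd"):
        cols[f"connectivity:{partner}"] = cols["connectivity"] * cols[partner]
    return np.column_stack([cols[c] for c in ALL_COLUMNS])


def _beta_vector(beta: dict[str, float]) -> np.ndarray:
    return np.array([beta.get(c, 0.0) for c in ALL_COLUMNS])


def _simulate_pass(patches_sub: pd.DataFrame, X_occ: np.ndarray,
                   X_gen: dict[str, np.ndarray], config: DynamicsConfig,
                   durations: list[int], rng: np.random.Generator) -> pd.DataFrame:
    years = np.arange(1, config.years + 1)
    spring_years = set(range(1, config.both_generations_through_year + 1))
    n = len(patches_sub)
    p_occ = expit(X_occ @ _beta_vector(config.beta_occ))
    occupied = rng.random((n, config.years)) < p_occ[:, None]  # year-level state

    records = []
    for gen in ("spring", "summer"):
        gen_years = [y for y in years if gen == "summer" or y in spring_years]
        if not gen_years:
            continue
        lam_base = np.exp(X_gen[gen] @ _beta_vector(config.beta_abund))
        if gen == "summer":
            lam_base = lam_base * config.summer_abundance_multiplier
        for j, y in enumerate(gen_years):
            eps = rng.normal(0.0, config.overdispersion_sd, n)
            lam = lam_base * np.exp(eps)
            counts = np.where(occupied[:, y - 1], rng.poisson(lam), 0)
            start = np.array([config.years - d + 1 for d in durations])
            in_window = y >= start
            records.append(pd.DataFrame({
                "patch_id": patches_sub["patch_id"].to_numpy(),
                "year": y, "generation": gen,
                "count": np.where(in_window, counts, 0),
                "surveyed": in_window,
            }))
    return pd.concat(records, ignore_index=True)


def simulate_surveys(patches: pd.DataFrame, config: DynamicsConfig) -> pd.DataFrame:
    """Simulate the monitoring record for the surveyed patches.

    Two-pass scheme: pass 1 draws dynamics with the connectivity terms
    silenced; per-generation mean connectivity is computed from that draw
    (unmonitored patches contributing their fallback abundance); pass 2
    redraws the dynamics with the full linear predictor. Occasions outside
    a patch's survey window are emitted with ``surveyed=False``.
    """
    patches = validate_patches(patches)
    sub = patches.loc[patches["surveyed"]].reset_index(drop=True)
    if len(sub) < 2:
        raise ValidationError(["need at least 2 surveyed patches"])
    durations = _resolve_durations(sub, config)
    ss = np.random.SeedSequence([config.seed, 1]).spawn(2)
    rng1, rng2 = (np.random.default_rng(s) for s in ss)

    # pass 1: connectivity-free draw, used only to realize neighbour abundances
    X0 = _covariate_design(sub, None)
    pass1 = validate_surveys(_simulate_pass(sub, X0, {"spring": X0, "summer": X0},
                                            config, durations, rng1))

    conn = conn_mod.mean_connectivity(patches, pass1, config.alpha)
    conn_wide = conn.pivot(index="patch_id", columns="generation",
                           values="connectivity")
    conn_wide = conn_wide.reindex(sub["patch_id"])
    gens = [g for g in ("spring", "summer") if g in conn_wide.columns]
    conn_std = {g: standardize(conn_wide[g].to_numpy(), f"connectivity[{g}]")[0]
                for g in gens}
    # occupancy is a year-level state, so it uses a single patch-level
    # connectivity covariate: the mean of the generations' standardized values
    occ_conn = np.mean(np.column_stack([conn_std[g] for g in gens]), axis=1)

    X_occ = _covariate_design(sub, occ_conn)
    X_gen = {g: _covariate_design(sub, conn_std[g]) for g in gens}
    if "spring" not in X_gen:
        X_gen["spring"] = X_occ
    surveys = _simulate_pass(sub, X_occ, X_gen, config, durations, rng2)
    return validate_surveys(surveys)


def _resolve_durations(sub: pd.DataFrame, config: DynamicsConfig) -> list[int]:
    if config.survey_duration_scheme is None:
        return durations_from_breakdown(SURVEY_DURATION_BREAKDOWN, len(sub))
    scheme = config.survey_duration_scheme
    missing = set(sub["patch_id"]) - set(scheme)
    if missing:
        raise ValidationError(
            [f"survey_duration_scheme missing patch(es): {sorted(missing)}"])
    return [min(int(scheme[p]), config.years) for p in sub["patch_id"]]


def simulate_dataset(landscape: LandscapeConfig, dynamics: DynamicsConfig
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Landscape + surveys in one call."""
    patches = generate_landscape(landscape)
    return patches, simulate_surveys(patches, dynamics)


def write_dataset(patches: pd.DataFrame, surveys: pd.DataFrame,
                  outdir: str | Path, landscape: LandscapeConfig | None = None,
                  dynamics: DynamicsConfig | None = None) -> None:
    """Write patches.csv, surveys.csv and a JSON metadata sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_patches(patches, outdir / "patches.csv")
    write_surveys(surveys, outdir / "surveys.csv")
    from . import __version__
    meta: dict = {"version": __version__}
    if landscape is not None:
        meta["landscape"] = {k: (list(v) if isinstance(v, tuple) else v)
                             for k, v in vars(landscape).items()}
    if dynamics is not None:
        meta["dynamics"] = {k: v for k, v in vars(dynamics).items()}
    (outdir / "simulation_meta.json").write_text(json.dumps(meta, indent=2))
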