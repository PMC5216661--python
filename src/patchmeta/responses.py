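"""Per-patch, per-generation response variables.

Three responses are built from the raw counts, separately for the spring
and summer flight periods of a bivoltine species:

* **occupancy fraction** — years deemed occupied divided by years surveyed
  in that generation, after a conservative false-absence correction;
* **mean abundance** — mean adult count across the surveyed years of the
  generation, zeros included;
* **CV of abundance** — sample SD of the yearly counts divided by their
  mean, a measure of population variability.

The false-absence correction addresses single-visit monitoring: a patch is
deemed unoccupied on an occasion only when no individuals were recorded on
that occasion *and* on an adjacent occasion in the patch's own surveyed
chronology — two consecutive zeroes, whether in the same year (spring and
summer) or in consecutive years. An isolated zero flanked by positive
counts is treated as a detection failure and kept occupied. The correction
can only raise occupancy relative to the naive zero-count-means-absent
reading, never lower it.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import GENERATION_ORDER, AnalysisConfig

logger = logging.getLogger(__name__)

RESPONSE_COLUMNS = [
    "patch_id",
    "generation",
    "n_years",
    "n_occupied",
    "occupancy_fraction",
    "mean_abundance",
    "cv_abundance",
    "ever_occupied",
    "log_mean",
    "log_cv",
]


def correct_false_absences(counts) -> np.ndarray:
    """Corrected occupancy indicators for one patch's surveyed chronology.

    Parameters
    ----------
    counts
        Adult counts on the patch's surveyed occasions, in chronological
        order (gaps in the design are allowed; adjacency is adjacency in
        this sequence).

    Returns
    -------
    numpy.ndarray of bool
        True where the occasion is deemed occupied. A zero count is marked
        unoccupied iff an adjacent surveyed occasion also has a zero count;
        a sole zero in a one-occasion series is unoccupied (no evidence of
        presence, ever).
    """
    c = np.asarray(counts)
    n = len(c)
    if n == 0:
        raise ValueError("empty occupancy series")
    zero = c == 0
    occupied = ~zero
    if n == 1:
        return occupied  # a single zero stays unoccupied
    left = np.zeros(n, dtype=bool)
    right = np.zeros(n, dtype=bool)
    left[1:] = zero[:-1]
    right[:-1] = zero[1:]
    # zero occasions with a zero neighbour are confirmed absences; the rest
    # are conservatively kept occupied
    occupied = np.where(zero & ~(left | right), True, occupied)
    return occupied


def _patch_generation_stats(years: np.ndarray, counts: np.ndarray,
                            occupied: np.ndarray) -> dict:
    n_years = len(years)
    n_occ = int(occupied.sum())
    mean = float(counts.mean())
    if mean > 0 and n_years >= 2:
        cv = float(counts.std(ddof=1) / mean)  # sample SD: small-n convention
    else:
        cv = np.nan
    return {
        "n_years": n_years,
        "n_occupied": n_occ,
        "occupancy_fraction": n_occ / n_years,
        "mean_abundance": mean,
        "cv_abundance": cv,
    }


def build_response_table(surveys: pd.DataFrame, patches: pd.DataFrame,
                         config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Build the response table, one row per (patch, generation).

    Occupancy fractions use the corrected indicators; a year counts as
    occupied in a generation when that generation's corrected indicator is
    true. Mean and CV of abundance use the raw counts over the surveyed
    years of the generation, zeros included. ``ever_occupied`` is true when
    any positive count was recorded in any generation; never-occupied
    patches stay in the occupancy model but are excluded from the abundance
    and CV models downstream. ``log_mean`` applies the small offset so that
    a zero mean (e.g. a patch only ever seen in the other generation)
    remains usable; the CV is log-transformed without offset and is
    undefined (NaN) when the generation mean is zero.

    Patches with zero surveyed years in a generation are excluded from that
    generation's rows (logged).
    """
    if config is None:
        config = AnalysisConfig()
    obs = surveys.loc[surveys["surveyed"]].copy()
    obs = obs.assign(_g=obs["generation"].map(GENERATION_ORDER))
    obs = obs.sort_values(["patch_id", "year", "_g"], kind="mergesort")

    rows = []
    for patch_id, grp in obs.groupby("patch_id", sort=True):
        counts = grp["count"].to_numpy()
        occupied = correct_false_absences(counts)
        ever = bool((counts > 0).any())
        for gen in ("spring", "summer"):
            sel = (grp["generation"] == gen).to_numpy()
            if not sel.any():
                logger.info("patch %s has no surveyed %s occasions; excluded "
                            "from the %s table", patch_id, gen, gen)
                continue
            stats = _patch_generation_stats(
                grp["year"].to_numpy()[sel], counts[sel], occupied[sel])
            stats.update(patch_id=patch_id, generation=gen, ever_occupied=ever)
            rows.append(stats)
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no surveyed records: cannot build response table")
    table["log_mean"] = np.log(table["mean_abundance"] + config.abundance_offset)
    with np.errstate(divide="ignore", invalid="ignore"):
        table["log_cv"] = np.log(table["cv_abundance"])
    return table[RESPONSE_COLUMNS].reset_index(drop=True)


def write_responses(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
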