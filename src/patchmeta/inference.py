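"""Information-theoretic multimodel inference.

The statistical core of the package: standardization of predictors,
binomial-logit and Gaussian maximum-likelihood fitting, enumeration of the
all-subsets candidate model space under marginality, the small-sample
Akaike information criterion (AICc), Akaike weights, confidence-set model
averaging with unconditional standard errors, and sum-of-weights variable
importance.

Term structure
--------------
Six main effects — patch area, connectivity, grazing regime (two dummies
against the reference level "never", moving as a block), host-plant
density, and mean and SD of solar irradiance — plus the four two-way
interactions of connectivity with each habitat-quality / microclimate
variable. Candidate models are all subsets of these ten terms that respect
marginality (an interaction requires both parents), 194 models in total
including the intercept-only model.

Continuous predictors are z-scored (sample SD) before interaction products
are formed, so coefficients are comparable "standardized estimates";
dummies stay on the 0/1 scale.

Model averaging follows the Burnham & Anderson conventions: models are
ranked by AICc, weights w_i = exp(-delta_i/2) normalized over the candidate
set, the confidence set is the smallest top-ranked set whose cumulative
weight reaches the requested mass, and averaged coefficients use either
zero-substitution ("full") or containing-models-only ("conditional")
averaging. Variable importance is the sum of the weights of all candidate
models containing the term.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

logger = logging.getLogger(__name__)

MAIN_TERMS = ("area", "connectivity", "grazing", "host_density",
              "irr_mean", "irr_sd")
INTERACTION_TERMS = ("connectivity:grazing", "connectivity:host_density",
                     "connectivity:irr_mean", "connectivity:irr_sd")
ALL_TERMS = MAIN_TERMS + INTERACTION_TERMS
CONTINUOUS_TERMS = ("area", "connectivity", "host_density", "irr_mean", "irr_sd")

#: design columns contributed by each term (grazing enters as a block)
TERM_COLUMNS: dict[str, tuple[str, ...]] = {
    "area": ("area",),
    "connectivity": ("connectivity",),
    "grazing": ("grazing_sometimes", "grazing_always"),
    "host_density": ("host_density",),
    "irr_mean": ("irr_mean",),
    "irr_sd": ("irr_sd",),
    "connectivity:grazing": ("connectivity:grazing_sometimes",
                             "connectivity:grazing_always"),
    "connectivity:host_density": ("connectivity:host_density",),
    "connectivity:irr_mean": ("connectivity:irr_mean",),
    "connectivity:irr_sd": ("connectivity:irr_sd",),
}

ALL_COLUMNS = ("intercept",) + tuple(
    c for t in ALL_TERMS for c in TERM_COLUMNS[t])

#: divergence of a standardized coefficient flags (quasi-)separation
SEPARATION_THRESHOLD = 15.0
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100
VARIANCE_FLOOR = 1e-12


class ZeroVarianceError(ValueError):
    pass


class RankDeficiencyError(ValueError):
    pass


def standardize(values, name: str = "x") -> tuple[np.ndarray, float, float]:
    """z-score a continuous column with the sample SD; returns (z, mean, sd)."""
    x = np.asarray(values, dtype=float)
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ZeroVarianceError(f"column {name!r} has zero variance")
    return (x - mean) / sd, float(mean), float(sd)


@dataclass
class DesignMatrix:
    """Standardized design columns plus the metadata to undo the scaling.

    ``data`` holds one column per entry of :data:`ALL_COLUMNS` (intercept
    included); interaction columns are products of the standardized
    parents. ``scalers`` maps each continuous main-effect column to its
    original (mean, sd).
    """
    data: pd.DataFrame
    scalers: dict[str, tuple[float, float]]
    patch_ids: np.ndarray

    @property
    def n(self) -> int:
        return len(self.data)

    def matrix(self, columns) -> np.ndarray:
        return self.data.loc[:, list(columns)].to_numpy(dtype=float)


def build_design(df: pd.DataFrame, log_transform_area: bool = False) -> DesignMatrix:
    """Build the standardized design from a covariate table.

    ``df`` needs columns patch_id, area, connectivity, host_density,
    irr_mean, irr_sd and grazing (three-level). Continuous mains are
    z-scored; grazing is dummy-coded against "never"; interaction columns
    are products of the standardized connectivity with each standardized
    (or dummy) partner.
    """
    out = pd.DataFrame(index=df.index)
    out["intercept"] = 1.0
    scalers: dict[str, tuple[float, float]] = {}
    raw_area = df["area"].to_numpy(dtype=float)
    if log_transform_area:
        raw_area = np.log10(raw_area)
    out["area"], m, s = standardize(raw_area, "area")
    scalers["area"] = (m, s)
    for col in ("connectivity", "host_density", "irr_mean", "irr_sd"):
        out[col], m, s = standardize(df[col], col)
        scalers[col] = (m, s)
    out["grazing_sometimes"] = (df["grazing"] == "sometimes").astype(float).to_numpy()
    out["grazing_always"] = (df["grazing"] == "always").astype(float).to_numpy()
    for partner in ("grazing_sometimes", "grazing_always", "host_density",
                    "irr_mean", "irr_sd"):
        out[f"connectivity:{partner}"] = out["connectivity"] * out[partner]
    return DesignMatrix(data=out[list(ALL_COLUMNS)],
                        scalers=scalers,
                        patch_ids=df["patch_id"].to_numpy())


def enumerate_models(mains=MAIN_TERMS, interactions=INTERACTION_TERMS) -> list[tuple[str, ...]]:
    """All term subsets respecting marginality, intercept-only included.

    An interaction named "a:b" may enter only when both parent terms are
    present. Terms within a subset keep the canonical order of
    ``mains + interactions``.
    """
    order = {t: i for i, t in enumerate(tuple(mains) + tuple(interactions))}
    models = []
    for main_subset in itertools.chain.from_iterable(
            itertools.combinations(mains, r) for r in range(len(mains) + 1)):
        present = set(main_subset)
        allowed = [ia for ia in interactions
                   if set(ia.split(":")) <= present]
        for r in range(len(allowed) + 1):
            for ia_subset in itertools.combinations(allowed, r):
                subset = tuple(sorted(main_subset + ia_subset,
                                      key=order.__getitem__))
                models.append(subset)
    return models


def columns_for_terms(terms) -> tuple[str, ...]:
    return ("intercept",) + tuple(c for t in terms for c in TERM_COLUMNS[t])


@dataclass
class ModelFit:
    """One candidate model: estimates, likelihood, AICc and weight."""
    terms: tuple[str, ...]
    columns: tuple[str, ...]
    coef: dict[str, float]
    se: dict[str, float]
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool = True
    valid: bool = True
    reason: str = ""
    delta: float = np.nan
    weight: float = np.nan


def _binomial_loglik(beta: np.ndarray, X: np.ndarray, successes: np.ndarray,
                     trials: np.ndarray) -> float:
    eta = X @ beta
    mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    const = (gammaln(trials + 1) - gammaln(successes + 1)
             - gammaln(trials - successes + 1))
    return float(np.sum(const + successes * np.log(mu)
                        + (trials - successes) * np.log1p(-mu)))


def fit_binomial(X: np.ndarray, successes, trials,
                 columns=None) -> tuple[np.ndarray, np.ndarray, float, bool, bool]:
    """Grouped binomial-logit ML fit by iteratively reweighted least squares.

    Returns (beta, se, loglik, converged, separated). The log-likelihood
    includes the binomial combinatorial constant so that likelihoods are
    comparable across models. Convergence: max |score| or relative change
    in deviance below 1e-8, capped at 100 iterations. Separation is flagged
    when any standardized coefficient diverges beyond ±15.
    """
    X = np.asarray(X, dtype=float)
    s = np.asarray(successes, dtype=float)
    t = np.asarray(trials, dtype=float)
    if np.any(s > t):
        raise ValueError("successes exceed trials")
    n, p = X.shape
    beta = np.zeros(p)
    prev_dev = np.inf
    converged = False
    for _ in range(IRLS_MAX_ITER):
        eta = X @ beta
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        w = t * mu * (1 - mu)
        score = X.T @ (s - t * mu)
        z = eta + (s - t * mu) / w
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        beta = beta_new
        eta = X @ beta
        mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        dev = -2 * (np.sum(s * np.log(mu) + (t - s) * np.log1p(-mu)))
        if (np.max(np.abs(score)) < IRLS_TOL
                or abs(prev_dev - dev) < IRLS_TOL * (abs(prev_dev) + 1)):
            converged = True
            break
        prev_dev = dev
    separated = bool(np.any(np.abs(beta) > SEPARATION_THRESHOLD))
    mu = np.clip(expit(X @ beta), 1e-10, 1 - 1e-10)
    w = t * mu * (1 - mu)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    loglik = _binomial_loglik(beta, X, s, t)
    return beta, se, loglik, converged, separated


def fit_gaussian(X: np.ndarray, y, columns=None) -> tuple[np.ndarray, np.ndarray, float]:
    """Gaussian ML fit (ordinary least squares).

    Returns (beta, se, loglik). The log-likelihood is evaluated at the ML
    variance (n denominator, floored at 1e-12 so an exact-fit toy does not
    produce an infinite likelihood); coefficient SEs use the conventional
    unbiased residual variance. Raises :class:`RankDeficiencyError` naming
    the collinear columns on a rank-deficient design.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr
        _, r, piv = qr(X, pivoting=True, mode="economic")
        keep = np.abs(np.diag(r)) > np.abs(r[0, 0]) * 1e-10
        bad = [str((columns[i] if columns is not None else i))
               for i in piv[len(keep[keep]):]]
        raise RankDeficiencyError(f"rank-deficient design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2_ml = max(rss / n, VARIANCE_FLOOR)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + rss / (n * sigma2_ml))
    if n > p:
        sigma2_u = max(rss / (n - p), VARIANCE_FLOOR)
        cov = sigma2_u * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    else:
        se = np.full(p, np.nan)
    return beta, se, loglik


def aicc(loglik: float, k: int, n: int) -> float:
    """Second-order Akaike information criterion.

    AICc = -2 logL + 2k + 2k(k+1)/(n-k-1); requires n - k - 1 > 0.
    """
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (n-k-1 <= 0)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_model(terms: tuple[str, ...], design: DesignMatrix, kind: str,
              response: np.ndarray, trials: np.ndarray | None = None) -> ModelFit:
    """Fit one candidate model of the given kind ("binomial" or "gaussian")."""
    cols = columns_for_terms(terms)
    X = design.matrix(cols)
    n = design.n
    valid, reason, converged = True, "", True
    if kind == "binomial":
        k = len(cols)
        try:
            beta, se, loglik, converged, separated = fit_binomial(
                X, response, trials, cols)
            if separated:
                valid, reason = False, "separation (diverging coefficient)"
            elif not converged:
                valid, reason = False, "IRLS did not converge"
        except (ValueError, np.linalg.LinAlgError) as exc:
            beta = np.full(len(cols), np.nan)
            se = beta.copy()
            loglik = np.nan
            valid, reason, converged = False, str(exc), False
    elif kind == "gaussian":
        k = len(cols) + 1  # error variance counts as a parameter
        try:
            beta, se, loglik = fit_gaussian(X, response, cols)
        except RankDeficiencyError as exc:
            beta = np.full(len(cols), np.nan)
            se = beta.copy()
            loglik = np.nan
            valid, reason = False, str(exc)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    if valid and n - k - 1 <= 0:
        valid, reason = False, f"n-k-1 <= 0 (n={n}, k={k})"
    value = aicc(loglik, k, n) if valid else np.inf
    if not valid:
        logger.warning("model %s excluded: %s", "+".join(terms) or "intercept",
                       reason)
    return ModelFit(terms=terms, columns=cols,
                    coef=dict(zip(cols, beta)), se=dict(zip(cols, se)),
                    loglik=loglik, k=k, n=n, aicc=value,
                    converged=converged, valid=valid, reason=reason)


def fit_all_models(design: DesignMatrix, kind: str, response,
                   trials=None, terms_list=None) -> list[ModelFit]:
    """Fit the whole candidate set and attach deltas and Akaike weights."""
    if terms_list is None:
        terms_list = enumerate_models()
    response = np.asarray(response, dtype=float)
    if trials is not None:
        trials = np.asarray(trials, dtype=float)
    fits = [fit_model(t, design, kind, response, trials) for t in terms_list]
    return akaike_weights(fits)


def akaike_weights(fits: list[ModelFit]) -> list[ModelFit]:
    """Attach delta-AICc and Akaike weights; invalid fits get weight 0."""
    valid = [f for f in fits if f.valid]
    if not valid:
        raise ValueError("no valid model fits")
    best = min(f.aicc for f in valid)
    rel = np.array([np.exp(-(f.aicc - best) / 2.0) for f in valid])
    total = rel.sum()
    for f, r in zip(valid, rel):
        f.delta = f.aicc - best
        f.weight = r / total
    for f in fits:
        if not f.valid:
            f.delta, f.weight = np.nan, 0.0
    return fits


def _sort_key(fit: ModelFit):
    return (-fit.weight, len(fit.terms), fit.terms)


def confidence_set(fits: list[ModelFit], mass: float = 0.95) -> list[ModelFit]:
    """Smallest top-ranked set whose cumulative weight reaches ``mass``.

    Models are taken in decreasing weight order (ties broken by fewer
    terms, then lexicographic term order); the model whose inclusion first
    reaches the mass is retained.
    """
    ranked = sorted([f for f in fits if f.valid], key=_sort_key)
    out, cum = [], 0.0
    for f in ranked:
        out.append(f)
        cum += f.weight
        if cum >= mass - 1e-12:
            break
    return out


@dataclass
class AveragedInference:
    """Model-averaged coefficients, unconditional SEs and term importance."""
    estimates: dict[str, float]
    unconditional_se: dict[str, float]
    importance: dict[str, float]
    mode: str
    confidence_set: list[ModelFit] = field(repr=False, default_factory=list)

    def table(self) -> pd.DataFrame:
        """Coefficient table: one row per design column, with the
        importance of the parent term repeated on its rows."""
        col_term = {c: t for t in ALL_TERMS for c in TERM_COLUMNS[t]}
        rows = []
        for col in ALL_COLUMNS:
            if col == "intercept":
                continue
            rows.append({
                "term": col,
                "estimate": self.estimates.get(col, 0.0),
                "se": self.unconditional_se.get(col, 0.0),
                "importance": self.importance.get(col_term[col], 0.0),
            })
        return pd.DataFrame(rows)


def model_average(conf_fits: list[ModelFit], mode: str = "full",
                  all_fits: list[ModelFit] | None = None) -> AveragedInference:
    """Average coefficients over a confidence set of models.

    Weights are renormalized within the set. In ``full`` mode a model that
    lacks a term contributes a zero coefficient (shrinkage); in
    ``conditional`` mode only containing models are averaged. The
    unconditional SE of a term is sum_m w_m * sqrt(se_m^2 + (b_m - avg)^2).
    Importance of a term is the sum of the (unrenormalized) weights of all
    candidate models containing it when ``all_fits`` is given, otherwise
    the sum of renormalized confidence-set weights.
    """
    if not conf_fits:
        raise ValueError("empty confidence set")
    if mode not in ("full", "conditional"):
        raise ValueError(f"unknown averaging mode {mode!r}")
    w = np.array([f.weight for f in conf_fits])
    w = w / w.sum()

    estimates: dict[str, float] = {}
    unc_se: dict[str, float] = {}
    for col in ALL_COLUMNS:
        betas = np.array([f.coef.get(col, 0.0) for f in conf_fits])
        ses = np.array([f.se.get(col, 0.0) for f in conf_fits])
        contains = np.array([col in f.coef for f in conf_fits])
        if mode == "full":
            avg = float(np.sum(w * betas))
            se = float(np.sum(w * np.sqrt(ses ** 2 + (betas - avg) ** 2)))
        else:
            if not contains.any():
                continue
            wc = w[contains] / w[contains].sum()
            avg = float(np.sum(wc * betas[contains]))
            se = float(np.sum(wc * np.sqrt(ses[contains] ** 2
                                           + (betas[contains] - avg) ** 2)))
        estimates[col] = avg
        unc_se[col] = se

    importance: dict[str, float] = {}
    if all_fits is not None:
        for term in ALL_TERMS:
            importance[term] = float(sum(
                f.weight for f in all_fits if f.valid and term in f.terms))
    else:
        for term in ALL_TERMS:
            importance[term] = float(sum(
                wi for wi, f in zip(w, conf_fits) if term in f.terms))
    importance = {t: min(max(v, 0.0), 1.0) for t, v in importance.items()}
    return AveragedInference(estimates=estimates, unconditional_se=unc_se,
                             importance=importance, mode=mode,
                             confidence_set=conf_fits)


def model_table(fits: list[ModelFit]) -> pd.DataFrame:
    """Ranked model table: terms, logL, k, AICc, delta, weight."""
    ranked = sorted([f for f in fits if f.valid], key=_sort_key)
    return pd.DataFrame({
        "terms": ["+".join(f.terms) if f.terms else "(intercept)" for f in ranked],
        "loglik": [f.loglik for f in ranked],
        "k": [f.k for f in ranked],
        "aicc": [f.aicc for f in ranked],
        "delta": [f.delta for f in ranked],
        "weight": [f.weight for f in ranked],
    })
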