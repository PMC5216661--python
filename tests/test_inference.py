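import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit, gammaln

from patchmeta import (aicc, akaike_weights, build_design, confidence_set,
                       enumerate_models, fit_all_models, fit_binomial,
                       fit_gaussian, model_average, standardize)
from patchmeta.inference import (ALL_COLUMNS, ALL_TERMS, INTERACTION_TERMS,
                                 MAIN_TERMS, ModelFit, RankDeficiencyError,
                                 ZeroVarianceError, columns_for_terms)


def _random_binomial_data(rng, n=30, p=3):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    beta = rng.normal(scale=0.8, size=p)
    trials = rng.integers(5, 13, n).astype(float)
    successes = rng.binomial(trials.astype(int), expit(X @ beta)).astype(float)
    return X, successes, trials


def _direct_binomial_mle(X, s, t):
    """Independent oracle: direct Newton-free likelihood maximization."""
    def nll(beta):
        mu = np.clip(expit(X @ beta), 1e-12, 1 - 1e-12)
        return -np.sum(s * np.log(mu) + (t - s) * np.log1p(-mu))
    res = minimize(nll, np.zeros(X.shape[1]), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    return res.x


class TestBinomialFit:
    def test_intercept_only_closed_form(self):
        """3 successes of 10 trials: the MLE intercept is logit(0.3)."""
        X = np.ones((1, 1))
        beta, _, loglik, converged, separated = fit_binomial(X, [3.0], [10.0])
        assert converged and not separated
        assert beta[0] == pytest.approx(np.log(0.3 / 0.7), abs=1e-6)
        expected_ll = (gammaln(11) - gammaln(4) - gammaln(8)
                       + 3 * np.log(0.3) + 7 * np.log(0.7))
        assert loglik == pytest.approx(expected_ll, abs=1e-8)

    def test_balanced_symmetric_design_gives_zero_slope(self):
        X = np.column_stack([np.ones(4), [-1.0, -0.5, 0.5, 1.0]])
        s = np.array([5.0, 5.0, 5.0, 5.0])
        t = np.full(4, 10.0)
        beta, *_ = fit_binomial(X, s, t)
        assert beta[1] == pytest.approx(0.0, abs=1e-8)

    def test_matches_direct_optimizer_on_random_datasets(self):
        """20 random small datasets: IRLS equals an independent direct
        likelihood optimizer to 1e-6."""
        rng = np.random.default_rng(2024)
        for _ in range(20):
            X, s, t = _random_binomial_data(rng)
            beta, *_ = fit_binomial(X, s, t)
            oracle = _direct_binomial_mle(X, s, t)
            np.testing.assert_allclose(beta, oracle, atol=1e-6)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        X, s, t = _random_binomial_data(rng, n=40, p=4)
        beta, se, loglik, *_ = fit_binomial(X, s, t)
        fit = sm.GLM(np.column_stack([s, t - s]), X,
                     family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(beta, fit.params, atol=1e-6)
        np.testing.assert_allclose(se, fit.bse, rtol=1e-4)
        assert loglik == pytest.approx(fit.llf, abs=1e-6)

    def test_separation_flagged(self):
        X = np.column_stack([np.ones(6), [-2, -1, -0.5, 0.5, 1, 2]])
        s = np.array([0.0, 0, 0, 8, 8, 8])
        t = np.full(6, 8.0)
        *_, separated = fit_binomial(X, s, t)
        assert separated


class TestGaussianFit:
    def test_exact_fit_toy(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([np.ones(4), x])
        beta, _, loglik = fit_gaussian(X, 2 * x)
        assert beta[0] == pytest.approx(0.0, abs=1e-10)
        assert beta[1] == pytest.approx(2.0, abs=1e-10)
        assert np.isfinite(loglik)      # variance floor guards the exact fit

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(12), rng.normal(size=(12, 2))])
        y = rng.normal(size=12)
        beta, se, ll = fit_gaussian(X, y)
        perm = rng.permutation(12)
        beta2, se2, ll2 = fit_gaussian(X[perm], y[perm])
        np.testing.assert_allclose(beta, beta2, atol=1e-10)
        assert ll == pytest.approx(ll2)

    def test_matches_normal_equations_five_rows(self):
        X = np.array([[1, 0.0], [1, 1.0], [1, 2.0], [1, 3.0], [1, 4.0]])
        y = np.array([1.1, 1.9, 3.2, 3.8, 5.1])
        beta, _, loglik = fit_gaussian(X, y)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(beta, oracle, atol=1e-12)
        resid = y - X @ oracle
        s2 = resid @ resid / 5
        assert loglik == pytest.approx(-2.5 * (np.log(2 * np.pi * s2) + 1))

    def test_matches_direct_optimizer_on_random_datasets(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = int(rng.integers(8, 20))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            y = X @ rng.normal(size=3) + rng.normal(size=n)
            beta, *_ = fit_gaussian(X, y)

            def nll(b):
                r = y - X @ b
                return float(r @ r)
            oracle = minimize(nll, np.zeros(3), method="BFGS",
                              options={"gtol": 1e-12}).x
            np.testing.assert_allclose(beta, oracle, atol=1e-6)

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(6), np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(RankDeficiencyError, match="collinear"):
            fit_gaussian(X, np.ones(6), columns=("intercept", "a", "b"))


class TestAicc:
    def test_closed_form(self):
        assert aicc(-5.0, 2, 10) == pytest.approx(10 + 4 + 12 / 7)

    def test_converges_to_aic_for_large_n(self):
        aic = -2 * (-5.0) + 2 * 3
        assert aicc(-5.0, 3, 10 ** 7) == pytest.approx(aic, abs=1e-5)

    def test_k_zero_correction_is_zero(self):
        assert aicc(-5.0, 0, 10) == pytest.approx(10.0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-5.0, 9, 10)


class TestEnumeration:
    def test_toy_two_mains_one_interaction(self):
        models = enumerate_models(mains=("A", "B"), interactions=("A:B",))
        assert sorted(models) == sorted(
            [(), ("A",), ("B",), ("A", "B"), ("A", "B", "A:B")])

    def test_power_set_without_interactions(self):
        models = enumerate_models(mains=("A", "B", "C"), interactions=())
        assert len(models) == 8

    def test_full_term_list_matches_bruteforce_marginality_filter(self):
        models = set(enumerate_models())
        order = {t: i for i, t in enumerate(ALL_TERMS)}
        brute = set()
        for r in range(len(ALL_TERMS) + 1):
            for subset in itertools.combinations(ALL_TERMS, r):
                ok = all(set(ia.split(":")) <= set(subset)
                         for ia in subset if ia in INTERACTION_TERMS)
                if ok:
                    brute.add(tuple(sorted(subset, key=order.__getitem__)))
        assert models == brute
        assert len(models) == 194

    def test_subset_uniqueness(self):
        models = enumerate_models()
        assert len(models) == len(set(models))


class TestStandardize:
    def test_z_score_small_example(self):
        z, mean, sd = standardize([1.0, 2.0, 3.0])
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])
        assert (mean, sd) == (2.0, 1.0)

    def test_idempotent_on_standardized_column(self):
        rng = np.random.default_rng(4)
        z, *_ = standardize(rng.normal(size=50))
        z2, *_ = standardize(z)
        np.testing.assert_allclose(z, z2, atol=1e-12)

    def test_zero_variance_names_column(self):
        with pytest.raises(ZeroVarianceError, match="flat"):
            standardize([3.0, 3.0, 3.0], name="flat")

    def test_design_dummies_and_interactions(self):
        df = pd.DataFrame({
            "patch_id": list("abcd"),
            "area": [1.0, 2.0, 3.0, 4.0], "connectivity": [0.0, 1.0, 2.0, 3.0],
            "host_density": [0.0, 5.0, 1.0, 2.0],
            "irr_mean": [1.0, 2.0, 3.0, 4.0], "irr_sd": [4.0, 3.0, 2.0, 1.0],
            "grazing": ["never", "always", "sometimes", "never"],
        })
        design = build_design(df)
        data = design.data
        assert list(data.loc[1, ["grazing_sometimes", "grazing_always"]]) == [0.0, 1.0]
        np.testing.assert_allclose(
            data["connectivity:host_density"],
            data["connectivity"] * data["host_density"], atol=1e-12)
        for col in ("area", "connectivity", "host_density"):
            assert data[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert data[col].std(ddof=1) == pytest.approx(1.0)


def _make_fit(terms, aicc_value, coef=None, se=None, n=50):
    cols = columns_for_terms(terms)
    coef = coef or {}
    se = se or {}
    return ModelFit(terms=terms, columns=cols,
                    coef={c: coef.get(c, 0.0) for c in cols},
                    se={c: se.get(c, 0.0) for c in cols},
                    loglik=0.0, k=len(cols), n=n, aicc=aicc_value)


class TestWeightsAndAveraging:
    def test_weights_for_delta_two(self):
        fits = akaike_weights([_make_fit((), 100.0), _make_fit(("area",), 102.0)])
        assert fits[0].weight == pytest.approx(0.7311, abs=1e-4)
        assert fits[1].weight == pytest.approx(0.2689, abs=1e-4)
        assert fits[0].weight + fits[1].weight == pytest.approx(1.0, abs=1e-12)

    def test_single_model_weight_one(self):
        fits = akaike_weights([_make_fit((), 10.0)])
        assert fits[0].weight == pytest.approx(1.0)

    def test_identical_aicc_equal_weights(self):
        fits = akaike_weights([_make_fit(t, 50.0) for t in
                               [(), ("area",), ("host_density",)]])
        for f in fits:
            assert f.weight == pytest.approx(1 / 3, abs=1e-12)

    def test_confidence_set_includes_crossing_model(self):
        # weights 0.6/0.3/0.06/0.04 via deltas chosen to reproduce them
        base = 100.0
        deltas = [-2 * np.log(w) for w in (0.6, 0.3, 0.06, 0.04)]
        fits = akaike_weights([
            _make_fit(t, base + d) for t, d in zip(
                [(), ("area",), ("host_density",), ("irr_mean",)], deltas)])
        kept = confidence_set(fits, 0.95)
        assert [f.terms for f in kept] == [(), ("area",), ("host_density",)]

    def test_confidence_set_mass_one_keeps_all(self):
        fits = akaike_weights([_make_fit(t, 100.0 + i) for i, t in
                               enumerate([(), ("area",), ("irr_sd",)])])
        assert len(confidence_set(fits, 1.0)) == 3

    def test_full_vs_conditional_average_and_importance(self):
        """Two models, weights 3:1, term only in the first with beta 1:
        full average 0.75, conditional 1.0, importance 0.75."""
        d = -2 * np.log(3.0)
        fits = akaike_weights([
            _make_fit(("area",), 100.0 + d, coef={"area": 1.0, "intercept": 0.0}),
            _make_fit((), 100.0)])
        conf = confidence_set(fits, 1.0)
        full = model_average(conf, "full")
        cond = model_average(conf, "conditional")
        assert full.estimates["area"] == pytest.approx(0.75, abs=1e-12)
        assert cond.estimates["area"] == pytest.approx(1.0, abs=1e-12)
        assert full.importance["area"] == pytest.approx(0.75, abs=1e-12)

    def test_constant_coefficient_is_preserved(self):
        fits = akaike_weights([
            _make_fit(("area",), 100.0, coef={"area": 0.4}),
            _make_fit(("area", "irr_mean"), 101.0, coef={"area": 0.4})])
        conf = confidence_set(fits, 1.0)
        for mode in ("full", "conditional"):
            avg = model_average(conf, mode)
            assert avg.estimates["area"] == pytest.approx(0.4, abs=1e-12)

    def test_unconditional_se_formula(self):
        d = -2 * np.log(3.0)
        fits = akaike_weights([
            _make_fit(("area",), 100.0 + d,
                      coef={"area": 1.0}, se={"area": 0.2}),
            _make_fit((), 100.0)])
        avg = model_average(confidence_set(fits, 1.0), "full")
        expected = (0.75 * np.sqrt(0.2 ** 2 + (1.0 - 0.75) ** 2)
                    + 0.25 * np.sqrt(0.0 + (0.0 - 0.75) ** 2))
        assert avg.unconditional_se["area"] == pytest.approx(expected, abs=1e-12)

    def test_full_average_shrinks_toward_zero(self):
        """|full| <= |conditional| when all containing betas share a sign."""
        rng = np.random.default_rng(8)
        fits = akaike_weights([
            _make_fit(("area",), 100 + rng.uniform(0, 3),
                      coef={"area": rng.uniform(0.2, 1.0)}),
            _make_fit(("area", "irr_sd"), 100 + rng.uniform(0, 3),
                      coef={"area": rng.uniform(0.2, 1.0)}),
            _make_fit((), 100 + rng.uniform(0, 3))])
        conf = confidence_set(fits, 1.0)
        full = model_average(conf, "full")
        cond = model_average(conf, "conditional")
        assert abs(full.estimates["area"]) <= abs(cond.estimates["area"]) + 1e-12

    def test_weights_sum_to_one_after_fit_all(self, study_dataset, config):
        from patchmeta import build_response_table, mean_connectivity
        from patchmeta.pipeline import covariate_frame
        patches, surveys = study_dataset
        table = build_response_table(surveys, patches, config)
        cm = mean_connectivity(patches, surveys, config.alpha)
        rows = table[table["generation"] == "summer"].merge(
            covariate_frame(patches, cm, "summer"), on="patch_id")
        design = build_design(rows)
        fits = fit_all_models(design, "binomial", rows["n_occupied"],
                              rows["n_years"])
        total = sum(f.weight for f in fits if f.valid)
        assert total == pytest.approx(1.0, abs=1e-12)
        conf = confidence_set(fits, 0.95)
        assert sum(f.weight for f in conf) >= 0.95 - 1e-12


class TestSmallSampleOracle:
    def test_aicc_ranking_matches_direct_ml_on_tiny_dataset(self):
        """On an 8-row dataset, the AICc ranking from the library equals the
        ranking recomputed with an independent direct likelihood optimizer."""
        rng = np.random.default_rng(17)
        n = 8
        X_full = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        trials = np.full(n, 10.0)
        successes = rng.binomial(10, expit(X_full @ [0.2, 0.8, 0.0])).astype(float)
        subsets = [(0,), (0, 1), (0, 2), (0, 1, 2)]

        def direct_rank():
            scores = []
            for cols in subsets:
                Xs = X_full[:, cols]
                beta = _direct_binomial_mle(Xs, successes, trials)
                mu = np.clip(expit(Xs @ beta), 1e-12, 1 - 1e-12)
                ll = float(np.sum(gammaln(trials + 1) - gammaln(successes + 1)
                                  - gammaln(trials - successes + 1)
                                  + successes * np.log(mu)
                                  + (trials - successes) * np.log1p(-mu)))
                k = len(cols)
                scores.append(-2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1))
            return np.argsort(scores)

        lib_scores = []
        for cols in subsets:
            Xs = X_full[:, cols]
            beta, _, ll, *_ = fit_binomial(Xs, successes, trials)
            lib_scores.append(aicc(ll, len(cols), n))
        np.testing.assert_array_equal(np.argsort(lib_scores), direct_rank())
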