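"""Regression families, specification tests, selection, marginal effects."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from atpa import component_models as cm
from atpa.component_models import ModelDesign, Term


def _count_data(rng, n, pi_logit, count_coefs, x=None):
    """ZIP-law data with a single standard-normal covariate."""
    x = rng.normal(size=n) if x is None else x
    df = pd.DataFrame({"x": x})
    pi = expit(pi_logit[0] + pi_logit[1] * x)
    lam = np.exp(count_coefs[0] + count_coefs[1] * x)
    structural = rng.random(n) < pi
    df["y"] = np.where(structural, 0, rng.poisson(lam))
    return df


DESIGN = ModelDesign("y", [Term("x")])


class TestZipFit:
    def test_loglike_closed_form_single_observation(self):
        rng = np.random.default_rng(0)
        df = _count_data(rng, 500, (-0.5, 0.3), (0.2, 0.2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = cm.fit_zip(df, DESIGN)
        # force pi = 0.5, lambda = 1 and evaluate at y = 0
        forced = fit.with_params(np.array([0.0, 0.0, 0.0, 0.0]))
        row = pd.DataFrame({"x": [0.0], "y": [0]})
        ll = forced.loglike_obs(row)[0]
        assert ll == pytest.approx(np.log(0.5 + 0.5 * np.exp(-1.0)), abs=1e-10)
        assert ll == pytest.approx(np.log(0.68394), abs=1e-5)

    def test_parameter_recovery_within_3_se(self):
        rng = np.random.default_rng(1)
        df = _count_data(rng, 20_000, (0.0, 0.0), (0.0, 0.0))  # pi=.5, lam=1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = cm.fit_zip(df, ModelDesign("y", []),
                             infl_design=ModelDesign("y", []))
        se_i = np.sqrt(fit.cov.iloc[0, 0])
        se_c = np.sqrt(fit.cov.iloc[1, 1])
        assert abs(fit.infl_params["Intercept"]) < 3 * se_i
        assert abs(fit.count_params["Intercept"]) < 3 * se_c

    def test_no_inflation_path_equals_plain_poisson(self):
        rng = np.random.default_rng(2)
        df = _count_data(rng, 3000, (-30.0, 0.0), (0.3, 0.4))
        pois = cm.fit_poisson(df, DESIGN)
        degen = cm.fit_zip(df, DESIGN, infl_design="none")
        pd.testing.assert_series_equal(pois.count_params, degen.count_params)

    def test_zip_likelihood_reduces_to_poisson_without_inflation(self):
        rng = np.random.default_rng(3)
        df = _count_data(rng, 400, (-0.3, 0.2), (0.1, 0.3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            zf = cm.fit_zip(df, DESIGN)
        pois = cm.fit_poisson(df, DESIGN)
        # push the inflation stage to pi ~ 0, copy the count stage
        vec = np.concatenate([[-40.0, 0.0], pois.count_params.to_numpy()])
        forced = zf.with_params(vec)
        np.testing.assert_allclose(
            forced.loglike_obs(df), pois.loglike_obs(df), atol=1e-10
        )

    def test_expected_count_closed_forms(self):
        rng = np.random.default_rng(4)
        df = _count_data(rng, 300, (0.0, 0.0), (0.5, 0.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = cm.fit_zip(df, ModelDesign("y", []),
                             infl_design=ModelDesign("y", []))
        row = pd.DataFrame({"x": [0.0]})
        # pi = 0.25, lambda = 2 -> 1.5
        forced = fit.with_params(np.array([np.log(0.25 / 0.75), np.log(2.0)]))
        assert cm.zip_expected_count(forced, row)[0] == pytest.approx(1.5)
        # pi -> 1 gives 0
        forced = fit.with_params(np.array([50.0, np.log(2.0)]))
        assert cm.zip_expected_count(forced, row)[0] == pytest.approx(0.0, abs=1e-12)

    def test_expected_count_matches_simulation(self):
        rng = np.random.default_rng(5)
        df = _count_data(rng, 5000, (-0.4, 0.5), (0.2, 0.3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = cm.fit_zip(df, DESIGN)
        row = pd.DataFrame({"x": [0.7]})
        expect = cm.zip_expected_count(fit, row)[0]
        pi = fit.pi(row)[0]
        lam = fit.lam(row)[0]
        n = 1_000_000
        draws = np.where(rng.random(n) < pi, 0, rng.poisson(lam, size=n))
        se = draws.std() / np.sqrt(n)
        assert abs(draws.mean() - expect) < 3 * se

    def test_expected_count_monotone_in_pi_and_lambda(self):
        rng = np.random.default_rng(6)
        df = _count_data(rng, 300, (0.0, 0.0), (0.0, 0.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = cm.fit_zip(df, ModelDesign("y", []),
                             infl_design=ModelDesign("y", []))
        row = pd.DataFrame({"x": [0.0]})
        values = [
            cm.zip_expected_count(fit.with_params(np.array([g, 0.3])), row)[0]
            for g in (-1.0, 0.0, 1.0)
        ]
        assert values[0] > values[1] > values[2]  # decreasing in pi
        values = [
            cm.zip_expected_count(fit.with_params(np.array([0.0, b])), row)[0]
            for b in (-0.5, 0.0, 0.5)
        ]
        assert values[0] < values[1] < values[2]  # increasing in lambda

    def test_all_zero_response_rejected(self):
        df = pd.DataFrame({"x": np.zeros(50), "y": np.zeros(50, dtype=int)})
        with pytest.raises(ValueError, match="zero"):
            cm.fit_zip(df, DESIGN)

    def test_json_round_trip_preserves_predictions(self):
        rng = np.random.default_rng(7)
        df = _count_data(rng, 2000, (-0.3, 0.4), (0.1, 0.3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = cm.fit_zip(df, DESIGN)
        back = cm.fit_from_json(fit.to_json(), df)
        np.testing.assert_allclose(back.expected_count(df),
                                   fit.expected_count(df), rtol=1e-12)


class TestSpecificationTests:
    def test_vuong_self_comparison_is_zero(self):
        rng = np.random.default_rng(8)
        df = _count_data(rng, 500, (-30.0, 0.0), (0.2, 0.3))
        pois = cm.fit_poisson(df, DESIGN)
        res = cm.vuong_test(pois, pois, df)
        assert res.statistic == 0.0

    def test_vuong_prefers_zip_under_heavy_inflation(self):
        rng = np.random.default_rng(9)
        df = _count_data(rng, 5000, (np.log(0.6 / 0.4), 0.0), (0.3, 0.2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            zf = cm.fit_zip(df, DESIGN)
        pois = cm.fit_poisson(df, DESIGN)
        res = cm.vuong_test(zf, pois, df)
        assert res.preferred == "zip"
        assert res.pvalue < 0.001

    def test_vuong_size_under_poisson_truth(self):
        rng = np.random.default_rng(10)
        prefer_zip = 0
        reps = 60
        for _ in range(reps):
            df = _count_data(rng, 2000, (-30.0, 0.0), (0.4, 0.3))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                zf = cm.fit_zip(df, DESIGN)
            pois = cm.fit_poisson(df, DESIGN)
            res = cm.vuong_test(zf, pois, df)
            if res.preferred == "zip" and res.pvalue < 0.05:
                prefer_zip += 1
        assert prefer_zip / reps <= 0.15  # ZIP not preferred in >=85%

    def test_lm_test_size_and_power(self):
        rng = np.random.default_rng(11)
        # size: Poisson truth, rejection rate near the nominal 5%
        rejections = 0
        reps = 80
        for _ in range(reps):
            df = _count_data(rng, 1500, (-30.0, 0.0), (0.3, 0.2))
            pois = cm.fit_poisson(df, DESIGN)
            if cm.lm_zero_inflation_test(pois, df).pvalue < 0.05:
                rejections += 1
        rate = rejections / reps
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)
        # power: strong inflation detected decisively
        df = _count_data(rng, 4000, (0.0, 0.0), (0.5, 0.2))  # pi = 0.5
        pois = cm.fit_poisson(df, DESIGN)
        res = cm.lm_zero_inflation_test(pois, df)
        assert res.pvalue < 1e-6 and res.preferred == "zip"

    def test_lm_test_all_zero_degenerate(self):
        rng = np.random.default_rng(99)
        df = _count_data(rng, 200, (-30.0, 0.0), (0.3, 0.2))
        pois = cm.fit_poisson(df, DESIGN)
        df0 = df.assign(y=0)
        with pytest.raises(ValueError):
            cm.lm_zero_inflation_test(pois, df0)


def _mnl_data(rng, n, coefs):
    """coefs: array (J-1, 2) of [intercept, slope] relative to outcome 0."""
    x = rng.normal(size=n)
    eta = np.column_stack(
        [np.zeros(n)] + [a + b * x for a, b in coefs]
    )
    p = np.exp(eta - eta.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    y = (rng.random(n)[:, None] > p.cumsum(axis=1)).sum(axis=1)
    labels = np.array(["work", "shopping", "social", "recreational",
                       "personal_family"])[y]
    return pd.DataFrame({"x": x, "purpose": labels})


MNL_DESIGN = ModelDesign("purpose", [Term("x")])


class TestPurposeMnl:
    def test_uniform_when_all_coefficients_zero(self):
        rng = np.random.default_rng(12)
        df = _mnl_data(rng, 2000, [(0, 0)] * 4)
        fit = cm.fit_purpose_mnl(df, MNL_DESIGN, base="work")
        forced = fit.with_params(np.zeros_like(fit.all_params))
        probs = cm.purpose_probabilities(forced, df.head(3))
        np.testing.assert_allclose(probs.to_numpy(), 0.2, atol=1e-12)

    def test_recovery_within_3_se(self):
        rng = np.random.default_rng(13)
        coefs = [(0.4, 0.3), (-0.2, 0.6), (0.1, -0.4), (-0.5, 0.2)]
        df = _mnl_data(rng, 20_000, coefs)
        fit = cm.fit_purpose_mnl(df, MNL_DESIGN, base="work")
        se = pd.Series(np.sqrt(np.diag(fit.cov)), index=fit.cov.index)
        order = ["personal_family", "recreational", "shopping", "social"]
        truth_by_outcome = dict(zip(["shopping", "social", "recreational",
                                     "personal_family"], coefs))
        for outcome in order:
            a, b = truth_by_outcome[outcome]
            assert abs(fit.params.loc["Intercept", outcome] - a) < \
                3 * se[f"{outcome}::Intercept"]
            assert abs(fit.params.loc["x", outcome] - b) < \
                3 * se[f"{outcome}::x"]

    def test_probabilities_sum_to_one(self, rng):
        df = _mnl_data(np.random.default_rng(14), 3000, [(0.3, 0.2)] * 4)
        fit = cm.fit_purpose_mnl(df, MNL_DESIGN, base="work")
        pts = pd.DataFrame({"x": rng.normal(size=100)})
        probs = cm.purpose_probabilities(fit, pts)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert (probs.to_numpy() >= 0).all()

    def test_agrees_with_brute_force_softmax(self):
        df = _mnl_data(np.random.default_rng(15), 3000, [(0.3, 0.2)] * 4)
        fit = cm.fit_purpose_mnl(df, MNL_DESIGN, base="work")
        pts = pd.DataFrame({"x": [0.0, 1.0, -2.0]})
        X = np.column_stack([np.ones(3), pts["x"]])
        eta = np.column_stack([np.zeros(3), X @ fit.params.to_numpy()])
        oracle = np.exp(eta) / np.exp(eta).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(
            cm.purpose_probabilities(fit, pts).to_numpy(), oracle, atol=1e-10
        )

    def test_own_index_increase_raises_probability(self):
        df = _mnl_data(np.random.default_rng(16), 2000, [(0.1, 0.1)] * 4)
        fit = cm.fit_purpose_mnl(df, MNL_DESIGN, base="work")
        pts = pd.DataFrame({"x": [0.5]})
        p0 = cm.purpose_probabilities(fit, pts)["shopping"][0]
        bumped = fit.all_params.copy()
        # bump the shopping equation's intercept (params are equation-major)
        k = fit.params.shape[0]
        offset = list(fit.params.columns).index("shopping") * k
        bumped[offset] += 0.5
        p1 = cm.purpose_probabilities(fit.with_params(bumped), pts)["shopping"][0]
        assert p1 > p0

    def test_missing_declared_outcome_rejected(self):
        df = _mnl_data(np.random.default_rng(17), 200, [(0, 0)] * 2)
        with pytest.raises(ValueError, match="personal_family"):
            cm.fit_purpose_mnl(
                df, MNL_DESIGN, base="work",
                outcomes=["work", "shopping", "social", "personal_family"],
            )


def _gee_data(rng, n_persons, beta, icc=0.4, log_sd=0.5, trips_per=3):
    sizes = rng.integers(1, trips_per + 1, n_persons)
    pid = np.repeat(np.arange(n_persons), sizes)
    x = rng.normal(size=len(pid))
    xp = rng.normal(size=n_persons)[pid]  # between-person covariate
    sb, se_ = log_sd * np.sqrt(icc), log_sd * np.sqrt(1 - icc)
    b = rng.normal(0, sb, n_persons)[pid]
    eps = rng.normal(0, se_, len(pid))
    mu = beta[0] + beta[1] * x + beta[2] * xp
    d = np.exp(mu - 0.5 * log_sd**2 + b + eps)
    return pd.DataFrame({"person_id": pid, "x": x, "xp": xp, "duration": d})


GEE_DESIGN = ModelDesign("duration", [Term("x"), Term("xp")])


class TestDurationGee:
    def test_recovery_within_3_se(self):
        rng = np.random.default_rng(18)
        beta = (2.5, 0.3, -0.2)
        df = _gee_data(rng, 4000, beta, icc=0.0)
        fit = cm.fit_duration_gee(df, GEE_DESIGN)
        se = np.sqrt(np.diag(fit.cov))
        for i, name in enumerate(["Intercept", "x", "xp"]):
            assert abs(fit.params[name] - beta[i]) < 3 * se[i]

    def test_intercept_only_recovers_sample_mean(self):
        rng = np.random.default_rng(19)
        df = _gee_data(rng, 1500, (2.8, 0.0, 0.0))
        fit = cm.fit_duration_gee(df, ModelDesign("duration", []))
        pred = fit.predict(df.head(1))[0]
        # equality holds up to the estimating-equation stopping tolerance
        assert pred == pytest.approx(df["duration"].mean(), rel=5e-3)

    def test_predictions_strictly_positive(self):
        rng = np.random.default_rng(20)
        df = _gee_data(rng, 800, (2.0, 0.5, 0.1))
        fit = cm.fit_duration_gee(df, GEE_DESIGN)
        pts = pd.DataFrame({"x": rng.normal(size=50) * 5,
                            "xp": rng.normal(size=50) * 5})
        assert (fit.predict(pts) > 0).all()

    def test_cluster_robust_se_exceeds_independence_for_between_covariate(self):
        rng = np.random.default_rng(21)
        df = _gee_data(rng, 2500, (2.5, 0.3, 0.4), icc=0.7, log_sd=0.8,
                       trips_per=5)
        fit_ex = cm.fit_duration_gee(df, GEE_DESIGN)
        shuffled = df.assign(person_id=np.arange(len(df)))  # break clusters
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_ind = cm.fit_duration_gee(shuffled, GEE_DESIGN)
        se_ex = np.sqrt(fit_ex.cov.loc["xp", "xp"])
        se_ind = np.sqrt(fit_ind.cov.loc["xp", "xp"])
        assert se_ex > se_ind

    def test_singleton_clusters_fall_back_with_warning(self):
        rng = np.random.default_rng(22)
        df = _gee_data(rng, 400, (2.5, 0.2, 0.0), trips_per=1)
        df["person_id"] = np.arange(len(df))
        with pytest.warns(UserWarning, match="independence"):
            fit = cm.fit_duration_gee(df, GEE_DESIGN)
        assert fit.working_corr == "independence"

    def test_nonpositive_duration_rejected(self):
        df = pd.DataFrame({"person_id": [0, 1], "x": [0.0, 1.0],
                           "xp": [0.0, 0.0], "duration": [5.0, 0.0]})
        with pytest.raises(ValueError, match="positive"):
            cm.fit_duration_gee(df, GEE_DESIGN)


class TestBackwardSelect:
    def _fitter(self, data, design):
        return cm.fit_poisson(data, design)

    def test_all_significant_design_unchanged(self):
        rng = np.random.default_rng(23)
        n = 4000
        df = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        df["y"] = rng.poisson(np.exp(0.2 + 0.4 * df.x1 - 0.3 * df.x2))
        design = ModelDesign("y", [Term("x1"), Term("x2")])
        out = cm.backward_select(df, design, self._fitter)
        assert out.formula == design.formula

    def test_null_covariate_removed_at_nominal_rate(self):
        rng = np.random.default_rng(24)
        removed = 0
        reps = 100
        for _ in range(reps):
            n = 800
            df = pd.DataFrame({"x1": rng.normal(size=n),
                               "x0": rng.normal(size=n)})
            df["y"] = rng.poisson(np.exp(0.1 + 0.4 * df.x1))
            design = ModelDesign("y", [Term("x1"), Term("x0")])
            out = cm.backward_select(df, design, self._fitter)
            if "x0" not in [t.expr for t in out.terms]:
                removed += 1
        # a true-null candidate is dropped with probability 1 - alpha = 0.90
        assert abs(removed / reps - 0.90) < 3 * np.sqrt(0.9 * 0.1 / reps) + 0.02

    def test_categorical_removed_as_block(self):
        rng = np.random.default_rng(25)
        n = 1500
        df = pd.DataFrame({
            "x1": rng.normal(size=n),
            "g": rng.choice(["a", "b", "c", "d"], size=n),
        })
        df["y"] = rng.poisson(np.exp(0.2 + 0.5 * df.x1))  # g is pure noise
        design = ModelDesign("y", [Term("x1"), Term(cm.cat("g", "a"))])
        out = cm.backward_select(df, design, self._fitter, alpha=0.01)
        exprs = [t.expr for t in out.terms]
        # either the whole block is gone or the whole block remains
        assert exprs in (["x1"], ["x1", cm.cat("g", "a")])

    def test_controls_never_removed(self):
        rng = np.random.default_rng(26)
        n = 500
        df = pd.DataFrame({"x0": rng.normal(size=n),
                           "ctrl": rng.normal(size=n)})
        df["y"] = rng.poisson(np.exp(0.2 + 0 * df.x0))
        design = ModelDesign("y", [Term("x0"), Term("ctrl", "control")])
        out = cm.backward_select(df, design, self._fitter, alpha=0.5)
        assert "ctrl" in [t.expr for t in out.terms]


class _LinearFit:
    """Identity-link stand-in implementing the marginal-effects protocol."""

    def __init__(self, params, cov):
        self.params = pd.Series(params)
        self.cov = pd.DataFrame(cov, index=self.params.index,
                                columns=self.params.index)

    @property
    def all_params(self):
        return self.params.to_numpy()

    def with_params(self, vec):
        return _LinearFit(pd.Series(vec, index=self.params.index), self.cov)

    def mean_response(self, data):
        return (self.params["a"] + self.params["b"]
                * data["x"].to_numpy(dtype=float))


class TestMarginalEffects:
    def test_linear_link_equals_coefficient(self):
        fit = _LinearFit({"a": 1.0, "b": 2.5},
                         np.diag([0.1, 0.04]))
        data = pd.DataFrame({"x": np.linspace(-2, 2, 20)})
        res = cm.marginal_effects(fit, data, "x")
        assert res.effect == pytest.approx(2.5, abs=1e-8)
        assert res.se == pytest.approx(0.2, abs=1e-6)  # sqrt(0.04)

    def test_zero_coefficient_gives_zero_effect(self):
        fit = _LinearFit({"a": 1.0, "b": 0.0}, np.zeros((2, 2)))
        data = pd.DataFrame({"x": np.linspace(-1, 1, 10)})
        res = cm.marginal_effects(fit, data, "x")
        assert res.effect == pytest.approx(0.0, abs=1e-10)

    def test_categorical_agrees_with_counterfactual_oracle(self):
        rng = np.random.default_rng(27)
        n = 2000
        df = pd.DataFrame({
            "g": rng.choice(["ref", "treat"], size=n),
            "x": rng.normal(size=n),
        })
        mu = np.exp(0.2 + 0.6 * (df.g == "treat") + 0.3 * df.x)
        df["y"] = rng.poisson(mu)
        design = ModelDesign("y", [Term(cm.cat("g", "ref")), Term("x")])
        fit = cm.fit_poisson(df, design)
        fixture = df.head(50)
        res = cm.marginal_effects(fit, fixture, "g", level="treat",
                                  reference="ref")
        oracle = (
            fit.expected_count(fixture.assign(g="treat"))
            - fit.expected_count(fixture.assign(g="ref"))
        ).mean()
        assert res.effect == pytest.approx(oracle, rel=1e-10)
        assert res.se > 0

    def test_reference_level_request_rejected(self):
        fit = _LinearFit({"a": 1.0, "b": 1.0}, np.eye(2))
        data = pd.DataFrame({"g": ["ref", "treat"]})
        with pytest.raises(ValueError, match="reference"):
            cm.marginal_effects(fit, data, "g", level="ref", reference="ref")

    def test_mnl_effects_are_per_outcome_and_sum_to_zero(self):
        df = _mnl_data(np.random.default_rng(28), 4000, [(0.2, 0.5)] * 4)
        fit = cm.fit_purpose_mnl(df, MNL_DESIGN, base="work")
        res = cm.marginal_effects(fit, df.head(100), "x")
        assert set(res.effect.index) == set(fit.outcomes)
        # probabilities sum to 1, so derivative effects sum to 0
        assert res.effect.sum() == pytest.approx(0.0, abs=1e-8)


class TestCoefVector:
    def test_friendly_keys_map_onto_patsy_columns(self):
        df = pd.DataFrame({
            "commute_mode": ["private_vehicle", "transit", "walk", "bike"],
            "pop_density_k": [1.0, 2.0, 3.0, 4.0],
            "purpose": ["work", "shopping", "work", "shopping"],
            "log_ttw": [3.0, 2.0, 1.0, 0.5],
            "duration": [1.0] * 4,
        })
        design = ModelDesign("duration", [
            Term(cm.cat("commute_mode", "private_vehicle")),
            Term("pop_density_k"),
            Term(f"{cm.cat('purpose', 'work')}:log_ttw"),
        ])
        X = design.matrix(df)
        vec = cm.coef_vector(list(X.columns), {
            "Intercept": 1.0,
            "commute_mode=walk": 2.0,
            "pop_density_k": 3.0,
            "purpose=shopping:log_ttw": 4.0,
        })
        named = dict(zip(X.columns, vec))
        assert named["Intercept"] == 1.0
        assert named["C(commute_mode, Treatment('private_vehicle'))[T.walk]"] == 2.0
        assert named["pop_density_k"] == 3.0
        assert named["C(purpose, Treatment('work'))[shopping]:log_ttw"] == 4.0

    def test_unmatched_key_raises(self):
        with pytest.raises(ValueError, match="nope"):
            cm.coef_vector(["Intercept", "x"], {"nope": 1.0})
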