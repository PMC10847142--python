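"""Two-stage regression, learning rates, VIFs, and the individual-level model."""

import numpy as np
import pandas as pd
import pytest

from urbanbias.datatypes import BiasObservation, City, ModelParameters
from urbanbias.inference import (
    estimate_learning_rates,
    fit_adjustments,
    fit_individual,
    fit_scaling,
    variance_decomposition,
    variance_inflation,
)
from urbanbias.synthetic import crossed_cities, generate_bias, generate_cities


@pytest.fixture(scope="module")
def noise_free_world():
    params = ModelParameters(noise_sd=0.0)
    cities = crossed_cities()
    obs = generate_bias(cities, params, seed=0, linearized=True)
    return params, cities, obs


class TestFitScaling:
    def test_exact_slope_on_noise_free_orthogonal_design(self, noise_free_world):
        params, cities, obs = noise_free_world
        sfit = fit_scaling(obs, cities)
        assert sfit.beta1 == pytest.approx(-params.delta * params.alpha, abs=1e-10)
        assert sfit.ci_beta1[0] <= sfit.beta1 <= sfit.ci_beta1[1]
        assert abs(sfit.residuals.mean()) < 1e-10

    def test_constant_bias_gives_zero_slope(self):
        cities = crossed_cities()
        obs = [BiasObservation(c.city_id, 2020, 0.5, 1000) for c in cities]
        sfit = fit_scaling(obs, cities)
        assert sfit.beta1 == pytest.approx(0.0, abs=1e-12)
        assert sfit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_respondent_cutoff_filters_cities(self, noise_free_world):
        _, cities, obs = noise_free_world
        thinned = [
            BiasObservation(o.city_id, o.year, o.b, 300 if i % 2 else 1000)
            for i, o in enumerate(obs)
        ]
        sfit = fit_scaling(thinned, cities, min_responses=500)
        assert sfit.n_cities == sum(1 for i in range(len(obs)) if i % 2)

    def test_too_few_cities_raises(self, noise_free_world):
        _, cities, obs = noise_free_world
        with pytest.raises(ValueError, match="at least 3"):
            fit_scaling(obs[:2], cities)


class TestFitAdjustments:
    def test_exact_recovery_of_diversity_coefficient(self, noise_free_world):
        params, cities, obs = noise_free_world
        sfit = fit_scaling(obs, cities)
        afit = fit_adjustments(sfit, cities)
        assert afit.beta2 == pytest.approx(-params.alpha, abs=1e-8)
        assert afit.beta3 == pytest.approx(params.alpha * params.b_bet / 2, abs=1e-8)

    def test_zero_residuals_give_zero_coefficients(self, noise_free_world):
        _, cities, obs = noise_free_world
        sfit = fit_scaling(obs, cities)
        flat = sfit.__class__(
            C=sfit.C, beta1=sfit.beta1, se_beta1=sfit.se_beta1, ci_beta1=sfit.ci_beta1,
            residuals=sfit.residuals * 0.0, r2=sfit.r2, n_cities=sfit.n_cities,
        )
        afit = fit_adjustments(flat, cities)
        assert afit.beta2 == pytest.approx(0.0, abs=1e-12)
        assert afit.beta3 == pytest.approx(0.0, abs=1e-12)

    def test_null_segregation_world_keeps_beta3_insignificant(self):
        """b_bet = 0: beta3's CI should cover 0 in >= 90% of noisy replicates."""
        from urbanbias.experiments import null_segregation_study

        df = null_segregation_study(n_replicates=60, seed=21)
        assert df.beta3_null_kept.mean() >= 0.90
        assert abs(df.beta2.mean() + 0.2) < 0.02  # beta2 still recovers -alpha

    def test_two_step_matches_joint_fit_on_orthogonal_design(self, noise_free_world):
        import statsmodels.api as sm

        params, cities, obs = noise_free_world
        sfit = fit_scaling(obs, cities)
        afit = fit_adjustments(sfit, cities)
        by_id = {c.city_id: c for c in cities}
        from urbanbias.segregation import mean_deviance

        rows = []
        for o in obs:
            c = by_id[o.city_id]
            f1 = c.group_fractions[0]
            rows.append(
                [np.log(o.b), np.log(c.total), np.log(f1 - f1**2),
                 mean_deviance(c, 0) + mean_deviance(c, 1)]
            )
        arr = np.array(rows)
        joint = sm.OLS(arr[:, 0], sm.add_constant(arr[:, 1:])).fit()
        assert afit.beta2 == pytest.approx(joint.params[2], abs=1e-8)
        assert afit.beta3 == pytest.approx(joint.params[3], abs=1e-8)


class TestLearningRates:
    def test_sign_convention_arithmetic(self, noise_free_world):
        _, cities, obs = noise_free_world
        sfit = fit_scaling(obs, cities)
        afit = fit_adjustments(sfit, cities)
        rates = estimate_learning_rates(sfit, afit, delta=1 / 6)
        assert rates.alpha_scaling == pytest.approx(-sfit.beta1 * 6, rel=1e-12)
        assert rates.alpha_diversity == pytest.approx(-afit.beta2, rel=1e-12)
        assert rates.ci_alpha_scaling[0] <= rates.ci_alpha_scaling[1]
        assert rates.ci_alpha_diversity[0] <= rates.ci_alpha_diversity[1]

    def test_worked_numbers(self, noise_free_world):
        _, cities, obs = noise_free_world
        sfit = fit_scaling(obs, cities)
        afit = fit_adjustments(sfit, cities)
        # beta1 = -1/30 with delta = 1/6 implies alpha_scaling = 0.2
        assert -sfit.beta1 / (1 / 6) == pytest.approx(0.2, abs=1e-8)


class TestVarianceInflation:
    def test_orthogonal_columns_give_unit_vifs(self):
        rng = np.random.default_rng(0)
        n = 400
        a = np.tile([1.0, -1.0], n // 2)
        b = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
        design = pd.DataFrame({"a": a, "b": b, "c": rng.normal(size=n)})
        vifs = variance_inflation(design)
        assert vifs["a"] == pytest.approx(1.0, abs=0.05)
        assert vifs["b"] == pytest.approx(1.0, abs=0.05)

    def test_duplicated_column_reports_infinity(self):
        x = np.arange(10.0)
        vifs = variance_inflation(pd.DataFrame({"x": x, "y": x * 2.0}))
        assert np.isinf(vifs["x"]) and np.isinf(vifs["y"])

    def test_matches_inverse_correlation_oracle(self):
        """VIFs equal the diagonal of the inverse correlation matrix."""
        rng = np.random.default_rng(5)
        n = 500
        z = rng.normal(size=n)
        design = pd.DataFrame(
            {
                "x1": 0.8 * z + 0.6 * rng.normal(size=n),
                "x2": 0.8 * z + 0.6 * rng.normal(size=n),
                "x3": rng.normal(size=n),
            }
        )
        vifs = variance_inflation(design)
        oracle = np.diag(np.linalg.inv(np.corrcoef(design.to_numpy().T)))
        for j, name in enumerate(design.columns):
            assert vifs[name] == pytest.approx(oracle[j], abs=1e-10)


class TestVarianceDecomposition:
    def test_fixed_composition_world_has_no_diversity_share(self):
        params = ModelParameters(noise_sd=0.05)
        # all templates share one composition -> zero variance in the regressor
        cities = crossed_cities(compositions=(0.7,), share_spreads=(0.02, 0.06, 0.10, 0.14))
        obs = generate_bias(cities, params, seed=4)
        sfit = fit_scaling(obs, cities)
        afit = fit_adjustments(sfit, cities)
        shares = variance_decomposition(sfit, afit)
        assert shares["diversity"] == pytest.approx(0.0, abs=1e-12)
        assert 0.0 <= sum(shares.values()) <= 1.0 + 1e-9

    def test_null_segregation_world_has_small_segregation_share(self):
        # crossed design keeps diversity and segregation orthogonal, so the
        # order-averaged share isolates segregation's own (null) contribution
        params = ModelParameters(b_bet=0.0, noise_sd=0.05)
        cities = crossed_cities()
        obs = generate_bias(cities, params, seed=10)
        sfit = fit_scaling(obs, cities)
        afit = fit_adjustments(sfit, cities)
        shares = variance_decomposition(sfit, afit)
        assert shares["segregation"] < 0.02
        assert shares["scaling"] > 0.0


class TestFitIndividual:
    @staticmethod
    def _world(seed: int, slope: float = -0.03, n_cities: int = 30, n_resp: int = 150):
        rng = np.random.default_rng(seed)
        ln_n = rng.uniform(np.log(1e5), np.log(1e7), n_cities)
        cov = pd.DataFrame(
            {
                "ln_N": ln_n,
                "diversity_adj": rng.uniform(-3, -1.4, n_cities),
                "seg_sum": rng.uniform(0.05, 0.5, n_cities),
            },
            index=[f"c{i}" for i in range(n_cities)],
        )
        rows = []
        for cid, r in cov.iterrows():
            logit = 0.5 + slope * (r["ln_N"] - ln_n.mean())
            p = 1 / (1 + np.exp(-logit))
            pos = rng.random(n_resp) < p
            rows.append(
                pd.DataFrame(
                    {
                        "city_id": cid,
                        "d_biep": np.where(pos, 0.5, -0.5),
                        "race_raw": rng.choice(["White", "Black", "unknown"], n_resp),
                        "edu14": rng.integers(1, 15, n_resp),
                        "birth_sex": rng.choice(["m", "f"], n_resp),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True), cov

    def test_recovers_population_slope_within_two_se(self):
        hits = 0
        for seed in range(10):
            resp, cov = self._world(seed)
            table = fit_individual(resp, cov)
            est, se = table.loc["ln_N", "coef"], table.loc["ln_N", "se"]
            hits += abs(est - (-0.03)) <= 2 * se
        assert hits >= 8

    def test_permuted_outcomes_are_mostly_insignificant(self):
        rejections = []
        for seed in range(15):
            resp, cov = self._world(seed, slope=0.0)
            rng = np.random.default_rng(100 + seed)
            resp["d_biep"] = rng.permutation(resp["d_biep"].to_numpy())
            table = fit_individual(resp, cov)
            structural = table.loc[["ln_N", "diversity_adj", "seg_sum"]]
            rejections.append((structural["p"] < 0.05).mean())
        assert np.mean(rejections) < 0.15

    def test_degenerate_outcome_is_reported_not_estimated(self):
        resp, cov = self._world(0)
        resp["d_biep"] = 1.0
        with pytest.raises(ValueError, match="separation"):
            fit_individual(resp, cov)

    def test_empty_category_dropped_with_warning(self, caplog):
        import logging

        resp, cov = self._world(1)
        resp["edu14"] = 7  # nobody below the some-college band
        with caplog.at_level(logging.WARNING, logger="urbanbias.inference"):
            table = fit_individual(resp, cov)
        assert "HS-or-below" in " ".join(r.message for r in caplog.records)
        assert not any("HS-or-below" in ix for ix in table.index)
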