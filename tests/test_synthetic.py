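"""Synthetic generators: determinism, conservation, forward-model fidelity."""

import logging
import math

import numpy as np
import pytest

from urbanbias.datatypes import BiasObservation, City, ModelParameters
from urbanbias.segregation import dissimilarity, mean_deviance
from urbanbias.synthetic import (
    Coupling,
    crossed_cities,
    generate_bias,
    generate_cities,
    generate_individuals,
    generate_panel,
    generate_respondents,
)

SMALL = dict(pop_range=(8e3, 6e4), tract_size=4000)


class TestGenerateCities:
    def test_deterministic_given_seed(self, params):
        a = generate_cities(params, 20, seed=7, **SMALL)
        b = generate_cities(params, 20, seed=7, **SMALL)
        for ca, cb in zip(a, b):
            assert ca.city_id == cb.city_id
            assert np.array_equal(ca.tract_counts, cb.tract_counts)

    def test_counts_conserved_exactly(self, params):
        for city in generate_cities(params, 30, seed=3, **SMALL):
            assert city.tract_counts.sum() == city.total
            assert city.group_totals.sum() == city.total
            assert np.all(city.tract_counts.sum(axis=1) == city.tract_totals)

    def test_zero_seg_level_gives_even_cities(self, params):
        cities = generate_cities(params, 10, seg_level_range=(0.0, 0.0), seed=1, **SMALL)
        for city in cities:
            assert mean_deviance(city, 0) < 0.02  # integer rounding only
            assert dissimilarity(city, 0) < 0.02

    def test_extreme_seg_level_approaches_complete_segregation(self, params):
        cities = generate_cities(
            params, 10, pop_range=(4e4, 6e4), tract_size=4000,
            seg_level_range=(0.97, 0.98), majority_frac_range=(0.5, 0.6), seed=1,
        )
        mixed = [c for c in cities if 0 < c.group_totals[0] < c.total]
        assert len(mixed) >= 8
        assert np.mean([dissimilarity(c, 0) for c in mixed]) > 0.9

    def test_mean_dissimilarity_increases_with_seg_level(self, params):
        means = []
        for level in (0.05, 0.2, 0.5):
            cities = generate_cities(
                params, 50, seg_level_range=(level, level), seed=11, **SMALL
            )
            mixed = [c for c in cities if 0 < c.group_totals[0] < c.total]
            means.append(np.mean([dissimilarity(c, 0) for c in mixed]))
        assert means[0] < means[1] < means[2]

    def test_degenerate_and_invalid_requests(self, params):
        assert generate_cities(params, 0, seed=0) == []
        with pytest.raises(ValueError, match="pop_range"):
            generate_cities(params, 2, pop_range=(1e3, 1e4), tract_size=4000, seed=0)
        with pytest.raises(ValueError, match="seg_level_range"):
            generate_cities(params, 2, seg_level_range=(0.5, 1.2), seed=0, **SMALL)


class TestGenerateBias:
    def test_alpha_zero_gives_prefactor_everywhere(self):
        p = ModelParameters(alpha=0.0, noise_sd=0.0, prefactor=0.4)
        cities = generate_cities(p, 10, seed=2, **SMALL)
        for obs in generate_bias(cities, p, seed=0):
            assert obs.b == pytest.approx(0.4)

    def test_population_doubling_scales_bias(self):
        p = ModelParameters(noise_sd=0.0, h_bet0=0.0, b_bet=0.0)
        base = City("a", np.array([[300, 200], [300, 200]]))
        double = City("b", np.array([[600, 400], [600, 400]]))
        b1, b2 = generate_bias([base, double], p, seed=0)
        assert b2.b / b1.b == pytest.approx(2 ** (-p.delta * p.alpha), rel=1e-12)

    def test_direct_formula_evaluation(self):
        p = ModelParameters(delta=1 / 6, alpha=0.2, h_bet0=0.0, b_bet=0.0,
                            prefactor=2.0, noise_sd=0.0)
        city = City("m", np.array([[250_000, 250_000], [250_000, 250_000]]))
        (obs,) = generate_bias([city], p, seed=0)
        expected = (math.log(2.0) - (1 / 30) * math.log(1e6)
                    - 0.2 * math.log(0.25) - 0.2 * math.log(2))
        assert math.log(obs.b) == pytest.approx(expected, abs=1e-12)

    def test_single_group_city_excluded_with_warning(self, caplog):
        p = ModelParameters(noise_sd=0.0)
        good = City("ok", np.array([[60, 40], [60, 40]]))
        solo = City("solo", np.array([[100, 0], [100, 0]]))
        with caplog.at_level(logging.WARNING, logger="urbanbias.synthetic"):
            obs = generate_bias([good, solo], p, seed=0)
        assert [o.city_id for o in obs] == ["ok"]
        assert any("solo" in rec.message for rec in caplog.records)


class TestGenerateIndividuals:
    def test_zero_individual_sd_copies_the_city_mean(self):
        p = ModelParameters(individual_sd=0.0)
        obs = BiasObservation("c", 2020, 0.42, 50)
        df = generate_individuals(obs, p, seed=0)
        assert (df["d_biep"] == 0.42).all()
        assert len(df) == 50

    def test_sample_mean_converges(self):
        p = ModelParameters(individual_sd=0.4)
        obs = BiasObservation("c", 2020, 0.42, 10_000)
        df = generate_individuals(obs, p, seed=1)
        assert abs(df["d_biep"].mean() - 0.42) < 3 * 0.4 / 100

    def test_deterministic_given_seed(self, params):
        obs = BiasObservation("c", 2020, 0.42, 200)
        a = generate_individuals(obs, params, seed=5)
        b = generate_individuals(obs, params, seed=5)
        assert a.equals(b)

    def test_respondent_table_covers_all_cities(self, params):
        observations = [BiasObservation(f"c{i}", 2020, 0.5, 10) for i in range(4)]
        df = generate_respondents(observations, params, seed=2)
        assert sorted(df["city_id"].unique()) == [f"c{i}" for i in range(4)]
        assert len(df) == 40


class TestGeneratePanel:
    def test_panel_shapes_match_the_ten_year_design(self):
        panels = generate_panel(43, 10, Coupling("none"), seed=0)
        assert len(panels) == 43
        assert all(p.series.shape == (10, 4) for p in panels)
        assert all(list(p.series.columns) == ["ln_N", "diversity_adj", "seg_sum", "ln_b"]
                   for p in panels)

    def test_deterministic_given_seed(self):
        a = generate_panel(5, 10, Coupling("structural->bias", 1, 0.5), seed=3)
        b = generate_panel(5, 10, Coupling("structural->bias", 1, 0.5), seed=3)
        for pa, pb in zip(a, b):
            assert pa.series.equals(pb.series)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            generate_panel(5, 7, Coupling("structural->bias", lag=3), seed=0)


class TestEndToEndRecovery:
    def test_noise_free_pipeline_recovers_alpha_exactly(self):
        """Crossed design + noise-free linearized bias -> alpha to 1e-6."""
        from urbanbias.inference import estimate_learning_rates, fit_adjustments, fit_scaling

        p = ModelParameters(noise_sd=0.0)
        cities = crossed_cities()
        obs = generate_bias(cities, p, seed=0, linearized=True)
        sfit = fit_scaling(obs, cities)
        afit = fit_adjustments(sfit, cities)
        rates = estimate_learning_rates(sfit, afit, delta=p.delta)
        assert rates.alpha_scaling == pytest.approx(p.alpha, abs=1e-6)
        assert rates.alpha_diversity == pytest.approx(p.alpha, abs=1e-6)
        assert sfit.beta1 == pytest.approx(-p.delta * p.alpha, abs=1e-10)
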