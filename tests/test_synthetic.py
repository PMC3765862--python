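"""Synthetic input generators, the pinned fixture, and calibration."""

import numpy as np
import pandas as pd
import pytest

import physupply as pp
from physupply.errors import InvalidParameterError


class TestCensus:
    def test_totals_exact(self):
        config = pp.SyntheticConfig(seed=3, base_total=200_000.0, obgyn_share=0.05)
        census = pp.generate_workforce_census(config)
        assert census["headcount"].sum() == pytest.approx(200_000.0)
        obgyn = census[census["speciality"] == "obgyn"]["headcount"].sum()
        assert obgyn == pytest.approx(10_000.0)

    def test_same_seed_identical_tables(self):
        a = pp.generate_workforce_census(pp.SyntheticConfig(seed=7))
        b = pp.generate_workforce_census(pp.SyntheticConfig(seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = pp.generate_workforce_census(pp.SyntheticConfig(seed=1))
        b = pp.generate_workforce_census(pp.SyntheticConfig(seed=2))
        assert not np.allclose(a["headcount"], b["headcount"])

    def test_zero_obgyn_share(self):
        config = pp.SyntheticConfig(seed=0, obgyn_share=0.0)
        census = pp.generate_workforce_census(config)
        assert census[census["speciality"] == "obgyn"]["headcount"].sum() == 0.0

    def test_fixture_census_matches_published_base_year(self, fx):
        census = pp.generate_workforce_census(pp.fixture_config())
        assert census["headcount"].sum() == pytest.approx(fx.base_total)
        obgyn = census[census["speciality"] == "obgyn"]["headcount"].sum()
        assert obgyn == pytest.approx(fx.base_obgyn)


class TestRequiredSurvey:
    def test_self_consistent_criterion_gives_unit_sufficiency(self):
        config = pp.SyntheticConfig(seed=0, required_ratio=1.0)
        census = pp.generate_workforce_census(config)
        survey, coefficient = pp.generate_required_survey(config, census)
        required_total = survey["required_hospital_number"].sum()
        level = pp.sufficiency_level(
            config.base_total,
            pp.SufficiencyCriterion(required_total, coefficient))
        assert level == pytest.approx(1.0, rel=1e-9)

    def test_coefficient_from_hospital_share(self):
        config = pp.SyntheticConfig(seed=0, hospital_share=0.60)
        census = pp.generate_workforce_census(config)
        _, coefficient = pp.generate_required_survey(config, census)
        assert coefficient == pytest.approx(1.0 / 0.60, rel=1e-9)

    def test_required_ratio_scales_base_sufficiency(self):
        config = pp.SyntheticConfig(seed=0, required_ratio=1.1)
        census = pp.generate_workforce_census(config)
        survey, coefficient = pp.generate_required_survey(config, census)
        level = pp.sufficiency_level(
            config.base_total,
            pp.SufficiencyCriterion(survey["required_hospital_number"].sum(), coefficient))
        assert level == pytest.approx(1.0 / 1.1, rel=1e-9)

    def test_empty_census_rejected(self):
        with pytest.raises(InvalidParameterError):
            pp.generate_required_survey(pp.SyntheticConfig(), pd.DataFrame(columns=["a"]))


class TestPopulation:
    def test_constant_when_change_zero(self):
        config = pp.SyntheticConfig(population_annual_change=0.0)
        series = pp.generate_population_projection(config)
        assert series.nunique() == 1

    def test_geometric_closed_form(self):
        config = pp.SyntheticConfig(population_start=123.0e6,
                                    population_annual_change=-0.0025)
        series = pp.generate_population_projection(config)
        assert series.loc[2030] == pytest.approx(123.0e6 * 0.9975 ** 22, rel=1e-12)
        assert series.loc[2030] == pytest.approx(116.41e6, rel=1e-4)

    def test_fixture_population_reproduces_published_per_capita(self, fx):
        population = pp.fixture_population()
        value = pp.per_capita(fx.forecast_total_2030, population.loc[2030])
        assert round(value, 2) == fx.per_capita_2030


class TestFixture:
    def test_pinned_constants(self, fx):
        assert fx.base_total == 271_897.0
        assert fx.base_obgyn == 10_388.0
        assert fx.historic[2008] == 286.70
        assert fx.forecast_total_2030 == 370_345.0

    def test_quota_anchors(self):
        quota = pp.fixture_quota_series()
        assert quota[1984] == pytest.approx(8_280.0)
        assert quota[2007] == pytest.approx(7_625.0)
        assert min(quota) <= 1990 and max(quota) >= 2030

    def test_fixture_parameter_set_covers_clock(self):
        pp.fixture_parameter_set().check_coverage(pp.fixture_clock())
        pp.fixture_backcast_params().check_coverage(pp.fixture_backcast_clock())

    def test_self_consistency_of_generated_inputs(self):
        """A generated census run with its generating parameters follows the
        implied single-hazard recursion to high precision."""
        config = pp.SyntheticConfig(seed=11, base_year=2008, horizon_year=2020)
        params = pp.default_parameter_set(config)
        totals = pp.clinical_totals(pp.project(params, pp.SimulationClock(2008, 2020)))
        expected = config.base_total
        lag = config.school_duration + config.training_duration
        for year in range(2008, 2021):
            assert totals.loc[year] == pytest.approx(expected, rel=1e-6)
            inflow = params.quota(year - lag) * config.pass_rate
            expected = expected * (1 - config.retirement_rate) + inflow


class TestCalibration:
    def test_perfect_fit_recovers_zero_rmse(self):
        params = pp.fixture_backcast_params().replace(retirement_rates=0.0125)
        clock = pp.fixture_backcast_clock()
        historic = pp.clinical_totals(pp.project(params, clock))
        result = pp.calibrate(params, clock, historic,
                              {"retirement_rate": (0.001, 0.05)})
        assert result.rmse < 1e-6
        assert result.fitted["retirement_rate"] == pytest.approx(0.0125, abs=1e-4)

    def test_parameter_recovery_known_rate(self):
        rng = np.random.default_rng(42)
        for _ in range(3):
            true_rate = float(rng.uniform(0.005, 0.04))
            params = pp.fixture_backcast_params().replace(retirement_rates=true_rate)
            clock = pp.fixture_backcast_clock()
            historic = pp.clinical_totals(pp.project(params, clock))
            result = pp.calibrate(params.replace(retirement_rates=0.02), clock,
                                  historic.iloc[::2],
                                  {"retirement_rate": (0.001, 0.05)})
            assert result.fitted["retirement_rate"] == pytest.approx(true_rate, abs=1e-3)

    def test_two_parameter_coordinate_descent(self):
        clock = pp.fixture_backcast_clock()
        truth = pp.fixture_backcast_params().replace(retirement_rates=0.018)
        historic = pp.clinical_totals(pp.project(truth, clock))
        start = truth.replace(retirement_rates=0.01)
        result = pp.calibrate(
            start, clock, historic,
            {"retirement_rate": (0.001, 0.05),
             "initial_total": (200_000.0, 300_000.0)})
        assert result.rmse < 1e-4
        assert result.fitted["retirement_rate"] == pytest.approx(0.018, abs=5e-4)

    def test_too_short_series_rejected(self):
        with pytest.raises(InvalidParameterError):
            pp.calibrate(pp.fixture_backcast_params(), pp.fixture_backcast_clock(),
                         pd.Series({1998: 1.0, 2000: 2.0}),
                         {"retirement_rate": (0.001, 0.05)})

    def test_unknown_free_parameter_rejected(self):
        with pytest.raises(pp.ConfigurationError):
            pp.calibrate(pp.fixture_backcast_params(), pp.fixture_backcast_clock(),
                         pp.japan_fixture().historic_persons,
                         {"quota_magic": (0.0, 1.0)})

    def test_fixture_calibration_quality(self, calibration):
        """Refit hazard reproduces the historic series closely and sits near
        the frozen fixture value."""
        assert calibration.converged
        assert calibration.rmse <= 0.005
        assert calibration.fitted["retirement_rate"] == pytest.approx(0.0125, abs=5e-4)
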