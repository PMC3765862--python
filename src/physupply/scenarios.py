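"""Scenario construction and sensitivity sweeps over the career pipeline.

Two policy levers are perturbed: the medical-school enrolment quota (a
multiplicative change, e.g. +/-15 %) and the fraction of new clinicians
choosing a focal speciality such as OB/GYN (an additive change in percentage
points by default, or a relative change when ``choice_delta_mode`` is
"relative").  When the focal fraction moves, the remaining specialities are
rescaled proportionally so that the fractions still sum to one.

Quota changes propagate with the full school-plus-training delay; speciality
choice acts on every cohort entering practice from the start year onwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import pandas as pd

from .engine import SimulationClock, Trajectory
from .errors import InvalidParameterError, InvalidScenarioError
from .pipeline import ParameterSet, clinical_totals, project, speciality_totals
from .sufficiency import SufficiencyCriterion, SufficiencySeries, crossing_year

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class Scenario:
    """A named perturbation of the baseline parameters.

    ``choice_delta`` moves the selection fraction of ``choice_speciality``:
    in "points" mode a value of +1 means one percentage point (0.04 -> 0.05),
    in "relative" mode it means a relative change of 1 % (0.04 -> 0.0404).
    """

    name: str
    quota_multiplier: float = 1.0
    choice_delta: float = 0.0
    choice_speciality: str = "obgyn"
    choice_delta_mode: str = "points"
    start_year: int | None = None

    def __post_init__(self):
        if self.quota_multiplier < 0:
            raise InvalidScenarioError("quota multiplier must be non-negative")
        if self.choice_delta_mode not in ("points", "relative"):
            raise InvalidScenarioError(
                f"unknown choice_delta_mode {self.choice_delta_mode!r}"
            )

    @property
    def is_identity(self) -> bool:
        return self.quota_multiplier == 1.0 and self.choice_delta == 0.0


def apply_scenario(params: ParameterSet, scenario: Scenario,
                   base_year: int | None = None) -> ParameterSet:
    """Return a new parameter set with the scenario applied; the input is untouched.

    The quota is scaled from ``scenario.start_year`` (default: the base year)
    onwards.  The focal selection fraction is shifted and the remaining
    fractions rescaled proportionally to restore a unit sum.
    """
    start = scenario.start_year
    if start is None:
        start = base_year
    if start is None:
        raise InvalidScenarioError(
            f"scenario {scenario.name!r} has no start year and no base year was given"
        )

    quota = {
        year: value * scenario.quota_multiplier if year >= start else value
        for year, value in params.quota_series.items()
    }

    fractions = dict(params.selection_fractions)
    if scenario.choice_delta != 0.0:
        focal = scenario.choice_speciality
        if focal not in fractions:
            raise InvalidScenarioError(
                f"scenario {scenario.name!r} perturbs unknown speciality {focal!r}"
            )
        old = fractions[focal]
        if scenario.choice_delta_mode == "points":
            new = old + scenario.choice_delta / 100.0
        else:
            new = old * (1.0 + scenario.choice_delta / 100.0)
        if not 0.0 <= new <= 1.0:
            raise InvalidScenarioError(
                f"scenario {scenario.name!r} drives fraction of {focal!r} to {new:.4f}"
            )
        rest = 1.0 - old
        if rest > _FRACTION_TOL:
            scale = (1.0 - new) / rest
            for spec in fractions:
                if spec != focal:
                    fractions[spec] *= scale
        elif abs(new - 1.0) > _FRACTION_TOL:
            raise InvalidScenarioError(
                f"scenario {scenario.name!r}: no other speciality can absorb the shift"
            )
        fractions[focal] = new

    return params.replace(quota_series=quota, selection_fractions=fractions)


@dataclass
class SensitivityResult:
    """Outcome of one scenario run for one or more groups."""

    scenario: Scenario
    sufficiency: dict[str, SufficiencySeries]
    forecasts: dict[str, pd.Series]
    crossing_years: dict[str, int | None] = field(default_factory=dict)
    impacts: dict[str, float] = field(default_factory=dict)

    @property
    def name(self) -> str:
        return self.scenario.name


#: Group name for the all-clinicians aggregate in sensitivity results.
ALL_CLINICIANS = "all"


def run_sensitivity(
    base_params: ParameterSet,
    scenarios: list[Scenario],
    clock: SimulationClock,
    criteria: Mapping[str, SufficiencyCriterion],
    baseline_name: str = "baseline",
    builder: Callable[[ParameterSet, SimulationClock], Trajectory] = project,
) -> list[SensitivityResult]:
    """Run every scenario on an identical clock and criteria set.

    ``criteria`` maps group names to criteria; the special group ``"all"``
    evaluates the all-clinicians total, any other name a speciality stock.
    The scenario list must contain the baseline (identified by name), against
    whose horizon-year sufficiency the impact metric is measured.
    """
    if not scenarios:
        raise InvalidParameterError("at least one scenario is required")
    names = [s.name for s in scenarios]
    if baseline_name not in names:
        raise InvalidParameterError(f"baseline scenario {baseline_name!r} missing")
    if len(set(names)) != len(names):
        raise InvalidParameterError("scenario names must be unique")

    results: list[SensitivityResult] = []
    for scenario in scenarios:
        try:
            params = apply_scenario(base_params, scenario, base_year=clock.base_year)
            trajectory = builder(params, clock)
        except Exception as exc:
            raise type(exc)(f"scenario {scenario.name!r}: {exc}") from exc
        sufficiency: dict[str, SufficiencySeries] = {}
        forecasts: dict[str, pd.Series] = {}
        for group, criterion in criteria.items():
            series = (clinical_totals(trajectory) if group == ALL_CLINICIANS
                      else speciality_totals(trajectory, group))
            forecasts[group] = series
            sufficiency[group] = SufficiencySeries.from_forecast(series, criterion)
        result = SensitivityResult(scenario, sufficiency, forecasts)
        result.crossing_years = {
            group: crossing_year(series) for group, series in sufficiency.items()
        }
        results.append(result)

    baseline = next(r for r in results if r.name == baseline_name)
    horizon = int(clock.horizon_year)
    for result in results:
        for group, series in result.sufficiency.items():
            base_level = baseline.sufficiency[group].levels.loc[horizon]
            result.impacts[group] = float(series.levels.loc[horizon] - base_level)
    return results


def rank_impacts(results: list[SensitivityResult], group: str) -> list[tuple[str, float]]:
    """Scenarios ordered by |horizon-year impact| on a group, ties broken by name."""
    horizons = {tuple(r.sufficiency[group].levels.index[[0, -1]]) for r in results}
    if len(horizons) > 1:
        raise InvalidParameterError("results span different horizons")
    pairs = [(r.name, r.impacts[group]) for r in results]
    return sorted(pairs, key=lambda p: (-abs(p[1]), p[0]))


def results_frame(results: list[SensitivityResult]) -> pd.DataFrame:
    """Tidy sensitivity output: scenario, group, year, level, crossing, impact."""
    rows = []
    for result in results:
        for group, series in result.sufficiency.items():
            for _, rec in series.frame.iterrows():
                rows.append({
                    "scenario": result.name,
                    "group": group,
                    "year": int(rec["year"]),
                    "sufficiency": rec["level"],
                    "classification": rec["classification"],
                    "crossing_year": result.crossing_years[group],
                    "impact": result.impacts.get(group),
                })
    return pd.DataFrame(rows)
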