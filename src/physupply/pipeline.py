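"""The Japanese physician career pipeline as a stock-and-flow model.

Six sectors are wired on top of the engine: enrolment (the medical-school
quota), the national licensing examination, postgraduate clinical training,
entry into clinical practice, choice of speciality, and retirement.

Structural assumptions, all exposed as parameters:

* every enrolled student graduates (graduates = quota, domestic students
  only), after ``school_duration`` years (default 6);
* a constant ``pass_rate`` fraction of each graduating cohort passes the
  licensing examination; failures either leave the system (one-shot default)
  or enter a retake pool and re-sit with the same pass rate each year;
* passers complete a ``training_duration``-year training stage (default 2),
  then choose a speciality according to constant ``selection_fractions`` and
  enter the corresponding clinical-practice stock;
* each practice stock loses a constant per-capita fraction per year to
  retirement (an aggregate hazard that also absorbs deaths and mid-career
  speciality changes).

Headcounts are real-valued throughout, matching the continuous
system-dynamics formalism; nothing is rounded to whole persons.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .engine import (
    EXTERNAL,
    DelayChain,
    Flow,
    SimulationClock,
    Stock,
    StockFlowModel,
    Trajectory,
    run_simulation,
)
from .errors import ConfigurationError, InvalidParameterError

_FRACTION_TOL = 1e-9


@dataclass
class ParameterSet:
    """All exogenous rates and series driving the career pipeline.

    ``retirement_rates`` may be a single float (applied to every speciality)
    or a per-speciality mapping.  ``initial_stocks`` holds base-year
    clinical-practice headcounts by speciality.
    """

    quota_series: dict[int, float]
    pass_rate: float
    selection_fractions: dict[str, float]
    retirement_rates: float | dict[str, float]
    initial_stocks: dict[str, float]
    career_option_rate: float = 1.0
    school_duration: int = 6
    training_duration: int = 2
    exam_retake: bool = False
    max_exam_attempts: int | None = None

    def __post_init__(self):
        self.quota_series = {int(y): float(q) for y, q in dict(self.quota_series).items()}
        if any(q < 0 for q in self.quota_series.values()):
            raise InvalidParameterError("quota values must be non-negative")
        for name, value in [("pass_rate", self.pass_rate),
                            ("career_option_rate", self.career_option_rate)]:
            if not 0 <= value <= 1:
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {value}")
        total = sum(self.selection_fractions.values())
        if abs(total - 1.0) > _FRACTION_TOL:
            raise ConfigurationError(
                f"selection fractions must sum to 1, got {total!r}"
            )
        if any(not 0 <= f <= 1 for f in self.selection_fractions.values()):
            raise InvalidParameterError("selection fractions must lie in [0, 1]")
        for rate in self._rates_dict().values():
            if not 0 <= rate <= 1:
                raise InvalidParameterError(f"retirement rate {rate} outside [0, 1]")
        if self.school_duration < 1 or self.training_duration < 1:
            raise InvalidParameterError("stage durations must be at least one year")
        unknown = set(self.initial_stocks) - set(self.selection_fractions)
        if unknown:
            raise ConfigurationError(
                f"initial stocks for undeclared specialities: {sorted(unknown)}"
            )

    def _rates_dict(self) -> dict[str, float]:
        if isinstance(self.retirement_rates, Mapping):
            return dict(self.retirement_rates)
        return {s: float(self.retirement_rates) for s in self.selection_fractions}

    @property
    def specialities(self) -> list[str]:
        return sorted(self.selection_fractions)

    @property
    def pipeline_lag(self) -> int:
        """Years between enrolment and entry into clinical practice."""
        return self.school_duration + self.training_duration

    def quota(self, year: int) -> float:
        try:
            return self.quota_series[int(year)]
        except KeyError:
            raise ConfigurationError(
                f"quota series does not cover year {int(year)}"
            ) from None

    def retirement_rate(self, speciality: str) -> float:
        rates = self._rates_dict()
        try:
            return rates[speciality]
        except KeyError:
            raise ConfigurationError(
                f"no retirement rate for speciality {speciality!r}"
            ) from None

    def check_coverage(self, clock: SimulationClock) -> None:
        """Verify the quota series covers every year any rate rule will read."""
        first = int(clock.base_year) - self.pipeline_lag
        last = int(clock.horizon_year) - 1
        missing = [y for y in range(first, last + 1) if y not in self.quota_series]
        if missing:
            raise ConfigurationError(
                "quota series is missing years required by the simulation: "
                + ", ".join(str(y) for y in missing)
            )

    def replace(self, **changes) -> "ParameterSet":
        """Return a deep-ish copy with the given fields replaced."""
        copied = {
            "quota_series": dict(self.quota_series),
            "selection_fractions": dict(self.selection_fractions),
            "initial_stocks": dict(self.initial_stocks),
            "retirement_rates": (dict(self.retirement_rates)
                                 if isinstance(self.retirement_rates, Mapping)
                                 else self.retirement_rates),
        }
        copied.update(changes)
        return dataclasses.replace(self, **copied)


def graduates(year: int, params: ParameterSet) -> float:
    """Graduating cohort of a given year: the quota enrolled school_duration years earlier."""
    return params.quota(year - params.school_duration)


def exam_passes(n_graduates: float, pass_rate: float) -> float:
    """Headcount passing the national licensing examination."""
    if not 0 <= pass_rate <= 1:
        raise InvalidParameterError(f"pass_rate must lie in [0, 1], got {pass_rate}")
    if n_graduates < 0:
        raise InvalidParameterError("graduate count must be non-negative")
    return n_graduates * pass_rate

def allocate_speciality(new_clinicians: float,
                        selection_fractions: Mapping[str, float]) -> dict[str, float]:
    """Split a cohort entering practice across specialities; totals are conserved exactly."""
    total = sum(selection_fractions.values())
    if abs(total - 1.0) > _FRACTION_TOL:
        raise ConfigurationError(f"selection fractions must sum to 1, got {total!r}")
    if new_clinicians < 0:
        raise InvalidParameterError("cohort size must be non-negative")
    return {s: new_clinicians * f for s, f in selection_fractions.items()}


def retirement_outflow(stock: float, rate: float) -> float:
    """Annual retirement (incl. death and speciality movement) from a practice stock."""
    if not 0 <= rate <= 1:
        raise InvalidParameterError(f"retirement rate must lie in [0, 1], got {rate}")
    if stock < 0:
        raise InvalidParameterError("stock must be non-negative")
    return stock * rate


def practice_stock_name(speciality: str) -> str:
    return f"practice_{speciality}"


def build_career_model(params: ParameterSet, clock: SimulationClock) -> StockFlowModel:
    """Wire the six-sector career-path model for a given parameter set.

    The same builder serves both the all-clinicians configuration (a single
    speciality) and the per-speciality configuration used for the OB/GYN
    analysis: practice stocks are created per speciality and the all-clinician
    total is their sum.

    Delay chains are back-filled from the historical quota series so the first
    ``pipeline_lag`` simulated years see the true cohorts already in school or
    training at the base year, not an empty ramp-up.
    """
    params.check_coverage(clock)
    base = int(clock.base_year)
    model = StockFlowModel()

    school_cohorts = [params.quota(y)
                      for y in range(base - params.school_duration, base)]
    school = DelayChain(
        name="school",
        duration=params.school_duration,
        cohorts=school_cohorts,
        entrants_rule=lambda t, state, p: p.quota(int(t)),
        tags={"stage": "school"},
    )
    model.add_chain(school)

    def _passed_cohort(p: ParameterSet, enrol_year: int) -> float:
        return exam_passes(p.quota(enrol_year), p.pass_rate) * p.career_option_rate

    training_cohorts = [
        _passed_cohort(params, y - params.school_duration)
        for y in range(base - params.training_duration, base)
    ]

    if not params.exam_retake:
        def training_entrants(t, state, p):
            return exam_passes(state.exits["school"], p.pass_rate) * p.career_option_rate
    else:
        # Failures wait in retake pools and re-sit yearly with the same pass
        # rate.  Bounded attempts use one pool per attempt already used;
        # unlimited retakes collapse to a single self-draining pool.
        n_pools = (1 if params.max_exam_attempts is None
                   else max(params.max_exam_attempts - 1, 0))
        pools = [model.add_stock(Stock(f"exam_retakers_{i + 1}", 0.0,
                                       tags={"stage": "exam"}))
                 for i in range(n_pools)]
        if pools:
            model.add_flow(Flow(
                "exam_failures", EXTERNAL, pools[0].name,
                lambda t, state, p: state.exits["school"] * (1 - p.pass_rate),
            ))
        for i, pool in enumerate(pools):
            model.add_flow(Flow(
                f"retake_passes_{i + 1}", pool.name, EXTERNAL,
                lambda t, state, p, _n=pool.name: state.stocks[_n] * p.pass_rate,
            ))
            fail_sink = (EXTERNAL if (i == len(pools) - 1 and params.max_exam_attempts is not None)
                         else pools[i + 1].name if i + 1 < len(pools) else None)
            if params.max_exam_attempts is None:
                continue  # single pool retains its own failures
            model.add_flow(Flow(
                f"retake_failures_{i + 1}", pool.name, fail_sink,
                lambda t, state, p, _n=pool.name: state.stocks[_n] * (1 - p.pass_rate),
            ))

        def training_entrants(t, state, p):
            passes = exam_passes(state.exits["school"], p.pass_rate)
            for pool in pools:
                passes += state.stocks[pool.name] * p.pass_rate
            return passes * p.career_option_rate

    training = DelayChain(
        name="training",
        duration=params.training_duration,
        cohorts=training_cohorts,
        entrants_rule=training_entrants,
        tags={"stage": "training"},
    )
    model.add_chain(training)

    for spec in params.specialities:
        stock = Stock(
            practice_stock_name(spec),
            value=float(params.initial_stocks.get(spec, 0.0)),
            tags={"stage": "practice", "speciality": spec},
        )
        model.add_stock(stock)
        model.add_flow(Flow(
            f"practice_entry_{spec}", EXTERNAL, stock.name,
            lambda t, state, p, _s=spec: allocate_speciality(
                state.exits["training"], p.selection_fractions)[_s],
        ))
        model.add_flow(Flow(
            f"retirement_{spec}", stock.name, EXTERNAL,
            lambda t, state, p, _s=spec, _n=stock.name: retirement_outflow(
                state.stocks[_n], p.retirement_rate(_s)),
        ))

    return model


def project(params: ParameterSet, clock: SimulationClock) -> Trajectory:
    """Build the career model and run it over the clock."""
    model = build_career_model(params, clock)
    return run_simulation(model, clock, params)


def clinical_totals(trajectory: Trajectory) -> pd.Series:
    """All-clinician headcount per year (sum of the practice stocks)."""
    return trajectory.total(stage="practice")


def speciality_totals(trajectory: Trajectory, speciality: str) -> pd.Series:
    return trajectory.series(practice_stock_name(speciality))
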