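"""Discrete-time stock-and-flow simulation engine.

The engine integrates the standard system-dynamics balance equation

    d(stock)/dt = inflow(t) - outflow(t)

with an explicit Euler step (default ``dt`` = 1 year, matching annual census
data).  Multi-year pipeline stages such as medical school or postgraduate
clinical training are represented by *delay chains* (conveyors): a cohort
entering in year ``t`` leaves ``duration`` years later, and the chain's
occupancy is the sum of the cohorts currently inside it.

Update semantics, fixed for determinism:

* all flow rates and chain entrants are evaluated against the state at the
  start of the step (synchronous update, order-independent);
* outflows from a stock are capped at the stock available at the start of the
  step, scaled proportionally if several outflows compete, so that headcounts
  never go negative;
* chain exits for a step are the oldest cohort, available to rate rules via
  ``state.exits``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, InvalidParameterError

logger = logging.getLogger(__name__)

#: Sentinel endpoint for flows that enter from or leave to outside the model
#: boundary (e.g. enrolment from the applicant pool, retirement out of the
#: workforce).
EXTERNAL = "EXTERNAL"

RateRule = Callable[[int, "State", Any], float]


@dataclass(frozen=True)
class SimulationClock:
    """Simulation time frame: report years ``base_year .. horizon_year`` inclusive."""

    base_year: int
    horizon_year: int
    dt: float = 1.0

    def __post_init__(self):
        if self.dt <= 0:
            raise InvalidParameterError(f"dt must be positive, got {self.dt}")
        if self.base_year >= self.horizon_year:
            raise InvalidParameterError(
                f"base_year ({self.base_year}) must precede horizon_year ({self.horizon_year})"
            )
        n = (self.horizon_year - self.base_year) / self.dt
        if abs(n - round(n)) > 1e-9:
            raise InvalidParameterError(
                "horizon_year - base_year must be an integer multiple of dt"
            )

    @property
    def n_steps(self) -> int:
        return round((self.horizon_year - self.base_year) / self.dt)

    @property
    def step_times(self) -> list[float]:
        """Start times of every integration step."""
        return [self.base_year + i * self.dt for i in range(self.n_steps)]

    @property
    def report_years(self) -> list[float]:
        return [self.base_year + i * self.dt for i in range(self.n_steps + 1)]


@dataclass
class Stock:
    """An accumulating state variable (headcount, persons)."""

    name: str
    value: float = 0.0
    tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.value < 0:
            raise InvalidParameterError(f"stock {self.name!r} initialised negative")


@dataclass
class Flow:
    """A rate (persons/year) moving headcount between stocks or across the boundary."""

    name: str
    source: str
    sink: str
    rate_rule: RateRule

    def __post_init__(self):
        if self.source == self.sink:
            raise ConfigurationError(f"flow {self.name!r} has identical source and sink")


@dataclass
class DelayChain:
    """Fixed-duration conveyor: the cohort entering at step t exits at step t + duration.

    ``cohorts`` is ordered oldest first; ``duration`` counts integration steps
    (calendar years at the default dt = 1).  ``entrants_rule`` feeds the chain
    each step; exits are exposed to downstream rate rules through
    ``state.exits[name]``.
    """

    name: str
    duration: int
    cohorts: list[float] = field(default_factory=list)
    entrants_rule: RateRule | None = None
    tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.duration < 1:
            raise InvalidParameterError(f"chain {self.name!r} needs duration >= 1")
        if not self.cohorts:
            self.cohorts = [0.0] * self.duration
        if len(self.cohorts) != self.duration:
            raise ConfigurationError(
                f"chain {self.name!r}: {len(self.cohorts)} cohorts for duration {self.duration}"
            )
        if any(c < 0 for c in self.cohorts):
            raise InvalidParameterError(f"chain {self.name!r} holds a negative cohort")

    @property
    def occupancy(self) -> float:
        return float(sum(self.cohorts))


@dataclass(frozen=True)
class State:
    """Read-only snapshot handed to rate rules at the start of each step."""

    year: float
    stocks: Mapping[str, float]
    chains: Mapping[str, tuple[float, ...]]
    exits: Mapping[str, float]

    def occupancy(self, chain: str) -> float:
        return float(sum(self.chains[chain]))


@dataclass
class StockFlowModel:
    """A wired set of stocks, delay chains and flows."""

    stocks: dict[str, Stock] = field(default_factory=dict)
    delay_chains: dict[str, DelayChain] = field(default_factory=dict)
    flows: list[Flow] = field(default_factory=list)

    def add_stock(self, stock: Stock) -> Stock:
        if stock.name in self.stocks or stock.name in self.delay_chains:
            raise ConfigurationError(f"duplicate node name {stock.name!r}")
        self.stocks[stock.name] = stock
        return stock

    def add_chain(self, chain: DelayChain) -> DelayChain:
        if chain.name in self.stocks or chain.name in self.delay_chains:
            raise ConfigurationError(f"duplicate node name {chain.name!r}")
        self.delay_chains[chain.name] = chain
        return chain

    def add_flow(self, flow: Flow) -> Flow:
        self.flows.append(flow)
        return flow

    def validate(self) -> None:
        for flow in self.flows:
            for endpoint in (flow.source, flow.sink):
                if endpoint != EXTERNAL and endpoint not in self.stocks:
                    raise ConfigurationError(
                        f"flow {flow.name!r} endpoint {endpoint!r} is not a declared stock"
                    )


def step_stock(value: float, inflow: float, outflow: float, dt: float = 1.0) -> float:
    """One Euler step of the stock balance equation.

    The outflow is capped so that no more than the headcount present at the
    start of the step can leave during it.
    """
    if dt <= 0:
        raise InvalidParameterError(f"dt must be positive, got {dt}")
    if inflow < 0 or outflow < 0:
        raise InvalidParameterError("flow rates must be non-negative")
    if value < 0:
        raise InvalidParameterError("stock value must be non-negative")
    effective_outflow = min(outflow, value / dt)
    return value + (inflow - effective_outflow) * dt


def advance_delay_chain(chain: DelayChain, entrants: float) -> tuple[DelayChain, float]:
    """Advance a conveyor one step: pop the oldest cohort, push the entrants.

    Returns the updated chain (a new object; the input is not mutated) and the
    exiting headcount.  Occupancy is conserved: new = old + entrants - exits.
    """
    if entrants < 0:
        raise InvalidParameterError(f"chain {chain.name!r}: negative entrants {entrants}")
    exits = chain.cohorts[0]
    new = DelayChain(
        name=chain.name,
        duration=chain.duration,
        cohorts=list(chain.cohorts[1:]) + [float(entrants)],
        entrants_rule=chain.entrants_rule,
        tags=chain.tags,
    )
    return new, exits


class Trajectory:
    """Per-year headcounts for every stock and delay chain of a simulation run.

    Stored as a tidy frame (year, name, kind, speciality, headcount); per-step
    flow rates and chain exits are kept alongside so that the full bookkeeping
    of a run can be audited after the fact.
    """

    def __init__(self, states: pd.DataFrame, flows: pd.DataFrame):
        self.states = states
        self.flows = flows
        self.years = sorted(states["year"].unique())

    def series(self, name: str) -> pd.Series:
        sub = self.states[self.states["name"] == name]
        if sub.empty:
            raise KeyError(name)
        return sub.set_index("year")["headcount"].sort_index()

    def total(self, **tag_filters: str) -> pd.Series:
        """Sum headcounts over all nodes matching the given tag values."""
        sub = self.states
        for key, value in tag_filters.items():
            sub = sub[sub[key] == value]
        if sub.empty:
            raise KeyError(f"no nodes match {tag_filters}")
        return sub.groupby("year")["headcount"].sum().sort_index()

    def flow_series(self, name: str) -> pd.Series:
        sub = self.flows[self.flows["name"] == name]
        if sub.empty:
            raise KeyError(name)
        return sub.set_index("year")["rate"].sort_index()

    def to_frame(self) -> pd.DataFrame:
        return self.states.copy()

    def to_csv(self, path) -> None:
        out = self.states.rename(columns={"name": "stock"})
        out.to_csv(path, index=False)


def _snapshot(year, stocks, chains) -> State:
    return State(
        year=year,
        stocks={k: v for k, v in stocks.items()},
        chains={k: tuple(c.cohorts) for k, c in chains.items()},
        exits={k: c.cohorts[0] for k, c in chains.items()},
    )


def run_simulation(model: StockFlowModel, clock: SimulationClock, params: Any = None) -> Trajectory:
    """Run the model from base to horizon year and record every stock each year.

    Rates are evaluated synchronously on the start-of-step state; outflows from
    a stock are proportionally rescaled if together they would overdraw it.
    """
    model.validate()
    stocks = {name: float(s.value) for name, s in model.stocks.items()}
    chains = {name: c for name, c in model.delay_chains.items()}

    state_rows: list[dict] = []
    flow_rows: list[dict] = []

    def record(year: float) -> None:
        for name, value in stocks.items():
            tags = model.stocks[name].tags
            state_rows.append(
                {"year": year, "name": name, "kind": "stock",
                 "headcount": value, **tags}
            )
        for name, chain in chains.items():
            state_rows.append(
                {"year": year, "name": name, "kind": "chain",
                 "headcount": chain.occupancy, **chain.tags}
            )

    record(clock.base_year)

    for t in clock.step_times:
        state = _snapshot(t, stocks, chains)

        rates: dict[str, float] = {}
        for flow in model.flows:
            rate = float(flow.rate_rule(t, state, params))
            if rate < 0 or not math.isfinite(rate):
                raise InvalidParameterError(
                    f"flow {flow.name!r} returned invalid rate {rate} at year {t}"
                )
            rates[flow.name] = rate

        # proportional clamp: outflows may not overdraw the start-of-step stock
        for name, value in stocks.items():
            out_flows = [f for f in model.flows if f.source == name]
            total_out = sum(rates[f.name] for f in out_flows) * clock.dt
            if total_out > value and total_out > 0:
                scale = value / total_out
                for f in out_flows:
                    rates[f.name] *= scale

        entrants: dict[str, float] = {}
        for name, chain in chains.items():
            e = 0.0
            if chain.entrants_rule is not None:
                e = float(chain.entrants_rule(t, state, params))
            if e < 0 or not math.isfinite(e):
                raise InvalidParameterError(
                    f"chain {name!r} received invalid entrants {e} at year {t}"
                )
            entrants[name] = e

        new_stocks = dict(stocks)
        for flow in model.flows:
            amount = rates[flow.name] * clock.dt
            if flow.source != EXTERNAL:
                new_stocks[flow.source] -= amount
            if flow.sink != EXTERNAL:
                new_stocks[flow.sink] += amount
        for name, value in new_stocks.items():
            # clamped above; tiny negatives can only be roundoff
            new_stocks[name] = max(value, 0.0)

        new_chains = {}
        for name, chain in chains.items():
            new_chain, exits = advance_delay_chain(chain, entrants[name])
            new_chains[name] = new_chain
            flow_rows.append({"year": t, "name": f"{name}.exits", "rate": exits})
            flow_rows.append({"year": t, "name": f"{name}.entrants", "rate": entrants[name]})
        for fname, rate in rates.items():
            flow_rows.append({"year": t, "name": fname, "rate": rate})

        if logger.isEnabledFor(logging.DEBUG):
            before = sum(stocks.values()) + sum(c.occupancy for c in chains.values())
            after = sum(new_stocks.values()) + sum(c.occupancy for c in new_chains.values())
            logger.debug("step %s: total %.3f -> %.3f", t, before, after)

        stocks, chains = new_stocks, new_chains
        record(t + clock.dt)

    states = pd.DataFrame(state_rows)
    if "speciality" not in states.columns:
        states["speciality"] = ""
    states["speciality"] = states["speciality"].fillna("")
    flows = pd.DataFrame(flow_rows) if flow_rows else pd.DataFrame(columns=["year", "name", "rate"])
    return Trajectory(states, flows)
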