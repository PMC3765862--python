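"""Unit and property tests for the stock-and-flow engine."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from physupply import (
    EXTERNAL,
    DelayChain,
    Flow,
    InvalidParameterError,
    SimulationClock,
    Stock,
    StockFlowModel,
    advance_delay_chain,
    run_simulation,
    step_stock,
)
from physupply.errors import ConfigurationError


class TestStepStock:
    @pytest.mark.parametrize(
        "value,inflow,outflow,dt,expected",
        [(100, 10, 5, 1, 105), (0, 0, 0, 1, 0), (50, 0, 10, 0.5, 45)],
    )
    def test_euler_arithmetic(self, value, inflow, outflow, dt, expected):
        assert step_stock(value, inflow, outflow, dt) == pytest.approx(expected)

    def test_geometric_decay_closed_form(self):
        # outflow proportional to stock, no inflow: 100 * 0.9**10
        value = 100.0
        for _ in range(10):
            value = step_stock(value, 0.0, 0.1 * value, 1.0)
        assert value == pytest.approx(34.86784401, abs=1e-9)

    def test_outflow_clamped_at_available_stock(self):
        assert step_stock(10.0, 0.0, 20.0, 1.0) == 0.0
        assert step_stock(10.0, 3.0, 20.0, 1.0) == pytest.approx(3.0)

    @pytest.mark.parametrize("kwargs", [
        dict(value=1, inflow=-1, outflow=0, dt=1),
        dict(value=1, inflow=0, outflow=-2, dt=1),
        dict(value=1, inflow=0, outflow=0, dt=0),
        dict(value=1, inflow=0, outflow=0, dt=-1),
    ])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(InvalidParameterError):
            step_stock(**kwargs)


class TestDelayChain:
    def test_unit_delay_is_identity_with_lag(self):
        chain = DelayChain("c", 1, [50.0])
        chain, exits = advance_delay_chain(chain, 60.0)
        assert exits == 50.0
        assert chain.cohorts == [60.0]

    def test_conveyor_ledger(self):
        # constant entrants into an empty 3-year conveyor: exits 0,0,0,10,10
        chain = DelayChain("c", 3)
        seen = []
        for _ in range(5):
            chain, exits = advance_delay_chain(chain, 10.0)
            seen.append(exits)
        assert seen == [0.0, 0.0, 0.0, 10.0, 10.0]

    def test_occupancy_conserved_draining(self):
        chain = DelayChain("c", 6, [100.0] * 6)
        total_exits = 0.0
        for _ in range(6):
            chain, exits = advance_delay_chain(chain, 0.0)
            total_exits += exits
        assert total_exits == pytest.approx(600.0)
        assert chain.occupancy == 0.0

    @given(
        entrants=st.lists(st.floats(0, 1e6), min_size=1, max_size=30),
        duration=st.integers(1, 8),
    )
    def test_occupancy_balance_property(self, entrants, duration):
        chain = DelayChain("c", duration)
        for e in entrants:
            before = chain.occupancy
            chain, exits = advance_delay_chain(chain, e)
            assert chain.occupancy == pytest.approx(before + e - exits, rel=1e-12, abs=1e-9)

    def test_negative_entrants_rejected(self):
        with pytest.raises(InvalidParameterError):
            advance_delay_chain(DelayChain("c", 2), -1.0)


class TestClock:
    @pytest.mark.parametrize("kwargs", [
        dict(base_year=2008, horizon_year=2008),
        dict(base_year=2010, horizon_year=2008),
        dict(base_year=2008, horizon_year=2030, dt=0),
        dict(base_year=2008, horizon_year=2030, dt=0.3),
    ])
    def test_invalid_clock(self, kwargs):
        with pytest.raises(InvalidParameterError):
            SimulationClock(**kwargs)

    def test_report_years(self):
        clock = SimulationClock(2008, 2012)
        assert clock.report_years == [2008, 2009, 2010, 2011, 2012]
        assert clock.n_steps == 4


def _single_stock_model(inflow_rule, outflow_rule, init=0.0):
    model = StockFlowModel()
    model.add_stock(Stock("s", init))
    model.add_flow(Flow("in", EXTERNAL, "s", inflow_rule))
    model.add_flow(Flow("out", "s", EXTERNAL, outflow_rule))
    return model


class TestRunSimulation:
    def test_linear_accumulation(self):
        model = _single_stock_model(lambda t, s, p: 100.0, lambda t, s, p: 0.0)
        traj = run_simulation(model, SimulationClock(2000, 2005))
        assert traj.series("s").loc[2005] == pytest.approx(500.0)

    def test_constant_hazard_matches_closed_form(self):
        model = _single_stock_model(lambda t, s, p: 0.0,
                                    lambda t, s, p: 0.03 * s.stocks["s"],
                                    init=1000.0)
        traj = run_simulation(model, SimulationClock(2000, 2020))
        series = traj.series("s")
        for n, year in enumerate(range(2000, 2021)):
            assert series.loc[year] == pytest.approx(1000.0 * 0.97 ** n, rel=1e-12)

    def test_equilibrium_inflow_over_hazard(self):
        # constant inflow I with hazard r converges monotonically to I / r
        model = _single_stock_model(lambda t, s, p: 100.0,
                                    lambda t, s, p: 0.1 * s.stocks["s"],
                                    init=0.0)
        traj = run_simulation(model, SimulationClock(2000, 2060))
        gaps = (1000.0 - traj.series("s")).abs()
        assert (gaps.diff().dropna() < 0).all()
        assert gaps.loc[2060] < 2.5  # within 0.25 % of I/r after 60 years

    def test_unwired_flow_endpoint_rejected(self):
        model = StockFlowModel()
        model.add_stock(Stock("s", 1.0))
        model.add_flow(Flow("bad", "s", "nowhere", lambda t, s, p: 0.0))
        with pytest.raises(ConfigurationError):
            run_simulation(model, SimulationClock(2000, 2001))

    @given(
        init_a=st.floats(0, 1e6), init_b=st.floats(0, 1e6),
        rate=st.floats(0, 0.5),
    )
    def test_conservation_closed_system(self, init_a, init_b, rate):
        # no EXTERNAL flows: total headcount is invariant
        model = StockFlowModel()
        model.add_stock(Stock("a", init_a))
        model.add_stock(Stock("b", init_b))
        model.add_flow(Flow("a_to_b", "a", "b", lambda t, s, p: rate * s.stocks["a"]))
        model.add_flow(Flow("b_to_a", "b", "a", lambda t, s, p: 0.1 * s.stocks["b"]))
        traj = run_simulation(model, SimulationClock(2000, 2030))
        totals = traj.states.groupby("year")["headcount"].sum()
        expected = init_a + init_b
        assert totals.max() - totals.min() <= 1e-9 * max(expected, 1.0)

    def test_competing_outflows_scaled_proportionally(self):
        model = StockFlowModel()
        model.add_stock(Stock("s", 10.0))
        model.add_flow(Flow("out1", "s", EXTERNAL, lambda t, s, p: 30.0))
        model.add_flow(Flow("out2", "s", EXTERNAL, lambda t, s, p: 10.0))
        traj = run_simulation(model, SimulationClock(2000, 2001))
        assert traj.series("s").loc[2001] == pytest.approx(0.0, abs=1e-12)
        # 3:1 ratio preserved under the clamp
        assert traj.flow_series("out1").loc[2000] == pytest.approx(7.5)
        assert traj.flow_series("out2").loc[2000] == pytest.approx(2.5)

    def test_monotonicity_in_inflow_series(self):
        def build(inflow_level):
            model = StockFlowModel()
            model.add_stock(Stock("s", 100.0))
            chain = DelayChain("pipe", 3,
                               entrants_rule=lambda t, s, p: inflow_level + 0.1 * t % 7)
            model.add_chain(chain)
            model.add_flow(Flow("enter", EXTERNAL, "s",
                                lambda t, s, p: s.exits["pipe"]))
            model.add_flow(Flow("leave", "s", EXTERNAL,
                                lambda t, s, p: 0.05 * s.stocks["s"]))
            return run_simulation(model, SimulationClock(2000, 2030))

        low = build(10.0).series("s")
        high = build(12.0).series("s")
        assert (high >= low - 1e-12).all()


def test_bookkeeping_ledger_oracle():
    """An independent per-year re-evaluation of all flows reproduces a 30-year run."""
    model = StockFlowModel()
    model.add_stock(Stock("practice", 500.0))
    chain = DelayChain("school", 4, [10.0, 20.0, 30.0, 40.0],
                       entrants_rule=lambda t, s, p: 25.0 + (t % 3))
    model.add_chain(chain)
    model.add_flow(Flow("entry", EXTERNAL, "practice",
                        lambda t, s, p: s.exits["school"]))
    model.add_flow(Flow("retire", "practice", EXTERNAL,
                        lambda t, s, p: 0.04 * s.stocks["practice"]))
    clock = SimulationClock(2000, 2030)
    traj = run_simulation(model, clock)

    # brute-force ledger, written independently of the engine internals
    stock = 500.0
    cohorts = [10.0, 20.0, 30.0, 40.0]
    for year in range(2000, 2030):
        exits = cohorts[0]
        entry = exits
        retire = min(0.04 * stock, stock)
        stock = stock + entry - retire
        cohorts = cohorts[1:] + [25.0 + (year % 3)]
        assert traj.series("practice").loc[year + 1] == pytest.approx(stock, rel=1e-12)
        assert traj.series("school").loc[year + 1] == pytest.approx(sum(cohorts), rel=1e-12)
        assert traj.flow_series("entry").loc[year] == pytest.approx(entry, rel=1e-12)
        assert traj.flow_series("retire").loc[year] == pytest.approx(retire, rel=1e-12)


def test_trajectory_contains_every_stock_every_year():
    model = _single_stock_model(lambda t, s, p: 1.0, lambda t, s, p: 0.0)
    traj = run_simulation(model, SimulationClock(2000, 2010))
    counts = traj.states.groupby("year")["name"].count()
    assert (counts == 1).all()
    assert traj.years == list(range(2000, 2011))
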