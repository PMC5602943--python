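"""Per-cell behavioural rules: state gating, energetics, motion, division."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from qs_arena.agents import (Cell, CellState, LocalSensing, SpeciesParams,
                             decide_state, feed_and_pay, maybe_divide, move,
                             secretion_plan)
from qs_arena.environment import ConfigurationError, TrackGeometry


def make_cell(params, state=CellState.SOLITARY, energy=6.0, x=5.0, y=5.0):
    return Cell(id=0, species=params, x=x, y=y, energy=energy, state=state)


@pytest.fixture
def abs_params():
    return SpeciesParams(name="ABS", division_threshold=11.0,
                         ab_sensitive=True, ab_kill_threshold=10.0)


@pytest.fixture
def abp_params():
    return SpeciesParams(name="ABP", ab_producer=True,
                         ab_trigger_channel="S_other",
                         ab_trigger_threshold=10.0)


class TestSpeciesParamsValidation:
    def test_rate_ordering_enforced(self):
        with pytest.raises(ConfigurationError, match="weakly increasing"):
            SpeciesParams(name="x", uptake_rate=(0.5, 0.3, 0.2))

    def test_solitary_factor_emission_must_be_zero(self):
        with pytest.raises(ConfigurationError, match="factor"):
            SpeciesParams(name="x", factor_emission=(0.1, 0.1, 0.2))

    def test_producer_and_sensitive_mutually_exclusive(self):
        with pytest.raises(ConfigurationError):
            SpeciesParams(name="x", ab_producer=True,
                          ab_trigger_channel="S", ab_sensitive=True)

    def test_positive_division_threshold(self):
        with pytest.raises(ConfigurationError):
            SpeciesParams(name="x", division_threshold=0.0)

    def test_initial_energy_defaults_to_half_division_threshold(self):
        assert SpeciesParams(name="x", division_threshold=7.0).initial_energy == 3.5
        assert SpeciesParams(name="x", initial_energy=2.0).initial_energy == 2.0


class TestDecideState:
    def test_signal_at_threshold_activates(self):
        wt = SpeciesParams(name="WT")  # T_S = T_F = 10
        sense = LocalSensing(own_signal=10.0, factor=0.0)
        assert decide_state(sense, wt) is CellState.ACTIVE

    def test_ground_state_without_signal(self, wt):
        assert decide_state(LocalSensing(), wt) is CellState.SOLITARY

    def test_elevated_factor_threshold_gates_swarming(self):
        tf_plus = SpeciesParams(name="TF+", factor_threshold=45.0)
        active = LocalSensing(own_signal=10.0, factor=44.0)
        swarm = LocalSensing(own_signal=10.0, factor=45.0)
        assert decide_state(active, tf_plus) is CellState.ACTIVE
        assert decide_state(swarm, tf_plus) is CellState.SWARMING

    def test_antibiotic_forces_ground_state(self, abs_params):
        sense = LocalSensing(own_signal=50.0, factor=50.0, antibiotic=10.0)
        assert decide_state(sense, abs_params) is CellState.SOLITARY

    def test_antibiotic_override_dominates_exhaustively(self, abs_params):
        """antibiotic >= T_kill forces SOLITARY over a full sensing grid."""
        levels = [0.0, 5.0, 10.0, 20.0, 100.0]
        for own in levels:
            for fac in levels:
                for ab in (10.0, 15.0, 1e6):
                    sense = LocalSensing(own_signal=own, factor=fac,
                                         antibiotic=ab)
                    assert decide_state(sense, abs_params) is CellState.SOLITARY

    def test_insensitive_species_ignores_antibiotic(self, wt):
        sense = LocalSensing(own_signal=50.0, factor=50.0, antibiotic=1e6)
        assert decide_state(sense, wt) is CellState.SWARMING

    def test_factor_alone_can_swarm_when_configured(self):
        sp = SpeciesParams(name="x", require_signal_for_swarm=False)
        sense = LocalSensing(own_signal=0.0, factor=10.0)
        assert decide_state(sense, sp) is CellState.SWARMING

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(own=st.floats(0, 100), fac=st.floats(0, 100),
           ts=st.floats(0, 50), tf=st.floats(0, 50),
           dts=st.floats(0, 50), dtf=st.floats(0, 50))
    def test_raising_thresholds_never_upgrades_state(self, own, fac, ts, tf,
                                                     dts, dtf):
        lo = SpeciesParams(name="lo", signal_threshold=ts, factor_threshold=tf)
        hi = SpeciesParams(name="hi", signal_threshold=ts + dts,
                           factor_threshold=tf + dtf)
        sense = LocalSensing(own_signal=own, factor=fac)
        assert decide_state(sense, hi) <= decide_state(sense, lo)


class TestSecretionPlan:
    def test_eavesdropper_attacks_at_trigger(self, abp_params):
        cell = make_cell(abp_params)
        plan = secretion_plan(cell, LocalSensing(foreign_signal=10.0),
                              abp_params)
        assert plan.antibiotic == abp_params.ab_emission_rate

    def test_eavesdropper_silent_below_trigger(self):
        abp = SpeciesParams(name="ABP", ab_producer=True,
                            ab_trigger_channel="S_other",
                            ab_trigger_threshold=30.0)
        plan = secretion_plan(make_cell(abp),
                              LocalSensing(foreign_signal=29.9), abp)
        assert plan.antibiotic == 0.0

    def test_non_producer_never_emits_antibiotic(self, wt):
        plan = secretion_plan(make_cell(wt, CellState.SWARMING),
                              LocalSensing(foreign_signal=1e6), wt)
        assert plan.antibiotic == 0.0

    def test_state_sets_emission_rates(self, wt):
        for state in CellState:
            plan = secretion_plan(make_cell(wt, state), LocalSensing(), wt)
            assert plan.signal == wt.signal_emission[state]
            assert plan.factor == wt.factor_emission[state]


class TestFeedAndPay:
    def test_starving_solitary_direction(self, wt):
        cell = make_cell(wt, CellState.SOLITARY)
        delta, request = feed_and_pay(cell, LocalSensing(nutrient=0.0), wt)
        expected = (-wt.maintenance_cost[0]
                    - wt.emission_cost * wt.signal_emission[0])
        assert delta == expected
        assert request == wt.uptake_rate[0]

    def test_fed_swarming_cell_gains(self, wt):
        cell = make_cell(wt, CellState.SWARMING)
        delta, _ = feed_and_pay(cell, LocalSensing(nutrient=1e6), wt)
        assert delta > 0

    def test_dormant_cells_cannot_reach_division(self, wt):
        """100 fed solitary steps accrue less than T_D - initial energy:
        growth is only possible through quorum-sensing activation."""
        cell = make_cell(wt, CellState.SOLITARY, energy=wt.initial_energy)
        total = 0.0
        for _ in range(100):
            delta, _ = feed_and_pay(cell, LocalSensing(nutrient=1e6), wt)
            total += delta
        assert total < wt.division_threshold - wt.initial_energy

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(nutrient=st.floats(0, 10), state=st.sampled_from(list(CellState)),
           foreign=st.floats(0, 50))
    def test_energy_accounting_closure(self, nutrient, state, foreign):
        """delta == yield*uptake - maintenance - sum of emission costs."""
        sp = SpeciesParams(name="p", ab_producer=True,
                           ab_trigger_channel="S2", ab_trigger_threshold=25.0)
        cell = make_cell(sp, state)
        sense = LocalSensing(nutrient=nutrient, foreign_signal=foreign)
        delta, request = feed_and_pay(cell, sense, sp)
        plan = secretion_plan(cell, sense, sp)
        actual = min(request, nutrient)
        expected = (sp.energy_yield * actual - sp.maintenance_cost[state]
                    - sp.emission_cost * (plan.signal + plan.factor)
                    - sp.ab_emission_cost * plan.antibiotic)
        assert delta == expected


class TestMove:
    def test_zero_step_is_stationary(self, wt, track, rng):
        cell = make_cell(wt, CellState.SOLITARY, x=3.3, y=4.4)
        assert wt.move_step[CellState.SOLITARY] == 0.0
        assert move(cell, wt, track, rng) == (3.3, 4.4)

    def test_periodic_wrap_in_y(self, wt, rng):
        geom = TrackGeometry(length_x=60, width_y=10)
        sp = dataclasses.replace(wt, move_step=(0.0, 0.2, 0.5))
        cell = make_cell(sp, CellState.SWARMING, x=30.0, y=0.1)
        # force a straight downward move via a rigged rng
        class Down:
            def uniform(self, lo, hi):
                return 1.5 * math.pi  # sin = -1
        nx, ny = move(cell, sp, geom, Down())
        assert ny == pytest.approx(10.0 - 0.4, abs=1e-12)
        assert nx == pytest.approx(30.0, abs=1e-12)

    def test_reflection_at_closed_end(self, wt, track):
        sp = dataclasses.replace(wt, move_step=(0.0, 0.2, 1.0))
        cell = make_cell(sp, CellState.SWARMING, x=0.2, y=5.0)
        class Left:
            def uniform(self, lo, hi):
                return math.pi  # cos = -1
        nx, _ = move(cell, sp, track, Left())
        assert nx == pytest.approx(0.8, abs=1e-12)

    def test_step_length_and_isotropy(self, wt, rng):
        geom = TrackGeometry(length_x=1000, width_y=1000)
        sp = dataclasses.replace(wt, move_step=(0.0, 0.2, 1.0))
        cell = make_cell(sp, CellState.SWARMING, x=500.0, y=500.0)
        angles = []
        for _ in range(10_000):
            nx, ny = move(cell, sp, geom, rng)
            dx, dy = nx - cell.x, ny - cell.y
            assert math.hypot(dx, dy) == pytest.approx(1.0, abs=1e-9)
            angles.append(math.atan2(dy, dx))
        counts, _ = np.histogram(angles, bins=12, range=(-math.pi, math.pi))
        assert stats.chisquare(counts).pvalue > 0.01


class TestMaybeDivide:
    def test_division_at_threshold_halves_energy(self, wt, track, rng):
        cell = make_cell(wt, CellState.ACTIVE, energy=12.0)
        daughter = maybe_divide(cell, wt, track, rng, daughter_id=99)
        assert daughter is not None
        assert cell.energy == 6.0 and daughter.energy == 6.0
        assert daughter.generation == cell.generation + 1
        assert daughter.state is cell.state
        assert daughter.id == 99

    def test_no_division_below_threshold(self, track, rng):
        abs_sp = SpeciesParams(name="ABS", division_threshold=11.0)
        cell = make_cell(abs_sp, energy=10.9)
        assert maybe_divide(cell, abs_sp, track, rng, 1) is None
        assert cell.energy == 10.9

    def test_daughter_born_near_parent(self, wt, track, rng):
        for _ in range(50):
            cell = make_cell(wt, energy=13.0, x=20.0, y=5.0)
            d = maybe_divide(cell, wt, track, rng, 1)
            assert math.hypot(d.x - cell.x, d.y - cell.y) <= 0.5 + 1e-12
            assert track.contains(d.x, d.y)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(energy=st.floats(12.0, 24.0), seed=st.integers(0, 2**31 - 1))
    def test_division_conserves_energy_exactly(self, energy, seed):
        wt = SpeciesParams(name="WT")
        geom = TrackGeometry(length_x=60, width_y=10)
        cell = make_cell(wt, energy=energy)
        d = maybe_divide(cell, wt, geom, np.random.default_rng(seed), 1)
        assert cell.energy + d.energy == energy

    def test_halved_threshold_doubles_division_rate(self, track, rng):
        """Constant net gain g: T_D=6 divides twice as often as T_D=12."""
        def divisions(threshold, gain=0.25, steps=400):
            sp = SpeciesParams(name="x", division_threshold=threshold)
            cell = make_cell(sp, energy=threshold / 2)
            n = 0
            for _ in range(steps):
                cell.energy += gain
                if maybe_divide(cell, sp, track, rng, 1) is not None:
                    n += 1
            return n
        slow = divisions(12.0)
        fast = divisions(6.0)
        assert fast == pytest.approx(2 * slow, abs=1)
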