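"""Species parameterisation and per-cell behavioural rules.

Each agent is a bacterial cell with a continuous position, an energy store
and one of three behavioural states:

* ``SOLITARY`` — the ground state: slow feeding, no motion, a trickle of
  quorum-sensing signal, no cooperation factor.
* ``ACTIVE``   — entered when the locally sensed signal reaches the species'
  signal threshold T_S; the cell feeds faster and starts secreting the
  cooperation factor (a public good).
* ``SWARMING`` — entered when, in addition, the local factor concentration
  reaches the factor threshold T_F; food intake, movement and both
  secretions are all turned up.

State switching is memoryless: every step the state is recomputed from the
current local concentrations, so cells "fall back" as soon as a
concentration drops below its threshold.  For antibiotic-sensitive species,
local antibiotic at or above the kill threshold forces the ground state
regardless of everything else (or removes the cell outright in ``kill``
mode — see the engine).

Division is energy-gated: a cell divides when its energy store reaches the
division threshold T_D, so a lower T_D means faster division and higher
fitness.  Antibiotic producers eavesdrop: they secrete antibiotic whenever
the concentration on a designated *foreign* signal channel reaches their
trigger threshold T_AB, independent of their own behavioural state.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .environment import ConfigurationError, TrackGeometry

__all__ = [
    "CellState",
    "SpeciesParams",
    "Cell",
    "LocalSensing",
    "SecretionPlan",
    "decide_state",
    "feed_and_pay",
    "secretion_plan",
    "move",
    "maybe_divide",
]

#: Maximum distance between a mother cell and her daughter at division.
DIVISION_OFFSET = 0.5


class CellState(enum.IntEnum):
    SOLITARY = 0
    ACTIVE = 1
    SWARMING = 2


def _check_rate_triple(name: str, triple: tuple[float, float, float],
                       ordered: bool) -> None:
    if len(triple) != 3:
        raise ConfigurationError(f"{name} needs one rate per state "
                                 f"(solitary, active, swarming)")
    if any(r < 0 for r in triple):
        raise ConfigurationError(f"{name} rates must be >= 0, got {triple}")
    if ordered and not (triple[0] <= triple[1] <= triple[2]):
        raise ConfigurationError(
            f"{name} must be weakly increasing solitary <= active <= "
            f"swarming, got {triple}"
        )


@dataclass(frozen=True)
class SpeciesParams:
    """Thresholds and per-state rates of one species.

    The three response thresholds are the heart of the model: T_S and T_F
    gate the behavioural states, T_D gates division (fitness).  Rate triples
    are indexed (solitary, active, swarming) and must be weakly increasing
    for uptake, movement and the two secretions — the up-shifted states do
    everything faster.  Solitary cells never secrete factor.

    Defaults below are the calibrated baseline rate table shared by all
    shipped presets; presets differ only in thresholds and the antibiotic
    flags.
    """

    name: str
    division_threshold: float = 12.0
    signal_threshold: float = 10.0
    factor_threshold: float = 10.0
    signal_channel_emit: str = "S"
    signal_channel_sense: str = "S"
    # antibiotic warfare (off by default)
    ab_producer: bool = False
    ab_trigger_threshold: float = math.inf
    ab_trigger_channel: str | None = None
    ab_sensitive: bool = False
    ab_kill_threshold: float = math.inf
    # per-state rates (solitary, active, swarming)
    uptake_rate: tuple[float, float, float] = (0.11, 0.25, 0.55)
    maintenance_cost: tuple[float, float, float] = (0.12, 0.17, 0.20)
    move_step: tuple[float, float, float] = (0.0, 0.2, 0.28)
    signal_emission: tuple[float, float, float] = (0.06, 0.08, 0.10)
    factor_emission: tuple[float, float, float] = (0.0, 0.10, 0.25)
    emission_cost: float = 0.05
    ab_emission_rate: float = 0.2
    ab_emission_cost: float = 0.05
    energy_yield: float = 1.0
    #: energy at seeding; None means half the division threshold, the same
    #: level a newborn daughter starts from
    initial_energy: float | None = None
    #: if False, factor >= T_F alone (without signal >= T_S) also swarms
    require_signal_for_swarm: bool = True

    def __post_init__(self) -> None:
        if self.initial_energy is None:
            object.__setattr__(self, "initial_energy",
                               self.division_threshold / 2.0)
        if self.division_threshold <= 0:
            raise ConfigurationError(f"{self.name}: division_threshold must be > 0")
        if self.signal_threshold < 0 or self.factor_threshold < 0:
            raise ConfigurationError(f"{self.name}: thresholds must be >= 0")
        _check_rate_triple(f"{self.name}.uptake_rate", self.uptake_rate, True)
        _check_rate_triple(f"{self.name}.maintenance_cost",
                           self.maintenance_cost, False)
        _check_rate_triple(f"{self.name}.move_step", self.move_step, True)
        _check_rate_triple(f"{self.name}.signal_emission",
                           self.signal_emission, True)
        _check_rate_triple(f"{self.name}.factor_emission",
                           self.factor_emission, True)
        if self.factor_emission[CellState.SOLITARY] != 0.0:
            raise ConfigurationError(
                f"{self.name}: solitary cells must not secrete factor"
            )
        if self.ab_producer and self.ab_sensitive:
            raise ConfigurationError(
                f"{self.name}: a species cannot both produce and be "
                f"sensitive to the antibiotic"
            )
        if self.ab_producer and self.ab_trigger_channel is None:
            raise ConfigurationError(
                f"{self.name}: antibiotic producer needs a trigger channel"
            )
        for scalar in ("emission_cost", "ab_emission_rate", "ab_emission_cost",
                       "energy_yield", "initial_energy"):
            if getattr(self, scalar) < 0:
                raise ConfigurationError(f"{self.name}: {scalar} must be >= 0")


@dataclass
class Cell:
    """One agent."""

    id: int
    species: SpeciesParams
    x: float
    y: float
    energy: float
    state: CellState = CellState.SOLITARY
    generation: int = 0


@dataclass(frozen=True)
class LocalSensing:
    """Concentrations at the agent's lattice cell, as entering the rules."""

    nutrient: float = 0.0
    own_signal: float = 0.0
    factor: float = 0.0
    foreign_signal: float = 0.0
    antibiotic: float = 0.0


@dataclass(frozen=True)
class SecretionPlan:
    """Amounts deposited into each field this step."""

    signal: float = 0.0
    factor: float = 0.0
    antibiotic: float = 0.0


def decide_state(sense: LocalSensing, params: SpeciesParams) -> CellState:
    """Threshold-gated state for this step.

    Antibiotic suppression dominates everything for sensitive species.
    Otherwise: signal >= T_S activates; signal >= T_S and factor >= T_F
    swarms; anything else is the ground state.
    """
    if params.ab_sensitive and sense.antibiotic >= params.ab_kill_threshold:
        return CellState.SOLITARY
    if sense.own_signal >= params.signal_threshold:
        if sense.factor >= params.factor_threshold:
            return CellState.SWARMING
        return CellState.ACTIVE
    if (not params.require_signal_for_swarm
            and sense.factor >= params.factor_threshold):
        return CellState.SWARMING
    return CellState.SOLITARY


def secretion_plan(cell: Cell, sense: LocalSensing,
                   params: SpeciesParams) -> SecretionPlan:
    """What the cell deposits this step, given its (already updated) state.

    Antibiotic output is gated purely on the eavesdropped foreign signal
    channel, not on the producer's own behavioural state.
    """
    st = cell.state
    ab = 0.0
    if params.ab_producer and sense.foreign_signal >= params.ab_trigger_threshold:
        ab = params.ab_emission_rate
    return SecretionPlan(
        signal=params.signal_emission[st],
        factor=params.factor_emission[st],
        antibiotic=ab,
    )


def feed_and_pay(cell: Cell, sense: LocalSensing,
                 params: SpeciesParams) -> tuple[float, float]:
    """Energy balance of one step.

    Returns ``(energy_delta, uptake_request)``.  The uptake request is the
    state's uptake rate; the realised uptake is clamped by what the local
    lattice cell holds (``sense.nutrient``).  The delta is

        yield * uptake_actual - maintenance - emission costs,

    where emission costs cover every secretion made this step.  Energy may
    go negative; death is the engine's job.
    """
    st = cell.state
    request = params.uptake_rate[st]
    actual = request if request <= sense.nutrient else sense.nutrient
    plan = secretion_plan(cell, sense, params)
    delta = (
        params.energy_yield * actual
        - params.maintenance_cost[st]
        - params.emission_cost * (plan.signal + plan.factor)
        - params.ab_emission_cost * plan.antibiotic
    )
    return delta, request


def displace(x: float, y: float, step: float, angle: float,
             geometry: TrackGeometry) -> tuple[float, float]:
    """Apply one displacement with the track's boundary rules.

    y wraps periodically; x reflects at the closed end and is clamped just
    inside the last column at the open end (agents never leave the track).
    Works elementwise on arrays as well as scalars.
    """
    nx = x + step * np.cos(angle)
    ny = np.mod(y + step * np.sin(angle), geometry.width_y)
    nx = np.abs(nx)
    nx = np.minimum(nx, geometry.length_x * (1.0 - 1e-12))
    return nx, ny


def move(cell: Cell, params: SpeciesParams, geometry: TrackGeometry,
         rng: np.random.Generator) -> tuple[float, float]:
    """New position after one random-walk step of the state's step length."""
    step = params.move_step[cell.state]
    if step == 0.0:
        return cell.x, cell.y
    angle = rng.uniform(0.0, 2.0 * math.pi)
    nx, ny = displace(cell.x, cell.y, step, angle, geometry)
    return float(nx), float(ny)


def maybe_divide(cell: Cell, params: SpeciesParams, geometry: TrackGeometry,
                 rng: np.random.Generator, daughter_id: int) -> Cell | None:
    """Divide if energy has reached T_D; otherwise return None.

    Mother and daughter each get exactly half the mother's energy.  The
    daughter appears within ``DIVISION_OFFSET`` units of the mother, keeps
    her state, and carries generation index ``mother + 1``.
    """
    if cell.energy < params.division_threshold:
        return None
    angle = rng.uniform(0.0, 2.0 * math.pi)
    radius = rng.uniform(0.0, DIVISION_OFFSET)
    half = cell.energy / 2.0
    cell.energy = half
    dx, dy = displace(cell.x, cell.y, radius, angle, geometry)
    return Cell(
        id=daughter_id,
        species=cell.species,
        x=float(dx),
        y=float(dy),
        energy=half,
        state=cell.state,
        generation=cell.generation + 1,
    )
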