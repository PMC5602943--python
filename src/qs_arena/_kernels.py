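"""Packed-array agent update kernel.

The engine stores agents as a struct-of-arrays and runs the per-cell phase
of each step (sense -> decide state -> feed/pay -> secrete) through a
numba-compiled loop.  Agents are visited in a freshly shuffled order every
step and read/write the field lattices as they go, so each agent sees the
environment as left by the agents before it — the randomised-sequential
schedule.  The rules in this loop mirror, line for line, the scalar
functions in :mod:`qs_arena.agents`; the test suite checks the two paths
against each other on a small world.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .agents import SpeciesParams

_N_STATES = 3


@dataclass(frozen=True)
class ParamPack:
    """SpeciesParams flattened into arrays indexed by species number."""

    species_names: tuple[str, ...]
    channels: tuple[str, ...]
    division_threshold: np.ndarray
    signal_threshold: np.ndarray
    factor_threshold: np.ndarray
    kill_threshold: np.ndarray
    trigger_threshold: np.ndarray
    sense_channel: np.ndarray
    emit_channel: np.ndarray
    trigger_channel: np.ndarray
    ab_producer: np.ndarray
    ab_sensitive: np.ndarray
    require_signal: np.ndarray
    uptake: np.ndarray            # (n_species, 3)
    maintenance: np.ndarray       # (n_species, 3)
    move_step: np.ndarray         # (n_species, 3)
    signal_emission: np.ndarray   # (n_species, 3)
    factor_emission: np.ndarray   # (n_species, 3)
    emission_cost: np.ndarray
    ab_rate: np.ndarray
    ab_cost: np.ndarray
    energy_yield: np.ndarray
    initial_energy: np.ndarray

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def any_ab(self) -> bool:
        return bool(self.ab_producer.any() or self.ab_sensitive.any())


def signal_channels(species: list[SpeciesParams]) -> tuple[str, ...]:
    """Ordered unique signal channel ids referenced by any species."""
    seen: list[str] = []
    for sp in species:
        for ch in (sp.signal_channel_emit, sp.signal_channel_sense,
                   sp.ab_trigger_channel):
            if ch is not None and ch not in seen:
                seen.append(ch)
    return tuple(seen)


def pack_params(species: list[SpeciesParams]) -> ParamPack:
    channels = signal_channels(species)
    idx = {ch: i for i, ch in enumerate(channels)}
    n = len(species)

    def arr(getter, dtype=np.float64):
        return np.array([getter(sp) for sp in species], dtype=dtype)

    def table(getter):
        return np.array([list(getter(sp)) for sp in species], dtype=np.float64)

    return ParamPack(
        species_names=tuple(sp.name for sp in species),
        channels=channels,
        division_threshold=arr(lambda s: s.division_threshold),
        signal_threshold=arr(lambda s: s.signal_threshold),
        factor_threshold=arr(lambda s: s.factor_threshold),
        kill_threshold=arr(lambda s: s.ab_kill_threshold),
        trigger_threshold=arr(lambda s: s.ab_trigger_threshold),
        sense_channel=arr(lambda s: idx[s.signal_channel_sense], np.int64),
        emit_channel=arr(lambda s: idx[s.signal_channel_emit], np.int64),
        trigger_channel=arr(
            lambda s: idx.get(s.ab_trigger_channel, -1), np.int64),
        ab_producer=arr(lambda s: s.ab_producer, np.bool_),
        ab_sensitive=arr(lambda s: s.ab_sensitive, np.bool_),
        require_signal=arr(lambda s: s.require_signal_for_swarm, np.bool_),
        uptake=table(lambda s: s.uptake_rate),
        maintenance=table(lambda s: s.maintenance_cost),
        move_step=table(lambda s: s.move_step),
        signal_emission=table(lambda s: s.signal_emission),
        factor_emission=table(lambda s: s.factor_emission),
        emission_cost=arr(lambda s: s.emission_cost),
        ab_rate=arr(lambda s: s.ab_emission_rate),
        ab_cost=arr(lambda s: s.ab_emission_cost),
        energy_yield=arr(lambda s: s.energy_yield),
        initial_energy=arr(lambda s: s.initial_energy),
    )


@njit(cache=True)
def agent_phase(order, x, y, energy, state, species,
                nutrient, signals, factor, antibiotic,
                sense_ch, emit_ch, trig_ch,
                t_signal, t_factor, t_kill, t_trigger,
                ab_sensitive, ab_producer, require_signal,
                uptake, maintenance, sig_emit, fac_emit,
                emission_cost, ab_rate, ab_cost, energy_yield,
                kill_mode, uptake_out):  # pragma: no cover - exercised via engine
    """Sequential sense/decide/feed/secrete sweep over all agents.

    Mutates ``energy``, ``state`` and the four field arrays in place and
    accumulates realised nutrient uptake per species into ``uptake_out``.
    In ``kill_mode``, antibiotic above the kill threshold marks the cell
    dead (energy set negative) instead of merely suppressing it.
    """
    for k in range(order.shape[0]):
        i = order[k]
        s = species[i]
        iy = int(y[i])
        ix = int(x[i])

        nut = nutrient[iy, ix]
        own = signals[sense_ch[s], iy, ix]
        fac = factor[iy, ix]
        abv = antibiotic[iy, ix]
        fsig = signals[trig_ch[s], iy, ix] if trig_ch[s] >= 0 else 0.0

        # threshold-gated behavioural state (mirrors agents.decide_state)
        if ab_sensitive[s] and abv >= t_kill[s]:
            if kill_mode:
                energy[i] = -1.0
                state[i] = 0
                continue
            st = 0
        elif own >= t_signal[s]:
            st = 2 if fac >= t_factor[s] else 1
        elif (not require_signal[s]) and fac >= t_factor[s]:
            st = 2
        else:
            st = 0
        state[i] = st

        # feeding, clamped by the local lattice cell
        req = uptake[s, st]
        got = req if req <= nut else nut
        nutrient[iy, ix] = nut - got
        uptake_out[s] += got

        # secretion (antibiotic gated on the eavesdropped foreign channel)
        se = sig_emit[s, st]
        fe = fac_emit[s, st]
        if se > 0.0:
            signals[emit_ch[s], iy, ix] += se
        if fe > 0.0:
            factor[iy, ix] += fe
        abe = 0.0
        if ab_producer[s] and fsig >= t_trigger[s]:
            abe = ab_rate[s]
            antibiotic[iy, ix] += abe

        energy[i] += (energy_yield[s] * got - maintenance[s, st]
                      - emission_cost[s] * (se + fe) - ab_cost[s] * abe)
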