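"""World construction and the per-step update schedule.

A step executes a fixed phase order:

1. diffuse/decay every field;
2. agent phase in a freshly shuffled order — each agent senses its lattice
   cell, recomputes its behavioural state, feeds (clamped by the local
   nutrient), pays maintenance and emission costs, and deposits its
   secretions, so later agents see the environment left by earlier ones;
3. random-walk movement for all agents;
4. division sweep (energy >= T_D splits the cell's energy equally between
   mother and daughter);
5. death sweep (energy <= 0 removes the cell);
6. bookkeeping and step counter.

All randomness flows through one ``numpy.random.Generator`` drawn in a
fixed program order per step: the shuffle permutation, then one movement
angle per cell, then one division angle and one division radius per cell
(drawn whether or not the cell divides).  Runs are therefore bitwise
reproducible for a given config and seed, and the pure-Python reference
step used by the test suite can replay the identical stream.

Agents are stored as a struct of arrays (:class:`CellArrays`); the agent
phase itself runs through the numba kernel in :mod:`._kernels`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .agents import DIVISION_OFFSET, SpeciesParams, displace
from .environment import (ConfigurationError, FieldGrid, FieldSpec,
                          TrackGeometry, diffuse_decay)
from .phenotype import PopulationTimeSeries

__all__ = [
    "SimulationConfig",
    "WorldState",
    "SimulationResult",
    "CellArrays",
    "default_field_specs",
    "seed_population",
    "step",
    "run",
]

#: Target seeding density (cells per lattice cell) when the seeding region
#: is derived automatically from the inoculum size.
SEED_DENSITY = 25.0

#: Default calibrated field constants.  The nutrient is immobile food
#: pre-spread over the whole track; signal, factor and antibiotic diffuse
#: and decay.  The nutrient level sets the carrying capacity of the active
#: zone and, with the rate table, the pace of the generation clock.
DEFAULT_FIELD_CONSTANTS: dict[str, tuple[float, float, float]] = {
    # name: (diffusion_coeff, decay_rate, initial_value)
    "nutrient": (0.0, 0.0, 2000.0),
    "signal": (0.005, 0.03, 0.0),
    "factor": (0.05, 0.08, 0.0),
    "antibiotic": (0.02, 0.05, 0.0),
}


def default_field_specs(include_antibiotic: bool = False,
                        **overrides) -> dict[str, FieldSpec]:
    """The calibrated default field table.

    ``overrides`` maps field name to a ``(D, decay, initial)`` tuple or to
    a dict of the FieldSpec keywords to replace.
    """
    names = ["nutrient", "signal", "factor"]
    if include_antibiotic or "antibiotic" in overrides:
        names.append("antibiotic")
    specs = {}
    for name in names:
        d, lam, init = DEFAULT_FIELD_CONSTANTS[name]
        kw = {"diffusion_coeff": d, "decay_rate": lam, "initial_value": init}
        ov = overrides.get(name)
        if isinstance(ov, tuple):
            kw = {"diffusion_coeff": ov[0], "decay_rate": ov[1],
                  "initial_value": ov[2]}
        elif isinstance(ov, dict):
            kw.update(ov)
        specs[name] = FieldSpec(name=name, **kw)
    return specs


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one run."""

    geometry: TrackGeometry
    species: tuple[SpeciesParams, ...]
    initial_counts: tuple[int, ...]
    field_specs: dict[str, FieldSpec] = field(default_factory=default_field_specs)
    seeding_region: tuple[float, float] | None = None
    steps: int = 5000
    rng_seed: int = 0
    record_every: int = 10
    snapshot_steps: tuple[int, ...] = ()
    density_cap: float = 50.0
    ab_mode: str = "suppress"
    track_signal_bands: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (1 <= len(self.species) <= 2):
            raise ConfigurationError("need 1 or 2 species")
        if len(self.initial_counts) != len(self.species):
            raise ConfigurationError("one initial count per species")
        if any(c < 0 for c in self.initial_counts):
            raise ConfigurationError("initial counts must be >= 0")
        if self.steps < 1:
            raise ConfigurationError("steps must be >= 1")
        if self.record_every < 1:
            raise ConfigurationError("record_every must be >= 1")
        if self.ab_mode not in ("suppress", "kill"):
            raise ConfigurationError("ab_mode must be 'suppress' or 'kill'")
        names = [sp.name for sp in self.species]
        if len(set(names)) != len(names):
            raise ConfigurationError("species names must be unique")
        for key in ("nutrient", "signal", "factor"):
            if key not in self.field_specs:
                raise ConfigurationError(f"field_specs must include {key!r}")
        uses_ab = any(sp.ab_producer or sp.ab_sensitive for sp in self.species)
        if uses_ab and "antibiotic" not in self.field_specs:
            raise ConfigurationError(
                "species use antibiotics but the antibiotic field is disabled"
            )
        region = self.resolved_seeding_region()
        if not (0.0 <= region[0] < region[1] <= self.geometry.length_x):
            raise ConfigurationError(
                f"seeding_region {region} outside [0, {self.geometry.length_x})"
            )
        area = (region[1] - region[0]) * self.geometry.width_y
        total = sum(self.initial_counts)
        if total > 0 and total / area > self.density_cap:
            raise ConfigurationError(
                f"seeding density {total / area:.1f} exceeds cap "
                f"{self.density_cap} cells per lattice cell"
            )

    def resolved_seeding_region(self) -> tuple[float, float]:
        """Explicit region, or one sized for ``SEED_DENSITY`` at the start.

        Deriving the region length from the inoculum keeps the initial cell
        density — and with it the early signal build-up — comparable across
        inoculum sizes and track scales.
        """
        if self.seeding_region is not None:
            return self.seeding_region
        total = max(sum(self.initial_counts), 1)
        x1 = max(1.0, total / (SEED_DENSITY * self.geometry.width_y))
        return (0.0, min(x1, float(self.geometry.length_x)))


@dataclass
class CellArrays:
    """Struct-of-arrays agent store."""

    x: np.ndarray
    y: np.ndarray
    energy: np.ndarray
    state: np.ndarray       # int8, CellState values
    species: np.ndarray     # int8 species index
    generation: np.ndarray  # int32
    id: np.ndarray          # int64

    @classmethod
    def empty(cls) -> "CellArrays":
        return cls(x=np.empty(0), y=np.empty(0), energy=np.empty(0),
                   state=np.empty(0, np.int8), species=np.empty(0, np.int8),
                   generation=np.empty(0, np.int32), id=np.empty(0, np.int64))

    @property
    def n(self) -> int:
        return self.x.size

    def keep(self, mask: np.ndarray) -> None:
        for name in ("x", "y", "energy", "state", "species", "generation", "id"):
            setattr(self, name, getattr(self, name)[mask])

    def append(self, other: "CellArrays") -> None:
        for name in ("x", "y", "energy", "state", "species", "generation", "id"):
            setattr(self, name, np.concatenate(
                [getattr(self, name), getattr(other, name)]))

    def counts(self, n_species: int) -> np.ndarray:
        return np.bincount(self.species, minlength=n_species).astype(np.int64)

    def mean_generation(self, n_species: int) -> np.ndarray:
        out = np.full(n_species, np.nan)
        for s in range(n_species):
            mask = self.species == s
            if mask.any():
                out[s] = self.generation[mask].mean()
        return out


@dataclass
class WorldState:
    """Full mutable simulation state."""

    config: SimulationConfig
    geometry: TrackGeometry
    pack: _kernels.ParamPack
    fields: dict[str, FieldGrid]
    cells: CellArrays
    rng: np.random.Generator
    step: int = 0
    next_id: int = 0
    divisions: np.ndarray = None
    deaths: np.ndarray = None
    uptake_total: np.ndarray = None
    band_occupancy: np.ndarray = None  # (n_species, 2) cell-steps
    band_divisions: np.ndarray = None  # (n_species, 2) events

    def field_mass(self, name: str) -> float:
        return self.fields[name].total_mass()

    def seeded_counts(self) -> np.ndarray:
        return np.asarray(self.config.initial_counts, dtype=np.int64)


def seed_population(config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> WorldState:
    """Initial world: fields at their initial values, all agents solitary
    at generation 0, placed uniformly at random in the seeding region."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    pack = _kernels.pack_params(list(config.species))
    geometry = config.geometry

    fields: dict[str, FieldGrid] = {}
    for name, spec in config.field_specs.items():
        if name == "signal":
            for ch in pack.channels:
                chspec = replace(spec, name=f"signal:{ch}")
                fields[f"signal:{ch}"] = FieldGrid.uniform(chspec, geometry)
        else:
            fields[name] = FieldGrid.uniform(spec, geometry)

    x0, x1 = config.resolved_seeding_region()
    xs, ys, energies, species_idx = [], [], [], []
    for si, (sp, count) in enumerate(zip(config.species, config.initial_counts)):
        xs.append(rng.uniform(x0, x1, count))
        ys.append(rng.uniform(0.0, geometry.width_y, count))
        energies.append(np.full(count, sp.initial_energy))
        species_idx.append(np.full(count, si, dtype=np.int8))
    total = int(sum(config.initial_counts))
    cells = CellArrays(
        x=np.concatenate(xs) if xs else np.empty(0),
        y=np.concatenate(ys) if ys else np.empty(0),
        energy=np.concatenate(energies) if energies else np.empty(0),
        state=np.zeros(total, np.int8),
        species=np.concatenate(species_idx) if species_idx else np.empty(0, np.int8),
        generation=np.zeros(total, np.int32),
        id=np.arange(total, dtype=np.int64),
    )
    n_sp = len(config.species)
    return WorldState(
        config=config, geometry=geometry, pack=pack, fields=fields,
        cells=cells, rng=rng, step=0, next_id=total,
        divisions=np.zeros(n_sp, np.int64),
        deaths=np.zeros(n_sp, np.int64),
        uptake_total=np.zeros(n_sp),
        band_occupancy=np.zeros((n_sp, 2)),
        band_divisions=np.zeros((n_sp, 2)),
    )


def _signal_stack(world: WorldState) -> np.ndarray:
    return np.stack([world.fields[f"signal:{ch}"].values
                     for ch in world.pack.channels])


def _unstack_signals(world: WorldState, stack: np.ndarray) -> None:
    for i, ch in enumerate(world.pack.channels):
        world.fields[f"signal:{ch}"].values = stack[i]


def step(world: WorldState) -> WorldState:
    """Advance the world by one step (in place; returns the world)."""
    config = world.config
    geom = world.geometry
    pack = world.pack
    cells = world.cells
    rng = world.rng

    # 1. field physics
    for name, grid in world.fields.items():
        spec = grid.spec
        if spec.diffusion_coeff == 0.0 and spec.decay_rate == 0.0:
            continue
        world.fields[name] = diffuse_decay(grid, geom)

    n = cells.n
    # fixed per-step random draw order (see module docstring)
    order = rng.permutation(n)
    move_angles = rng.uniform(0.0, 2.0 * math.pi, n)
    div_angles = rng.uniform(0.0, 2.0 * math.pi, n)
    div_radii = rng.uniform(0.0, DIVISION_OFFSET, n)

    if n > 0:
        # 2. randomised-sequential agent phase
        signals = _signal_stack(world)
        nutrient = world.fields["nutrient"].values
        factor = world.fields["factor"].values
        if "antibiotic" in world.fields:
            antibiotic = world.fields["antibiotic"].values
        else:
            antibiotic = np.zeros_like(nutrient)
        uptake_out = np.zeros(pack.n_species)
        _kernels.agent_phase(
            order, cells.x, cells.y, cells.energy, cells.state, cells.species,
            nutrient, signals, factor, antibiotic,
            pack.sense_channel, pack.emit_channel, pack.trigger_channel,
            pack.signal_threshold, pack.factor_threshold,
            pack.kill_threshold, pack.trigger_threshold,
            pack.ab_sensitive, pack.ab_producer, pack.require_signal,
            pack.uptake, pack.maintenance,
            pack.signal_emission, pack.factor_emission,
            pack.emission_cost, pack.ab_rate, pack.ab_cost, pack.energy_yield,
            config.ab_mode == "kill", uptake_out,
        )
        _unstack_signals(world, signals)
        world.uptake_total += uptake_out

        # 3. movement
        step_len = pack.move_step[cells.species, cells.state]
        cells.x, cells.y = displace(cells.x, cells.y, step_len,
                                    move_angles, geom)

        # optional per-band bookkeeping for growth-rate-vs-signal analyses
        if config.track_signal_bands is not None:
            lo, hi = config.track_signal_bands
            iy = cells.y.astype(np.int64)
            ix = cells.x.astype(np.int64)
            local = signals[pack.sense_channel[cells.species], iy, ix]
            mid = (local >= lo) & (local < hi)
            high = local >= hi
        else:
            mid = high = None

        # 4. division sweep
        div_mask = cells.energy >= pack.division_threshold[cells.species]
        if div_mask.any():
            cells.energy[div_mask] *= 0.5
            dx, dy = displace(cells.x[div_mask], cells.y[div_mask],
                              div_radii[div_mask], div_angles[div_mask], geom)
            n_new = int(div_mask.sum())
            daughters = CellArrays(
                x=np.asarray(dx), y=np.asarray(dy),
                energy=cells.energy[div_mask].copy(),
                state=cells.state[div_mask].copy(),
                species=cells.species[div_mask].copy(),
                generation=cells.generation[div_mask] + 1,
                id=np.arange(world.next_id, world.next_id + n_new,
                             dtype=np.int64),
            )
            world.next_id += n_new
            world.divisions += np.bincount(cells.species[div_mask],
                                           minlength=pack.n_species)
            if mid is not None:
                for s in range(pack.n_species):
                    sp_div = div_mask & (cells.species == s)
                    world.band_divisions[s, 0] += int((sp_div & mid).sum())
                    world.band_divisions[s, 1] += int((sp_div & high).sum())
            cells.append(daughters)

        if mid is not None:
            for s in range(pack.n_species):
                sp = cells.species[:len(mid)] == s  # daughters not counted
                world.band_occupancy[s, 0] += int((sp & mid).sum())
                world.band_occupancy[s, 1] += int((sp & high).sum())

        # 5. death sweep
        dead = cells.energy <= 0.0
        if dead.any():
            world.deaths += np.bincount(cells.species[dead],
                                        minlength=pack.n_species)
            cells.keep(~dead)

    world.step += 1
    return world


@dataclass(frozen=True)
class SimulationResult:
    """Recorded output of one full run."""

    config: SimulationConfig
    timeseries: PopulationTimeSeries
    divisions: np.ndarray          # cumulative per species at each record
    deaths: np.ndarray             # cumulative per species at each record
    final_world: WorldState
    snapshots: dict = field(default_factory=dict)

    @property
    def species_names(self) -> tuple[str, ...]:
        return self.timeseries.species


def _snapshot(world: WorldState) -> dict:
    snap = {name: grid.values.copy() for name, grid in world.fields.items()}
    snap["cells"] = {
        "x": world.cells.x.copy(),
        "y": world.cells.y.copy(),
        "species": world.cells.species.copy(),
        "state": world.cells.state.copy(),
    }
    return snap


def run(config: SimulationConfig) -> SimulationResult:
    """Seed a world and run the full schedule, recording the time series
    every ``record_every`` steps (record 0 is the seeded state)."""
    world = seed_population(config)
    n_sp = len(config.species)

    steps_rec = [0]
    counts_rec = [world.cells.counts(n_sp)]
    gen_rec = [world.cells.mean_generation(n_sp)]
    div_rec = [world.divisions.copy()]
    death_rec = [world.deaths.copy()]
    snapshots = {}
    if 0 in config.snapshot_steps:
        snapshots[0] = _snapshot(world)

    for t in range(1, config.steps + 1):
        step(world)
        if t % config.record_every == 0:
            steps_rec.append(t)
            counts_rec.append(world.cells.counts(n_sp))
            gen_rec.append(world.cells.mean_generation(n_sp))
            div_rec.append(world.divisions.copy())
            death_rec.append(world.deaths.copy())
        if t in config.snapshot_steps:
            snapshots[t] = _snapshot(world)

    ts = PopulationTimeSeries(
        steps=np.asarray(steps_rec, dtype=np.int64),
        species=tuple(sp.name for sp in config.species),
        counts=np.stack(counts_rec, axis=1),
        mean_generation=np.stack(gen_rec, axis=1),
    )
    return SimulationResult(
        config=config, timeseries=ts,
        divisions=np.stack(div_rec, axis=1),
        deaths=np.stack(death_rec, axis=1),
        final_world=world, snapshots=snapshots,
    )
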