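"""Declarative run configuration: YAML schema, validation, echo.

A run config is a small YAML document with sections ``world``, ``fields``,
``species``, ``run`` and ``classify``.  Every invariant of the underlying
types (stability bound, rate ordering, threshold positivity, seeding
density cap) is checked at load time and violations are reported with the
path of the offending key.  Unknown keys are rejected.  The fully
materialised configuration — with every default filled in — can be echoed
back to YAML, and the echo reloads to an identical configuration, so every
run is self-describing.

Omitting the ``fields.antibiotic`` section disables the antibiotic field
entirely (valid only when no species produces or senses it).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .agents import SpeciesParams
from .engine import DEFAULT_FIELD_CONSTANTS, SimulationConfig
from .environment import ConfigurationError, FieldSpec, TrackGeometry
from .phenotype import StabilityCriterion
from .scenarios import PRESETS, get_preset

__all__ = ["load_config", "load_config_dict", "config_to_dict", "echo_config"]

_WORLD_KEYS = {"length_x", "width_y"}
_FIELD_KEYS = {"diffusion", "decay", "initial"}
_RUN_KEYS = {"steps", "seed", "record_every", "initial_counts",
             "seeding_region", "snapshot_steps", "density_cap", "ab_mode"}
_CLASSIFY_KEYS = {"window_generations", "relative_tolerance", "growth_factor",
                  "extinction_fraction", "collapse_fraction"}
_SPECIES_KEYS = {"preset", "overrides", "name"} | {
    f.name for f in dataclasses.fields(SpeciesParams)}
_TOP_KEYS = {"world", "fields", "species", "run", "classify"}
_FIELD_NAMES = ("nutrient", "signal", "factor", "antibiotic")


def _reject_unknown(mapping: dict, allowed: set, path: str) -> None:
    if not isinstance(mapping, dict):
        raise ConfigurationError(f"{path}: expected a mapping")
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigurationError(
            f"{path}: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}"
        )


def _parse_field(name: str, section: dict | None) -> FieldSpec:
    d, lam, init = DEFAULT_FIELD_CONSTANTS[name]
    if section is not None:
        _reject_unknown(section, _FIELD_KEYS, f"fields.{name}")
        d = section.get("diffusion", d)
        lam = section.get("decay", lam)
        init = section.get("initial", init)
    try:
        return FieldSpec(name=name, diffusion_coeff=float(d),
                         decay_rate=float(lam), initial_value=float(init))
    except ConfigurationError as exc:
        raise ConfigurationError(f"fields.{name}: {exc}") from None


def _parse_species(entry: dict, index: int) -> SpeciesParams:
    path = f"species[{index}]"
    _reject_unknown(entry, _SPECIES_KEYS, path)
    if "preset" in entry:
        base = get_preset(entry["preset"])
        overrides = dict(entry.get("overrides") or {})
        extra = set(entry) - {"preset", "overrides", "name"}
        for key in extra:
            overrides[key] = entry[key]
        if "name" in entry:
            overrides["name"] = entry["name"]
        bad = set(overrides) - {f.name for f in dataclasses.fields(SpeciesParams)}
        if bad:
            raise ConfigurationError(f"{path}.overrides: unknown {sorted(bad)}")
        try:
            return dataclasses.replace(base, **_tuplify(overrides))
        except ConfigurationError as exc:
            raise ConfigurationError(f"{path}: {exc}") from None
    if "name" not in entry:
        raise ConfigurationError(f"{path}: needs 'preset' or a full "
                                 f"definition with 'name'")
    kwargs = _tuplify({k: v for k, v in entry.items()})
    try:
        return SpeciesParams(**kwargs)
    except (ConfigurationError, TypeError) as exc:
        raise ConfigurationError(f"{path}: {exc}") from None


def _tuplify(kwargs: dict) -> dict:
    out = {}
    for k, v in kwargs.items():
        out[k] = tuple(v) if isinstance(v, list) else v
    return out


def load_config_dict(doc: dict) -> tuple[SimulationConfig, StabilityCriterion]:
    """Validate a parsed config document into runnable objects."""
    _reject_unknown(doc, _TOP_KEYS, "<root>")

    world = doc.get("world") or {}
    _reject_unknown(world, _WORLD_KEYS, "world")
    try:
        geometry = TrackGeometry(length_x=int(world.get("length_x", 400)),
                                 width_y=int(world.get("width_y", 20)))
    except ConfigurationError as exc:
        raise ConfigurationError(f"world: {exc}") from None

    fields_doc = doc.get("fields") or {}
    _reject_unknown(fields_doc, set(_FIELD_NAMES), "fields")
    field_specs = {}
    for name in ("nutrient", "signal", "factor"):
        field_specs[name] = _parse_field(name, fields_doc.get(name))
    if "antibiotic" in fields_doc or _species_use_ab(doc):
        field_specs["antibiotic"] = _parse_field(
            "antibiotic", fields_doc.get("antibiotic"))

    species_doc = doc.get("species")
    if not species_doc:
        raise ConfigurationError("species: at least one species required")
    species = tuple(_parse_species(e, i) for i, e in enumerate(species_doc))

    run_doc = doc.get("run") or {}
    _reject_unknown(run_doc, _RUN_KEYS, "run")
    counts = run_doc.get("initial_counts", [1000] * len(species))
    region = run_doc.get("seeding_region")
    config = SimulationConfig(
        geometry=geometry,
        species=species,
        initial_counts=tuple(int(c) for c in counts),
        field_specs=field_specs,
        seeding_region=tuple(float(x) for x in region) if region else None,
        steps=int(run_doc.get("steps", 5000)),
        rng_seed=int(run_doc.get("seed", 0)),
        record_every=int(run_doc.get("record_every", 10)),
        snapshot_steps=tuple(run_doc.get("snapshot_steps", ())),
        density_cap=float(run_doc.get("density_cap", 50.0)),
        ab_mode=run_doc.get("ab_mode", "suppress"),
    )

    classify_doc = doc.get("classify") or {}
    _reject_unknown(classify_doc, _CLASSIFY_KEYS, "classify")
    crit = StabilityCriterion(**{k: float(v) for k, v in classify_doc.items()})
    return config, crit


def _species_use_ab(doc: dict) -> bool:
    for entry in doc.get("species") or []:
        if not isinstance(entry, dict):
            continue
        if entry.get("ab_producer") or entry.get("ab_sensitive"):
            return True
        preset = entry.get("preset")
        if preset in PRESETS and (PRESETS[preset].ab_producer
                                  or PRESETS[preset].ab_sensitive):
            return True
    return False


def load_config(path: str | Path) -> tuple[SimulationConfig, StabilityCriterion]:
    """Load and validate a YAML run configuration file."""
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"{path}: parse error: {exc}") from None
    if doc is None:
        raise ConfigurationError(f"{path}: empty configuration")
    return load_config_dict(doc)


def config_to_dict(config: SimulationConfig,
                   crit: StabilityCriterion) -> dict:
    """Materialise a configuration (all defaults resolved) as a document."""
    fields = {}
    for name, spec in config.field_specs.items():
        fields[name] = {"diffusion": spec.diffusion_coeff,
                        "decay": spec.decay_rate,
                        "initial": spec.initial_value}
    species = []
    for sp in config.species:
        entry = dataclasses.asdict(sp)
        entry = {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in entry.items()}
        species.append(entry)
    return {
        "world": {"length_x": config.geometry.length_x,
                  "width_y": config.geometry.width_y},
        "fields": fields,
        "species": species,
        "run": {
            "steps": config.steps,
            "seed": config.rng_seed,
            "record_every": config.record_every,
            "initial_counts": list(config.initial_counts),
            "seeding_region": list(config.resolved_seeding_region()),
            "snapshot_steps": list(config.snapshot_steps),
            "density_cap": config.density_cap,
            "ab_mode": config.ab_mode,
        },
        "classify": dataclasses.asdict(crit),
    }


def echo_config(config: SimulationConfig, crit: StabilityCriterion,
                path: str | Path) -> None:
    """Write the materialised configuration next to a run's outputs."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config, crit), fh, sort_keys=False)
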