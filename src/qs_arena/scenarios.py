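"""Named competition experiments and their species presets.

The shipped presets cover the wild type, its threshold-modified variants
(elevated signal threshold T_S 10 -> 20, elevated factor threshold
T_F 10 -> 45, reduced division threshold T_D 12 -> 6, and their
combinations), an antibiotic-sensitive strain (ABS, slightly fitter at
T_D 11) and two antibiotic-producing eavesdroppers that trigger on the ABS
signal channel at T_AB 10 ("equal") or 30 ("high").  A signalling-deaf
control (``noQS``) and a non-secreting ``cheater`` complete the set.

Each registered scenario pairs two presets and carries the outcome label
the competition is expected to produce: exclusion of the slower divider
when thresholds are equal, exclusion of the higher-threshold species when
fitness is equal, coexistence when the fitter species also carries the
higher response threshold (self-restraint), and likewise for the
antibiotic pair once the eavesdropper's trigger threshold is raised above
the victim's own response threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd

from .agents import SpeciesParams
from .engine import (SimulationConfig, default_field_specs, run)
from .environment import TrackGeometry
from .phenotype import (ClassificationResult, PhenotypeLabel,
                        StabilityCriterion, classify)

__all__ = [
    "PRESETS",
    "SCENARIOS",
    "ScenarioSpec",
    "get_preset",
    "get_scenario",
    "run_scenario",
    "run_matrix",
    "MatrixResult",
    "check_self_viability",
]

_BASE = dict(
    division_threshold=12.0,
    signal_threshold=10.0,
    factor_threshold=10.0,
)

_ZERO3 = (0.0, 0.0, 0.0)

#: Antibiotic suppression threshold; the concentration of antibiotic at
#: which a sensitive cell is forced back to the ground state.  Chosen equal
#: to the wild-type factor threshold; exposed here and in run configs.
AB_KILL_THRESHOLD = 10.0

PRESETS: dict[str, SpeciesParams] = {}


def _preset(name: str, **kw) -> None:
    params = dict(_BASE)
    params.update(kw)
    PRESETS[name] = SpeciesParams(name=name, **params)


_preset("WT")
_preset("WT_slow", division_threshold=13.0)        # the "less fit" competitor
_preset("TS+", signal_threshold=20.0)
_preset("TF+", factor_threshold=45.0)
_preset("TS+TF+", signal_threshold=20.0, factor_threshold=45.0)
_preset("TS+TD-", signal_threshold=20.0, division_threshold=6.0)
_preset("TF+TD-", factor_threshold=45.0, division_threshold=6.0)
_preset("TS+TF+TD-", signal_threshold=20.0, factor_threshold=45.0,
        division_threshold=6.0)
_preset("noQS", signal_threshold=math.inf)          # deaf: never activates
_preset("cheater", signal_emission=_ZERO3, factor_emission=_ZERO3)
# antibiotic warfare: each strain signals on its own channel; the producer
# eavesdrops on the sensitive strain's channel
# The antibiotic pair signal at a lower per-cell rate than the baseline
# strain, so their channels report local density on a coarser scale and the
# eavesdropper's elevated trigger corresponds to genuine local dominance of
# the sensitive strain rather than its mere presence.
_AB_EMIT = (0.06, 0.08, 0.08)
_preset("ABS", division_threshold=11.0,
        signal_channel_emit="S_abs", signal_channel_sense="S_abs",
        signal_emission=_AB_EMIT,
        ab_sensitive=True, ab_kill_threshold=AB_KILL_THRESHOLD)
_preset("ABP_eq", signal_channel_emit="S_abp", signal_channel_sense="S_abp",
        signal_emission=_AB_EMIT,
        ab_producer=True, ab_trigger_channel="S_abs",
        ab_trigger_threshold=10.0)
_preset("ABP_high", signal_channel_emit="S_abp", signal_channel_sense="S_abp",
        signal_emission=_AB_EMIT,
        ab_producer=True, ab_trigger_channel="S_abs",
        ab_trigger_threshold=30.0)


def get_preset(name: str) -> SpeciesParams:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


@dataclass(frozen=True)
class ScenarioSpec:
    """One registered competition experiment."""

    name: str
    species: tuple[str, ...]
    expected_label: PhenotypeLabel
    expected_winner: str | None
    figure_ref: str


def _scen(name, species, label, winner, fig):
    return ScenarioSpec(name=name, species=species,
                        expected_label=PhenotypeLabel[label],
                        expected_winner=winner, figure_ref=fig)


SCENARIOS: dict[str, ScenarioSpec] = {s.name: s for s in [
    _scen("fig1a_noQS", ("noQS", "noQS2"), "NO_GROWTH", None, "1a"),
    _scen("fig1b_WTvsWT", ("WT", "WT2"), "COEXISTENCE", None, "1b"),
    _scen("fig1c_WTvsSlow", ("WT", "WT_slow"), "EXCLUSION", "WT", "1c"),
    _scen("fig1d_cheater", ("WT", "cheater"), "COLLAPSE", None, "1d"),
    _scen("fig2a", ("WT", "TS+"), "EXCLUSION", "WT", "2a"),
    _scen("fig2b", ("WT", "TF+"), "EXCLUSION", "WT", "2b"),
    _scen("fig2c", ("WT", "TS+TF+"), "EXCLUSION", "WT", "2c"),
    _scen("fig2d", ("WT", "TS+TD-"), "COEXISTENCE", None, "2d"),
    _scen("fig2e", ("WT", "TF+TD-"), "COEXISTENCE", None, "2e"),
    _scen("fig2f", ("WT", "TS+TF+TD-"), "COEXISTENCE", None, "2f"),
    _scen("fig3a", ("ABS", "ABP_eq"), "EXCLUSION", "ABP_eq", "3a"),
    _scen("fig3b", ("ABS", "ABP_high"), "COEXISTENCE", None, "3b"),
]}

#: Run scales: (cells per species, track length, steps).  The full scale is
#: the headline experiment (1000 + 1000 agents, 5000 steps); the reduced
#: scale reproduces the same qualitative outcomes at lower cost.
SCALES = {
    "full": (1000, 400, 5000),
    "reduced": (200, 200, 2500),
}


def _resolve_species(name: str) -> SpeciesParams:
    # "<preset>2" aliases let a preset compete against a copy of itself
    if name not in PRESETS and name.endswith("2") and name[:-1] in PRESETS:
        return replace(PRESETS[name[:-1]], name=name)
    return get_preset(name)


def get_scenario(name: str, scale: str = "reduced",
                 seed: int = 0, **config_overrides
                 ) -> tuple[SimulationConfig, ScenarioSpec]:
    """Materialise a registered scenario into a runnable config."""
    try:
        spec = SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None
    if scale not in SCALES:
        raise KeyError(f"unknown scale {scale!r}; available: {sorted(SCALES)}")
    count, length, steps = SCALES[scale]
    species = tuple(_resolve_species(n) for n in spec.species)
    uses_ab = any(sp.ab_producer or sp.ab_sensitive for sp in species)
    kw = dict(
        geometry=TrackGeometry(length_x=length, width_y=20),
        species=species,
        initial_counts=(count,) * len(species),
        field_specs=default_field_specs(include_antibiotic=uses_ab),
        steps=steps,
        rng_seed=seed,
    )
    kw.update(config_overrides)
    return SimulationConfig(**kw), spec


def run_scenario(name: str, scale: str = "reduced", seed: int = 0,
                 crit: StabilityCriterion = StabilityCriterion(),
                 **config_overrides):
    """Run one scenario and classify it; returns (result, classification)."""
    config, _ = get_scenario(name, scale=scale, seed=seed, **config_overrides)
    result = run(config)
    return result, classify(result.timeseries, crit)


@dataclass(frozen=True)
class MatrixResult:
    """Per-run labels and per-scenario majority verdicts."""

    runs: pd.DataFrame      # scenario, seed, label, winner, final counts
    verdicts: pd.DataFrame  # scenario, majority_label, agreement, expected, match


def run_matrix(names: list[str] | None = None,
               seeds: list[int] | None = None,
               scale: str = "reduced",
               crit: StabilityCriterion = StabilityCriterion()) -> MatrixResult:
    """Run every named scenario at every seed and take majority verdicts.

    The per-scenario verdict is the modal label across seeds (the winner is
    attached for exclusion verdicts); ``agreement`` is the fraction of
    seeds voting for the modal label.
    """
    if names is None:
        names = list(SCENARIOS)
    if seeds is None:
        seeds = [1, 2, 3, 4, 5]
    rows = []
    for name in names:
        for seed in seeds:
            result, cls = run_scenario(name, scale=scale, seed=seed, crit=crit)
            counts = result.timeseries.counts[:, -1]
            rows.append({
                "scenario": name,
                "seed": seed,
                "label": cls.label.value,
                "winner": cls.winner,
                "final_counts": tuple(int(c) for c in counts),
            })
    runs = pd.DataFrame(rows, columns=["scenario", "seed", "label", "winner",
                                       "final_counts"])
    verdict_rows = []
    for name in names:
        sub = runs[runs["scenario"] == name]
        if len(sub) == 0:
            continue
        modal = sub["label"].mode().iloc[0]
        agreement = float((sub["label"] == modal).mean())
        winner = None
        if modal == PhenotypeLabel.EXCLUSION.value:
            winners = sub.loc[sub["label"] == modal, "winner"]
            winner = winners.mode().iloc[0]
        spec = SCENARIOS[name]
        expected = spec.expected_label.value
        match = modal == expected and (
            spec.expected_winner is None or winner == spec.expected_winner)
        verdict_rows.append({
            "scenario": name, "majority_label": modal, "winner": winner,
            "agreement": agreement, "expected": expected, "match": match,
        })
    verdicts = pd.DataFrame(
        verdict_rows, columns=["scenario", "majority_label", "winner",
                               "agreement", "expected", "match"])
    return MatrixResult(runs=runs, verdicts=verdicts)


def check_self_viability(preset_name: str, scale: str = "reduced",
                         seed: int = 0,
                         crit: StabilityCriterion = StabilityCriterion()
                         ) -> ClassificationResult:
    """Grow one preset alone and classify the outcome.

    Viable presets (everything except the deaf control and the cheater)
    are expected to reach a stable plateau (``STABLE_ALONE``).
    """
    sp = get_preset(preset_name)
    count, length, steps = SCALES[scale]
    count *= 2  # grown alone with the full inoculum of a competition run
    uses_ab = sp.ab_producer or sp.ab_sensitive
    config = SimulationConfig(
        geometry=TrackGeometry(length_x=length, width_y=20),
        species=(sp,),
        initial_counts=(count,),
        field_specs=default_field_specs(include_antibiotic=uses_ab),
        steps=SCALES[scale][2],
        rng_seed=seed,
    )
    result = run(config)
    return classify(result.timeseries, crit)
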