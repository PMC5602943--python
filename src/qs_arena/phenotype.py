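"""Outcome taxonomy: turning population trajectories into labels.

A competition run ends in one of four community-level outcomes:

* ``NO_GROWTH``   — the community never grew (cells stayed dormant, ate the
  local nutrient and starved out).
* ``COEXISTENCE`` — both species persist and the community sits on a stable
  plateau at the carrying capacity of the track.
* ``EXCLUSION``   — one species is driven to (near-)extinction while the
  other plateaus: classical competitive exclusion.
* ``COLLAPSE``    — the community grew and then crashed (typical for
  cheater invasion).

``STABLE_ALONE`` is the single-species analogue of coexistence, used by
the self-viability checks of the scenario presets.

"Stable" is operationalised as: over the trailing window in which the mean
generation index advanced by at least ``window_generations`` (default 20),
the population count stays within ``relative_tolerance`` (default 10%,
max-min over mean).  The window is measured in generations via the run's
own mean-generation trajectory, not a fixed steps-per-generation constant,
so slow- and fast-dividing communities are judged on the same biological
timescale.  All numeric cutoffs are explicit fields of
:class:`StabilityCriterion` and are echoed into every result.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .environment import ConfigurationError

__all__ = [
    "PopulationTimeSeries",
    "PhenotypeLabel",
    "StabilityCriterion",
    "ClassificationResult",
    "is_stable",
    "classify",
    "active_zone",
    "generations_elapsed",
]

log = logging.getLogger(__name__)


class PhenotypeLabel(str, enum.Enum):
    NO_GROWTH = "NO_GROWTH"
    COEXISTENCE = "COEXISTENCE"
    EXCLUSION = "EXCLUSION"
    COLLAPSE = "COLLAPSE"
    STABLE_ALONE = "STABLE_ALONE"  # single-species runs only


@dataclass(frozen=True)
class PopulationTimeSeries:
    """Per-record species counts and mean generation indices.

    ``counts`` and ``mean_generation`` have shape (n_species, n_records);
    ``mean_generation`` is NaN at records where a species has no living
    cells.
    """

    steps: np.ndarray
    species: tuple[str, ...]
    counts: np.ndarray
    mean_generation: np.ndarray

    def __post_init__(self) -> None:
        n_sp, n_rec = np.asarray(self.counts).shape
        if len(self.species) != n_sp:
            raise ValueError("species names do not match counts rows")
        if self.steps.shape != (n_rec,) or self.mean_generation.shape != (n_sp, n_rec):
            raise ValueError("inconsistent time-series shapes")
        if n_rec == 0:
            raise ValueError("time series must have at least one record")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")
        if (np.diff(self.steps) <= 0).any():
            raise ValueError("steps must be strictly increasing")

    @property
    def n_records(self) -> int:
        return self.steps.size

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def pooled_generation(self) -> np.ndarray:
        """Count-weighted mean generation over all species, per record.

        Records with no living cells carry the last nonempty value forward
        (0 before any cell ever lived).
        """
        totals = self.totals()
        gen = np.where(np.isnan(self.mean_generation), 0.0, self.mean_generation)
        weighted = (gen * self.counts).sum(axis=0)
        pooled = np.zeros_like(weighted)
        last = 0.0
        for i in range(totals.size):
            if totals[i] > 0:
                last = weighted[i] / totals[i]
            pooled[i] = last
        return pooled

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns step, species, count, mean_generation."""
        rows = []
        for si, name in enumerate(self.species):
            rows.append(pd.DataFrame({
                "step": self.steps,
                "species": name,
                "count": self.counts[si],
                "mean_generation": self.mean_generation[si],
            }))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PopulationTimeSeries":
        species = tuple(dict.fromkeys(frame["species"]))
        steps = np.sort(frame["step"].unique())
        counts = np.zeros((len(species), steps.size), dtype=np.int64)
        gens = np.full((len(species), steps.size), np.nan)
        step_idx = {s: i for i, s in enumerate(steps)}
        for si, name in enumerate(species):
            sub = frame[frame["species"] == name]
            for st, c, g in zip(sub["step"], sub["count"], sub["mean_generation"]):
                counts[si, step_idx[st]] = c
                gens[si, step_idx[st]] = g
        return cls(steps=steps.astype(np.int64), species=species,
                   counts=counts, mean_generation=gens)


@dataclass(frozen=True)
class StabilityCriterion:
    """Numeric cutoffs operationalising the qualitative outcome taxonomy."""

    window_generations: float = 20.0
    relative_tolerance: float = 0.10
    growth_factor: float = 2.0
    extinction_fraction: float = 0.01
    collapse_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.window_generations <= 0:
            raise ConfigurationError("window_generations must be > 0")
        if not (0 < self.relative_tolerance < 1):
            raise ConfigurationError("relative_tolerance must be in (0, 1)")
        if self.growth_factor <= 1:
            raise ConfigurationError("growth_factor must be > 1")
        if not (0 < self.extinction_fraction < 0.5):
            raise ConfigurationError("extinction_fraction must be in (0, 0.5)")
        if not (0 < self.collapse_fraction < 1):
            raise ConfigurationError("collapse_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ClassificationResult:
    label: PhenotypeLabel
    winner: str | None = None
    loser: str | None = None
    stable: bool = False
    window_reached: bool = True
    metrics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "label": self.label.value,
            "winner": self.winner,
            "loser": self.loser,
            "stable": self.stable,
            "window_reached": self.window_reached,
        }
        d.update(self.metrics)
        return d


def _stability(ts: PopulationTimeSeries, series: np.ndarray,
               crit: StabilityCriterion) -> tuple[bool, bool]:
    """(stable, window_reached) of ``series`` over the trailing window in
    which the pooled mean generation advanced by ``window_generations``."""
    pooled = ts.pooled_generation()
    g_end = pooled[-1]
    eligible = np.flatnonzero(g_end - pooled >= crit.window_generations)
    if eligible.size == 0:
        return False, False
    start = eligible[-1]  # shortest trailing window covering the advance
    window = series[start:]
    mean = window.mean()
    if mean <= 0:
        return False, True
    spread = (window.max() - window.min()) / mean
    return bool(spread <= crit.relative_tolerance), True


def is_stable(ts: PopulationTimeSeries,
              crit: StabilityCriterion = StabilityCriterion(),
              species: str | None = None) -> bool:
    """True iff the population plateaued for the stability window.

    By default the total count is judged; pass ``species`` to judge one
    species' count (used for the survivor in exclusion calls).  Runs too
    short for the generation window are never stable.
    """
    if species is None:
        series = ts.totals()
    else:
        series = ts.counts[ts.species.index(species)]
    stable, _ = _stability(ts, series.astype(float), crit)
    return stable


def classify(ts: PopulationTimeSeries,
             crit: StabilityCriterion = StabilityCriterion()) -> ClassificationResult:
    """Assign exactly one outcome label to a finished run.

    Evaluation order is fixed: no-growth, then collapse, then exclusion /
    coexistence (both of which additionally require stability); anything
    that grew but neither stabilised nor cleanly excluded is a collapse.
    """
    totals = ts.totals().astype(float)
    initial = totals[0]
    peak = totals.max()
    final = totals[-1]
    metrics: dict = {
        "initial_total": int(initial),
        "peak_total": int(peak),
        "final_total": int(final),
        "criteria": asdict(crit),
    }

    if peak == 0 or peak < crit.growth_factor * initial:
        return ClassificationResult(PhenotypeLabel.NO_GROWTH, metrics=metrics)
    if final <= crit.collapse_fraction * peak:
        return ClassificationResult(PhenotypeLabel.COLLAPSE, metrics=metrics)

    if len(ts.species) == 1:
        stable, reached = _stability(ts, totals, crit)
        if stable:
            return ClassificationResult(PhenotypeLabel.STABLE_ALONE,
                                        stable=True, window_reached=reached,
                                        metrics=metrics)
        # grew, did not crash below the collapse cutoff, but no plateau:
        # not a viable community under the stability criterion
        return ClassificationResult(PhenotypeLabel.COLLAPSE,
                                    window_reached=reached, metrics=metrics)

    shares = ts.counts[:, -1] / final
    metrics["final_shares"] = {name: float(s)
                               for name, s in zip(ts.species, shares)}
    extinct = shares <= crit.extinction_fraction
    if extinct.sum() == 1:
        loser_i = int(np.flatnonzero(extinct)[0])
        winner_i = 1 - loser_i
        winner = ts.species[winner_i]
        stable, reached = _stability(
            ts, ts.counts[winner_i].astype(float), crit)
        if stable:
            return ClassificationResult(
                PhenotypeLabel.EXCLUSION, winner=winner,
                loser=ts.species[loser_i], stable=True,
                window_reached=reached, metrics=metrics)
    if not extinct.any():
        stable, reached = _stability(ts, totals, crit)
        if stable:
            return ClassificationResult(PhenotypeLabel.COEXISTENCE,
                                        stable=True, window_reached=reached,
                                        metrics=metrics)
    return ClassificationResult(PhenotypeLabel.COLLAPSE, metrics=metrics)


def active_zone(world, params) -> tuple[int, int] | None:
    """The swarming region of the track for one species.

    Returns the longest contiguous run of columns whose column-mean signal
    (on the species' sensed channel) is >= T_S *and* whose column-mean
    factor is >= T_F, as an inclusive column interval, or None if no column
    qualifies.  Ties go to the leftmost run.
    """
    signal = world.fields[f"signal:{params.signal_channel_sense}"].values
    factor = world.fields["factor"].values
    mask = ((signal.mean(axis=0) >= params.signal_threshold)
            & (factor.mean(axis=0) >= params.factor_threshold))
    if not mask.any():
        return None
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2] - 1
    best = int(np.argmax(ends - starts))
    return int(starts[best]), int(ends[best])


def generations_elapsed(ts: PopulationTimeSeries) -> float:
    """Count-weighted mean generation index of living cells at the end.

    If the final record is empty the last nonempty record is used instead
    (logged as a warning); 0.0 if no cell ever lived.
    """
    totals = ts.totals()
    if totals[-1] == 0:
        log.warning("final record empty; reporting generations at the last "
                    "nonempty record")
    return float(ts.pooled_generation()[-1])
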