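"""Diffusible chemical fields on a half-closed 2D track.

The arena is a longitudinal lattice: the x axis runs along the track, the
y axis across it.  The x = 0 end is closed (no-flux), the x = L end is open
(absorbing: material diffusing past it is lost), and the two sides wrap
periodically.  This mimics one dendrite of a colony growing outward on a
plate.  Four kinds of material live on the lattice: an immobile nutrient,
one or more diffusible quorum-sensing signal channels, a diffusible
cooperation factor (public good), and optionally a diffusible antibiotic.

Agents interact with fields only through the lattice cell that contains
their continuous position: :func:`deposit`, :func:`sample` and
:func:`consume` all use nearest-cell (floor) indexing, so a value deposited
at a point is recovered exactly by sampling the same point.

Diffusion uses an explicit forward-time centred-space 5-point stencil with
``dt = 1`` step and ``dx = 1`` lattice unit; the stability bound
``D <= 0.25`` is enforced when a :class:`FieldSpec` is constructed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrackGeometry",
    "FieldSpec",
    "FieldGrid",
    "diffuse_decay",
    "deposit",
    "sample",
    "consume",
]

#: Largest diffusion coefficient the explicit stencil tolerates (D*dt/dx^2).
STABILITY_LIMIT = 0.25

_FIELD_KINDS = ("nutrient", "signal", "factor", "antibiotic")


class ConfigurationError(ValueError):
    """A simulation parameter violates one of its invariants."""


@dataclass(frozen=True)
class TrackGeometry:
    """Lattice geometry of the longitudinal track.

    Parameters
    ----------
    length_x:
        Number of lattice columns along the track axis (the long dimension).
    width_y:
        Number of lattice rows across the track.
    cell_size:
        Spatial unit; the model is dimensionless so this is 1.0.
    closed_end:
        Testing aid: when True the open end at x = L is masked and behaves
        like the closed end, giving a fully conservative domain.  Production
        runs leave this False.

    Boundary kinds are fixed: no-flux at x = 0, absorbing at x = L (unless
    masked), periodic in y.  No other combination is constructible.
    """

    length_x: int
    width_y: int
    cell_size: float = 1.0
    closed_end: bool = False

    def __post_init__(self) -> None:
        if not (self.length_x >= self.width_y >= 1):
            raise ConfigurationError(
                f"track must be longitudinal: need length_x >= width_y >= 1, "
                f"got {self.length_x} x {self.width_y}"
            )
        if self.cell_size != 1.0:
            raise ConfigurationError("cell_size is fixed at 1.0")

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape (rows, columns) = (width_y, length_x)."""
        return (self.width_y, self.length_x)

    def contains(self, x: float, y: float) -> bool:
        return 0.0 <= x < self.length_x and 0.0 <= y < self.width_y

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """(row, column) of the lattice cell containing a continuous point."""
        if not self.contains(x, y):
            raise ValueError(f"position ({x}, {y}) outside track")
        return int(y), int(x)


@dataclass(frozen=True)
class FieldSpec:
    """Per-field constants: diffusivity, first-order decay, initial level.

    ``diffusion_coeff`` is the per-step diffusivity D in lattice-units^2 per
    step; ``decay_rate`` is the fraction lost per step (applied after the
    diffusion half of the update).
    """

    name: str
    diffusion_coeff: float = 0.0
    decay_rate: float = 0.0
    initial_value: float = 0.0

    def __post_init__(self) -> None:
        kind = self.name.split(":", 1)[0]
        if kind not in _FIELD_KINDS:
            raise ConfigurationError(
                f"field name {self.name!r} must be one of {_FIELD_KINDS} "
                f"(signal channels as 'signal:<id>')"
            )
        if not (0.0 <= self.diffusion_coeff <= STABILITY_LIMIT):
            raise ConfigurationError(
                f"field {self.name!r}: diffusion_coeff {self.diffusion_coeff} "
                f"violates explicit-scheme stability bound 0 <= D <= {STABILITY_LIMIT}"
            )
        if not (0.0 <= self.decay_rate < 1.0):
            raise ConfigurationError(
                f"field {self.name!r}: decay_rate must be in [0, 1), "
                f"got {self.decay_rate}"
            )
        if self.initial_value < 0.0:
            raise ConfigurationError(
                f"field {self.name!r}: initial_value must be >= 0"
            )


@dataclass
class FieldGrid:
    """One concentration lattice plus its spec.  Values are never negative."""

    spec: FieldSpec
    values: np.ndarray

    @classmethod
    def uniform(cls, spec: FieldSpec, geometry: TrackGeometry) -> "FieldGrid":
        vals = np.full(geometry.shape, float(spec.initial_value))
        return cls(spec=spec, values=vals)

    def total_mass(self) -> float:
        return float(self.values.sum())

    def copy(self) -> "FieldGrid":
        return FieldGrid(spec=self.spec, values=self.values.copy())


def diffuse_decay(grid: FieldGrid, geometry: TrackGeometry) -> FieldGrid:
    """One explicit diffusion step followed by first-order decay.

    Boundary handling: mirror ghost at x = 0 (no flux), zero ghost at x = L
    (absorbing, unless ``geometry.closed_end``), periodic wrap in y.  Returns
    a new grid; the input is not modified.
    """
    v = grid.values
    D = grid.spec.diffusion_coeff
    lam = grid.spec.decay_rate
    if D == 0.0:
        out = v * (1.0 - lam)
        return FieldGrid(spec=grid.spec, values=out)

    up = np.roll(v, -1, axis=0)
    down = np.roll(v, 1, axis=0)
    left = np.empty_like(v)
    left[:, 1:] = v[:, :-1]
    left[:, 0] = v[:, 0]  # mirror ghost: zero flux through the closed end
    right = np.empty_like(v)
    right[:, :-1] = v[:, 1:]
    right[:, -1] = v[:, -1] if geometry.closed_end else 0.0  # absorbing ghost

    out = v + D * (up + down + left + right - 4.0 * v)
    if lam != 0.0:
        out *= 1.0 - lam
    np.maximum(out, 0.0, out=out)
    return FieldGrid(spec=grid.spec, values=out)


def deposit(grid: FieldGrid, geometry: TrackGeometry,
            position: tuple[float, float], amount: float) -> None:
    """Add ``amount`` to the lattice cell containing ``position`` (in place)."""
    if amount < 0.0:
        raise ValueError("deposit amount must be >= 0")
    iy, ix = geometry.cell_index(*position)
    grid.values[iy, ix] += amount


def sample(grid: FieldGrid, geometry: TrackGeometry,
           position: tuple[float, float]) -> float:
    """Concentration of the lattice cell containing ``position``."""
    iy, ix = geometry.cell_index(*position)
    return float(grid.values[iy, ix])


def consume(grid: FieldGrid, geometry: TrackGeometry,
            position: tuple[float, float], requested: float) -> float:
    """Remove up to ``requested`` from the containing cell; return the amount
    actually removed.  The cell value never goes negative."""
    if requested < 0.0:
        raise ValueError("requested amount must be >= 0")
    iy, ix = geometry.cell_index(*position)
    available = grid.values[iy, ix]
    got = requested if requested <= available else available
    grid.values[iy, ix] = available - got
    return float(got)
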