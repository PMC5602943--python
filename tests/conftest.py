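import numpy as np
import pytest

from qs_arena.agents import SpeciesParams
from qs_arena.engine import SimulationConfig, default_field_specs
from qs_arena.environment import FieldGrid, FieldSpec, TrackGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def closed_geometry():
    """Small fully conservative test domain (open end masked)."""
    return TrackGeometry(length_x=21, width_y=21, closed_end=True)


@pytest.fixture
def track():
    return TrackGeometry(length_x=60, width_y=10)


@pytest.fixture
def wt():
    return SpeciesParams(name="WT")


def make_grid(geometry, diffusion=0.0, decay=0.0, initial=0.0,
              name="factor"):
    spec = FieldSpec(name=name, diffusion_coeff=diffusion, decay_rate=decay,
                     initial_value=initial)
    return FieldGrid.uniform(spec, geometry)


def tiny_config(species, counts=(40, 40), length=40, width=8, steps=60,
                seed=0, nutrient=200.0, **kw):
    """A deliberately small world for fast engine-level tests."""
    uses_ab = any(sp.ab_producer or sp.ab_sensitive for sp in species)
    fs = kw.pop("field_specs", None) or default_field_specs(
        include_antibiotic=uses_ab, nutrient={"initial_value": nutrient})
    return SimulationConfig(
        geometry=TrackGeometry(length_x=length, width_y=width),
        species=tuple(species),
        initial_counts=tuple(counts[:len(species)]),
        field_specs=fs,
        steps=steps,
        rng_seed=seed,
        **kw,
    )
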