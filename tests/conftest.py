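import numpy as np
import pytest

from cytoprofile.features import build_schema
from cytoprofile.synthesize import (PhenotypeArchetype, SceneConfig,
                                    default_archetypes, sample_cell_geometry)


@pytest.fixture(scope="session")
def archetypes():
    return default_archetypes()


@pytest.fixture(scope="session")
def schema():
    return build_schema()


@pytest.fixture(scope="session")
def geometry_draws(archetypes):
    """500 placement-free geometry draws per phenotype (shared: population
    statistics are expensive to resample per test)."""
    rng = np.random.default_rng(12345)
    out = {}
    for name, arch in archetypes.items():
        draws = [sample_cell_geometry(arch, rng) for _ in range(500)]
        out[name] = {
            "cell_area": np.array([g.cell_area for g in draws], dtype=float),
            "nucleus_area": np.array([g.nucleus_area for g in draws],
                                     dtype=float),
        }
    return out


def make_disc_archetype(radius: float, nucleus_radius: float = None,
                        **overrides) -> PhenotypeArchetype:
    """Deterministic circular archetype for analytic oracles."""
    if nucleus_radius is None:
        nucleus_radius = max(2.0, radius / 3)
    kwargs = dict(name="M1", cell_radius_mean=radius, cell_radius_sd=0.0,
                  elongation_mean=1.0, elongation_sd=0.0,
                  boundary_irregularity=0.0,
                  nucleus_radius_mean=nucleus_radius, nucleus_radius_sd=0.0,
                  nucleus_offset_frac=0.0)
    kwargs.update(overrides)
    return PhenotypeArchetype(**kwargs)


def quiet_scene(**overrides) -> SceneConfig:
    """Noise-free, jitter-free scene configuration for exact oracles."""
    kwargs = dict(gaussian_noise_sd=0.0, poisson_noise=False,
                  staining_cv=0.0, texture_jitter=0.0, outlier_frac=0.0)
    kwargs.update(overrides)
    return SceneConfig(**kwargs)
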