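"""Shared fixtures: small, fast synthetic configurations."""

from __future__ import annotations

import numpy as np
import pytest

from sersquant import GeneratorConfig, generate_dataset

#: The eight carbendazim SERS band centers (cm^-1).
BAND_CENTERS = np.array([629.0, 736.0, 770.0, 1007.0, 1227.0, 1271.0, 1462.0, 1521.0])


def small_config(**overrides) -> GeneratorConfig:
    """A reduced-grid configuration for fast unit tests (peaks that fit the
    short grid, fewer replicates)."""
    defaults = dict(
        grid_min=400.0,
        grid_max=1700.0,
        n_points=400,
        replicates=6,
        seed=11,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def noise_free_config(**overrides) -> GeneratorConfig:
    """All stochastic components switched off: deterministic spectra."""
    defaults = dict(
        baseline_scale=0.0,
        background_sd=0.0,
        sigma_a=0.0,
        sigma_b=0.0,
        noise_sd=0.0,
    )
    defaults.update(overrides)
    return small_config(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config())


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()
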