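"""Shared fixtures: small synthetic worlds reused across test modules."""

import pytest

from proglacial import WorldConfig, generate_world


def small_config(**overrides) -> WorldConfig:
    base = dict(
        n_glaciers=6,
        stations_per_glacier=4,
        n_months=12,
        dem_size=24,
        seed=11,
    )
    base.update(overrides)
    return WorldConfig(**base)


@pytest.fixture(scope="session")
def small_world():
    """Six glaciers x four stations x one year, with noise."""
    return generate_world(small_config())


@pytest.fixture(scope="session")
def noise_free_world():
    """Same layout but residual_sd = 0 and a vanishing snow-free diurnal
    amplitude, so monthly means and snow states are exact."""
    return generate_world(
        small_config(
            seed=12,
            residual_sd=0.0,
            diurnal_amplitude_snowfree=1e-9,
            diurnal_amplitude_snow=0.0,
        )
    )


@pytest.fixture(scope="session")
def snowgap_world():
    """Noise-free world with the default (0.4, 10) °C diurnal-range gap,
    full satellite coverage: snow detection must be exact."""
    return generate_world(
        small_config(seed=13, residual_sd=0.0, cloud_missing_prob=0.0)
    )
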