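import numpy as np
import pytest

from dropfreeze import (
    DropletSpec,
    INPSpectrum,
    SpectrumComponent,
    SpectrumModel,
    TemperatureProtocol,
    default_background,
)


@pytest.fixture
def protocol() -> TemperatureProtocol:
    """Standard screening ramp: -2 to -28 °C in 2 °C steps."""
    return TemperatureProtocol.default()


@pytest.fixture
def droplet() -> DropletSpec:
    return DropletSpec(volume_ul=20.0, cells_per_ul=100.0)


@pytest.fixture
def background() -> SpectrumComponent:
    return default_background()


def make_spectrum(
    protocol: TemperatureProtocol,
    values,
    flags,
    droplet: DropletSpec | None = None,
    n_wells: int = 32,
    replicate_id: str = "r1",
    treatment: str = "untreated",
) -> INPSpectrum:
    """Hand-build a spectrum with degenerate confidence bounds for tests
    that only exercise flags and point estimates."""
    droplet = droplet or DropletSpec(volume_ul=20.0, cells_per_ul=100.0)
    return INPSpectrum(
        protocol=protocol,
        values=tuple(values),
        ci_low=tuple(values),
        ci_high=tuple(values),
        flags=tuple(flags),
        unit=droplet.unit,
        n_wells=n_wells,
        droplet=droplet,
        sample_id="S",
        treatment=treatment,
        replicate_id=replicate_id,
    )
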