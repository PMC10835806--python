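import numpy as np
import pytest

from cpdus.synthetic_flora import render_sample, sample_variety_specs


@pytest.fixture(scope="session")
def specs6():
    """Six variety archetypes covering all three colour groups."""
    return sample_variety_specs(6, 7)


@pytest.fixture(scope="session")
def rendered(specs6):
    """One rendered flower per archetype, alternating backgrounds."""
    rng = np.random.default_rng(0)
    return [
        render_sample(spec, rng, size=256, background="dark" if i % 2 == 0 else "light")
        for i, spec in enumerate(specs6)
    ]


@pytest.fixture(scope="session")
def disk_mask():
    """Digital disk of radius 100 on a 256x256 canvas."""
    yy, xx = np.mgrid[0:256, 0:256]
    return (yy - 128) ** 2 + (xx - 128) ** 2 <= 100**2
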