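import numpy as np
import pytest

import herpranges as hr


@pytest.fixture(scope="session")
def landscape():
    """Mid-size habitat raster shared across tests."""
    return hr.generate_fbm_landscape(256, 256, 10.0, hurst=0.5, seed=42)


@pytest.fixture(scope="session")
def year_tracks(landscape):
    """One full-year track per archetype (fixed seeds)."""
    return {
        sp: hr.simulate_individual(
            hr.archetype_presets(sp), landscape, duration_days=365, seed=100 + sp
        )
        for sp in (1, 2, 3)
    }


@pytest.fixture(scope="session")
def short_track(landscape):
    """A 30-day species-1 track for cheaper tests."""
    return hr.simulate_individual(
        hr.archetype_presets(1), landscape, duration_days=30, seed=7
    )
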