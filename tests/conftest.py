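import numpy as np
import pytest

import spadinv as sv


@pytest.fixture(scope="session")
def grid() -> sv.WavelengthGrid:
    return sv.WavelengthGrid.default()


@pytest.fixture(scope="session")
def default_samples() -> sv.SampleSet:
    """The default synthetic sample set (400 samples, seed 0)."""
    return sv.generate_sample_set()


@pytest.fixture(scope="session")
def study_samples() -> sv.SampleSet:
    """Study-scale sample set: 1,200 samples for an 800/400 split."""
    return sv.generate_sample_set(sv.GeneratorConfig(n_samples=1200, seed=0))


@pytest.fixture(scope="session")
def default_spa(default_samples) -> sv.SPAResult:
    return sv.spa_select(
        default_samples.reflectance, default_samples.spad,
        sv.SPAConfig(max_k=10), grid=default_samples.grid,
    )
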