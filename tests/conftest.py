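import numpy as np
import pandas as pd
import pytest

from raredrop import synthgen


@pytest.fixture(scope="session")
def ndmm_sample():
    """One NDMM-preset sample: (events, truth), 2000 background cells."""
    spec = synthgen.SampleSpec.from_preset("NDMM", n_background_cells=2000)
    return synthgen.generate_event_table(spec, seed=11)


@pytest.fixture(scope="session")
def curation_training():
    return synthgen.generate_curation_set(n_events=600, artifact_fraction=0.3, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def gaussian_events(n: int, d: int = 5, seed: int = 0) -> pd.DataFrame:
    """Featureless null: iid standard-normal feature table."""
    r = np.random.default_rng(seed)
    return pd.DataFrame(r.normal(size=(n, d)), columns=[f"f{i}" for i in range(d)])
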