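import numpy as np
import pytest

import eegemo as E
from eegemo.synth import NO_ARTIFACTS, default_profiles


@pytest.fixture(scope="session")
def baseline_epochs() -> E.EpochSet:
    """Clean preprocessed baseline recording (60 s, 30 epochs)."""
    rec = E.make_recording(
        default_profiles()["baseline"], NO_ARTIFACTS, "P01", "baseline",
        fs=256, duration=60, seed=11,
    )
    return E.preprocess_recording(rec)


@pytest.fixture(scope="session")
def small_cohort() -> list[E.Recording]:
    """8 participants x 4 conditions, 40 s each, artifact-free."""
    return E.make_cohort(
        default_profiles(), NO_ARTIFACTS, n_participants=8, duration=40, seed=21
    )


@pytest.fixture(scope="session")
def small_table(small_cohort):
    """Feature table extracted from the small cohort (32 rows x 54 features)."""
    return E.extract_table([E.preprocess_recording(r) for r in small_cohort])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
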