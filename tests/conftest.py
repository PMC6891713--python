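import numpy as np
import pytest

from fallrnn import GeneratorProfile, SegmentationConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_profile():
    """A quick 3-subject cohort for pipeline tests."""
    return GeneratorProfile(
        n_adults=2, n_elderly=1, recording_duration_s=30.0, seed=7
    )


@pytest.fixture(scope="session")
def small_dataset(small_profile):
    return generate_dataset(small_profile)


@pytest.fixture(scope="session")
def small_blocks(small_dataset):
    """Width-32 (25 Hz) blocks from the small cohort."""
    from fallrnn import build_block_datasets

    return build_block_datasets(small_dataset, SegmentationConfig(), levels=3)[3]
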