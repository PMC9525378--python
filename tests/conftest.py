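import pandas as pd
import pytest

from penergetics.simulate import SyntheticStudyConfig, generate_study


@pytest.fixture(scope="session")
def default_config() -> SyntheticStudyConfig:
    return SyntheticStudyConfig(rng_seed=20200127)


@pytest.fixture(scope="session")
def default_tables(default_config) -> dict[str, pd.DataFrame]:
    return generate_study(default_config)


@pytest.fixture(scope="session")
def zero_noise_tables(default_config) -> dict[str, pd.DataFrame]:
    return generate_study(default_config.zero_noise())
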