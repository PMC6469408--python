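import numpy as np
import pandas as pd
import pytest

from hmscreen import datasets


@pytest.fixture(scope="session")
def study_flags() -> pd.DataFrame:
    """Misregulation flags of the published expression screen."""
    return datasets.load_flags()


@pytest.fixture(scope="session")
def ga22690_positions() -> list[int]:
    """TSS positions of the 15 confirmed fixed changes upstream of GA22690."""
    return [p for p, *_ in datasets.FIXED_SUBSTITUTIONS["GA22690"]]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
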