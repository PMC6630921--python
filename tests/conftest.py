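import numpy as np
import pandas as pd
import pytest

import thermotype as tt


@pytest.fixture(scope="session")
def reference_env() -> pd.DataFrame:
    """The packaged ten-environment summary table."""
    return tt.load_reference_environments()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


@pytest.fixture()
def flat_image() -> tt.ThermalImage:
    """Constant 22 °C field, 120x120."""
    return tt.ThermalImage(np.full((120, 120), 22.0))
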