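import numpy as np
import pandas as pd
import pytest

from rhythmomics.simulate import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def study_dataset():
    """One study-condition dataset: 120 features, CV vs ABX, 12 h shift."""
    spec = SyntheticSpec(seed=20260927)
    return (spec, *generate_dataset(spec))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_table():
    """Tiny hand-checkable feature table (3 features x 4 samples)."""
    return pd.DataFrame(
        [[1.0, 5.0, 2.0, 16.0],
         [4.0, 5.0, 2.0, 4.0],
         [16.0, 5.0, 2.0, 1.0]],
        index=["f1", "f2", "f3"],
        columns=["s1", "s2", "s3", "s4"],
    )
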