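import numpy as np
import pandas as pd
import pytest

from cpgclock.data_io import MethylationMatrix
from cpgclock.synthetic import SyntheticSpec, generate_clock_dataset

# The documented synthetic study conditions used throughout the recovery
# tests: 200 samples x 1000 CpGs with 5 planted age-CpGs of slope
# +/-0.004 beta/year, noise SD 0.03, ages 20-90.
ACCEPTANCE_SPEC = dict(
    n_samples=200, n_cpgs=1000, n_informative=5,
    effect_sizes=0.004, noise_sd=0.03, age_range=(20.0, 90.0),
)


def planted_dataset(seed: int, **overrides):
    """One draw of the documented planted-signal study conditions."""
    params = {**ACCEPTANCE_SPEC, **overrides}
    return generate_clock_dataset(SyntheticSpec(seed=seed, **params))


@pytest.fixture
def toy_matrix() -> MethylationMatrix:
    """5 samples x 3 CpGs, hand-checkable, ages 20..60."""
    betas = pd.DataFrame(
        {
            "cgA": [0.10, 0.22, 0.30, 0.41, 0.50],   # rises with age, not affine
            "cgB": [0.90, 0.70, 0.52, 0.33, 0.11],   # falls with age
            "cgC": [0.42, 0.38, 0.45, 0.40, 0.41],   # ~flat
        },
        index=[f"s{i}" for i in range(5)],
    )
    ages = pd.Series([20.0, 30.0, 40.0, 50.0, 60.0], index=betas.index, name="age")
    return MethylationMatrix(betas, ages)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
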