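import numpy as np
import pandas as pd
import pytest

from anthemet.preprocess import MetaboliteMatrix
from anthemet.simulate import ExperimentSpec, SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Reduced study: 2 weeks x 6 timepoints x 2 cultivars x 2 reps = 48
    samples, 40 detectable metabolites, 8-sparse support."""
    return SyntheticSpec(
        n_weeks=2, timepoints_per_day=6, m_metabolites=40, n_undetected=8,
        n_blocks=4, support_indices=tuple(range(0, 40, 5)),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec)


def make_matrix(values: np.ndarray, state: str = "raw-relative",
                prefix: str = "met") -> MetaboliteMatrix:
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    cols = [f"{prefix}_{j + 1:03d}" for j in range(m)]
    idx = [f"s{i + 1:03d}" for i in range(n)]
    meta = pd.DataFrame({
        "sample_id": idx,
        "experiment": "TK01",
        "cultivar": "CFMY",
        "plant": "p1",
        "datetime": pd.date_range("2016-08-16", periods=n, freq="2h").strftime("%Y-%m-%dT%H:%M:%S"),
        "replicate": 1,
    }, index=idx)
    return MetaboliteMatrix(pd.DataFrame(values, index=idx, columns=cols), meta, state)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
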