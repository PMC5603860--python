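import numpy as np
import pytest

from qsarscreen import DescriptorTable, SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_dataset():
    """46 compounds, 40 descriptors, 5 planted signals — the GA-scale fixture."""
    return generate_dataset(
        SyntheticSpec(
            n_compounds=46,
            n_descriptors=40,
            n_active=5,
            noise_sd=0.2,
            n_collinear_pairs=2,
            n_constant=1,
            seed=11,
        )
    )


@pytest.fixture
def default_dataset():
    """The default study-scale matrix: 46 × 300 with 8 active descriptors."""
    return generate_dataset(SyntheticSpec(seed=1))


def random_table(rng, n, p, noise_sd=0.5, n_signal=3):
    """Ad-hoc random regression table used by several suites."""
    X = rng.standard_normal((n, p))
    n_signal = min(n_signal, p)
    beta = rng.uniform(0.5, 1.5, size=n_signal)
    y = X[:, :n_signal] @ beta + rng.normal(0, noise_sd, size=n)
    return DescriptorTable(
        compound_ids=[f"c{i}" for i in range(n)],
        descriptor_names=[f"d{j}" for j in range(p)],
        values=X,
        activity=y,
    )
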