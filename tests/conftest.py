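import hypothesis
import numpy as np
import pandas as pd
import pytest

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """A small screening cohort with strong planted effects."""
    from cardiometh.synthetic import CohortDesign, gen_beta_matrix

    design = CohortDesign(
        n_genes=300, n_planted=30, delta=0.2, precision=50.0, seed=7
    )
    dataset, truth = gen_beta_matrix(design)
    return dataset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def screen_table():
    """Hand-built screening-result table for selection tests."""
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(10)],
            "p_value": [0.001, 0.002, 0.01, 0.02, 0.03, 0.2, 0.3, 0.4, 0.5, 0.9],
            "median_diff": [0.3, -0.25, 0.2, -0.15, 0.1, -0.05, 0.04, -0.03, 0.02, -0.01],
            "direction": ["hyper", "hypo"] * 5,
            "n_probes": [1] * 10,
            "degenerate": [False] * 10,
        }
    )
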