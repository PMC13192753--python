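import numpy as np
import pandas as pd
import pytest

from gutlink import FeatureTable, SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small three-region cohort with planted factors, direct pairs and
    contaminants, shared across read-only tests."""
    config = SynthConfig(
        n_samples_per_region=10, n_regions=3, n_patients=15,
        n_genes=120, n_taxa=40, n_latent_factors=2,
        n_direct_pairs=4, n_contaminants=6, n_negative_controls=2,
        sequencing_depth_mean=5000, expression_depth_mean=30_000, seed=11,
    )
    return generate_cohort(config)


@pytest.fixture
def counts_table():
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.integers(0, 50, size=(12, 8)),
        index=[f"f{i}" for i in range(12)],
        columns=[f"s{j}" for j in range(8)],
    )
    return FeatureTable(data, "counts")
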