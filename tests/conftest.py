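import numpy as np
import pandas as pd
import pytest

from semr.simulate import SimConfig, generate_expression, generate_landscape
from semr.pipeline import run_all


@pytest.fixture(scope="session")
def default_result():
    """One full pipeline run at the default study conditions."""
    return run_all(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_landscape():
    """A small, fast landscape for structural checks."""
    config = SimConfig(
        seed=7, n_lines=4, replicates_per_line=2,
        n_ubiquitous_se=8, n_subtype_se=8, n_line_se=8, n_typical=120,
        n_genes=500, dropout_rate=0.0,
    )
    return generate_landscape(config)


@pytest.fixture(scope="session")
def small_expression(small_landscape):
    return generate_expression(small_landscape.config, small_landscape.truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
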