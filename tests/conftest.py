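import numpy as np
import pytest

import phytostress as ps


@pytest.fixture(scope="session")
def paper_design():
    """The full 4x4x3 factorial with 5 measurement times (240 records)."""
    return ps.generate_design(4, 4, replicates=3, time_points=5)


@pytest.fixture(scope="session")
def paper_dataset(paper_design):
    return ps.generate_feature_table(paper_design, seed=42)


@pytest.fixture(scope="session")
def paper_table(paper_dataset):
    return paper_dataset.to_feature_table()


@pytest.fixture(scope="session")
def small_table():
    """A reduced design (64 records) for fast pipeline-level tests."""
    design = ps.generate_design(4, 4, replicates=2, time_points=2)
    return ps.generate_feature_table(design, seed=7).to_feature_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
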