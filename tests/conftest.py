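import numpy as np
import pandas as pd
import pytest

from obesifact.synthetic import (default_truth, generate_district_panel,
                                 generate_districts, generate_individual_records,
                                 records_to_frame)


@pytest.fixture(scope="session")
def truth():
    return default_truth(seed=11)


@pytest.fixture(scope="session")
def district_panel(truth):
    geoms = generate_districts(25, seed=11)
    panel, true_coefs = generate_district_panel(geoms, truth)
    return panel, true_coefs


@pytest.fixture(scope="session")
def individual_frame(truth):
    records = generate_individual_records(2000, truth)
    return records_to_frame(records)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
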