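import numpy as np
import pandas as pd
import pytest

from ewaskit.simulate import (
    CohortDesign,
    generate_cohort,
    generate_reference_methylome,
)


@pytest.fixture(scope="session")
def reference_small():
    return generate_reference_methylome(1200, 20, seed=3)


@pytest.fixture(scope="session")
def cohort_small(reference_small):
    design = CohortDesign(n_probes=1200, n_planted_dmes=20, seed=11)
    return generate_cohort(design, reference_small)


@pytest.fixture(scope="session")
def two_group_labels():
    def make(n1, n2, index=None):
        labels = ["IC"] * n1 + ["BFC"] * n2
        if index is None:
            index = [f"s{i}" for i in range(n1 + n2)]
        return pd.Series(labels, index=index)

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
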