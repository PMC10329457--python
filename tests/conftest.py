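import numpy as np
import pandas as pd
import pytest

from syncom.cooccurrence import AbundanceTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_abundance(rng):
    """5 strains x 4 samples, strictly positive."""
    values = pd.DataFrame(
        rng.uniform(0.1, 5.0, size=(5, 4)),
        index=[f"s{i}" for i in range(5)],
        columns=[f"smp{j}" for j in range(4)],
    )
    return AbundanceTable(values=values)


@pytest.fixture
def phenotype_frame():
    rows = []
    for treatment, mean in [("NB", 6.0), ("strainA", 2.0), ("strainB", 4.0)]:
        for i in range(6):
            rows.append({
                "plate": "p1", "treatment": treatment, "genotype": "Col-0",
                "seedling": f"{treatment}_{i}", "elongation_cm": mean + 0.1 * (i - 2.5),
            })
    return pd.DataFrame(rows)
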