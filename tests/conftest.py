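import pandas as pd
import pytest

import frontload as fl
from frontload.simulate import design_sheet

# Hand-designed classification scenario: planted group means per gene,
# ordered (HI_N1, HI_N0, LO_N1, LO_N0). Ten flat "anchor" genes keep
# median-of-ratios normalization honest; the six pattern genes each probe
# one rule of the classifier with focal genotype HI.
FIXTURE_MEANS = {
    "g_front": (400, 400, 100, 1600),       # frontloaded in HI
    "g_relup": (50, 50, 200, 12),           # relatively upregulated in HI
    "g_failratio": (400, 400, 100, 40),     # candidate, fails the ratio rules
    "g_failde": (150, 150, 100, 1600),      # fails between-genotype DE at N1
    "g_notexpr": (0, 0, 100, 1600),         # unexpressed in the focal genotype
    "g_shared": (100, 1600, 100, 1600),     # responds in both genotypes
}
JITTER = {1: 0.97, 2: 1.0, 3: 1.03}


def build_fixture_matrix() -> fl.CountMatrix:
    means = dict(FIXTURE_MEANS)
    for i in range(10):
        means[f"anchor_{i}"] = (500 + 10 * i,) * 4
    sheet = design_sheet(3)
    cell_idx = {("HI", "N1"): 0, ("HI", "N0"): 1, ("LO", "N1"): 2, ("LO", "N0"): 3}
    cols = {}
    for row in sheet.table.itertuples():
        k = cell_idx[(row.genotype, row.treatment)]
        cols[row.sample_id] = [
            int(round(means[g][k] * JITTER[row.replicate])) for g in means
        ]
    return fl.CountMatrix(pd.DataFrame(cols, index=list(means)), sheet)


@pytest.fixture(scope="session")
def fixture_matrix() -> fl.CountMatrix:
    return build_fixture_matrix()


@pytest.fixture(scope="session")
def fixture_quartet(fixture_matrix):
    return fl.de_quartet(fixture_matrix)


@pytest.fixture(scope="session")
def default_run():
    """One fitted default-benchmark simulation shared across tests."""
    model, truth = fl.FrontloadModel.from_simulation(fl.default_config(seed=1))
    return model, truth, model.fit()
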