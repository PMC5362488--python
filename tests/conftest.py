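import numpy as np
import pandas as pd
import pytest

from lfqpanel.matrix import IntensityMatrix
from lfqpanel.simulate import SimulationConfig, simulate_catalog, simulate_matrix


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_proteins=120, seed=11)


@pytest.fixture(scope="session")
def truth(small_config):
    return simulate_catalog(small_config)


@pytest.fixture(scope="session")
def sim_matrix(truth, small_config):
    return simulate_matrix(truth, small_config)


@pytest.fixture(scope="session")
def fixture_paths(truth, sim_matrix, tmp_path_factory):
    from lfqpanel.simulate import write_fixtures

    out = tmp_path_factory.mktemp("fixtures")
    return write_fixtures(truth, sim_matrix, str(out))


def toy_matrix(values, rep_kinds=None, parents=None, log2=False, **meta):
    """Build a minimal IntensityMatrix from a dict of sample -> values."""
    intensities = pd.DataFrame(values, dtype=float)
    intensities.index = [f"P{i}" for i in range(len(intensities))]
    samples = list(intensities.columns)
    rep_kinds = rep_kinds or {s: "BR" for s in samples}
    parents = parents or {}
    design = pd.DataFrame(
        {
            "cell_line": [meta.get("cell_line", "L1")] * len(samples),
            "treatment": [meta.get("treatment", "control")] * len(samples),
            "timepoint": [meta.get("timepoint", "8h")] * len(samples),
            "bio_rep": list(range(1, len(samples) + 1)),
            "rep_kind": [rep_kinds[s] for s in samples],
            "parent_sample": [parents.get(s, "") for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    peptides = pd.Series(5, index=intensities.index)
    flags = pd.DataFrame(
        False, index=intensities.index, columns=["reverse", "contaminant", "only_by_site"]
    )
    return IntensityMatrix(
        intensities=intensities, design=design, peptides=peptides, flags=flags, log2=log2
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
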