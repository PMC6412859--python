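import warnings

import pandas as pd
import pytest

from mirtanet import datasets
from mirtanet.simulate import ArraySimConfig, simulate_arrays


@pytest.fixture(scope="session")
def panel_effects() -> dict[str, float]:
    """The eight example-panel log2 effects used as planted truth."""
    panel = datasets.example_array_results()
    return dict(zip(panel["mirna"], panel["mean_log2"]))


@pytest.fixture(scope="session")
def simulated_arrays(panel_effects):
    """One simulated two-color experiment with the panel effects planted."""
    cfg = ArraySimConfig(planted_effects=panel_effects, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        intensities, metadata, truth = simulate_arrays(cfg)
    return intensities, metadata, truth


@pytest.fixture()
def tiny_ct() -> pd.DataFrame:
    """Deterministic Cp table forcing simple ddCp arithmetic."""
    rows = []
    for i in range(1, 4):
        rows += [(f"c{i}", "control", "GENE", 25.0),
                 (f"c{i}", "control", "REF", 20.0),
                 (f"n{i}", "neuropathy", "GENE", 24.0),
                 (f"n{i}", "neuropathy", "REF", 20.0)]
    return pd.DataFrame(rows, columns=["sample_id", "group", "assay", "cp"])
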