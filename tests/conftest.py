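import numpy as np
import pandas as pd
import pytest

from txpod.io import Experiment


def make_design(concentrations, n_replicates=3):
    """Design frame with sample ids c{j}_r{r}, control first."""
    rows = []
    for j, c in enumerate(concentrations):
        for r in range(1, n_replicates + 1):
            rows.append({"sample_id": f"c{j:02d}_r{r}", "concentration_uM": c,
                         "replicate": r})
    return pd.DataFrame(rows).set_index("sample_id")


def make_experiment(counts, concentrations, n_replicates=3, chemical_id="50-00-0"):
    design = make_design(concentrations, n_replicates)
    counts_df = pd.DataFrame(
        np.asarray(counts),
        index=[f"P{i:04d}" for i in range(np.asarray(counts).shape[0])],
        columns=design.index,
    )
    return Experiment(
        chemical_id=chemical_id, cell_model="TEST", exposure_days=1.0,
        counts=counts_df, design=design,
    ).validate()


@pytest.fixture
def concentrations():
    """Control plus ten half-log-ish spaced doses."""
    return [0.0] + list(np.logspace(np.log10(0.0005), 2, 10))


@pytest.fixture
def small_experiment(concentrations):
    rng = np.random.default_rng(42)
    counts = rng.poisson(100.0, size=(50, len(concentrations) * 3))
    return make_experiment(counts, concentrations)
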