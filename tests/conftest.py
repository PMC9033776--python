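import numpy as np
import pandas as pd
import pytest

from synergyseq.simdata import SimulationConfig, simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """A modest default-design dataset with mixed planted effects."""
    cfg = SimulationConfig(n_genes=600, seed=11)
    counts, samples, truth = simulate_counts(cfg)
    return counts, samples, truth


@pytest.fixture(scope="session")
def null_sim():
    """No planted effects: every gene is null."""
    cfg = SimulationConfig(n_genes=800, effect_fractions=(0, 0, 0), seed=5)
    return simulate_counts(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def study_samples():
    """The 4/3/4/3 sample sheet of the hiPSC-neuron design."""
    rows = []
    for group, diag, treat, n in [
        ("CTRL_VEH", "CTRL", "VEH", 4),
        ("SZ_VEH", "SZ", "VEH", 3),
        ("CTRL_JQ", "CTRL", "JQ1", 4),
        ("SZ_JQ", "SZ", "JQ1", 3),
    ]:
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{group}_{i + 1}",
                    "diagnosis": diag,
                    "treatment": treat,
                    "group": group,
                }
            )
    return pd.DataFrame(rows)
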