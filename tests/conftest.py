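import numpy as np
import pandas as pd
import pytest

from cafsubsets import (
    GateConfig,
    IntensityModel,
    default_profiles,
    generate_flow_sample,
    generate_mif_core,
    generate_scrna_counts,
)


@pytest.fixture(scope="session")
def model():
    return IntensityModel()


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def gate_cfg():
    return GateConfig()


@pytest.fixture(scope="session")
def s1_sample(model):
    """Pure CAF-S1 flow sample, no contamination."""
    events, truth = generate_flow_sample(
        mixture={"CAF-S1": 1.0}, n_events=2000, model=model, seed=42)
    return events, truth


@pytest.fixture(scope="session")
def mixed_core():
    """Default-mix multiplex-IF core with planted spatial ordering."""
    return generate_mif_core(n_cells=3000, seed=7)


@pytest.fixture(scope="session")
def scrna_default():
    """Default scRNA matrix with the eight planted effect genes."""
    return generate_scrna_counts(seed=11)


def make_survival_table(times, events, **covariates):
    n = len(times)
    tbl = pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "time": np.asarray(times, dtype=float),
        "event": np.asarray(events, dtype=int),
    })
    for name, vals in covariates.items():
        tbl[name] = vals
    return tbl
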