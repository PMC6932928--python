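import numpy as np
import pandas as pd
import pytest

from esometh.simulate import (
    CLASSES,
    ESOPHAGEAL_CLASSES,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Eight-class dataset with planted markers, decoys and prognostic CpGs."""
    cfg = SimulationConfig(
        n_cpgs=300,
        n_per_class={c: 30 for c in CLASSES},
        n_decoys_per_class=3,
        seed=42,
    )
    return (*simulate_dataset(cfg), cfg)


@pytest.fixture(scope="session")
def esophageal_xy(small_dataset):
    """Feature matrix (samples x CpGs) and labels for the four target classes."""
    matrix, sheet, truth, _cfg = small_dataset
    eso = sheet.index[sheet["tissue_class"].isin(ESOPHAGEAL_CLASSES)]
    X = matrix[eso].T
    y = sheet.loc[eso, "tissue_class"].to_numpy()
    return X, y, truth


@pytest.fixture(scope="session")
def survival_cohort():
    """A 200-patient EAC cohort with planted prognostic signal."""
    cfg = SimulationConfig(n_cpgs=200, seed=7)
    matrix, sheet, truth = simulate_dataset(cfg, n_per_class={"EAC": 200, "NSE": 40})
    tumors = sheet.index[sheet["tissue_class"] == "EAC"]
    return matrix, sheet, truth, tumors


def toy_probabilities(seed=0, n=40, k=4):
    rng = np.random.default_rng(seed)
    raw = rng.random((n, k))
    probs = raw / raw.sum(axis=1, keepdims=True)
    labels = rng.choice([f"C{j}" for j in range(k)], n)
    return labels, pd.DataFrame(probs, columns=[f"C{j}" for j in range(k)])
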