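from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import sarcoscreen as ss

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def reported_screen_stats() -> pd.DataFrame:
    """Published screen statistics (ANOVA p, logrank p, integrated p',
    adjusted p display) for the 29 probe sets of the original 88-patient
    sarcoma cohort analysis."""
    return pd.read_csv(DATA / "reported_screen_stats.tsv", sep="\t")


@pytest.fixture(scope="session")
def reported_pairwise_stats() -> pd.DataFrame:
    """Published Welch p / BH q values for the three UPS pairwise
    comparisons over the same 29 probe sets."""
    return pd.read_csv(DATA / "reported_pairwise_stats.tsv", sep="\t")


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset (cohort, matrix, annotation, truth,
    knowledge map) shared across read-only tests."""
    return ss.simulate_dataset(ss.SimulationConfig(seed=20240917))


@pytest.fixture()
def small_matrix() -> ss.ExpressionMatrix:
    rng = np.random.default_rng(7)
    return ss.ExpressionMatrix(
        tuple(f"p{i}" for i in range(6)),
        tuple(f"s{j}" for j in range(8)),
        rng.uniform(10, 5000, size=(6, 8)),
    )


@pytest.fixture()
def tiny_clinical() -> ss.ClinicalTable:
    rng = np.random.default_rng(11)
    n = 12
    return ss.ClinicalTable(
        pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "subtype": ["UPS", "MFS", "MLS", "SS"] * 3,
                "gender": ["male", "female"] * 6,
                "age": rng.integers(20, 80, n),
                "grade": rng.integers(1, 4, n),
                "metastasis": rng.integers(0, 2, n),
                "survival_time": np.round(rng.uniform(1, 70, n), 1),
                "death_event": rng.integers(0, 2, n),
            }
        )
    )
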