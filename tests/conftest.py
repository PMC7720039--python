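import numpy as np
import pandas as pd
import pytest

from panproteo.io_tables import IntensityMatrix, SampleMetadata, TISSUES
from panproteo.simulate import SimConfig, generate_cohort


def small_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """Down-scaled cohort used across tests: full 16-tissue design, fewer
    proteins, planted signal counts scaled to match."""
    defaults = dict(
        n_proteins=600,
        n_housekeeping=60,
        n_tissue_enriched={"1": 15, "2": 6, "3": 3, "4+": 2},
        n_cancer_up=5,
        n_cancer_down=5,
        rng_seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic down-scaled cohort shared by read-only tests."""
    return generate_cohort(small_sim_config(seed=11))


@pytest.fixture
def two_tissue_metadata():
    """Minimal metadata: 4 liver + 4 colon samples, 2 tumor / 2 normal each."""
    rows = []
    for tissue in ("liver", "colon"):
        for i in range(2):
            rows.append((f"{tissue}_T{i}", f"{tissue}_P{i}", tissue, "tumor"))
            rows.append((f"{tissue}_N{i}", f"{tissue}_P{i}", tissue, "NAT"))
    return SampleMetadata(
        pd.DataFrame(rows, columns=["sample_id", "patient_id", "tissue", "state"])
    )


def make_matrix(values, protein_ids=None, sample_ids=None) -> IntensityMatrix:
    values = np.asarray(values, dtype=float)
    protein_ids = protein_ids or [f"p{i + 1}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j + 1}" for j in range(values.shape[1])]
    return IntensityMatrix(
        pd.DataFrame(values, index=protein_ids, columns=sample_ids)
    )
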