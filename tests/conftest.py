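import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from immunotransit import CohortDataset, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Small but fully structured cohort configuration for module tests."""
    return SimConfig(
        seed=7,
        n_patients_per_group=(2, 2, 3),
        timepoints=("PRE", "C1", "C2"),
        n_genes=300,
        n_cells_per_patient_timepoint=120,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> CohortDataset:
    return simulate_cohort(small_config)


def make_toy_dataset(
    counts=None,
    n_genes: int = 3,
    n_cells: int = 4,
    with_clonotypes: bool = False,
    with_survival: bool = False,
) -> CohortDataset:
    """Hand-sized dataset for I/O and validation tests."""
    if counts is None:
        counts = np.arange(n_genes * n_cells).reshape(n_genes, n_cells) % 5
    counts = sp.csr_matrix(np.asarray(counts))
    n_genes, n_cells = counts.shape
    meta = pd.DataFrame(
        {
            "barcode": [f"BC{i}" for i in range(n_cells)],
            "patient": ["P1"] * n_cells,
            "arm": ["LITT_PEM"] * n_cells,
            "survival_group": ["LITT_GT_MOS"] * n_cells,
            "timepoint": ["PRE" if i % 2 == 0 else "C1" for i in range(n_cells)],
            "cell_type": ["CD8_T"] * n_cells,
            "subcluster": ["CD8_CM"] * n_cells,
        }
    )
    clono = None
    if with_clonotypes:
        clono = pd.DataFrame(
            {
                "barcode": meta["barcode"],
                "chain": "TRB",
                "cdr3_aa": ["CASSAF"] * (n_cells - 1) + ["CASSGF"],
                "patient": "P1",
                "timepoint": meta["timepoint"],
            }
        )
    survival = None
    if with_survival:
        survival = pd.DataFrame(
            {
                "patient": ["P1"],
                "os_months": [12.0],
                "event": [True],
                "age": [61.0],
                "arm": ["LITT_PEM"],
            }
        )
    return CohortDataset(
        counts=counts,
        gene_ids=[f"G{i:04d}" for i in range(n_genes)],
        cell_meta=meta,
        clonotypes=clono,
        survival=survival,
    )
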