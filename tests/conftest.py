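import numpy as np
import pandas as pd
import pytest

from lfqpipe import (
    SyntheticConfig,
    generate_annotations,
    generate_area_matrix,
    generate_proteome,
)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_proteins=400, seed=11, term_size_range=(10, 60))


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """One in-memory fixture bundle shared across tests (read-only)."""
    proteome = generate_proteome(small_config)
    matrix, truth = generate_area_matrix(small_config, proteome)
    cc, kegg = generate_annotations(small_config, proteome, truth)
    return {
        "config": small_config,
        "proteome": proteome,
        "matrix": matrix,
        "truth": truth,
        "cc": cc,
        "kegg": kegg,
        "design": small_config.design(),
    }


@pytest.fixture
def toy_norm():
    """Tiny normalized matrix: 4 proteins x 2 groups x 3 runs, known values."""
    from lfqpipe import NormalizedMatrix

    runs = ["A_r1", "A_r2", "A_r3", "B_r1", "B_r2", "B_r3"]
    log2 = pd.DataFrame(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
            [5.0, 5.1, 4.9, 3.0, 3.2, 2.8],
            [0.0, 0.1, -0.1, 0.05, 0.0, -0.05],
        ],
        index=["P1", "P2", "P3", "P4"],
        columns=runs,
    )
    mask = pd.DataFrame(False, index=log2.index, columns=log2.columns)
    return NormalizedMatrix(np.exp2(log2), log2, mask)


@pytest.fixture
def toy_design():
    rows = [("A_r1", "A", 1), ("A_r2", "A", 2), ("A_r3", "A", 3),
            ("B_r1", "B", 1), ("B_r2", "B", 2), ("B_r3", "B", 3)]
    return pd.DataFrame(rows, columns=["run_id", "group", "replicate"]).set_index("run_id")
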