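import numpy as np
import pytest
import scipy.sparse as sp

from cclone import AlleleCounts, SimulationConfig, VariantRecord, generate_clonal_dataset
from cclone.synthetic_data import apply_truth_annotations

REF_ALT = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


def make_counts(ad, dp, cell_types=None, flags=None):
    """Build an AlleleCounts from dense arrays (cells x variants)."""
    ad = np.asarray(ad)
    dp = np.asarray(dp)
    n_cells, n_vars = dp.shape
    variants = []
    for j in range(n_vars):
        ref, alt = REF_ALT[j % 4]
        kw = flags[j] if flags else {}
        variants.append(VariantRecord("chr1", j + 1, ref, alt, **kw))
    cells = [f"CELL{i:04d}" for i in range(n_cells)]
    return AlleleCounts(
        AD=sp.csr_matrix(ad), DP=sp.csr_matrix(dp),
        cells=cells, variants=variants, cell_types=cell_types,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced simulated sample used by fast integration tests."""
    config = SimulationConfig(
        n_cells=150,
        n_somatic_variants=20,
        n_germline_variants=20,
        n_loh_variants=4,
        n_noise_variants=40,
        p_expr=0.5,
        mean_depth=6.0,
        seed=7,
    )
    dataset = generate_clonal_dataset(config)
    apply_truth_annotations(dataset)
    return dataset


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Dense, noise-free simulation where truth is exactly recoverable."""
    config = SimulationConfig(
        n_cells=80,
        n_somatic_variants=10,
        n_germline_variants=8,
        n_loh_variants=2,
        n_noise_variants=0,
        p_expr=1.0,
        mean_depth=30.0,
        dropout=0.0,
        error_rate=0.0,
        seed=3,
    )
    dataset = generate_clonal_dataset(config)
    apply_truth_annotations(dataset)
    return dataset
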