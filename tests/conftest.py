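import numpy as np
import pytest

import tissuemod as tm


@pytest.fixture(scope="session")
def small_cohort():
    """80 samples, two 30-gene modules + 60 noise genes, trait on module 1."""
    params = tm.BulkSimParams(
        n_samples=80, n_genes=120, module_sizes=(30, 30),
        trait_effects={1: 1.0}, seed=11,
    )
    expr, traits, truth, latent = tm.simulate_bulk_cohort(params)
    return params, expr, traits, truth, latent


@pytest.fixture(scope="session")
def small_log_cohort(small_cohort):
    params, expr, traits, truth, latent = small_cohort
    return params, tm.filter_and_log(expr), traits, truth, latent


@pytest.fixture(scope="session")
def small_cells():
    params = tm.CellSimParams(n_cells=500, n_genes=300, n_marker_genes=15,
                              n_gradient_genes=30, seed=5)
    adata, table = tm.simulate_cells(params)
    return params, adata, table


def best_jaccard(true_labels: np.ndarray, found_labels: np.ndarray, module: int) -> float:
    """Jaccard of a true module against its best-matching detected module."""
    truth = set(np.flatnonzero(true_labels == module))
    best = 0.0
    for lab in set(found_labels) - {0}:
        found = set(np.flatnonzero(found_labels == lab))
        best = max(best, len(truth & found) / len(truth | found))
    return best
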