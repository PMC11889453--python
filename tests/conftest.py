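import numpy as np
import pytest

from ltnn import RunConfig, run_pipeline, simulate_trajectory, simulate_training_time


@pytest.fixture(scope="session")
def branching():
    """Small branching dataset with truth, shared across tests."""
    matrix, truth = simulate_trajectory(
        n_cells=400, n_genes=300, n_branches=2, seed=0
    )
    training = simulate_training_time(truth, noise_sd=0.05, seed=1)
    return matrix, truth, training


@pytest.fixture(scope="session")
def branching_result(branching):
    """One full pipeline run on the small branching dataset."""
    matrix, truth, training = branching
    cfg = RunConfig(hvg_count=250, epochs=40, seed=0)
    res = run_pipeline(matrix, training, cfg, annotation_column="milestone")
    keep = np.isin(matrix.cell_ids, res.matrix.cell_ids)
    return res, truth.subset(keep), cfg
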