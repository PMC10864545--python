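import numpy as np
import pytest

from proteocohere import (CohortConfig, ExpressionMatrix, GenePanel, STAGES,
                          generate_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def panel():
    return GenePanel.default()


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (41 genes x 31 samples, stages 9/7/8/7)."""
    return generate_cohort(CohortConfig(seed=7))


def make_matrix(values, gene_ids=None, sample_ids=None, stage=None):
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    return ExpressionMatrix(
        values=values,
        gene_ids=gene_ids or [f"G{i}" for i in range(g)],
        sample_ids=sample_ids or [f"S{j}" for j in range(n)],
        stage=stage or {},
    )


def staged_random_matrix(rng, n_genes=10, sizes=(5, 4, 4, 4)):
    """Random stage-labelled matrix for oracle tests."""
    n = sum(sizes)
    values = rng.normal(size=(n_genes, n))
    sample_ids, stage = [], {}
    for s, k in zip(STAGES, sizes):
        for i in range(k):
            sid = f"{s}{i}"
            sample_ids.append(sid)
            stage[sid] = s
    return make_matrix(values, sample_ids=sample_ids, stage=stage)
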