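import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from incitekit import pipeline, synthetic
from incitekit.datatypes import GeneCountMatrix, ProteinCaptureMatrix


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort used by end-to-end checks."""
    return synthetic.generate_cohort(synthetic.CohortConfig(seed=1))


@pytest.fixture(scope="session")
def analysis(default_cohort):
    """Full pipeline run on the default cohort (QC -> clusters -> GSEA)."""
    return pipeline.run_default_analysis(default_cohort, seed=0, gsea_n_perm=500)


def make_adt(counts, names, roles, ids=None):
    ids = ids or [f"n{i}" for i in range(np.asarray(counts).shape[0])]
    return ProteinCaptureMatrix(sp.csr_matrix(np.asarray(counts)), names, roles, ids)


def make_gex(counts, genes=None, ids=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{j}" for j in range(counts.shape[1])]
    ids = ids or [f"n{i}" for i in range(counts.shape[0])]
    return GeneCountMatrix(sp.csr_matrix(counts), genes, ids)
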