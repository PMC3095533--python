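import numpy as np
import pandas as pd
import pytest

from nbsubtype import ClinicalTable, ClusterAssignment, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, genes=None, samples=None, tag="test") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), tag)


def blob_matrix(centers, n_per_blob, noise_sd, seed=0, n_genes=None):
    """Samples drawn around per-blob centroids in gene space, plus labels."""
    rng = np.random.default_rng(seed)
    centers = np.asarray(centers, dtype=float)
    n_genes = n_genes or centers.shape[1]
    cols, labels = [], []
    for b, c in enumerate(centers, start=1):
        for j in range(n_per_blob):
            cols.append(c + rng.normal(0, noise_sd, size=n_genes))
            labels.append(b)
    values = np.asarray(cols).T
    samples = [f"s{j:02d}" for j in range(values.shape[1])]
    m = make_matrix(values, samples=samples)
    truth = ClusterAssignment.from_labels(pd.Series(labels, index=samples), "planted")
    return m, truth


@pytest.fixture
def small_clinical() -> ClinicalTable:
    df = pd.DataFrame(
        {
            "inss_stage": ["1", "4", "3", "4S", "unknown", "2"],
            "mna": [0, 1, 0, np.nan, 0, 0],
            "del1p": [0, 1, 0, 0, 0, 0],
            "del11q": [0, 0, 1, 1, np.nan, 0],
            "del3p": [0, 0, 0, 0, 0, 0],
            "gain17q": [0, 1, 1, 0, 0, 0],
            "dod": [0, 1, 0, 0, 0, 0],
            "os_time": [60.0, 12.0, 48.0, 30.0, 55.0, 70.0],
            "os_event": [0, 1, 0, 0, 0, 0],
            "efs_time": [60.0, 10.0, 40.0, 30.0, 55.0, 70.0],
            "efs_event": [0, 1, 1, 0, 0, 0],
        },
        index=[f"s{i}" for i in range(6)],
    )
    return ClinicalTable(df)
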