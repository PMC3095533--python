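"""Cross-dataset validation: fit PCA loadings on one dataset and project the
others onto the same components.

Each dataset is standardized with its own per-gene statistics before
projection, so the loadings model carries no centering constants and
cross-platform location differences cannot leak into the scores.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionMatrix
from .pca import fit_pca
from .preprocess import standardize_genes


@dataclass
class LoadingsModel:
    """Orthonormal PCA loadings over a fixed (common) gene list."""

    loadings: pd.DataFrame       # genes x components
    source_tag: str = ""

    @property
    def genes(self) -> list[str]:
        return list(self.loadings.index)

    def to_tsv(self, path: str | Path) -> None:
        self.loadings.to_csv(path, sep="\t", index_label="gene",
                             float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, source_tag: str = "") -> "LoadingsModel":
        return cls(pd.read_csv(path, sep="\t", index_col="gene"), source_tag)


def fit_loadings(m: ExpressionMatrix, n_components: int = 3) -> LoadingsModel:
    """Top-component loadings of a standardized, common-gene matrix.

    The matrix must have full enough rank: a rank-deficient input (fewer
    informative directions than requested components) raises.
    """
    if m.n_genes < n_components:
        raise ValueError("fewer genes than components")
    pca = fit_pca(m, n_components)
    ev = pca.explained_variance.to_numpy()
    if ev[-1] <= 1e-10 * max(ev[0], 1.0):
        raise ValueError(
            f"matrix rank below {n_components}; cannot fit that many components")
    return LoadingsModel(loadings=pca.loadings, source_tag=m.platform_tag)


def project(m: ExpressionMatrix, model: LoadingsModel) -> pd.DataFrame:
    """Scores of ``m`` on the model's components (samples x components).

    ``m`` is standardized per gene with its own statistics and restricted to
    the model's gene order; every model gene must be present.
    """
    missing = [g for g in model.genes if g not in m.data.index]
    if missing:
        raise ValueError(f"missing model gene(s): {missing[:5]}")
    std = standardize_genes(m.select_genes(model.genes))
    if std.n_genes != len(model.genes):
        raise ValueError("constant gene in projection target")
    x = std.data.loc[model.genes].to_numpy().T  # samples x genes
    scores = x @ model.loadings.to_numpy()
    return pd.DataFrame(scores, index=m.samples, columns=model.loadings.columns)
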