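"""Expression-matrix reduction: low-expression filter, probe collapse,
per-gene standardization, variance filter.

All filters operate on log2 values.  Variance uses the n-1 denominator
throughout, so SD-unit thresholds downstream stay consistent with sample
statistics.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .core import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class ProbeMatrix:
    """Probe-level matrix with a probe -> gene-symbols mapping.

    A probe may hybridize to several genes; such probes are optionally
    discarded before the collapse to symbols.
    """

    values: pd.DataFrame                  # probes x samples
    probe_to_genes: Mapping[str, Sequence[str]]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate probe IDs")
        missing = [p for p in self.values.index if p not in self.probe_to_genes]
        if missing:
            raise ValueError(f"probes without gene mapping: {missing[:5]}")
        empty = [p for p in self.values.index if not self.probe_to_genes[p]]
        if empty:
            raise ValueError(f"probes mapping to no gene: {empty[:5]}")

    @property
    def probes(self) -> list[str]:
        return list(self.values.index)


def read_probe_map(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV: probe ID, comma-joined gene symbols."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe", "genes"], dtype=str)
    return {row.probe: [g.strip() for g in row.genes.split(",") if g.strip()]
            for row in df.itertuples()}


def filter_low_expression(m: ExpressionMatrix | ProbeMatrix, floor: float):
    """Drop rows whose maximum over samples is strictly below ``floor``.

    The comparison is strict ("max log2 expression < floor" removed), so a
    row peaking exactly at the floor is kept.  Row order is preserved.
    """
    if isinstance(m, ProbeMatrix):
        keep = m.values.max(axis=1) >= floor
        if not keep.any():
            raise ValueError("empty matrix after expression filter")
        return ProbeMatrix(m.values.loc[keep].copy(), dict(m.probe_to_genes))
    keep = m.data.max(axis=1) >= floor
    if not keep.any():
        raise ValueError("empty matrix after expression filter")
    return ExpressionMatrix(m.data.loc[keep].copy(), m.platform_tag)


def collapse_probes_to_genes(m: ProbeMatrix, drop_multi_gene: bool = True,
                             platform_tag: str = "") -> ExpressionMatrix:
    """Average probes per gene symbol (arithmetic mean of log2 values).

    With ``drop_multi_gene``, probes hybridizing to more than one gene are
    discarded before averaging.
    """
    keep = [p for p in m.probes
            if not (drop_multi_gene and len(m.probe_to_genes[p]) > 1)]
    if not keep:
        raise ValueError("no probes remain after multi-gene filter")
    rows = m.values.loc[keep]
    symbol_of = {p: m.probe_to_genes[p][0] for p in keep}
    if not drop_multi_gene:
        # replicate a probe's values under each of its symbols
        expanded, symbols = [], []
        for p in keep:
            for g in m.probe_to_genes[p]:
                expanded.append(rows.loc[p])
                symbols.append(g)
        rows = pd.DataFrame(expanded)
        rows.index = symbols
    else:
        rows = rows.rename(index=symbol_of)
    collapsed = rows.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(collapsed, platform_tag)


def standardize_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every gene to mean 0 and unit variance (n-1) across samples.

    Constant genes cannot be standardized and are dropped with a logged
    warning.
    """
    means = m.data.mean(axis=1)
    sds = m.data.std(axis=1, ddof=1)
    constant = sds == 0
    if constant.any():
        log.warning("dropping %d constant gene(s) during standardization: %s",
                    int(constant.sum()), list(m.data.index[constant][:5]))
    keep = ~constant
    if not keep.any():
        raise ValueError("no non-constant genes to standardize")
    data = m.data.loc[keep].sub(means[keep], axis=0).div(sds[keep], axis=0)
    return ExpressionMatrix(data, m.platform_tag)


def variance_filter(m: ExpressionMatrix, cutoff: float) -> ExpressionMatrix:
    """Keep genes with sample variance >= cutoff (on unstandardized values).

    Mirrors the variance-slider filtering of the discovery stage; the
    boundary is inclusive so the documented cutoff 0.4 can be used verbatim.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    keep = m.data.var(axis=1, ddof=1) >= cutoff
    if not keep.any():
        raise ValueError("empty matrix after variance filter")
    return ExpressionMatrix(m.data.loc[keep].copy(), m.platform_tag)
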