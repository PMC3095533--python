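"""Shared domain containers, TSV I/O and cross-dataset gene alignment.

The pipeline works on log2-scale expression matrices (genes x samples),
per-sample clinical annotation tables, and cluster assignments.  Everything
is plain pandas underneath; the thin dataclass wrappers enforce the
invariants the downstream stages rely on (unique gene symbols and sample
IDs, finite values, tri-state clinical encoding).
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

#: Sentinel cluster label for samples no stage could place.
UNASSIGNED = 0

#: Recognized INSS stage tokens.  Stage 4S is a distinct stratum (infants with
#: metastases limited to skin/liver/marrow) and never counts as "high stage".
STAGES = ("1", "2", "3", "4", "4S", "unknown")

CLINICAL_TRISTATE = ("mna", "del1p", "del11q", "del3p", "gain17q", "dod")
CLINICAL_COLUMNS = (
    "inss_stage", "mna", "del1p", "del11q", "del3p", "gain17q", "dod",
    "os_time", "os_event", "efs_time", "efs_event",
)


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Log2 expression values indexed by gene symbol (rows) and sample ID.

    Parameters
    ----------
    data
        genes x samples DataFrame of finite log2 intensities.
    platform_tag
        Free-text platform/dataset label carried through the pipeline.
    """

    data: pd.DataFrame
    platform_tag: str = ""

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str).str.strip()
        self.data.columns = self.data.columns.astype(str).str.strip()
        if self.data.shape[0] == 0:
            raise ParseError("no genes")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique()
            raise ValueError(f"duplicate gene symbols: {list(dups)[:5]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample IDs: {list(dups)[:5]}")
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)].copy(), self.platform_tag)

    def select_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[list(samples)].copy(), self.platform_tag)

    def drop_sample(self, sample: str) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.drop(columns=[sample]), self.platform_tag)


def read_expression(path: str | Path, platform_tag: str = "") -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    First column holds gene symbols, the header row the sample IDs, and the
    body numeric log2 values.  Malformed numeric cells raise :class:`ParseError`
    naming the offending row and column; duplicate sample IDs are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    cols = [c.strip() for c in header.split("\t")[1:]]
    if len(cols) != len(set(cols)):
        dups = sorted({c for c in cols if cols.count(c) > 1})
        raise ParseError(f"duplicate sample ID in {path.name}: {dups}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.shape[0] == 0:
        raise ParseError(f"no genes in {path.name}")
    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & raw.notna()
    bad |= raw.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric cell at gene {raw.index[r]!r}, sample {raw.columns[c]!r}"
            f" in {path.name}: {raw.iat[r, c]!r}"
        )
    return ExpressionMatrix(numeric, platform_tag=platform_tag or path.stem)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with >= 6 significant digits per cell."""
    m.data.to_csv(path, sep="\t", float_format="%.8g", index_label="gene")


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------

@dataclass
class ClinicalTable:
    """Per-sample clinical annotation.

    Tri-state factors (``mna``, ``del1p``, ``del11q``, ``del3p``, ``gain17q``,
    ``dod``) are floats in {1.0, 0.0, NaN}; NaN marks "not determined" and is
    excluded pairwise from every statistic.  Survival columns are OS/EFS times
    in months with {0,1,NaN} event indicators.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        df.index = df.index.astype(str).str.strip()
        if df.index.duplicated().any():
            raise ValueError("duplicate sample IDs in clinical table")
        for col in CLINICAL_COLUMNS:
            if col not in df.columns:
                df[col] = "unknown" if col == "inss_stage" else np.nan
        bad_stage = ~df["inss_stage"].astype(str).isin(STAGES)
        if bad_stage.any():
            tok = df.loc[bad_stage, "inss_stage"].iloc[0]
            raise ParseError(f"unrecognised INSS stage token: {tok!r}")
        for col in ("os_time", "efs_time"):
            t = df[col].astype(float)
            if (t.dropna() < 0).any():
                raise ParseError(f"negative {col}")
            df[col] = t
        for col in ("os_event", "efs_event"):
            df[col] = df[col].astype(float)
            ev = df[col] == 1.0
            if df.loc[ev, col.replace("_event", "_time")].isna().any():
                raise ValueError(f"{col}=1 with unknown time")
        self.data = df[list(CLINICAL_COLUMNS)]

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def factor(self, name: str) -> pd.Series:
        """Binary indicator (1/0/NaN) for a prognostic factor.

        Besides the stored tri-state columns, the derived factors
        ``high_stage`` (INSS 3 or 4), ``stage4`` and ``outcome`` (alias of
        dead-of-disease) are available.
        """
        df = self.data
        if name in CLINICAL_TRISTATE:
            return df[name].astype(float)
        stage = df["inss_stage"].astype(str)
        known = stage != "unknown"
        if name == "high_stage":
            out = pd.Series(np.nan, index=df.index)
            out[known] = stage[known].isin(["3", "4"]).astype(float)
            return out
        if name == "stage4":
            out = pd.Series(np.nan, index=df.index)
            out[known] = (stage[known] == "4").astype(float)
            return out
        if name == "outcome":
            return df["dod"].astype(float)
        raise KeyError(f"unknown clinical factor: {name}")


def _parse_tristate(series: pd.Series, col: str) -> pd.Series:
    tokens = series.astype(str).str.strip()
    mapping = {"1": 1.0, "0": 0.0, "1.0": 1.0, "0.0": 0.0,
               "NA": np.nan, "nan": np.nan, "": np.nan}
    bad = ~tokens.isin(mapping)
    if bad.any():
        raise ParseError(f"bad tri-state token in column {col}: {tokens[bad].iloc[0]!r}")
    return tokens.map(mapping)


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a tab-separated clinical table (tri-states encoded 1/0/NA).

    Missing optional columns are filled as unknown.
    """
    raw = pd.read_csv(Path(path), sep="\t", dtype=str)
    if "sample_id" not in raw.columns:
        raise ParseError("clinical table needs a sample_id column")
    raw = raw.set_index("sample_id")
    df = pd.DataFrame(index=raw.index)
    stage = raw["inss_stage"] if "inss_stage" in raw else pd.Series("unknown", index=raw.index)
    df["inss_stage"] = (
        stage.astype(str).str.strip().str.upper()
        .replace({"NA": "unknown", "NAN": "unknown", "": "unknown", "UNKNOWN": "unknown"})
    )
    for col in CLINICAL_TRISTATE:
        df[col] = _parse_tristate(raw[col], col) if col in raw else np.nan
    for col in ("os_time", "efs_time", "os_event", "efs_event"):
        if col in raw:
            df[col] = pd.to_numeric(raw[col].replace({"NA": None, "": None}), errors="raise")
        else:
            df[col] = np.nan
    return ClinicalTable(df)


def write_clinical(t: ClinicalTable, path: str | Path) -> None:
    out = t.data.copy()
    for col in CLINICAL_TRISTATE + ("os_event", "efs_event"):
        out[col] = out[col].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


# ---------------------------------------------------------------------------
# Cluster assignments
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """Sample -> cluster label (1..K, or UNASSIGNED = 0) with provenance.

    Provenance records which stage produced each label: ``pca``,
    ``hierarchical``, ``nn_rescue``, ``rule`` or ``planted`` (generator truth).
    """

    labels: pd.Series
    provenance: pd.Series

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(int)
        self.labels.index = self.labels.index.astype(str)
        self.provenance = self.provenance.astype(str).reindex(self.labels.index)
        if (self.labels < 0).any():
            raise ValueError("cluster labels must be >= 0 (0 = unassigned)")

    @classmethod
    def from_labels(cls, labels: pd.Series | dict, provenance: str) -> "ClusterAssignment":
        labels = pd.Series(labels)
        return cls(labels, pd.Series(provenance, index=labels.index))

    @property
    def samples(self) -> list[str]:
        return list(self.labels.index)

    @property
    def k(self) -> int:
        assigned = self.labels[self.labels != UNASSIGNED]
        return int(assigned.max()) if len(assigned) else 0

    @property
    def n_unassigned(self) -> int:
        return int((self.labels == UNASSIGNED).sum())

    def assigned(self) -> pd.Series:
        return self.labels[self.labels != UNASSIGNED]

    def members(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"cluster": self.labels, "provenance": self.provenance}) \
            .to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ClusterAssignment":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(df["cluster"], df["provenance"])


# ---------------------------------------------------------------------------
# Gene alignment across datasets
# ---------------------------------------------------------------------------

def align_common_genes(matrices: Sequence[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict >= 2 matrices to their common genes, in a shared order.

    The common order follows the first matrix's gene order; re-aligning
    already aligned matrices is a no-op.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to align")
    common = set(matrices[0].genes)
    for m in matrices[1:]:
        common &= set(m.genes)
    if not common:
        raise ValueError("no genes shared across all matrices")
    order = [g for g in matrices[0].genes if g in common]
    return [m.select_genes(order) for m in matrices]


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class SamConfig:
    """Settings for the SAM-style permutation differential expression."""

    n_permutations: int = 200
    seed: int = 0
    fc_log2_threshold: float = 1.0   # fold change "above 2" on the log2 scale
    top_n_significant: int = 4000
    top_n_per_contrast: int = 30


@dataclass
class SignatureConfig:
    """Settings for the 6-gene SD-rule classifier."""

    threshold_sd: float = 0.5
    min_agree: int = 5


@dataclass
class HierConfig:
    """Settings for the hierarchical verification stage."""

    k_samples: int = 4
    k_genes: int = 5
    min_cluster_size: int = 3


@dataclass
class AnalysisConfig:
    """All tunable constants of the pipeline with their defaults.

    ``expression_floor`` drops probe rows whose maximum log2 value stays
    below it; ``variance_cutoff`` keeps genes with sample variance >= cutoff
    before PCA; the remainder mirror the stage-specific settings.
    """

    expression_floor: float = 6.0
    variance_cutoff: float = 0.4
    n_components: int = 3
    loo_enabled: bool = True
    sam: SamConfig = field(default_factory=SamConfig)
    signature: SignatureConfig = field(default_factory=SignatureConfig)
    hier: HierConfig = field(default_factory=HierConfig)

    def __post_init__(self) -> None:
        if self.variance_cutoff < 0:
            raise ValueError("variance_cutoff must be >= 0")
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")
        if not (1 <= self.signature.min_agree <= 6):
            raise ValueError("min_agree must be in 1..6")
        if self.signature.threshold_sd <= 0:
            raise ValueError("threshold_sd must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        sam = SamConfig(**d.pop("sam", {}))
        sig = SignatureConfig(**d.pop("signature", {}))
        hier = HierConfig(**d.pop("hier", {}))
        return cls(sam=sam, signature=sig, hier=hier, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
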