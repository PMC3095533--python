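"""Clinical association layer: Fisher enrichment per cluster, ANOVA/Tukey
and Welch tests for the signature genes, Pearson correlation, Kaplan-Meier
survival with log-rank tests, five-year Fisher comparisons, and the
genomic-subtype rule (Type 1 / 2A / 2B / Other).

Unknown ("not determined") clinical values are excluded pairwise from every
statistic; no multiple-testing correction is applied by default (an optional
Bonferroni flag is provided for the enrichment table).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .core import ClinicalTable, ClusterAssignment, UNASSIGNED

log = logging.getLogger(__name__)

DEFAULT_FACTORS = ("high_stage", "stage4", "outcome", "mna",
                   "del1p", "del11q", "del3p", "gain17q")

GENOMIC_SUBTYPES = ("Type1", "Type2A", "Type2B", "Other")


# ---------------------------------------------------------------------------
# Contingency tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: factor present/absent (rows) x in-cluster/rest (columns)."""

    a: int  # present, in cluster
    b: int  # present, rest
    c: int  # absent, in cluster
    d: int  # absent, rest

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


def fisher_exact(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: total probability of tables (same margins)
    no more likely than the observed one.  Degenerate margins give p = 1.
    """
    if min(t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d) == 0:
        return 1.0
    return float(st.fisher_exact([[t.a, t.b], [t.c, t.d]])[1])


def cluster_factor_enrichment(assign: ClusterAssignment, clin: ClinicalTable,
                              factors: Sequence[str] = DEFAULT_FACTORS,
                              bonferroni: bool = False) -> pd.DataFrame:
    """Fisher enrichment p of each factor in each cluster vs the rest.

    Output rows are factors and columns clusters, mirroring the layout of a
    per-cluster characteristics table.  Samples with unknown factor status
    are left out of that factor's tables.
    """
    labels = assign.assigned()
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    out = pd.DataFrame(index=list(factors), columns=clusters, dtype=float)
    n_tests = len(factors) * len(clusters)
    for factor in factors:
        ind = clin.factor(factor).reindex(labels.index)
        known = ind.notna()
        if not known.any():
            raise ValueError(f"factor {factor} entirely unknown")
        for cl in clusters:
            in_cl = (labels == cl) & known
            rest = (labels != cl) & known
            t = ContingencyTable2x2(
                a=int((ind[in_cl] == 1).sum()), b=int((ind[rest] == 1).sum()),
                c=int((ind[in_cl] == 0).sum()), d=int((ind[rest] == 0).sum()))
            p = fisher_exact(t)
            out.loc[factor, cl] = min(1.0, p * n_tests) if bonferroni else p
    return out


# ---------------------------------------------------------------------------
# Group-comparison tests
# ---------------------------------------------------------------------------

def _groups_of(values: pd.Series, labels: pd.Series) -> list[np.ndarray]:
    labels = labels[labels != UNASSIGNED]
    shared = values.index.intersection(labels.index)
    values, labels = values[shared], labels[shared]
    known = values.notna()
    groups = [values[known & (labels == g)].to_numpy()
              for g in sorted(labels.unique())]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 members")
    return groups


def anova_oneway(values: pd.Series, labels: pd.Series) -> tuple[float, float]:
    """Classic one-way ANOVA F and p across cluster groups."""
    groups = _groups_of(values, labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:  # all observations identical: no variance anywhere
        return 0.0, 1.0
    f, p = st.f_oneway(*groups)
    return float(f), float(p)


def tukey_posthoc(values: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Tukey HSD pairwise p-values (Tukey-Kramer at unequal group sizes)."""
    groups = _groups_of(values, labels)
    names = sorted(pd.Series(labels)[pd.Series(labels) != UNASSIGNED].unique())
    res = st.tukey_hsd(*groups)
    out = pd.DataFrame(res.pvalue, index=names, columns=names)
    return out


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Welch two-sample t (unequal variance, Satterthwaite df), two-sided."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 0.0, 1.0
    t, p = st.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with its t-distributed two-sided test."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input")
    r, p = st.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    ``times`` are the observed event times (ascending); ``survival`` the
    estimate immediately after each time; S = 1 before the first event.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        if (np.diff(self.survival) > 1e-12).any():
            raise ValueError("survival estimates must be non-increasing")


def km_curve(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Product-limit estimator; at tied times events precede censorings."""
    times = np.asarray(times, float)
    events = np.asarray(events, float)
    if len(times) == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tab = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"].reindex(tab.index)
    if tab.index[0] == 0.0 and tab["removed"].iloc[0] == 0:
        tab, surv = tab.iloc[1:], surv.iloc[1:]  # implicit S(0-) = 1 baseline
    return SurvivalCurve(times=tab.index.to_numpy(float),
                         survival=surv.to_numpy(float),
                         at_risk=tab["at_risk"].to_numpy(float))


def survival_at(curve: SurvivalCurve, t: float) -> float:
    """Step-function lookup of S(t)."""
    idx = np.searchsorted(curve.times, t, side="right") - 1
    return 1.0 if idx < 0 else float(curve.survival[idx])


def logrank(groups: Sequence[tuple[Sequence[float], Sequence[int]]]
            ) -> tuple[float, float]:
    """Mantel-Cox log-rank chi-square across >= 2 groups (df = groups - 1)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    times, events, labels = [], [], []
    for i, (t, e) in enumerate(groups):
        times.extend(np.asarray(t, float))
        events.extend(np.asarray(e, float))
        labels.extend([i] * len(t))
    if sum(events) == 0:
        raise ValueError("no events in any group")
    res = multivariate_logrank_test(pd.Series(times), pd.Series(labels),
                                    pd.Series(events))
    return float(res.test_statistic), float(res.p_value)


def five_year_fisher(assign: ClusterAssignment, clin: ClinicalTable,
                     horizon: float = 60.0) -> pd.Series:
    """Per-cluster Fisher test of dead-vs-alive status at five years.

    A subject is dead at the horizon if it has an OS event at or before it,
    alive if followed at least to the horizon; subjects censored earlier are
    excluded.
    """
    labels = assign.assigned()
    df = clin.data.reindex(labels.index)
    dead = (df["os_event"] == 1) & (df["os_time"] <= horizon)
    alive = df["os_time"] >= horizon
    known = (dead | alive) & df["os_time"].notna()
    out = {}
    for cl in sorted(labels.unique()):
        in_cl = (labels == cl) & known
        rest = (labels != cl) & known
        t = ContingencyTable2x2(
            a=int(dead[in_cl].sum()), b=int(dead[rest].sum()),
            c=int(alive[in_cl].sum()), d=int(alive[rest].sum()))
        out[cl] = fisher_exact(t)
    return pd.Series(out)


def km_by_cluster(assign: ClusterAssignment, clin: ClinicalTable,
                  endpoint: str = "os") -> dict[int, SurvivalCurve]:
    """Kaplan-Meier curve per cluster for OS or EFS (unknowns dropped)."""
    labels = assign.assigned()
    df = clin.data.reindex(labels.index)
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    out = {}
    for cl in sorted(labels.unique()):
        sel = (labels == cl) & df[tcol].notna() & df[ecol].notna()
        if sel.any():
            out[cl] = km_curve(df.loc[sel, tcol], df.loc[sel, ecol])
    return out


def logrank_by_cluster(assign: ClusterAssignment, clin: ClinicalTable,
                       endpoint: str = "os") -> tuple[float, float]:
    labels = assign.assigned()
    df = clin.data.reindex(labels.index)
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    groups = []
    for cl in sorted(labels.unique()):
        sel = (labels == cl) & df[tcol].notna() & df[ecol].notna()
        groups.append((df.loc[sel, tcol].to_numpy(), df.loc[sel, ecol].to_numpy()))
    return logrank(groups)


# ---------------------------------------------------------------------------
# Genomic subtypes
# ---------------------------------------------------------------------------

def assign_genomic_subtype(row: pd.Series) -> str:
    """Map one clinical record to Type1 / Type2A / Type2B / Other.

    MYCN-amplified tumours are Type 2B; 11q-deleted non-amplified tumours
    Type 2A; low/intermediate-stage tumours (INSS 1-3) free of all four
    aberrations and not dead of disease are the favourable Type 1.  A flag
    required by a rule but not determined sends the sample to Other.
    """
    mna, del11q = row.get("mna"), row.get("del11q")
    if mna == 1:
        return "Type2B"
    if mna == 0 and del11q == 1:
        return "Type2A"
    stage = str(row.get("inss_stage"))
    flags = [row.get(f) for f in ("mna", "del11q", "del1p", "del3p")]
    dod = row.get("dod")
    if (stage in ("1", "2", "3") and all(f == 0 for f in flags) and dod == 0):
        return "Type1"
    return "Other"


def genomic_subtypes(clin: ClinicalTable) -> pd.Series:
    """Genomic subtype per sample (a total function of the clinical row)."""
    return pd.Series({s: assign_genomic_subtype(clin.data.loc[s])
                      for s in clin.samples})


def crosstab(assign: ClusterAssignment, subtypes: pd.Series) -> pd.DataFrame:
    """Counts of expression cluster (columns) by genomic subtype (rows)."""
    labels = assign.assigned()
    shared = labels.index.intersection(subtypes.index)
    tab = pd.crosstab(subtypes[shared], labels[shared])
    return tab.reindex(index=[s for s in GENOMIC_SUBTYPES if s in tab.index])
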