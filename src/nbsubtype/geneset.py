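"""One-vs-rest moderated differential expression with permutation p-values,
cross-dataset overlap, combined fold-change ranking, and the sample-size
weighted z-combination.

The statistic is the SAM-style moderated t: d = (mean_g - mean_rest) /
(s + s0), where s is the pooled two-group standard error and the fudge
factor s0 (by default the median of all gene-wise standard errors) damps
the inflated statistics of near-constant genes.  Significance comes from
group-size-preserving label permutations with the permuted statistics
pooled across genes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import ClusterAssignment, ExpressionMatrix, UNASSIGNED

log = logging.getLogger(__name__)

CONTRASTS = (1, 2, 3, 4)


def _as_labels(labels) -> pd.Series:
    if isinstance(labels, ClusterAssignment):
        labels = labels.labels
    labels = pd.Series(labels).astype(int)
    return labels[labels != UNASSIGNED]


def _group_stats(x: np.ndarray, mask: np.ndarray):
    """Means and pooled standard error for group-vs-rest, vectorized.

    ``mask`` may be a boolean vector (samples,) or matrix (samples, n_perm).
    """
    n = x.shape[1]
    w = mask.astype(float)
    k = w.sum(axis=0)
    tot = x.sum(axis=1, keepdims=True)
    sqtot = (x ** 2).sum(axis=1, keepdims=True)
    s1 = x @ w
    sq1 = (x ** 2) @ w
    m1 = s1 / k
    m2 = (tot - s1) / (n - k)
    v1 = (sq1 - k * m1 ** 2) / (k - 1)
    v2 = ((sqtot - sq1) - (n - k) * m2 ** 2) / (n - k - 1)
    pooled = ((k - 1) * v1 + (n - k - 1) * v2) / (n - 2)
    pooled = np.maximum(pooled, 0.0)
    se = np.sqrt(pooled * (1.0 / k + 1.0 / (n - k)))
    return m1, m2, se


def one_vs_rest_stat(m: ExpressionMatrix, labels, group: int,
                     s0: float | None = None) -> pd.DataFrame:
    """Per-gene moderated d statistic for one group against the rest.

    Returns a DataFrame indexed by gene with columns ``d``, ``log2_fc``
    (mean_group - mean_rest), ``se`` and the attribute ``s0`` in
    ``DataFrame.attrs``.  With s0 = 0, d is the ordinary pooled-variance
    two-sample t statistic.
    """
    lab = _as_labels(labels)
    samples = [s for s in m.samples if s in lab.index]
    lab = lab[samples]
    mask = (lab == group).to_numpy()
    if mask.sum() < 2:
        raise ValueError(f"group {group} has fewer than 2 members")
    if (~mask).sum() < 2:
        raise ValueError(f"rest of group {group} has fewer than 2 members")
    x = m.select_samples(samples).values
    m1, m2, se = _group_stats(x, mask[:, None])
    m1, m2, se = m1.ravel(), m2.ravel(), se.ravel()
    if s0 is None:
        s0 = float(np.median(se))
    d = (m1 - m2) / (se + s0)
    out = pd.DataFrame({"d": d, "log2_fc": m1 - m2, "se": se}, index=m.genes)
    out.attrs["s0"] = s0
    return out


def permutation_pvalues(m: ExpressionMatrix, labels, group: int,
                        n_perm: int = 200, seed: int = 0,
                        s0: float | None = None,
                        exhaustive: bool = False) -> pd.DataFrame:
    """Permutation p-values for the one-vs-rest d statistic.

    Group labels are permuted uniformly with group sizes preserved; the
    permuted |d*| are pooled across genes, and
    p = (1 + #{|d*| >= |d|} / n_genes) / (n_perm + 1).  With ``exhaustive``,
    all distinct group/rest splits are enumerated instead of sampled.
    Identical seeds give identical p-values.
    """
    obs = one_vs_rest_stat(m, labels, group, s0=s0)
    s0_val = obs.attrs["s0"]
    lab = _as_labels(labels)
    samples = [s for s in m.samples if s in lab.index]
    lab = lab[samples]
    x = m.select_samples(samples).values
    n = len(samples)
    k = int((lab == group).sum())
    if exhaustive:
        splits = list(combinations(range(n), k))
        if len(splits) > 100_000:
            raise ValueError("too many splits to enumerate; use sampling")
        masks = np.zeros((n, len(splits)), dtype=bool)
        for j, idx in enumerate(splits):
            masks[list(idx), j] = True
        n_perm = len(splits)
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        masks = np.zeros((n, n_perm), dtype=bool)
        for j in range(n_perm):
            masks[rng.permutation(n)[:k], j] = True
    m1, m2, se = _group_stats(x, masks)
    d_star = np.abs((m1 - m2) / (se + s0_val))
    pooled = np.sort(d_star.ravel())
    n_genes = x.shape[0]
    # fp-safe ">=": the observed split reappears among permutations and must
    # count as a tie even when matrix/vector arithmetic differ in the last ulp
    thresholds = np.abs(obs["d"].to_numpy()) * (1 - 1e-9) - 1e-12
    count_ge = pooled.size - np.searchsorted(pooled, thresholds, side="left")
    perm_p = (1.0 + count_ge / n_genes) / (n_perm + 1.0)
    out = obs.copy()
    out["perm_p"] = perm_p
    out.attrs["s0"] = s0_val
    out.attrs["n_perm"] = n_perm
    return out


def contrast_stats(m: ExpressionMatrix, labels, n_perm: int = 200,
                   seed: int = 0) -> dict[int, pd.DataFrame]:
    """d, fold change and permutation p for all four one-vs-rest contrasts."""
    return {g: permutation_pvalues(m, labels, g, n_perm=n_perm, seed=seed + g)
            for g in CONTRASTS}


def select_dataset_top(stats: pd.DataFrame, top_n: int = 4000,
                       fc_log2_threshold: float = 1.0) -> list[str]:
    """Rank by permutation p, keep top_n, then require |log2 FC| strictly
    above the threshold (fold change above 2 at the default 1.0).

    Ties in p are broken by |d| (descending), then gene symbol.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    df = stats.copy()
    df["_absd"] = -df["d"].abs()
    df["_symbol"] = df.index
    ranked = df.sort_values(["perm_p", "_absd", "_symbol"]).head(top_n)
    keep = ranked[ranked["log2_fc"].abs() > fc_log2_threshold]
    return list(keep.index)


@dataclass
class DiscriminativeGeneSet:
    """Per-contrast top gene lists and their deduplicated union."""

    per_contrast: dict[int, list[str]]
    combined_fc: dict[int, pd.Series]
    union: list[str]


def overlap_and_rank(per_dataset_lists: Sequence[Mapping[int, Sequence[str]]],
                     per_dataset_stats: Sequence[Mapping[int, pd.DataFrame]],
                     top_n_per_contrast: int = 30) -> DiscriminativeGeneSet:
    """Intersect per-dataset contrast lists, rank by combined fold change.

    The combined log2 fold change of a gene is the arithmetic mean of its
    per-dataset log2 fold changes; the ``top_n_per_contrast`` genes with the
    largest |combined FC| are kept per contrast (ties by symbol) and unioned
    without duplicates, preserving contrast order.
    """
    if len(per_dataset_lists) < 2:
        raise ValueError("need lists from at least two datasets")
    per_contrast: dict[int, list[str]] = {}
    combined_fc: dict[int, pd.Series] = {}
    for c in CONTRASTS:
        common: set[str] | None = None
        for lists in per_dataset_lists:
            genes = set(lists.get(c, ()))
            common = genes if common is None else (common & genes)
        common = common or set()
        if not common:
            log.warning("no overlapping genes for contrast %d", c)
            per_contrast[c] = []
            combined_fc[c] = pd.Series(dtype=float)
            continue
        fcs = pd.DataFrame({i: stats[c]["log2_fc"].reindex(sorted(common))
                            for i, stats in enumerate(per_dataset_stats)})
        comb = fcs.mean(axis=1)
        order = sorted(comb.index, key=lambda g: (-abs(comb[g]), g))
        top = order[:top_n_per_contrast]
        per_contrast[c] = top
        combined_fc[c] = comb[top]
    union: list[str] = []
    seen: set[str] = set()
    for c in CONTRASTS:
        for g in per_contrast[c]:
            if g not in seen:
                seen.add(g)
                union.append(g)
    return DiscriminativeGeneSet(per_contrast=per_contrast,
                                 combined_fc=combined_fc, union=union)


def combine_z(p_values: Sequence, signs: Sequence, sizes: Sequence[int]):
    """Sample-size-weighted combination of signed z-scores across datasets.

    Each two-sided p is transformed to a standard-normal quantile
    z_i = sign_i * Phi^{-1}(1 - p_i/2) (sign from the fold-change direction)
    and combined as sum_i sqrt(n_i / N) * z_i; the weights square-sum to 1,
    so the combined statistic stays standard normal under the null.

    Accepts scalars or equal-length arrays per dataset; p-values of exactly
    0 or 1 are clamped to machine-safe bounds with a warning.
    """
    sizes = np.asarray(sizes, dtype=float)
    if len(p_values) != len(sizes) or len(signs) != len(sizes):
        raise ValueError("p_values, signs and sizes must align")
    weights = np.sqrt(sizes / sizes.sum())
    scalar = np.isscalar(p_values[0]) or np.ndim(p_values[0]) == 0
    tiny = np.finfo(float).tiny
    total = None
    for p, sign, w in zip(p_values, signs, weights):
        p = np.asarray(p, dtype=float)
        if ((p <= 0) | (p >= 1)).any():
            log.warning("p-values at 0 or 1 clamped to machine-safe bounds")
            p = np.clip(p, tiny, 1.0 - 1e-16)
        z = np.sign(np.asarray(sign, dtype=float)) * norm.isf(p / 2.0)
        total = w * z if total is None else total + w * z
    return float(total) if scalar else total
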