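"""Unsupervised subgroup discovery: PCA, nearest-neighbour cluster joining,
leave-one-out stability.

Clustering follows the nearest-neighbour joining idea: every sample is
connected to its single nearest Euclidean neighbour in the low-dimensional
score space, and connected components of the resulting undirected graph are
the subgroups.  There is no preset number of clusters; separation in score
space determines how many components appear.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

from .core import AnalysisConfig, ClusterAssignment, ExpressionMatrix
from .preprocess import standardize_genes, variance_filter

log = logging.getLogger(__name__)


@dataclass
class PcaResult:
    """Principal components of a genes x samples matrix.

    ``scores`` is samples x components, ``loadings`` genes x components with
    orthonormal columns, components ordered by decreasing explained variance.
    ``gene_means``/``gene_sds`` record the standardization constants applied
    before the decomposition (SDs of 1 when the caller passed raw values).
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance: pd.Series
    gene_means: pd.Series
    gene_sds: pd.Series


def fit_pca(m: ExpressionMatrix, n_components: int,
            standardize: bool = False) -> PcaResult:
    """PCA via SVD of the sample-centered matrix.

    Columns follow a deterministic sign convention: the largest-magnitude
    loading entry of each component is positive, so repeated fits and
    cross-dataset comparisons are stable.
    """
    n, p = m.n_samples, m.n_genes
    if n_components > min(p, n - 1):
        raise ValueError(
            f"n_components={n_components} exceeds min(genes, samples-1)="
            f"{min(p, n - 1)}")
    means = m.data.mean(axis=1)
    if standardize:
        sds = m.data.std(axis=1, ddof=1)
        if (sds == 0).any():
            raise ValueError("constant gene; standardize_genes drops these first")
    else:
        sds = pd.Series(1.0, index=m.data.index)
    x = m.data.sub(means, axis=0).div(sds, axis=0).to_numpy().T  # samples x genes
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # sign convention: dominant loading entry positive
    for j in range(n_components):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    comps = [f"PC{j + 1}" for j in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(u * s, index=m.samples, columns=comps),
        loadings=pd.DataFrame(vt.T, index=m.genes, columns=comps),
        explained_variance=pd.Series(s ** 2 / (n - 1), index=comps),
        gene_means=means,
        gene_sds=sds,
    )


def _relabel_components(comp: np.ndarray, samples: list[str]) -> pd.Series:
    """Label components 1..K in decreasing size (ties by smallest member)."""
    ids = np.unique(comp)
    order = sorted(ids,
                   key=lambda c: (-int((comp == c).sum()),
                                  min(samples[i] for i in np.flatnonzero(comp == c))))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    return pd.Series([relabel[c] for c in comp], index=samples)


def nn_join_clusters(scores: pd.DataFrame,
                     consolidate: bool = False,
                     gap_factor: float = 2.0) -> ClusterAssignment:
    """Connected components of the nearest-neighbour-joining graph.

    Each sample contributes an undirected edge to its single nearest
    Euclidean neighbour (ties broken by smallest sample index); clusters are
    the connected components, labelled 1..K in decreasing size (size ties by
    smallest member sample ID).

    With ``consolidate``, the joining continues at the group level: the raw
    components are merged by single linkage, and the agglomeration stops at
    the largest relative jump (> ``gap_factor``) in the sequence of join
    distances.  A one-nearest-neighbour graph of even a well-separated point
    cloud fragments into mutual-NN islands at every scale, so the raw
    components subdivide true subgroups; the gap rule recovers the subgroup
    structure while remaining purely distance-driven (no preset cluster
    count).
    """
    n = len(scores)
    if n == 0:
        raise ValueError("no samples")
    samples = list(scores.index)
    if n == 1:
        return ClusterAssignment.from_labels(
            pd.Series([1], index=samples), provenance="pca")
    d = squareform(pdist(scores.to_numpy(), metric="euclidean"))
    np.fill_diagonal(d, np.inf)
    nn = np.argmin(d, axis=1)  # argmin returns the first (smallest) index on ties
    rows = np.arange(n)
    adj = coo_matrix((np.ones(n), (rows, nn)), shape=(n, n))
    _, comp = connected_components(adj, directed=False)
    if consolidate:
        d0 = float(d[rows, nn].max())  # largest join distance already accepted
        comp = _consolidate(d, comp, d0, gap_factor)
    return ClusterAssignment.from_labels(_relabel_components(comp, samples),
                                         provenance="pca")


def _consolidate(d: np.ndarray, comp: np.ndarray, d0: float,
                 gap_factor: float) -> np.ndarray:
    """Single-linkage merging of NN components with a largest-gap stop.

    Components are merged in order of minimum inter-component distance; the
    full merge sequence (prefixed by the largest within-component join
    distance d0) is scanned for the largest ratio between consecutive join
    distances, and all merges from that jump onwards are rejected.  If no
    ratio exceeds ``gap_factor`` everything merges into one cluster.
    """
    comp = comp.copy()
    ids = list(np.unique(comp))
    if len(ids) == 1:
        return comp
    heights: list[float] = []
    merges: list[tuple[int, int]] = []
    parent = {c: c for c in ids}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    active = set(ids)
    while len(active) > 1:
        best = (np.inf, None, None)
        act = sorted(active)
        for i, a in enumerate(act):
            ma = np.flatnonzero([find(c) == a for c in comp])
            for b in act[i + 1:]:
                mb = np.flatnonzero([find(c) == b for c in comp])
                dist = float(d[np.ix_(ma, mb)].min())
                if dist < best[0]:
                    best = (dist, a, b)
        dist, a, b = best
        heights.append(dist)
        merges.append((a, b))
        parent[b] = a
        active.discard(b)
    seq = [max(d0, 1e-300)] + heights
    ratios = [seq[i + 1] / max(seq[i], 1e-300) for i in range(len(heights))]
    cut = int(np.argmax(ratios))  # merges[cut:] are rejected
    if ratios[cut] <= gap_factor:
        cut = len(merges)
    parent = {c: c for c in ids}
    for a, b in merges[:cut]:
        parent[find(b)] = find(a)
    return np.array([find(c) for c in comp])


def discover_subgroups(m: ExpressionMatrix, cfg: AnalysisConfig | None = None,
                       standardize: bool = True
                       ) -> tuple[ClusterAssignment, PcaResult]:
    """The discovery chain: variance filter -> PCA -> NN joining."""
    cfg = cfg or AnalysisConfig()
    filtered = variance_filter(m, cfg.variance_cutoff)
    if standardize:
        filtered = standardize_genes(filtered)
    pca = fit_pca(filtered, cfg.n_components)
    assign = nn_join_clusters(pca.scores, consolidate=True)
    return assign, pca


@dataclass
class StabilityReport:
    """Per-sample leave-one-out label stability.

    ``shift_fraction`` is the fraction of reruns (in which the sample
    participated) where its matched cluster label differed from the full-run
    label.
    """

    shift_fraction: pd.Series
    n_runs: int


def _match_clusters(full: pd.Series, reduced: pd.Series) -> dict[int, int]:
    """Greedy maximum-overlap matching of reduced-run labels to full-run labels."""
    shared = reduced.index.intersection(full.index)
    overlap: dict[tuple[int, int], int] = {}
    for s in shared:
        key = (int(reduced[s]), int(full[s]))
        overlap[key] = overlap.get(key, 0) + 1
    mapping: dict[int, int] = {}
    used_full: set[int] = set()
    # ties broken by label order for determinism
    for (r, f), _cnt in sorted(overlap.items(), key=lambda kv: (-kv[1], kv[0])):
        if r not in mapping and f not in used_full:
            mapping[r] = f
            used_full.add(f)
    # unmatched reduced labels keep a fresh label (always counts as a shift)
    next_label = max(list(full.unique()) + list(mapping.values()), default=0) + 1
    for r in sorted(reduced.unique()):
        if r not in mapping:
            mapping[int(r)] = next_label
            next_label += 1
    return mapping


def loo_stability(m: ExpressionMatrix, cfg: AnalysisConfig | None = None,
                  standardize: bool = True) -> StabilityReport:
    """Leave-one-out cross-validation of the discovery chain.

    For each held-out sample the chain is rerun on the remaining samples;
    reduced-run clusters are matched to the full-run clusters by maximum
    member overlap, and every retained sample is checked for a label shift.
    Degenerate reruns (e.g. all remaining genes constant) are skipped with a
    warning.
    """
    cfg = cfg or AnalysisConfig()
    if m.n_samples < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    full, _ = discover_subgroups(m, cfg, standardize=standardize)
    shifts = pd.Series(0, index=m.samples, dtype=float)
    runs = pd.Series(0, index=m.samples, dtype=float)
    n_runs = 0
    for held_out in m.samples:
        reduced_m = m.drop_sample(held_out)
        try:
            reduced, _ = discover_subgroups(reduced_m, cfg, standardize=standardize)
        except ValueError as exc:
            log.warning("leave-one-out run without %s skipped: %s", held_out, exc)
            continue
        n_runs += 1
        mapping = _match_clusters(full.labels, reduced.labels)
        for s in reduced.labels.index:
            runs[s] += 1
            if mapping[int(reduced.labels[s])] != int(full.labels[s]):
                shifts[s] += 1
    frac = (shifts / runs.replace(0, np.nan)).fillna(0.0)
    return StabilityReport(shift_fraction=frac, n_runs=n_runs)
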