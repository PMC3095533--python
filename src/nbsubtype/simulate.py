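"""Synthetic two-platform neuroblastoma cohorts with four planted subgroups.

The generator emulates the structure the analysis pipeline expects from the
real microarray cohorts: log2 expression matrices on partially overlapping
gene universes, four latent subgroups carrying the 6-gene signature sign
pattern, per-group marker-gene blocks, subgroup-dependent clinical factor
frequencies (MYCN amplification concentrated in one group, 11q deletion in
two groups) and subgroup-dependent exponential survival.

Effect sizes are stated in SD units and realised as mean shifts of
``effect * signature_scale`` log2 units, with ``signature_scale`` fixed
independently of the noise level so that lowering ``noise_sd`` genuinely
sharpens the planted structure (a 1-SD-unit effect is a 2-fold change at the
default scale).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ClinicalTable, ClusterAssignment, ExpressionMatrix

#: The six signature genes, in canonical column order.
SIGNATURE_GENES = ("ALK", "BIRC5", "CCND1", "MYCN", "NTRK1", "PHOX2B")

#: c-MYC is planted anti-correlated with MYCN (high outside the MNA-like
#: group, strongly down inside it) so the MYCN/MYC correlation check has a
#: signal to find.
MYC_EFFECTS = (1.0, 1.0, -2.0, 1.0)

_CANONICAL = np.array([
    #  ALK BIRC5 CCND1 MYCN NTRK1 PHOX2B
    [-1.0, -1.0,  1.0, -1.0,  2.0,  1.0],   # group 1: NTRK1-high favourable
    [ 1.0,  2.0,  1.0,  0.0,  1.0,  1.0],   # group 2: BIRC5/CCND1-high, 11q-del like
    [ 2.0,  2.0,  0.0,  2.0, -2.0,  0.0],   # group 3: MYCN-high / NTRK1-low (MNA-like)
    [-1.0, -2.0, -2.0, -2.0, -1.0, -2.0],   # group 4: all six genes low
])


def canonical_profiles() -> pd.DataFrame:
    """The default 4x6 signature-effect table in SD units.

    Rows are subgroups 1-4, columns the six signature genes.  Signs follow
    the per-group fold-change pattern of the discovery cohorts; magnitudes
    are 1 for single-fold ("+"/"-") and 2 for strong ("++"/"--") effects.
    Group 4 is entirely non-positive (globally low expression of all six
    genes).
    """
    return pd.DataFrame(_CANONICAL.copy(), index=[1, 2, 3, 4],
                        columns=list(SIGNATURE_GENES))


_DEFAULT_CLINICAL_FREQS = {
    # per-group Bernoulli probabilities, groups 1..4
    "mna":     (0.05, 0.05, 0.90, 0.05),
    "del1p":   (0.10, 0.20, 0.70, 0.30),
    "del11q":  (0.10, 0.70, 0.10, 0.70),
    "del3p":   (0.05, 0.30, 0.20, 0.40),
    "gain17q": (0.10, 0.60, 0.70, 0.60),
    "stage4":  (0.05, 0.35, 0.75, 0.55),
}


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Notes
    -----
    ``n_samples`` may be a single int (every dataset the same size) or a
    tuple with one entry per generated dataset.  ``signature_effects``
    defaults to :func:`canonical_profiles`.  Survival hazards are exponential
    event rates per month; the default ordering puts the worst survival in
    group 3 (the MNA-like group), then 4, 2 and 1.
    """

    n_samples: int | tuple[int, ...] = 40
    group_proportions: tuple[float, float, float, float] = (0.30, 0.25, 0.25, 0.20)
    n_genes: int = 2000
    shared_gene_fraction: float = 0.6
    signature_effects: pd.DataFrame | None = None
    signature_scale: float = 1.0       # log2 units per SD-unit of effect
    marker_block_size: int = 40
    marker_delta: float = 2.0          # log2 shift of a marker in its own group
    noise_sd: float = 0.5
    baseline_range: tuple[float, float] = (6.0, 12.0)
    low_expressed_fraction: float = 0.05
    low_baseline_range: tuple[float, float] = (3.0, 4.5)
    clinical_freqs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_CLINICAL_FREQS))
    survival_hazards: tuple[float, float, float, float] = (0.0005, 0.009, 0.015, 0.012)
    censoring_rate: float = 0.006      # exponential censoring, per month
    follow_up_cap: float = 120.0       # administrative censoring, months
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.group_proportions, dtype=float)
        if props.shape != (4,) or (props < 0).any():
            raise ValueError("group_proportions must be 4 non-negative reals")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("group_proportions must sum to 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0.0 < self.shared_gene_fraction <= 1.0):
            raise ValueError("shared_gene_fraction must be in (0, 1]")
        for probs in self.clinical_freqs.values():
            if any(not (0.0 <= p <= 1.0) for p in probs):
                raise ValueError("clinical frequencies must be probabilities")
        if self.signature_effects is None:
            self.signature_effects = canonical_profiles()

    def effects(self) -> pd.DataFrame:
        return self.signature_effects

    def sizes(self, n_datasets: int) -> list[int]:
        if isinstance(self.n_samples, int):
            return [self.n_samples] * n_datasets
        if len(self.n_samples) != n_datasets:
            raise ValueError(f"n_samples must have {n_datasets} entries")
        return list(self.n_samples)


# ---------------------------------------------------------------------------
# Gene universes
# ---------------------------------------------------------------------------

def _core_genes(spec: CohortSpec) -> pd.DataFrame:
    """Signature + MYC + marker blocks: present on every platform."""
    rows = [(g, "signature", 0) for g in SIGNATURE_GENES]
    rows.append(("MYC", "myc", 0))
    for g in range(1, 5):
        rows += [(f"MK{g}_{i:03d}", "marker", g)
                 for i in range(spec.marker_block_size)]
    return pd.DataFrame(rows, columns=["symbol", "kind", "group"])


def _universe(spec: CohortSpec, tag: str, n_shared_fillers: int,
              n_specific: int) -> pd.DataFrame:
    core = _core_genes(spec)
    shared = pd.DataFrame(
        {"symbol": [f"GS_{i:04d}" for i in range(n_shared_fillers)],
         "kind": "noise", "group": 0})
    n_low = min(n_specific, int(round(spec.low_expressed_fraction * spec.n_genes)))
    spec_rows = pd.DataFrame(
        {"symbol": [f"G{tag}_{i:04d}" for i in range(n_specific)],
         "kind": "noise", "group": 0})
    if n_low:
        spec_rows.loc[spec_rows.index[-n_low:], "kind"] = "low"
    return pd.concat([core, shared, spec_rows], ignore_index=True)


def _allocate_groups(n: int, proportions: Sequence[float]) -> np.ndarray:
    """Largest-remainder allocation: group sizes are exact for the cohort."""
    quota = np.asarray(proportions, float) * n
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    for idx in np.argsort(-remainder)[: n - counts.sum()]:
        counts[idx] += 1
    return np.repeat(np.arange(1, 5), counts)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _generate(spec: CohortSpec, rng: np.random.Generator,
              universe: pd.DataFrame, n_samples: int, tag: str
              ) -> tuple[ExpressionMatrix, ClinicalTable, ClusterAssignment]:
    genes = universe["symbol"].to_numpy()
    n_genes = len(genes)
    samples = [f"{tag}_s{i:03d}" for i in range(n_samples)]

    groups = rng.permutation(_allocate_groups(n_samples, spec.group_proportions))

    low = universe["kind"].to_numpy() == "low"
    baselines = rng.uniform(*spec.baseline_range, size=n_genes)
    baselines[low] = rng.uniform(*spec.low_baseline_range, size=int(low.sum()))

    values = baselines[:, None] + rng.normal(0.0, spec.noise_sd,
                                             size=(n_genes, n_samples))
    effects = spec.effects()
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in SIGNATURE_GENES:
        values[gene_pos[g]] += effects.loc[groups, g].to_numpy() * spec.signature_scale
    myc = np.asarray(MYC_EFFECTS)
    values[gene_pos["MYC"]] += myc[groups - 1] * spec.signature_scale
    marker_mask = universe["kind"].to_numpy() == "marker"
    marker_group = universe["group"].to_numpy()
    for g in range(1, 5):
        rows = np.flatnonzero(marker_mask & (marker_group == g))
        values[np.ix_(rows, np.flatnonzero(groups == g))] += spec.marker_delta

    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            platform_tag=tag)

    # clinical factors
    clin = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    freqs = spec.clinical_freqs
    p_stage4 = np.asarray(freqs["stage4"])[groups - 1]
    stage4 = rng.random(n_samples) < p_stage4
    other_stages = np.array(["1", "2", "3", "4S"])
    weights = np.where((groups == 1)[:, None],
                       np.array([0.5, 0.3, 0.1, 0.1]),
                       np.array([0.2, 0.2, 0.5, 0.1]))
    picks = np.array([rng.choice(4, p=w) for w in weights])
    clin["inss_stage"] = np.where(stage4, "4", other_stages[picks])
    for factor in ("mna", "del1p", "del11q", "del3p", "gain17q"):
        p = np.asarray(freqs[factor])[groups - 1]
        clin[factor] = (rng.random(n_samples) < p).astype(float)

    # survival: exponential event times per group, independent censoring
    hazards = np.asarray(spec.survival_hazards)[groups - 1]
    t_event = rng.exponential(1.0 / hazards)
    t_prog = rng.exponential(1.0 / (0.8 * hazards))
    t_cens = np.minimum(rng.exponential(1.0 / spec.censoring_rate, n_samples),
                        spec.follow_up_cap)
    os_event = t_event <= t_cens
    clin["os_time"] = np.minimum(t_event, t_cens)
    clin["os_event"] = os_event.astype(float)
    t_efs = np.minimum(t_prog, t_event)
    clin["efs_event"] = (t_efs <= t_cens).astype(float)
    clin["efs_time"] = np.minimum(t_efs, t_cens)
    clin["dod"] = os_event.astype(float)

    # inject "not determined" entries into tri-state factors
    for factor in ("mna", "del1p", "del11q", "del3p", "gain17q", "dod"):
        mask = rng.random(n_samples) < spec.missing_rate
        clin.loc[mask, factor] = np.nan

    labels = ClusterAssignment.from_labels(
        pd.Series(groups, index=samples), provenance="planted")
    return expr, ClinicalTable(clin), labels


def generate_cohort(spec: CohortSpec
                    ) -> tuple[ExpressionMatrix, ClinicalTable, ClusterAssignment]:
    """Generate a single cohort on one platform.

    Identical spec (including seed) gives bitwise-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    core = len(_core_genes(spec))
    if spec.n_genes < core:
        raise ValueError(f"n_genes must be >= {core} to hold signature and markers")
    universe = _universe(spec, "A", n_shared_fillers=0,
                         n_specific=spec.n_genes - core)
    n = spec.sizes(1)[0]
    return _generate(spec, rng, universe, n, "A")


def generate_datasets(spec: CohortSpec, n_datasets: int = 2
                      ) -> list[tuple[ExpressionMatrix, ClinicalTable, ClusterAssignment]]:
    """Generate datasets with partially overlapping gene universes.

    Every pair of datasets shares exactly ``round(shared_gene_fraction *
    n_genes)`` symbols, always including the six signature genes, MYC and
    all marker blocks; the remainder of each universe is platform-specific.
    """
    rng = np.random.default_rng(spec.seed)
    n_shared = int(round(spec.shared_gene_fraction * spec.n_genes))
    core = len(_core_genes(spec))
    if n_shared < core:
        raise ValueError(
            f"shared gene set ({n_shared}) would exclude a signature or marker "
            f"gene (core set has {core} genes)")
    n_specific = spec.n_genes - n_shared
    sizes = spec.sizes(n_datasets)
    out = []
    for i, (tag, n) in enumerate(zip("ABCDEFGH", sizes)):
        universe = _universe(spec, tag, n_shared - core, n_specific)
        out.append(_generate(spec, rng, universe, n, tag))
    return out


def generate_dataset_pair(spec: CohortSpec):
    """Two-platform version of :func:`generate_datasets` (the common case)."""
    return generate_datasets(spec, 2)


# ---------------------------------------------------------------------------
# Direct SD-profile simulation (classifier stress testing)
# ---------------------------------------------------------------------------

def perturbed_profiles(n_per_group: int, noise_sd: float, seed: int = 0
                       ) -> tuple[pd.DataFrame, ClusterAssignment]:
    """Canonical SD profiles plus i.i.d. Gaussian noise, with true labels.

    Works directly in SD-unit profile space: each sample's profile is its
    group's canonical row plus N(0, noise_sd) per gene.  This isolates the
    rule classifier from cohort-level standardization effects.
    """
    rng = np.random.default_rng(seed)
    prof = canonical_profiles()
    rows, labels, ids = [], [], []
    for g in range(1, 5):
        base = prof.loc[g].to_numpy()
        noise = rng.normal(0.0, noise_sd, size=(n_per_group, 6))
        for j in range(n_per_group):
            ids.append(f"g{g}_{j:03d}")
            labels.append(g)
            rows.append(base + noise[j])
    profiles = pd.DataFrame(rows, index=ids, columns=list(SIGNATURE_GENES))
    truth = ClusterAssignment.from_labels(pd.Series(labels, index=ids), "planted")
    return profiles, truth
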