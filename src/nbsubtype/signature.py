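"""The 6-gene SD-interval rule classifier (r-groups).

Each subgroup r1-r4 is described by a direction (UP / DOWN / NEUTRAL) per
signature gene, evaluated on per-gene standardized expression (SD units).
A sample is assigned to a group when at least ``min_agree`` of the six genes
satisfy that group's intervals and no second group also qualifies; otherwise
it stays unassigned (ND), mirroring the conservative reject option of the
original rule set.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .core import ClusterAssignment, ExpressionMatrix, UNASSIGNED
from .simulate import SIGNATURE_GENES

UP, DOWN, NEUTRAL = "up", "down", "neutral"

# Direction pattern per r-group, from the per-group fold-change signs of the
# signature genes (r4: globally low expression of all six genes).
_DIRECTIONS = {
    1: {"ALK": DOWN, "BIRC5": DOWN, "CCND1": UP, "MYCN": DOWN,
        "NTRK1": UP, "PHOX2B": UP},
    2: {"ALK": UP, "BIRC5": UP, "CCND1": UP, "MYCN": NEUTRAL,
        "NTRK1": UP, "PHOX2B": UP},
    3: {"ALK": UP, "BIRC5": UP, "CCND1": NEUTRAL, "MYCN": UP,
        "NTRK1": DOWN, "PHOX2B": NEUTRAL},
    4: {g: DOWN for g in SIGNATURE_GENES},
}


@dataclass
class SignatureRuleSet:
    """Per r-group, per gene: a direction and an SD threshold.

    UP means value >= +t, DOWN value <= -t, NEUTRAL |value| < t.
    ``min_agree`` genes (of six) must satisfy a group's intervals for
    assignment.
    """

    rules: dict[int, dict[str, tuple[str, float]]]
    min_agree: int = 5
    genes: tuple[str, ...] = SIGNATURE_GENES

    def __post_init__(self) -> None:
        if set(self.rules) != {1, 2, 3, 4}:
            raise ValueError("rules must cover exactly groups 1..4")
        for g, per_gene in self.rules.items():
            if set(per_gene) != set(self.genes):
                raise ValueError(f"group {g} must state a rule for every gene")
            for gene, (direction, t) in per_gene.items():
                if direction not in (UP, DOWN, NEUTRAL):
                    raise ValueError(f"bad direction {direction!r}")
                if t <= 0:
                    raise ValueError("thresholds must be positive")
        if not (1 <= self.min_agree <= 6):
            raise ValueError("min_agree must be in 1..6")

    def satisfies(self, gene: str, group: int, value: float) -> bool:
        direction, t = self.rules[group][gene]
        if direction == UP:
            return value >= t
        if direction == DOWN:
            return value <= -t
        return abs(value) < t

    def to_yaml(self, path: str | Path) -> None:
        doc = {"min_agree": self.min_agree,
               "groups": {g: {gene: {"direction": d, "threshold": t}
                              for gene, (d, t) in per.items()}
                          for g, per in self.rules.items()}}
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SignatureRuleSet":
        doc = yaml.safe_load(Path(path).read_text())
        rules = {int(g): {gene: (spec["direction"], float(spec["threshold"]))
                          for gene, spec in per.items()}
                 for g, per in doc["groups"].items()}
        return cls(rules=rules, min_agree=int(doc.get("min_agree", 5)))


def default_rules(threshold_sd: float = 0.5, min_agree: int = 5) -> SignatureRuleSet:
    """The default rule set: directions per group with one symmetric threshold."""
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    rules = {g: {gene: (d, threshold_sd) for gene, d in per.items()}
             for g, per in _DIRECTIONS.items()}
    return SignatureRuleSet(rules=rules, min_agree=min_agree)


def sd_profile(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample signature profiles in SD units (samples x 6 genes).

    Each signature gene is standardized to mean 0 / SD 1 (n-1) across the
    cohort.  Missing or constant signature genes raise with the gene named.
    """
    missing = [g for g in SIGNATURE_GENES if g not in m.data.index]
    if missing:
        raise ValueError(f"missing signature gene(s): {missing}")
    sub = m.data.loc[list(SIGNATURE_GENES)]
    sds = sub.std(axis=1, ddof=1)
    constant = sds == 0
    if constant.any():
        raise ValueError(
            f"constant signature gene: {list(sub.index[constant])}")
    prof = sub.sub(sub.mean(axis=1), axis=0).div(sds, axis=0)
    return prof.T  # samples x genes


def agreement_counts(profile_row: Mapping[str, float],
                     rules: SignatureRuleSet) -> dict[int, int]:
    """Number of genes satisfying each group's intervals for one profile."""
    return {g: sum(rules.satisfies(gene, g, float(profile_row[gene]))
                   for gene in rules.genes)
            for g in (1, 2, 3, 4)}


def classify_sample(profile_row: Mapping[str, float],
                    rules: SignatureRuleSet) -> int:
    """Assign one SD profile to r1..r4 or UNASSIGNED.

    A unique group must reach ``min_agree`` agreements; zero or multiple
    qualifying groups yield UNASSIGNED.
    """
    counts = agreement_counts(profile_row, rules)
    qualifying = [g for g, c in counts.items() if c >= rules.min_agree]
    return qualifying[0] if len(qualifying) == 1 else UNASSIGNED


def classify_profiles(profiles: pd.DataFrame,
                      rules: SignatureRuleSet) -> ClusterAssignment:
    """Classify a samples x 6 SD-profile table."""
    labels = pd.Series(
        [classify_sample(profiles.loc[s], rules) for s in profiles.index],
        index=profiles.index)
    return ClusterAssignment.from_labels(labels, provenance="rule")


def classify_cohort(m: ExpressionMatrix,
                    rules: SignatureRuleSet | None = None) -> ClusterAssignment:
    """SD-profile the cohort and classify every sample by the rules."""
    rules = rules or default_rules()
    return classify_profiles(sd_profile(m), rules)
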