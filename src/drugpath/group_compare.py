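"""Compare pathway profiles across drug groups.

Given per-drug significant pathway sets for labelled groups (e.g.
cardiotoxic vs hepatotoxic vs cardiac-therapy), this module computes
affected-compound fractions per pathway, frequency-threshold sets with
pairwise shared and exclusive pathways, a bipartite drug-pathway edge list
for network tools, and a novelty report against a reference
compound-pathway edge list.

The fraction denominator is the number of drugs in the group with at least
one significant pathway (drugs whose pipeline run produced nothing are
recorded but do not dilute frequencies); the rule is echoed in the output
metadata of the CLI layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DrugGroup",
    "PathwayFrequency",
    "ThresholdSummary",
    "NoveltyReport",
    "pathway_frequencies",
    "threshold_sets",
    "bipartite_export",
    "novelty_vs_reference",
]


@dataclass
class DrugGroup:
    label: str
    results: dict[str, frozenset[str]]  # drug_id -> significant pathway st_ids

    @property
    def drug_ids(self) -> frozenset[str]:
        return frozenset(self.results)

    @property
    def n_with_pathways(self) -> int:
        return sum(1 for s in self.results.values() if s)


@dataclass(frozen=True)
class PathwayFrequency:
    st_id: str
    group: str
    n_hit: int
    n_group: int  # denominator: drugs with >=1 significant pathway

    @property
    def fraction(self) -> float:
        return self.n_hit / self.n_group


def pathway_frequencies(group: DrugGroup) -> list[PathwayFrequency]:
    """Affected-compound fraction per pathway hit by >=1 drug in the group.

    Ordered by fraction descending, then st_id ascending.
    """
    denom = group.n_with_pathways
    if denom == 0:
        raise ValueError(f"group {group.label!r}: no drugs with significant pathways")
    counts: dict[str, int] = {}
    for st_ids in group.results.values():
        for st_id in st_ids:
            counts[st_id] = counts.get(st_id, 0) + 1
    rows = [
        PathwayFrequency(st_id=st_id, group=group.label, n_hit=c, n_group=denom)
        for st_id, c in counts.items()
    ]
    return sorted(rows, key=lambda r: (-r.fraction, r.st_id))


@dataclass
class ThresholdSummary:
    """Frequency-threshold pathway sets and their overlaps."""

    min_fraction: float
    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    intersections: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    exclusives: dict[str, frozenset[str]] = field(default_factory=dict)


def threshold_sets(groups: Iterable[DrugGroup], min_fraction: float) -> ThresholdSummary:
    """Pathways affected by at least *min_fraction* of each group's drugs.

    Inclusive threshold. exclusive(A) = set(A) minus the union of every
    other group's set; pairwise intersections are keyed by sorted label
    pairs.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    summary = ThresholdSummary(min_fraction=min_fraction)
    groups = list(groups)
    for group in groups:
        summary.sets[group.label] = frozenset(
            f.st_id for f in pathway_frequencies(group) if f.fraction >= min_fraction
        )
    for a, b in combinations(sorted(summary.sets), 2):
        summary.intersections[(a, b)] = summary.sets[a] & summary.sets[b]
    for label, st_ids in summary.sets.items():
        others = frozenset().union(
            *(s for other, s in summary.sets.items() if other != label)
        ) if len(summary.sets) > 1 else frozenset()
        summary.exclusives[label] = st_ids - others
    return summary


def bipartite_export(groups: Iterable[DrugGroup]) -> pd.DataFrame:
    """Deterministic (drug_id, st_id, group) edge list for network tools."""
    rows = sorted(
        (drug, st_id, group.label)
        for group in groups
        for drug, st_ids in group.results.items()
        for st_id in st_ids
    )
    return pd.DataFrame(rows, columns=["drug_id", "st_id", "group"])


@dataclass
class NoveltyReport:
    """Discovered vs reference compound-pathway edges, per drug and overall."""

    per_drug: dict[str, dict[str, int]] = field(default_factory=dict)
    recovered: int = 0
    novel: int = 0
    missed: int = 0


def novelty_vs_reference(
    discovered: Mapping[str, frozenset[str]],
    reference: Iterable[tuple[str, str]],
) -> NoveltyReport:
    """Classify discovered edges as recovered/novel and reference edges as missed.

    Per drug: recovered = discovered AND reference, novel = discovered only,
    missed = reference only; recovered + novel = |discovered| per drug.
    Reference drug IDs must already be in the same (ChEMBL) namespace.
    """
    ref: dict[str, set[str]] = {}
    for drug, st_id in reference:
        ref.setdefault(drug, set()).add(st_id)
    report = NoveltyReport()
    for drug in sorted(set(discovered) | set(ref)):
        disc = frozenset(discovered.get(drug, frozenset()))
        refd = frozenset(ref.get(drug, frozenset()))
        entry = {
            "recovered": len(disc & refd),
            "novel": len(disc - refd),
            "missed": len(refd - disc),
        }
        report.per_drug[drug] = entry
        report.recovered += entry["recovered"]
        report.novel += entry["novel"]
        report.missed += entry["missed"]
    return report
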