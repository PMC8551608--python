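"""Domain records: evidenced drug-target links and per-drug target profiles.

A :class:`TargetRecord` is one evidenced link between a drug (ChEMBL-style
identifier) and a reviewed human protein (UniProt accession), annotated with
the database it came from and a free-text provenance note (e.g. how an
ortholog lift or protein-family expansion produced it). A
:class:`TargetProfile` is the deduplicated protein pool of one drug, with
per-accession source provenance retained for auditability.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "SOURCES",
    "ACCESSION_RE",
    "is_valid_accession",
    "TargetRecord",
    "TargetProfile",
]

#: The five supported target databases.
SOURCES = ("chembl", "drugbank", "ttd", "pharmgkb", "iuphar")

# UniProt accession syntax (canonical form, optional isoform suffix).
ACCESSION_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]"
    r"|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})(?:-\d+)?$"
)


def is_valid_accession(accession: str) -> bool:
    """Return True if *accession* matches UniProt accession syntax."""
    return bool(ACCESSION_RE.match(accession))


@dataclass(frozen=True, order=True)
class TargetRecord:
    """One evidenced drug -> protein link.

    Records emitted by the source adapters are always reviewed human
    proteins; the flags exist so the harmonizer can assert the invariant
    rather than trust it.
    """

    drug_id: str
    accession: str
    source: str
    reviewed: bool = True
    human: bool = True
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if not is_valid_accession(self.accession):
            raise ValueError(f"invalid UniProt accession {self.accession!r}")
        if not self.drug_id:
            raise ValueError("empty drug_id")


@dataclass
class TargetProfile:
    """Deduplicated protein pool of one drug.

    ``sources_per_accession`` maps every accession in ``accessions`` to the
    nonempty set of databases that evidenced it.
    """

    drug_id: str
    accessions: frozenset[str]
    sources_per_accession: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.sources_per_accession) != set(self.accessions):
            raise ValueError(
                "sources_per_accession keys must equal the accession set"
            )
        for acc, srcs in self.sources_per_accession.items():
            if not srcs:
                raise ValueError(f"accession {acc} has an empty source set")

    def __len__(self) -> int:
        return len(self.accessions)

    def restrict(self, keep: frozenset[str]) -> "TargetProfile":
        """Return a copy restricted to accessions in *keep*."""
        kept = self.accessions & keep
        return TargetProfile(
            drug_id=self.drug_id,
            accessions=kept,
            sources_per_accession={
                a: self.sources_per_accession[a] for a in kept
            },
        )
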