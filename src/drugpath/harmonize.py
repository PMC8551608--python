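"""Collate per-source TargetRecords into deduplicated per-drug profiles.

The protein pool of a drug is the union of its targets across all five
databases; duplicate (drug, accession) pairs collapse to one entry whose
source set records every database that evidenced the pair.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .records import TargetProfile, TargetRecord

__all__ = ["build_profiles", "profiles_to_frame", "write_profiles"]


def build_profiles(records: Iterable[TargetRecord]) -> dict[str, TargetProfile]:
    """Union records per drug into deduplicated TargetProfiles.

    Raises ValueError if any record is not reviewed human — the adapters
    guarantee this, so a violation is an upstream bug, not bad data.
    """
    sources: dict[str, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    for rec in records:
        if not (rec.reviewed and rec.human):
            raise ValueError(
                f"adapter bug: record {rec.drug_id}/{rec.accession} is not reviewed human"
            )
        sources[rec.drug_id][rec.accession].add(rec.source)
    return {
        drug: TargetProfile(
            drug_id=drug,
            accessions=frozenset(per_acc),
            sources_per_accession={a: frozenset(s) for a, s in per_acc.items()},
        )
        for drug, per_acc in sources.items()
    }


def profiles_to_frame(profiles: Mapping[str, TargetProfile]) -> pd.DataFrame:
    """Flatten profiles to a (drug_id, accession, sources) table."""
    rows = [
        (drug, acc, ";".join(sorted(profile.sources_per_accession[acc])))
        for drug, profile in sorted(profiles.items())
        for acc in sorted(profile.accessions)
    ]
    return pd.DataFrame(rows, columns=["drug_id", "accession", "sources"])


def write_profiles(profiles: Mapping[str, TargetProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False)
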