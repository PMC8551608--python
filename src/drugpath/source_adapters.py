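"""Adapters turning per-source snapshot tables into raw TargetRecords.

Each adapter applies its source's conventions — activity thresholding and
protein-family expansion for ChEMBL, identifier bridging for DrugBank /
TTD / PharmGKB, species collapsing for IUPHAR — and emits only reviewed
human proteins. Rows that cannot be processed (unknown enum value, missing
mapping, unreviewed accession) accumulate in a per-source rejects report
instead of raising, so a single malformed row cannot abort a batch run.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .crossref import CrossRefTable, ProteinTable, read_snapshot_tsv
from .errors import ConfigurationError, SchemaError
from .records import TargetRecord

__all__ = [
    "AdapterResult",
    "RejectRow",
    "parse_chembl_activities",
    "parse_drugbank_targets",
    "parse_ttd_targets",
    "parse_pharmgkb_targets",
    "parse_iuphar_targets",
]

ORGANISM_CLASSES = ("human", "mammal_nonhuman", "nonmammal")
TARGET_TYPES = ("single_protein", "protein_family", "non_protein")
EVIDENCE_KINDS = ("assay", "mechanism_of_action")

PCHEMBL_MAX = 14.0  # sanity bound: -log10 of any plausible molar activity


@dataclass(frozen=True)
class RejectRow:
    source: str
    reason: str
    drug_id: str = ""
    detail: str = ""


@dataclass
class AdapterResult:
    """Records plus the skip/reject bookkeeping of one adapter run."""

    source: str
    records: list[TargetRecord] = field(default_factory=list)
    rejects: list[RejectRow] = field(default_factory=list)
    counts: Counter = field(default_factory=Counter)

    def finish(self) -> "AdapterResult":
        # Deterministic contract: same snapshot -> identical sorted records.
        self.records = sorted(set(self.records))
        return self

    def rejects_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.source, r.reason, r.drug_id, r.detail) for r in self.rejects],
            columns=["source", "reason", "drug_id", "detail"],
        )


def _frame(snapshot: pd.DataFrame | str | Path) -> pd.DataFrame:
    if isinstance(snapshot, pd.DataFrame):
        return snapshot
    return read_snapshot_tsv(snapshot)


def _require(frame: pd.DataFrame, columns: list[str], source: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{source} snapshot: missing required column(s): {', '.join(missing)}"
        )


def _emit(
    out: AdapterResult,
    proteins: ProteinTable,
    drug_id: str,
    accession: str,
    provenance: str,
) -> None:
    """Emit a record if the accession is reviewed human, else count the drop."""
    if proteins.is_reviewed_human(accession):
        out.records.append(
            TargetRecord(
                drug_id=drug_id,
                accession=accession,
                source=out.source,
                provenance=provenance,
            )
        )
        out.counts["emitted"] += 1
    elif proteins.known(accession):
        out.counts["dropped_unreviewed_or_nonhuman"] += 1
    else:
        out.counts["dropped_unknown_accession"] += 1


def parse_chembl_activities(
    snapshot: pd.DataFrame | str | Path,
    proteins: ProteinTable,
    drugs: set[str] | None = None,
    pchembl_min: float = 5.0,
    include_ortholog_lift: bool = True,
) -> AdapterResult:
    """Parse ChEMBL-style activity records into TargetRecords.

    Assay rows qualify when pChEMBL >= *pchembl_min* (inclusive; pChEMBL 5
    corresponds to 10 uM); mechanism-of-action rows qualify unconditionally.
    Protein-family targets expand to all member accessions; non-protein and
    non-mammalian targets are dropped; non-human mammalian targets are
    lifted to the reviewed human accessions sharing the gene symbol when
    *include_ortholog_lift* is on. Unreviewed accessions are dropped.
    """
    frame = _frame(snapshot)
    _require(
        frame,
        ["drug_id", "target_accession", "gene_symbol", "pchembl",
         "organism_class", "target_type", "evidence"],
        "chembl",
    )
    has_family = "family_members" in frame.columns
    out = AdapterResult(source="chembl")

    for row in frame.itertuples(index=False):
        drug = row.drug_id
        if drugs is not None and drug not in drugs:
            out.counts["skipped_other_drug"] += 1
            continue
        if row.organism_class not in ORGANISM_CLASSES:
            out.rejects.append(
                RejectRow("chembl", "unknown_organism_class", drug, str(row.organism_class))
            )
            continue
        if row.target_type not in TARGET_TYPES:
            out.rejects.append(
                RejectRow("chembl", "unknown_target_type", drug, str(row.target_type))
            )
            continue
        if row.evidence not in EVIDENCE_KINDS:
            out.rejects.append(
                RejectRow("chembl", "unknown_evidence", drug, str(row.evidence))
            )
            continue

        if row.evidence == "assay":
            raw = str(row.pchembl).strip()
            if not raw:
                out.rejects.append(RejectRow("chembl", "assay_missing_pchembl", drug))
                continue
            try:
                pchembl = float(raw)
            except ValueError:
                out.rejects.append(RejectRow("chembl", "unparsable_pchembl", drug, raw))
                continue
            if not (0.0 <= pchembl <= PCHEMBL_MAX) or math.isnan(pchembl):
                out.rejects.append(RejectRow("chembl", "pchembl_out_of_range", drug, raw))
                continue
            if pchembl < pchembl_min:
                out.counts["below_pchembl_threshold"] += 1
                continue

        if row.target_type == "non_protein":
            out.counts["dropped_non_protein"] += 1
            continue
        if row.organism_class == "nonmammal":
            out.counts["dropped_nonmammal"] += 1
            continue

        if row.organism_class == "mammal_nonhuman":
            if not include_ortholog_lift:
                out.counts["skipped_mammal_lift_disabled"] += 1
                continue
            gene = str(row.gene_symbol).strip()
            if not gene:
                out.rejects.append(RejectRow("chembl", "mammal_row_missing_gene", drug))
                continue
            lifted = proteins.reviewed_human_for_gene(gene)
            if not lifted:
                out.counts["ortholog_lift_no_human_equivalent"] += 1
                continue
            for acc in lifted:
                _emit(out, proteins, drug, acc, f"ortholog-lift:{gene}")
            continue

        # human row
        if row.target_type == "protein_family":
            members = str(getattr(row, "family_members", "") if has_family else "").strip()
            if not members:
                out.rejects.append(RejectRow("chembl", "family_without_members", drug))
                continue
            for acc in members.split(";"):
                acc = acc.strip()
                if acc:
                    _emit(out, proteins, drug, acc, f"family-expansion:{row.target_accession}")
            continue

        acc = str(row.target_accession).strip()
        if not acc:
            out.rejects.append(RejectRow("chembl", "missing_accession", drug))
            continue
        _emit(out, proteins, drug, acc, row.evidence)

    return out.finish()


def parse_drugbank_targets(
    snapshot: pd.DataFrame | str | Path,
    crossrefs: CrossRefTable,
    proteins: ProteinTable,
) -> AdapterResult:
    """DrugBank-keyed targets, bridged to ChEMBL IDs via the crossref table."""
    frame = _frame(snapshot)
    _require(frame, ["drugbank_id", "accession"], "drugbank")
    if not crossrefs.has_namespace_pair("drugbank", "chembl"):
        raise ConfigurationError("crossref table has no drugbank<->chembl mappings")
    out = AdapterResult(source="drugbank")
    for row in frame.itertuples(index=False):
        chembl_ids = crossrefs.map("drugbank", row.drugbank_id, "chembl")
        if not chembl_ids:
            out.counts["unmapped_drug"] += 1
            out.rejects.append(
                RejectRow("drugbank", "no_chembl_mapping", detail=row.drugbank_id)
            )
            continue
        for chembl_id in sorted(chembl_ids):
            _emit(out, proteins, chembl_id, str(row.accession).strip(),
                  f"drugbank:{row.drugbank_id}")
    return out.finish()


def parse_ttd_targets(
    snapshot: pd.DataFrame | str | Path,
    crossrefs: CrossRefTable,
    proteins: ProteinTable,
) -> AdapterResult:
    """TTD targets: drug chain TTD->PubChem->ChEMBL, UniProt names -> accessions."""
    frame = _frame(snapshot)
    _require(frame, ["ttd_id", "pubchem_cid", "uniprot_name"], "ttd")
    if not crossrefs.has_namespace_pair("pubchem_cid", "chembl"):
        raise ConfigurationError("crossref table has no pubchem_cid<->chembl mappings")
    out = AdapterResult(source="ttd")
    for row in frame.itertuples(index=False):
        chembl_ids = crossrefs.map("pubchem_cid", str(row.pubchem_cid), "chembl")
        if not chembl_ids:
            out.counts["unmapped_drug"] += 1
            out.rejects.append(RejectRow("ttd", "no_chembl_mapping", detail=str(row.ttd_id)))
            continue
        accessions = crossrefs.map("uniprot_name", str(row.uniprot_name).strip(),
                                   "uniprot_accession")
        if not accessions:
            out.counts["untranslatable_uniprot_name"] += 1
            out.rejects.append(
                RejectRow("ttd", "no_accession_for_name", detail=str(row.uniprot_name))
            )
            continue
        for chembl_id in sorted(chembl_ids):
            for acc in sorted(accessions):
                _emit(out, proteins, chembl_id, acc, f"ttd:{row.ttd_id}")
    return out.finish()


def parse_pharmgkb_targets(
    snapshot: pd.DataFrame | str | Path,
    crossrefs: CrossRefTable,
    proteins: ProteinTable,
) -> AdapterResult:
    """PharmGKB drug-gene relationships resolved to reviewed human accessions."""
    frame = _frame(snapshot)
    _require(frame, ["pharmgkb_id", "gene_symbol"], "pharmgkb")
    if not crossrefs.has_namespace_pair("pharmgkb", "chembl"):
        raise ConfigurationError("crossref table has no pharmgkb<->chembl mappings")
    out = AdapterResult(source="pharmgkb")
    for row in frame.itertuples(index=False):
        chembl_ids = crossrefs.map("pharmgkb", row.pharmgkb_id, "chembl")
        if not chembl_ids:
            out.counts["unmapped_drug"] += 1
            out.rejects.append(
                RejectRow("pharmgkb", "no_chembl_mapping", detail=row.pharmgkb_id)
            )
            continue
        gene = str(row.gene_symbol).strip()
        accessions = proteins.reviewed_human_for_gene(gene)
        if not accessions:
            out.counts["unmapped_gene"] += 1
            out.rejects.append(RejectRow("pharmgkb", "no_accession_for_gene", detail=gene))
            continue
        for chembl_id in sorted(chembl_ids):
            for acc in accessions:
                _emit(out, proteins, chembl_id, acc, f"pharmgkb:{gene}")
    return out.finish()


def parse_iuphar_targets(
    snapshot: pd.DataFrame | str | Path,
    crossrefs: CrossRefTable,
    proteins: ProteinTable,
) -> AdapterResult:
    """IUPHAR ligand-target rows.

    IUPHAR target IDs are organism-agnostic (one ID covers the human,
    mouse and rat proteins); each is resolved to its human UniProt
    accession(s) only, via the iuphar_target<->uniprot_accession crossref.
    """
    frame = _frame(snapshot)
    _require(frame, ["ligand_id", "target_id"], "iuphar")
    if not crossrefs.has_namespace_pair("iuphar_ligand", "chembl"):
        raise ConfigurationError("crossref table has no iuphar_ligand<->chembl mappings")
    out = AdapterResult(source="iuphar")
    for row in frame.itertuples(index=False):
        chembl_ids = crossrefs.map("iuphar_ligand", str(row.ligand_id), "chembl")
        if not chembl_ids:
            out.counts["unmapped_ligand"] += 1
            out.rejects.append(
                RejectRow("iuphar", "no_chembl_mapping", detail=str(row.ligand_id))
            )
            continue
        accessions = crossrefs.map("iuphar_target", str(row.target_id),
                                   "uniprot_accession")
        if not accessions:
            out.counts["no_human_equivalent"] += 1
            out.rejects.append(
                RejectRow("iuphar", "no_human_accession", detail=str(row.target_id))
            )
            continue
        for chembl_id in sorted(chembl_ids):
            for acc in sorted(accessions):
                _emit(out, proteins, chembl_id, acc, f"iuphar-target:{row.target_id}")
    return out.finish()
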