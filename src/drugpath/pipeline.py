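"""End-to-end orchestration: adapters -> harmonize -> tissue filter -> ORA.

Runs the four pipeline stages sequentially for each input drug against a
local snapshot directory, collecting per-drug stage counts (raw records,
deduplicated pool, tissue-filtered pool, found-in-universe, significant
pathways) and per-source reject tallies into a machine-readable run
report. All outputs have fixed sort orders and contain no timestamps, so
identical inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import harmonize, source_adapters
from .crossref import CrossRefTable, ProteinTable, read_snapshot_tsv
from .enrichment import EnrichmentConfig, OraResult, run_ora
from .errors import ConfigurationError
from .pathways import PathwayAnnotation, PathwayHierarchy, load_annotations
from .records import TargetProfile
from .tissue_filter import ExpressionTable, TissueFilterConfig, filter_profile

__all__ = [
    "SNAPSHOT_FILES",
    "Snapshots",
    "RunConfig",
    "DrugRunRecord",
    "PipelineResult",
    "load_snapshots",
    "run_pipeline",
    "results_csv_frame",
    "write_outputs",
]

RESULTS_CSV_COLUMNS = ["molecule_chembl_id", "Names", "stIds", "fdrs", "pValues"]

SNAPSHOT_FILES = {
    "chembl": "chembl_activities.tsv",
    "drugbank": "drugbank_targets.tsv",
    "ttd": "ttd_targets.tsv",
    "pharmgkb": "pharmgkb_targets.tsv",
    "iuphar": "iuphar_targets.tsv",
    "crossrefs": "crossrefs.tsv",
    "proteins": "uniprot_proteins.tsv",
    "expression": "expression.tsv",
    "gmt": "pathways.gmt",
    "flags": "pathway_flags.tsv",
    "hierarchy": "pathway_hierarchy.tsv",
}


@dataclass
class Snapshots:
    """All parsed snapshot inputs of one run."""

    chembl: pd.DataFrame
    drugbank: pd.DataFrame
    ttd: pd.DataFrame
    pharmgkb: pd.DataFrame
    iuphar: pd.DataFrame
    crossrefs: CrossRefTable
    proteins: ProteinTable
    expression: ExpressionTable
    annotations: list[PathwayAnnotation]
    hierarchy: PathwayHierarchy


def load_snapshots(snapshot_dir: str | Path) -> Snapshots:
    """Load and validate a snapshot directory (pre-flight: all files named)."""
    root = Path(snapshot_dir)
    missing = [name for name in SNAPSHOT_FILES.values() if not (root / name).is_file()]
    if missing:
        raise ConfigurationError(
            f"snapshot directory {root} is missing: {', '.join(sorted(missing))}"
        )
    return Snapshots(
        chembl=read_snapshot_tsv(root / SNAPSHOT_FILES["chembl"]),
        drugbank=read_snapshot_tsv(root / SNAPSHOT_FILES["drugbank"]),
        ttd=read_snapshot_tsv(root / SNAPSHOT_FILES["ttd"]),
        pharmgkb=read_snapshot_tsv(root / SNAPSHOT_FILES["pharmgkb"]),
        iuphar=read_snapshot_tsv(root / SNAPSHOT_FILES["iuphar"]),
        crossrefs=CrossRefTable.from_tsv(root / SNAPSHOT_FILES["crossrefs"]),
        proteins=ProteinTable.from_tsv(root / SNAPSHOT_FILES["proteins"]),
        expression=ExpressionTable.from_tsv(root / SNAPSHOT_FILES["expression"]),
        annotations=load_annotations(
            root / SNAPSHOT_FILES["gmt"], root / SNAPSHOT_FILES["flags"]
        ),
        hierarchy=PathwayHierarchy.from_tsv(root / SNAPSHOT_FILES["hierarchy"]),
    )


@dataclass(frozen=True)
class RunConfig:
    drugs: tuple[str, ...]
    tissue: str | None = None
    min_ntpm: float = 1.0
    keep_unmeasured: bool = False
    pchembl_min: float = 5.0
    include_ortholog_lift: bool = True
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)

    def __post_init__(self) -> None:
        if not self.drugs:
            raise ConfigurationError("no drug identifiers provided")


@dataclass
class DrugRunRecord:
    """Stage-by-stage accounting for one drug."""

    drug_id: str
    status: str                    # "ok" | "no-targets-found" | "no-proteins-found"
    n_raw_records: int = 0
    n_pool: int = 0
    n_tissue_filtered: int = 0
    n_found_in_universe: int = 0
    n_significant: int = 0
    ora: OraResult | None = None


@dataclass
class PipelineResult:
    config: RunConfig
    drugs: list[DrugRunRecord]
    rejects: pd.DataFrame
    adapter_counts: dict[str, dict[str, int]]

    @property
    def significant_by_drug(self) -> dict[str, frozenset[str]]:
        return {
            d.drug_id: (d.ora.significant_st_ids if d.ora else frozenset())
            for d in self.drugs
        }


def run_pipeline(cfg: RunConfig, snapshots: Snapshots) -> PipelineResult:
    """Execute adapters -> harmonize -> (optional) tissue filter -> ORA."""
    drug_set = set(cfg.drugs)
    adapter_results = [
        source_adapters.parse_chembl_activities(
            snapshots.chembl, snapshots.proteins, drugs=drug_set,
            pchembl_min=cfg.pchembl_min,
            include_ortholog_lift=cfg.include_ortholog_lift,
        ),
        source_adapters.parse_drugbank_targets(
            snapshots.drugbank, snapshots.crossrefs, snapshots.proteins
        ),
        source_adapters.parse_ttd_targets(
            snapshots.ttd, snapshots.crossrefs, snapshots.proteins
        ),
        source_adapters.parse_pharmgkb_targets(
            snapshots.pharmgkb, snapshots.crossrefs, snapshots.proteins
        ),
        source_adapters.parse_iuphar_targets(
            snapshots.iuphar, snapshots.crossrefs, snapshots.proteins
        ),
    ]
    records = [
        r for res in adapter_results for r in res.records if r.drug_id in drug_set
    ]
    raw_counts: dict[str, int] = {d: 0 for d in cfg.drugs}
    for record in records:
        raw_counts[record.drug_id] += 1
    profiles = harmonize.build_profiles(records)

    acc2gene = snapshots.proteins.accession_to_genes()
    tissue_cfg = (
        TissueFilterConfig(
            tissue=cfg.tissue, min_ntpm=cfg.min_ntpm,
            keep_unmeasured=cfg.keep_unmeasured,
        )
        if cfg.tissue
        else None
    )

    drug_records: list[DrugRunRecord] = []
    for drug in cfg.drugs:  # input order preserved ("sequentially for each compound")
        if drug not in profiles:
            drug_records.append(
                DrugRunRecord(drug_id=drug, status="no-targets-found")
            )
            continue
        profile: TargetProfile = profiles[drug]
        n_pool = len(profile)
        if tissue_cfg is not None:
            profile, _report = filter_profile(
                profile, snapshots.expression, acc2gene, tissue_cfg
            )
        n_filtered = len(profile)
        if n_filtered == 0:
            drug_records.append(
                DrugRunRecord(
                    drug_id=drug, status="no-proteins-found",
                    n_raw_records=raw_counts[drug], n_pool=n_pool,
                )
            )
            continue
        ora = run_ora(profile, snapshots.annotations, snapshots.hierarchy,
                      cfg.enrichment)
        drug_records.append(
            DrugRunRecord(
                drug_id=drug, status=ora.status,
                n_raw_records=raw_counts[drug], n_pool=n_pool,
                n_tissue_filtered=n_filtered, n_found_in_universe=ora.n,
                n_significant=len(ora.results), ora=ora,
            )
        )

    rejects = pd.concat(
        [res.rejects_frame() for res in adapter_results], ignore_index=True
    )
    return PipelineResult(
        config=cfg,
        drugs=drug_records,
        rejects=rejects,
        adapter_counts={res.source: dict(res.counts) for res in adapter_results},
    )


def results_csv_frame(result: PipelineResult) -> pd.DataFrame:
    """Significant pathways of all drugs in the published output schema."""
    rows = [
        (d.drug_id, r.name, r.st_id, f"{r.fdr:.6g}", f"{r.p_value:.6g}")
        for d in result.drugs if d.ora is not None
        for r in d.ora.results
    ]
    return pd.DataFrame(rows, columns=RESULTS_CSV_COLUMNS)


def write_outputs(result: PipelineResult, out_dir: str | Path) -> Path:
    """Write results.csv, results.json, run_report.json and rejects.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results_csv_frame(result).to_csv(out / "results.csv", index=False)

    detail = {
        d.drug_id: {
            "status": d.status,
            "n": d.ora.n if d.ora else 0,
            "N": d.ora.N if d.ora else 0,
            "not_found": d.ora.n_not_found if d.ora else 0,
            "n_tested": d.ora.n_tested if d.ora else 0,
            "results": [
                {"st_id": r.st_id, "name": r.name, "k": r.k, "K": r.K,
                 "n": r.n, "N": r.N, "p_value": r.p_value, "fdr": r.fdr}
                for r in (d.ora.results if d.ora else [])
            ],
        }
        for d in result.drugs
    }
    with open(out / "results.json", "w", encoding="utf-8") as handle:
        json.dump(detail, handle, indent=2, sort_keys=True)
        handle.write("\n")

    report = {
        "frequency_denominator_rule": "drugs with >=1 significant pathway",
        "drugs": {
            d.drug_id: {
                "status": d.status,
                "raw_records": d.n_raw_records,
                "deduplicated_pool": d.n_pool,
                "tissue_filtered": d.n_tissue_filtered,
                "found_in_universe": d.n_found_in_universe,
                "significant_pathways": d.n_significant,
            }
            for d in result.drugs
        },
        "adapter_counts": result.adapter_counts,
        "n_rejected_rows": int(len(result.rejects)),
    }
    with open(out / "run_report.json", "w", encoding="utf-8") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
        handle.write("\n")

    result.rejects.to_csv(out / "rejects.tsv", sep="\t", index=False)
    return out
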