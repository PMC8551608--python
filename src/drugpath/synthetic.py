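"""Seeded generator for a miniature, coherent multi-source snapshot universe.

The generator emulates the inputs the pipeline consumes in production —
five drug-target source tables, identifier crossrefs, a protein status
table, consensus tissue expression, pathway sets with flags and a 3-level
hierarchy — with a planted ground truth: each planted drug draws most of
its targets from one assigned leaf pathway, so recovering that pathway as
the top enrichment hit is a testable expectation. Null drugs draw targets
uniformly, which makes the same universe (with planting disabled) a
false-discovery calibration bench.

Every output is a pure function of the master seed: each file draws from
its own labelled RNG substream, so adding an output never perturbs the
others, and equal seeds yield byte-identical file trees.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .crossref import CrossRefTable, ProteinTable
from .errors import ConfigurationError
from .pathways import PathwayAnnotation, PathwayHierarchy, write_flags, write_gmt
from .pipeline import SNAPSHOT_FILES, Snapshots
from .tissue_filter import ExpressionTable

__all__ = ["SimulationConfig", "SyntheticUniverse", "generate_universe", "generate_null"]

# Labelled RNG substreams (one per logical output) derived from the master seed.
_STREAMS = {
    "pathways": 1, "hierarchy": 2, "flags": 3, "drugs": 4, "targets": 5,
    "chembl": 6, "redundancy": 7, "expression": 8, "reference": 9,
}


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAMS[label]]))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic universe; defaults are the benchmark conditions."""

    seed: int
    n_proteins: int = 1000
    n_pathways: int = 100
    pathway_size_range: tuple[int, int] = (5, 50)
    n_drugs: int = 50
    targets_per_drug: int = 10
    planted_fraction: float = 0.8
    n_planted_drugs: int = 20
    tissues: tuple[str, ...] = ("heart", "liver")
    expressed_fraction_per_tissue: float = 0.6
    source_redundancy: float = 0.3
    pchembl_mean_active: float = 7.0
    pchembl_sd_active: float = 1.0
    pchembl_mean_inactive: float = 4.0
    pchembl_sd_inactive: float = 0.4
    disease_fraction: float = 0.1
    moa_fraction: float = 0.05
    mammal_duplicate_fraction: float = 0.1
    n_mammal_only_pairs: int = 5
    n_family_drugs: int = 3
    n_decoy_inactive: int = 50
    n_unreviewed: int = 10
    n_nonhuman: int = 10
    n_nonmammal_rows: int = 5

    def __post_init__(self) -> None:
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi <= self.n_proteins):
            raise ConfigurationError("pathway_size_range out of bounds")
        if not 0 <= self.planted_fraction <= 1:
            raise ConfigurationError("planted_fraction must be in [0, 1]")
        if self.n_planted_drugs > self.n_drugs:
            raise ConfigurationError("n_planted_drugs exceeds n_drugs")
        if self.targets_per_drug > self.n_proteins:
            raise ConfigurationError("targets_per_drug exceeds n_proteins")
        if self.n_pathways < 6:
            raise ConfigurationError("need at least 6 pathways for a 3-level tree")
        if not self.tissues:
            raise ConfigurationError("at least one tissue is required")
        if self.planted_need > hi:
            raise ConfigurationError(
                f"planted draw ({self.planted_need}) exceeds the largest "
                f"possible pathway ({hi})"
            )

    @property
    def planted_need(self) -> int:
        """Targets a planted drug must draw from its pathway."""
        return math.ceil(self.planted_fraction * self.targets_per_drug)


@dataclass
class SyntheticUniverse:
    """In-memory snapshot universe plus its ground-truth manifest."""

    cfg: SimulationConfig
    chembl: pd.DataFrame
    drugbank: pd.DataFrame
    ttd: pd.DataFrame
    pharmgkb: pd.DataFrame
    iuphar: pd.DataFrame
    crossrefs: pd.DataFrame
    proteins: pd.DataFrame
    expression: pd.DataFrame
    annotations: list[PathwayAnnotation]
    hierarchy_edges: list[tuple[str, str]]
    reference: pd.DataFrame
    manifest: dict

    def to_snapshots(self) -> Snapshots:
        """Wrap the in-memory tables in the pipeline's snapshot container."""
        return Snapshots(
            chembl=self.chembl, drugbank=self.drugbank, ttd=self.ttd,
            pharmgkb=self.pharmgkb, iuphar=self.iuphar,
            crossrefs=CrossRefTable(self.crossrefs),
            proteins=ProteinTable(self.proteins),
            expression=ExpressionTable(self.expression),
            annotations=list(self.annotations),
            hierarchy=PathwayHierarchy(self.hierarchy_edges),
        )

    def write(self, out_dir: str | Path) -> Path:
        """Write the full snapshot tree (TSVs, GMT, hierarchy, manifest)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)

        def tsv(frame: pd.DataFrame, name: str) -> None:
            with open(out / name, "w", encoding="utf-8") as handle:
                handle.write("# drugpath-snapshot v1\n")
                frame.to_csv(handle, sep="\t", index=False)

        tsv(self.chembl, SNAPSHOT_FILES["chembl"])
        tsv(self.drugbank, SNAPSHOT_FILES["drugbank"])
        tsv(self.ttd, SNAPSHOT_FILES["ttd"])
        tsv(self.pharmgkb, SNAPSHOT_FILES["pharmgkb"])
        tsv(self.iuphar, SNAPSHOT_FILES["iuphar"])
        tsv(self.crossrefs, SNAPSHOT_FILES["crossrefs"])
        tsv(self.proteins, SNAPSHOT_FILES["proteins"])
        tsv(self.expression, SNAPSHOT_FILES["expression"])
        write_gmt(self.annotations, out / SNAPSHOT_FILES["gmt"])
        write_flags(self.annotations, out / SNAPSHOT_FILES["flags"])
        PathwayHierarchy(self.hierarchy_edges).write_tsv(out / SNAPSHOT_FILES["hierarchy"])
        tsv(self.reference, "reactome_reference.tsv")
        with open(out / "manifest.json", "w", encoding="utf-8") as handle:
            json.dump(self.manifest, handle, indent=2, sort_keys=True)
            handle.write("\n")
        return out


def _drug_id(i: int) -> str:
    return f"CHEMBL{100001 + i}"


def generate_universe(
    cfg: SimulationConfig, out_dir: str | Path | None = None
) -> SyntheticUniverse:
    """Generate the snapshot universe for *cfg* (optionally writing it).

    Infeasible configurations (e.g. no leaf pathway large enough for the
    planted draw) raise ConfigurationError before any file is written.
    """
    accs = [f"P{i:05d}" for i in range(cfg.n_proteins)]
    genes = [f"G{i:05d}" for i in range(cfg.n_proteins)]
    gene_of = dict(zip(accs, genes))

    protein_rows = [(a, g, "true", "true") for a, g in zip(accs, genes)]
    protein_rows += [
        (f"Q9{i:04d}", f"GU{i:04d}", "false", "true") for i in range(cfg.n_unreviewed)
    ]
    protein_rows += [
        (f"O7{i:04d}", genes[i % cfg.n_proteins], "true", "false")
        for i in range(cfg.n_nonhuman)
    ]
    proteins = pd.DataFrame(
        protein_rows, columns=["accession", "gene_symbol", "reviewed", "human"]
    )

    # ---- pathways: 3-level tree (roots -> mid -> leaves) -------------------
    n_roots = max(2, cfg.n_pathways // 20)
    n_mid = max(n_roots, cfg.n_pathways // 5)
    n_leaf = cfg.n_pathways - n_roots - n_mid
    if n_leaf < 1:
        raise ConfigurationError("n_pathways too small for a 3-level tree")
    st_ids = [f"R-HSA-{9000000 + i}" for i in range(cfg.n_pathways)]
    levels = ["root"] * n_roots + ["mid"] * n_mid + ["leaf"] * n_leaf

    rng_p = _rng(cfg.seed, "pathways")
    lo, hi = cfg.pathway_size_range
    sizes = rng_p.integers(lo, hi + 1, size=cfg.n_pathways)
    members = [
        sorted(rng_p.choice(cfg.n_proteins, size=int(s), replace=False))
        for s in sizes
    ]

    rng_f = _rng(cfg.seed, "flags")
    is_disease = rng_f.random(cfg.n_pathways) < cfg.disease_fraction

    rng_h = _rng(cfg.seed, "hierarchy")
    mid_parent = rng_h.integers(0, n_roots, size=n_mid)
    leaf_parent = rng_h.integers(0, n_mid, size=n_leaf)
    hierarchy_edges = [
        (st_ids[mid_parent[i]], st_ids[n_roots + i]) for i in range(n_mid)
    ] + [
        (st_ids[n_roots + leaf_parent[i]], st_ids[n_roots + n_mid + i])
        for i in range(n_leaf)
    ]

    # ---- planted drug -> pathway assignments -------------------------------
    rng_d = _rng(cfg.seed, "drugs")
    planting = cfg.n_planted_drugs > 0 and cfg.planted_fraction > 0
    planted_assignment: dict[int, int] = {}
    if planting:
        eligible = [
            n_roots + n_mid + i
            for i in range(n_leaf)
            if sizes[n_roots + n_mid + i] >= cfg.planted_need
            and not is_disease[n_roots + n_mid + i]
        ]
        if not eligible:
            raise ConfigurationError(
                "no non-disease leaf pathway is large enough for the planted draw"
            )
        chosen = rng_d.choice(
            eligible, size=cfg.n_planted_drugs,
            replace=len(eligible) < cfg.n_planted_drugs,
        )
        planted_assignment = {i: int(chosen[i]) for i in range(cfg.n_planted_drugs)}

    # ---- drug target sets --------------------------------------------------
    rng_t = _rng(cfg.seed, "targets")
    drug_targets: dict[int, list[int]] = {}
    for i in range(cfg.n_drugs):
        if i in planted_assignment:
            pool = members[planted_assignment[i]]
            inside = rng_t.choice(pool, size=cfg.planted_need, replace=False)
            rest_pool = np.setdiff1d(np.arange(cfg.n_proteins), inside)
            outside = rng_t.choice(
                rest_pool, size=cfg.targets_per_drug - cfg.planted_need, replace=False
            )
            drug_targets[i] = sorted(int(t) for t in np.concatenate([inside, outside]))
        else:
            drug_targets[i] = sorted(
                int(t) for t in rng_t.choice(
                    cfg.n_proteins, size=cfg.targets_per_drug, replace=False
                )
            )

    null_drugs = [i for i in range(cfg.n_drugs) if i not in planted_assignment]

    # extra pairs only evidenced by a non-human mammalian assay row
    mammal_only: list[tuple[int, int]] = []
    for _ in range(cfg.n_mammal_only_pairs if null_drugs else 0):
        drug = int(rng_t.choice(null_drugs))
        pool = np.setdiff1d(np.arange(cfg.n_proteins), drug_targets[drug])
        target = int(rng_t.choice(pool))
        drug_targets[drug] = sorted(drug_targets[drug] + [target])
        mammal_only.append((drug, target))
    mammal_only_set = set(mammal_only)

    # a few drugs whose grouped targets are evidenced only via a family row
    family_groups: dict[int, list[int]] = {}
    for drug in null_drugs[: cfg.n_family_drugs]:
        grouped = [t for t in drug_targets[drug][:3]
                   if (drug, t) not in mammal_only_set]
        if len(grouped) >= 2:
            family_groups[drug] = grouped

    # ---- ChEMBL activity snapshot ------------------------------------------
    rng_c = _rng(cfg.seed, "chembl")

    def active_pchembl() -> str:
        return f"{float(np.clip(rng_c.normal(cfg.pchembl_mean_active, cfg.pchembl_sd_active), 5.0, 14.0)):.2f}"

    chembl_rows: list[tuple[str, ...]] = []
    for i in range(cfg.n_drugs):
        drug = _drug_id(i)
        grouped = set(family_groups.get(i, ()))
        for t in drug_targets[i]:
            if (i, t) in mammal_only_set:
                chembl_rows.append(
                    (drug, "", genes[t], active_pchembl(), "mammal_nonhuman",
                     "single_protein", "", "assay")
                )
                continue
            if t in grouped:
                continue  # evidenced via the family row below
            if rng_c.random() < cfg.moa_fraction:
                chembl_rows.append(
                    (drug, accs[t], genes[t], "", "human", "single_protein",
                     "", "mechanism_of_action")
                )
            else:
                chembl_rows.append(
                    (drug, accs[t], genes[t], active_pchembl(), "human",
                     "single_protein", "", "assay")
                )
            if rng_c.random() < cfg.mammal_duplicate_fraction:
                chembl_rows.append(
                    (drug, "", genes[t], active_pchembl(), "mammal_nonhuman",
                     "single_protein", "", "assay")
                )
        if i in family_groups:
            chembl_rows.append(
                (drug, f"FAM{i:04d}", "", active_pchembl(), "human",
                 "protein_family", ";".join(accs[t] for t in family_groups[i]),
                 "assay")
            )

    # decoys exercising every adapter filter
    for _ in range(cfg.n_decoy_inactive):
        drug = int(rng_c.integers(0, cfg.n_drugs))
        t = int(rng_c.integers(0, cfg.n_proteins))
        val = float(np.clip(
            rng_c.normal(cfg.pchembl_mean_inactive, cfg.pchembl_sd_inactive), 0.0, 4.99
        ))
        chembl_rows.append(
            (_drug_id(drug), accs[t], genes[t], f"{val:.2f}", "human",
             "single_protein", "", "assay")
        )
    for j in range(cfg.n_nonmammal_rows):
        drug = int(rng_c.integers(0, cfg.n_drugs))
        t = int(rng_c.integers(0, cfg.n_proteins))
        chembl_rows.append(
            (_drug_id(drug), accs[t], genes[t], active_pchembl(), "nonmammal",
             "single_protein", "", "assay")
        )
    for j in range(min(cfg.n_unreviewed, 3)):
        drug = int(rng_c.integers(0, cfg.n_drugs))
        chembl_rows.append(
            (_drug_id(drug), f"Q9{j:04d}", f"GU{j:04d}", active_pchembl(),
             "human", "single_protein", "", "assay")
        )

    chembl = pd.DataFrame(
        chembl_rows,
        columns=["drug_id", "target_accession", "gene_symbol", "pchembl",
                 "organism_class", "target_type", "family_members", "evidence"],
    )

    # ---- cross-source redundancy -------------------------------------------
    rng_r = _rng(cfg.seed, "redundancy")
    drugbank_rows, ttd_rows, pharmgkb_rows, iuphar_rows = [], [], [], []

    def add_to_source(source_index: int, drug: int, target: int) -> None:
        if source_index == 0:
            drugbank_rows.append((f"DB{drug:05d}", accs[target]))
        elif source_index == 1:
            ttd_rows.append((f"D{drug:05d}", str(10000 + drug),
                             f"{genes[target]}_HUMAN"))
        elif source_index == 2:
            pharmgkb_rows.append((f"PA{drug:05d}", genes[target]))
        else:
            iuphar_rows.append((str(5000 + drug), str(20000 + target)))

    for i in range(cfg.n_drugs):
        for t in drug_targets[i]:
            if rng_r.random() < cfg.source_redundancy:
                add_to_source(int(rng_r.integers(0, 4)), i, t)
    # every source table must be non-empty so its adapter always runs
    for source_index in range(4):
        if not (drugbank_rows, ttd_rows, pharmgkb_rows, iuphar_rows)[source_index]:
            add_to_source(source_index, 0, drug_targets[0][0])

    drugbank = pd.DataFrame(drugbank_rows, columns=["drugbank_id", "accession"])
    ttd = pd.DataFrame(ttd_rows, columns=["ttd_id", "pubchem_cid", "uniprot_name"])
    pharmgkb = pd.DataFrame(pharmgkb_rows, columns=["pharmgkb_id", "gene_symbol"])
    iuphar = pd.DataFrame(iuphar_rows, columns=["ligand_id", "target_id"])

    # ---- crossrefs ----------------------------------------------------------
    xref_rows = []
    for i in range(cfg.n_drugs):
        drug = _drug_id(i)
        xref_rows += [
            ("chembl", drug, "drugbank", f"DB{i:05d}"),
            ("chembl", drug, "pubchem_cid", str(10000 + i)),
            ("chembl", drug, "pharmgkb", f"PA{i:05d}"),
            ("chembl", drug, "iuphar_ligand", str(5000 + i)),
            ("chembl", drug, "chebi", f"CHEBI:{40000 + i}"),
        ]
    for t in range(cfg.n_proteins):
        xref_rows += [
            ("uniprot_name", f"{genes[t]}_HUMAN", "uniprot_accession", accs[t]),
            ("iuphar_target", str(20000 + t), "uniprot_accession", accs[t]),
        ]
    crossrefs = pd.DataFrame(
        xref_rows, columns=["namespace_a", "id_a", "namespace_b", "id_b"]
    )

    # ---- expression ---------------------------------------------------------
    rng_e = _rng(cfg.seed, "expression")
    expr_rows = []
    expressed_genes: dict[str, list[str]] = {}
    for tissue in cfg.tissues:
        mask = rng_e.random(cfg.n_proteins) < cfg.expressed_fraction_per_tissue
        values = np.where(
            mask,
            np.maximum(1.0, rng_e.lognormal(math.log(20.0), 1.0, cfg.n_proteins)),
            rng_e.uniform(0.0, 0.9, cfg.n_proteins),
        )
        expressed_genes[tissue] = [genes[i] for i in range(cfg.n_proteins) if mask[i]]
        expr_rows += [
            (genes[i], tissue, f"{values[i]:.2f}") for i in range(cfg.n_proteins)
        ]
    expression = pd.DataFrame(expr_rows, columns=["gene_symbol", "tissue", "ntpm"])

    # ---- reference compound-pathway edges ----------------------------------
    rng_ref = _rng(cfg.seed, "reference")
    ref_rows = []
    for i, pathway_index in planted_assignment.items():
        if rng_ref.random() < 0.5:
            ref_rows.append((f"CHEBI:{40000 + i}", st_ids[pathway_index], "9606"))
    for _ in range(3):
        drug = int(rng_ref.integers(0, cfg.n_drugs))
        leaf = int(rng_ref.integers(n_roots + n_mid, cfg.n_pathways))
        ref_rows.append((f"CHEBI:{40000 + drug}", st_ids[leaf], "9606"))
    # non-human rows that a species filter must remove
    ref_rows.append((f"CHEBI:{40000}", "R-MMU-0000001", "10090"))
    reference = pd.DataFrame(ref_rows, columns=["chebi_id", "st_id", "species_tax_id"])

    annotations = [
        PathwayAnnotation(
            st_id=st_ids[i],
            name=f"Synthetic {levels[i]} pathway {i:03d}",
            members=frozenset(accs[t] for t in members[i]),
            is_disease=bool(is_disease[i]),
        )
        for i in range(cfg.n_pathways)
    ]

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "planted": {_drug_id(i): st_ids[p] for i, p in planted_assignment.items()},
        "drug_targets": {
            _drug_id(i): [accs[t] for t in drug_targets[i]] for i in range(cfg.n_drugs)
        },
        "mammal_only_pairs": [[_drug_id(d), accs[t]] for d, t in mammal_only],
        "family_pairs": [
            [_drug_id(d), accs[t]] for d, grouped in family_groups.items()
            for t in grouped
        ],
        "expressed_genes": {t: sorted(g) for t, g in expressed_genes.items()},
    }

    universe = SyntheticUniverse(
        cfg=cfg, chembl=chembl, drugbank=drugbank, ttd=ttd, pharmgkb=pharmgkb,
        iuphar=iuphar, crossrefs=crossrefs, proteins=proteins,
        expression=expression, annotations=annotations,
        hierarchy_edges=hierarchy_edges, reference=reference, manifest=manifest,
    )
    if out_dir is not None:
        universe.write(out_dir)
    return universe


def generate_null(
    cfg: SimulationConfig, out_dir: str | Path | None = None
) -> SyntheticUniverse:
    """Same file set with no planted signal (for empirical FDR calibration)."""
    return generate_universe(
        replace(cfg, planted_fraction=0.0, n_planted_drugs=0), out_dir
    )
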