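"""Source adapters: per-source filters, ID translation, reject accounting."""

import pandas as pd
import pytest

from drugpath.errors import ConfigurationError, SchemaError
from drugpath.source_adapters import (
    parse_chembl_activities,
    parse_drugbank_targets,
    parse_iuphar_targets,
    parse_pharmgkb_targets,
    parse_ttd_targets,
)

from conftest import make_crossrefs, make_proteins

CHEMBL_COLUMNS = [
    "drug_id", "target_accession", "gene_symbol", "pchembl",
    "organism_class", "target_type", "family_members", "evidence",
]


def chembl_frame(rows):
    return pd.DataFrame(rows, columns=CHEMBL_COLUMNS)


@pytest.fixture
def proteins():
    return make_proteins([
        ("P21964", "COMT", True, True),
        ("P10001", "GENE1", True, True),
        ("P10002", "GENE2", True, True),
        ("P10003", "GENE3", True, True),
        ("Q99999", "GENEU", False, True),   # unreviewed
        ("O70351", "COMT", True, False),    # rat entry, same gene symbol
    ])


class TestChembl:
    def test_pchembl_threshold_is_inclusive(self, proteins):
        frame = chembl_frame([
            ("CHEMBL1", "P10001", "GENE1", "4.9", "human", "single_protein", "", "assay"),
            ("CHEMBL1", "P10002", "GENE2", "5.0", "human", "single_protein", "", "assay"),
        ])
        res = parse_chembl_activities(frame, proteins)
        assert [r.accession for r in res.records] == ["P10002"]
        assert res.counts["below_pchembl_threshold"] == 1

    def test_mechanism_of_action_needs_no_pchembl(self, proteins):
        frame = chembl_frame([
            ("CHEMBL1", "P10001", "GENE1", "", "human", "single_protein", "",
             "mechanism_of_action"),
        ])
        res = parse_chembl_activities(frame, proteins)
        assert [r.accession for r in res.records] == ["P10001"]

    def test_ortholog_lift_joins_rat_gene_to_human_accession(self, proteins):
        frame = chembl_frame([
            ("CHEMBL1", "", "Comt", "6.2", "mammal_nonhuman", "single_protein",
             "", "assay"),
        ])
        res = parse_chembl_activities(frame, proteins)
        assert [(r.accession, r.provenance) for r in res.records] == [
            ("P21964", "ortholog-lift:Comt")
        ]
        off = parse_chembl_activities(frame, proteins, include_ortholog_lift=False)
        assert off.records == []

    def test_family_expands_to_all_members(self, proteins):
        frame = chembl_frame([
            ("CHEMBL1", "FAM1", "", "7.0", "human", "protein_family",
             "P10001;P10002;P10003", "assay"),
        ])
        res = parse_chembl_activities(frame, proteins)
        assert sorted(r.accession for r in res.records) == [
            "P10001", "P10002", "P10003"
        ]
        assert all(r.provenance == "family-expansion:FAM1" for r in res.records)

    def test_non_protein_nonmammal_and_unreviewed_dropped(self, proteins):
        frame = chembl_frame([
            ("CHEMBL1", "P10001", "GENE1", "7.0", "human", "non_protein", "", "assay"),
            ("CHEMBL1", "P10002", "GENE2", "7.0", "nonmammal", "single_protein", "", "assay"),
            ("CHEMBL1", "Q99999", "GENEU", "7.0", "human", "single_protein", "", "assay"),
        ])
        res = parse_chembl_activities(frame, proteins)
        assert res.records == []
        assert res.counts["dropped_non_protein"] == 1
        assert res.counts["dropped_nonmammal"] == 1
        assert res.counts["dropped_unreviewed_or_nonhuman"] == 1

    def test_missing_column_names_the_column(self, proteins):
        with pytest.raises(SchemaError, match="organism_class"):
            parse_chembl_activities(
                pd.DataFrame(columns=[c for c in CHEMBL_COLUMNS
                                      if c != "organism_class"]),
                proteins,
            )

    def test_unknown_organism_class_goes_to_rejects(self, proteins):
        frame = chembl_frame([
            ("CHEMBL1", "P10001", "GENE1", "7.0", "martian", "single_protein", "", "assay"),
            ("CHEMBL1", "P10002", "GENE2", "7.0", "human", "single_protein", "", "assay"),
        ])
        res = parse_chembl_activities(frame, proteins)
        assert [r.accession for r in res.records] == ["P10002"]
        assert res.rejects[0].reason == "unknown_organism_class"

    def test_lowering_threshold_never_removes_records(self, proteins):
        frame = chembl_frame([
            ("CHEMBL1", acc, gene, f"{v:.1f}", "human", "single_protein", "", "assay")
            for acc, gene, v in [
                ("P10001", "GENE1", 4.2), ("P10002", "GENE2", 5.7),
                ("P10003", "GENE3", 6.9), ("P21964", "COMT", 5.0),
            ]
        ])
        previous = None
        for threshold in (7.0, 6.0, 5.0, 4.0):
            current = set(parse_chembl_activities(
                frame, proteins, pchembl_min=threshold).records)
            if previous is not None:
                assert previous <= current
            previous = current

    def test_deterministic_sorted_output(self, proteins):
        frame = chembl_frame([
            ("CHEMBL2", "P10002", "GENE2", "6.0", "human", "single_protein", "", "assay"),
            ("CHEMBL1", "P10001", "GENE1", "6.0", "human", "single_protein", "", "assay"),
        ])
        first = parse_chembl_activities(frame, proteins).records
        second = parse_chembl_activities(
            frame.iloc[::-1].reset_index(drop=True), proteins).records
        assert first == second == sorted(first)


class TestDrugbank:
    def test_mapping_fans_out_to_all_chembl_ids(self, proteins):
        snapshot = pd.DataFrame(
            [("DB1", "P10001")], columns=["drugbank_id", "accession"]
        )
        xrefs = make_crossrefs([
            ("chembl", "CHEMBL1", "drugbank", "DB1"),
            ("chembl", "CHEMBL2", "drugbank", "DB1"),
        ])
        res = parse_drugbank_targets(snapshot, xrefs, proteins)
        assert sorted(r.drug_id for r in res.records) == ["CHEMBL1", "CHEMBL2"]

    def test_unmapped_drug_skipped_and_counted(self, proteins):
        snapshot = pd.DataFrame(
            [("DBX", "P10001")], columns=["drugbank_id", "accession"]
        )
        xrefs = make_crossrefs([("chembl", "CHEMBL1", "drugbank", "DB1")])
        res = parse_drugbank_targets(snapshot, xrefs, proteins)
        assert res.records == [] and res.counts["unmapped_drug"] == 1

    def test_empty_crossref_is_configuration_error(self, proteins):
        snapshot = pd.DataFrame(
            [("DB1", "P10001")], columns=["drugbank_id", "accession"]
        )
        xrefs = make_crossrefs([("uniprot_name", "X_HUMAN",
                                 "uniprot_accession", "P10001")])
        with pytest.raises(ConfigurationError):
            parse_drugbank_targets(snapshot, xrefs, proteins)


class TestTtd:
    def make_xrefs(self):
        return make_crossrefs([
            ("chembl", "CHEMBLY", "pubchem_cid", "123"),
            ("uniprot_name", "COMT_HUMAN", "uniprot_accession", "P21964"),
        ])

    def test_two_step_join(self, proteins):
        snapshot = pd.DataFrame(
            [("D00ABC", "123", "COMT_HUMAN")],
            columns=["ttd_id", "pubchem_cid", "uniprot_name"],
        )
        res = parse_ttd_targets(snapshot, self.make_xrefs(), proteins)
        assert [(r.drug_id, r.accession) for r in res.records] == [
            ("CHEMBLY", "P21964")
        ]

    def test_untranslatable_name_counted(self, proteins):
        snapshot = pd.DataFrame(
            [("D00ABC", "123", "NOPE_HUMAN")],
            columns=["ttd_id", "pubchem_cid", "uniprot_name"],
        )
        res = parse_ttd_targets(snapshot, self.make_xrefs(), proteins)
        assert res.records == []
        assert res.counts["untranslatable_uniprot_name"] == 1

    def test_cid_without_chembl_mapping(self, proteins):
        snapshot = pd.DataFrame(
            [("D00ABC", "999", "COMT_HUMAN")],
            columns=["ttd_id", "pubchem_cid", "uniprot_name"],
        )
        res = parse_ttd_targets(snapshot, self.make_xrefs(), proteins)
        assert res.records == [] and res.counts["unmapped_drug"] == 1


class TestPharmgkb:
    def make_xrefs(self):
        return make_crossrefs([("chembl", "CHEMBL1", "pharmgkb", "PA1")])

    def test_gene_resolved_to_reviewed_human_accessions(self, proteins):
        snapshot = pd.DataFrame(
            [("PA1", "COMT")], columns=["pharmgkb_id", "gene_symbol"]
        )
        res = parse_pharmgkb_targets(snapshot, self.make_xrefs(), proteins)
        # rat COMT entry O70351 is not reviewed human, so only P21964 emits
        assert [(r.drug_id, r.accession) for r in res.records] == [
            ("CHEMBL1", "P21964")
        ]

    def test_unmapped_gene_counted(self, proteins):
        snapshot = pd.DataFrame(
            [("PA1", "NOGENE")], columns=["pharmgkb_id", "gene_symbol"]
        )
        res = parse_pharmgkb_targets(snapshot, self.make_xrefs(), proteins)
        assert res.records == [] and res.counts["unmapped_gene"] == 1

    def test_gene_with_two_reviewed_accessions_emits_both(self):
        proteins = make_proteins([
            ("P10001", "DUP", True, True),
            ("P10002", "DUP", True, True),
        ])
        snapshot = pd.DataFrame(
            [("PA1", "DUP")], columns=["pharmgkb_id", "gene_symbol"]
        )
        res = parse_pharmgkb_targets(snapshot, self.make_xrefs(), proteins)
        assert sorted(r.accession for r in res.records) == ["P10001", "P10002"]


class TestIuphar:
    def make_xrefs(self):
        return make_crossrefs([
            ("chembl", "CHEMBL1", "iuphar_ligand", "301"),
            ("iuphar_target", "2472", "uniprot_accession", "P21964"),
        ])

    def test_species_collapsed_target_resolves_to_human_accession(self, proteins):
        snapshot = pd.DataFrame(
            [("301", "2472")], columns=["ligand_id", "target_id"]
        )
        res = parse_iuphar_targets(snapshot, self.make_xrefs(), proteins)
        assert [(r.drug_id, r.accession) for r in res.records] == [
            ("CHEMBL1", "P21964")
        ]

    def test_target_without_human_equivalent_skipped(self, proteins):
        snapshot = pd.DataFrame(
            [("301", "9999")], columns=["ligand_id", "target_id"]
        )
        res = parse_iuphar_targets(snapshot, self.make_xrefs(), proteins)
        assert res.records == [] and res.counts["no_human_equivalent"] == 1

    def test_duplicate_ligand_rows_collapse(self, proteins):
        snapshot = pd.DataFrame(
            [("301", "2472"), ("301", "2472")], columns=["ligand_id", "target_id"]
        )
        res = parse_iuphar_targets(snapshot, self.make_xrefs(), proteins)
        assert len(res.records) == 1
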