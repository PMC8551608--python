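"""ORA orchestration: universe, BH family, hierarchy pruning, ordering."""

import pytest

from drugpath.enrichment import EnrichmentConfig, prune_high_level, run_ora
from drugpath.errors import SchemaError
from drugpath.pathways import PathwayAnnotation, PathwayHierarchy
from drugpath.records import TargetProfile


def make_profile(accessions, drug="CHEMBL1"):
    return TargetProfile(
        drug_id=drug,
        accessions=frozenset(accessions),
        sources_per_accession={a: frozenset({"chembl"}) for a in accessions},
    )


ACCS = [f"P1000{i}" for i in range(1, 9)]
ANNOTATIONS = [
    PathwayAnnotation("R-HSA-1", "Root term", frozenset(ACCS)),
    PathwayAnnotation("R-HSA-2", "Alpha", frozenset(ACCS[0:3])),
    PathwayAnnotation("R-HSA-3", "Beta", frozenset(ACCS[3:6])),
    PathwayAnnotation("R-HSA-4", "Gamma", frozenset(ACCS[6:8])),
]
HIERARCHY = PathwayHierarchy([
    ("R-HSA-1", "R-HSA-2"), ("R-HSA-1", "R-HSA-3"), ("R-HSA-1", "R-HSA-4"),
])


class TestHierarchy:
    def test_depths_and_roots(self):
        chain = PathwayHierarchy([("A", "B"), ("B", "C")])
        assert chain.roots == {"A"}
        assert [chain.depth(x) for x in "ABC"] == [0, 1, 2]

    def test_chain_min_depth_two_keeps_only_leaf(self):
        chain = PathwayHierarchy([("A", "B"), ("B", "C")])
        assert prune_high_level(["A", "B", "C"], chain, 2) == ["C"]

    def test_min_depth_zero_is_identity(self):
        assert prune_high_level(["A", "B", "C"],
                                PathwayHierarchy([("A", "B"), ("B", "C")]),
                                0) == ["A", "B", "C"]

    def test_root_excluded_at_min_depth_one(self):
        assert prune_high_level(["R-HSA-1"], HIERARCHY, 1) == []

    def test_unknown_pathway_is_kept_and_reported(self):
        kept, unknown = HIERARCHY.prune_high_level(["R-HSA-999"], 3)
        assert kept == ["R-HSA-999"] and unknown == ["R-HSA-999"]

    def test_cycle_is_schema_error(self):
        with pytest.raises(SchemaError, match="cycle"):
            PathwayHierarchy([("A", "B"), ("B", "A")])


class TestRunOra:
    def test_disjoint_profile_reports_no_proteins_found(self):
        outcome = run_ora(make_profile(["P99999"]), ANNOTATIONS, HIERARCHY)
        assert outcome.status == "no-proteins-found"
        assert outcome.results == [] and outcome.n == 0

    def test_perfect_overlap_ranks_planted_pathway_first(self):
        """Three targets covering Alpha exactly: p = 1/C(8,3), BH over m=2."""
        outcome = run_ora(make_profile(ACCS[0:3]), ANNOTATIONS, HIERARCHY)
        assert outcome.status == "ok"
        assert outcome.n_tested == 2  # Alpha and the root; Beta/Gamma have k=0
        (top,) = outcome.results      # root pruned at depth 0
        assert top.st_id == "R-HSA-2"
        assert top.p_value == pytest.approx(1 / 56, rel=1e-12)
        assert top.fdr == pytest.approx(2 / 56, rel=1e-12)
        assert top.fdr >= top.p_value

    def test_zero_overlap_pathway_never_changes_reported_p(self):
        """m counts only k >= 1 pathways: a zero-overlap pathway (members
        already inside the universe) neither enters the BH family nor moves
        any reported p-value."""
        extra = ANNOTATIONS + [
            PathwayAnnotation("R-HSA-5", "Zero overlap", frozenset(ACCS[6:8]))
        ]
        base = run_ora(make_profile(ACCS[0:3]), ANNOTATIONS, HIERARCHY)
        with_extra = run_ora(make_profile(ACCS[0:3]), extra, HIERARCHY)
        assert base.results  # sanity: the comparison is not vacuous
        assert with_extra.n_tested == base.n_tested
        assert [(r.st_id, r.p_value, r.fdr) for r in with_extra.results] == [
            (r.st_id, r.p_value, r.fdr) for r in base.results
        ]

    def test_disease_pathways_excluded_by_default(self):
        anns = [
            PathwayAnnotation("R-HSA-2", "Alpha", frozenset(ACCS[0:3])),
            PathwayAnnotation("R-HSA-9", "Disease", frozenset(ACCS),
                              is_disease=True),
        ]
        outcome = run_ora(make_profile(ACCS[0:3]), anns, HIERARCHY)
        assert outcome.N == 3  # universe excludes the disease pathway's members
        assert {r.st_id for r in outcome.results} <= {"R-HSA-2"}
        included = run_ora(
            make_profile(ACCS[0:3]), anns, HIERARCHY,
            EnrichmentConfig(exclude_disease=False),
        )
        assert included.N == 8

    def test_explicit_universe_mode(self):
        cfg = EnrichmentConfig(universe_mode="explicit_list",
                               universe=frozenset(ACCS + ["P30001"]))
        outcome = run_ora(make_profile(ACCS[0:3] + ["P30001"]),
                          ANNOTATIONS, HIERARCHY, cfg)
        assert outcome.N == 9 and outcome.n == 4

    def test_threshold_consistency(self):
        """Significant set at FDR 0.01 is a subset of the set at 0.05."""
        profile = make_profile(ACCS[0:4])
        strict = run_ora(profile, ANNOTATIONS, HIERARCHY,
                         EnrichmentConfig(fdr_cutoff=0.01))
        loose = run_ora(profile, ANNOTATIONS, HIERARCHY,
                        EnrichmentConfig(fdr_cutoff=0.05))
        assert strict.significant_st_ids <= loose.significant_st_ids

    def test_results_sorted_by_fdr_then_p_then_st_id(self):
        outcome = run_ora(make_profile(ACCS), ANNOTATIONS, HIERARCHY,
                          EnrichmentConfig(fdr_cutoff=1.0, min_depth=0))
        keys = [(r.fdr, r.p_value, r.st_id) for r in outcome.results]
        assert keys == sorted(keys)
        assert len(outcome.results) == 4  # every pathway has k >= 1 at cutoff 1
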