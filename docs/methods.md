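# Methods

## The model

`drugpath` treats a drug as the set of proteins it is evidenced to
modulate, and asks which curated pathways contain more of those proteins
than chance would allow. The statistical core is the one-sided
hypergeometric overrepresentation test. Let N be the number of distinct
proteins annotated to any eligible pathway (the *universe*), K the number
of universe proteins in a given pathway, n the number of submitted
proteins found in the universe, and k the observed overlap. Under the null
that the submitted pool is an unbiased draw from the universe,

P(X ≥ k) = Σ_{i=k}^{min(n,K)} C(K,i)·C(N−K,n−i) / C(N,n).

The sum is evaluated in log space (lgamma terms, max-shifted
log-sum-exp), which keeps relative error near machine precision even for
tail probabilities around 1e-300; the unit tests hold it to ≤ 1e-12
relative error against an exact rational oracle and cross-check it against
an independent library implementation at universe sizes up to 10⁴.

Multiplicity is controlled with the Benjamini–Hochberg step-up adjustment,
adj₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·m/j clipped at 1. The family size m counts only
pathways with k ≥ 1: zero-overlap pathways are never tested, mirroring
analysis services that report hit pathways only. This choice matters —
FDR values cannot be compared across tools without knowing m — so it is
explicit and asserted by a test (adding a zero-overlap pathway whose
members are already in the universe changes nothing).

### Universe definition

The universe defaults to the union of all member accessions over eligible
annotations (`annotated_union`); disease-flagged pathways are excluded
from both the universe and the test family by default. An
`explicit_list` mode accepts a user-supplied universe (e.g. a proteome)
for users who want the test conditioned on a fixed background. Submitted
proteins absent from the universe are counted and reported as not-found
but do not enter the test.

### Hierarchy pruning

Pathway collections are hierarchical; top-level terms are collective
labels rather than mechanisms. Depth is the shortest path from any root
of the parent→child relation, and reported pathways must satisfy
depth ≥ `min_depth` (default 1, i.e. roots are pruned). The cutoff is a
flag because no single depth is canonically "detailed enough"; pruning is
applied after the BH adjustment, as a reporting filter, so it cannot
change any p-value or the family size. Pathways missing from the relation
file are kept and flagged — a gap in one input should not silently delete
results.

## Target-profile construction

Each source adapter applies its database's conventions and emits only
reviewed human UniProt accessions:

- **ChEMBL-style activities.** Assay rows qualify at pChEMBL ≥ threshold
  (default 5.0, inclusive; a drug–target pair qualifies if *any* assay row
  qualifies). Mechanism-of-action rows qualify without a pChEMBL.
  Protein-family targets expand to every member accession. Non-protein
  and non-mammalian rows are dropped. Non-human mammalian rows are lifted
  to the reviewed human accessions sharing the gene symbol
  (case-insensitive, because orthologs are cased differently across
  species); the lift is a flag (default on) since cross-species
  concordance is imperfect.
- **DrugBank/TTD/PharmGKB/IUPHAR-style tables** are bridged to ChEMBL
  drug identifiers through a generic namespace crossref table (TTD via
  its PubChem CID column; IUPHAR via ligand IDs). TTD's UniProt entry
  *names* are translated to accessions; PharmGKB's target genes resolve
  to all reviewed human accessions of the gene; IUPHAR's organism-
  agnostic target IDs resolve to the human accession only.

Many-to-many identifier mappings always fan out to every mapped ID —
silently picking one would bias profiles. Unmapped or malformed rows
accumulate in a per-source rejects report with counts instead of raising,
so one bad row cannot abort a batch.

Harmonization unions records per drug, deduplicates (drug, accession)
pairs and retains per-accession source sets for auditability.

## Tissue filter

Expression evidence is consensus mRNA abundance (nTPM) in long format.
"Low or no expression" is quantified as nTPM < 1.0 by default — the
common not-detected convention for consensus transcript data — and the
threshold is inclusive and configurable. mRNA rather than protein
evidence is used because protein-level data is missing for relevant genes
(e.g. the hERG channel). Accessions with no gene mapping or no expression
row are dropped by default (we cannot attest expression) but counted, and
`keep_unmeasured` retains them. An accession mapping to several genes
passes if any gene passes.

## Group comparison

Per-pathway affected-compound fractions use as denominator the drugs in
the group with ≥ 1 significant pathway. Cohorts shrink along the pipeline
(drugs lose all targets to the tissue filter, or all pathways to the FDR
cutoff), so the denominator must be pinned to a stage; using the last
stage keeps fractions interpretable as "share of drugs with any pathway
signal", and the rule is echoed in the output metadata. Frequency
thresholds are inclusive ("at least 10%"), threshold sets are antitone in
the threshold by construction, and exclusive sets subtract the union of
all other groups. The novelty report partitions edges exactly:
recovered + novel = |discovered| per drug, recovered + missed =
|reference| per drug.

## Synthetic universe

The generator emulates every snapshot the pipeline consumes, with a
ground-truth manifest. Defaults: 1000 proteins, 100 pathways (3-level
tree: ~5 roots, ~20 mid, ~75 leaves; sizes 5–50 sampled without
replacement), 50 drugs with 10 targets each, 20 planted drugs drawing
⌈0.8·10⌉ = 8 targets from one assigned non-disease leaf pathway and the
rest uniformly; null drugs draw all targets uniformly. Every true pair
gets a qualifying ChEMBL assay row (pChEMBL ~ N(7, 1) clipped to
[5, 14]); ~30% of pairs are duplicated into a second source; decoy rows
exercise every adapter filter (sub-threshold pChEMBL ~ N(4, 0.4), non-
mammalian, unreviewed accessions, family rows, mammalian-only pairs that
require the ortholog lift). Expression per tissue: 60% of genes expressed
with lognormal abundance (median 20 nTPM, floored at 1.0), the rest
uniform in [0, 0.9], guaranteeing separation around the default 1.0
cutoff. Each output file draws from its own labelled RNG substream of the
master seed, so outputs are individually stable and equal seeds give
byte-identical trees.

What the generator does **not** emulate: realistic chemistry, correlated
pathway membership (parent/child member sets are sampled independently),
inter-drug target correlation, or realistic expression covariance.
Passing the planted-recovery benchmark therefore demonstrates the
statistical machinery and plumbing are correct, not that any particular
biological conclusion transfers to real database snapshots.

## Calibration and problem sizes

The planted-signal benchmark runs the default universe end to end; the
expected separation is pre-verified analytically (overlap 8 of 10 in a
≤ 50-member pathway within a 1000-protein universe has
P(X ≥ 8) ≈ 9.3e-10, orders of magnitude below the BH bar at m ≤ 100).
The null calibration runs 1000 reduced universes (300 proteins, 40
pathways, 4 drugs each; the acceptance script uses 300), a size chosen so
the full in-memory pipeline — generation, adapters, harmonization, ORA —
executes per replicate in a few milliseconds while leaving the per-family
BH guarantee intact; under the global null the per-drug false-discovery
proportion is 1 exactly when anything is reported, and its mean is
bounded by the 0.05 cutoff (observed ≈ 0.03, conservative because the
hypergeometric p-values are discrete).

## Numerical and determinism choices

- Ties in the ORA output are broken by (fdr, p, st_id), making results
  byte-stable across runs; no output file contains timestamps.
- CSV statistics are printed with 6 significant digits.
- The pChEMBL sanity range is [0, 14]; out-of-range values are rejected
  rows, not clamped.
- BH input p-values must lie in (0, 1]; the adjustment never lowers a
  p-value, which the result type asserts (fdr ≥ p).
- Degenerate inputs are statuses, not crashes: a drug absent from all
  sources reports `no-targets-found`; a pool disjoint from the universe
  reports `no-proteins-found`; both leave the batch running.

## Known limitations

- The snapshot schemas are this package's own testable stand-ins for the
  live services a production run would query; a live retrieval layer is
  intentionally out of scope.
- BH's FDR guarantee assumes independence or positive regression
  dependence across pathway tests; overlapping pathways violate this
  mildly, as they do in all standard ORA tools.
- The hierarchy depth rule treats all collections alike; collections
  whose roots are already mechanistic should run with `min_depth 0`.
- Frequency comparisons are descriptive; no between-group test is
  performed.
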