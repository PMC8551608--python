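# drugpath

Connect drugs to the biological pathways they modulate, via the proteins
they bind. `drugpath` is an offline, testable pipeline for pathway-level
drug profiling — the kind of analysis used to ask whether cardiotoxic,
hepatotoxic and therapeutic compound groups hit systematically different
biology.

The pipeline has four stages:

1. **Target profiles.** Drug-target evidence is parsed from local snapshot
   tables of five curated databases (ChEMBL-, DrugBank-, TTD-, PharmGKB-
   and IUPHAR-style). ChEMBL assay rows qualify at pChEMBL ≥ 5
   (pChEMBL = −log₁₀ molar IC50/XC50/EC50/AC50/Ki/Kd/Potency; 5 ≡ 10 µM),
   mechanism-of-action annotations qualify unconditionally; protein-family
   targets expand to all members; non-human mammalian targets are
   optionally lifted to the human protein sharing the gene symbol. Only
   reviewed human UniProt accessions survive.
2. **Harmonization.** Per-source records are unioned per drug into a
   deduplicated protein pool, keeping per-accession source provenance.
3. **Tissue filter (optional).** The pool is restricted to proteins whose
   genes reach a consensus expression threshold (default 1 nTPM) in a
   chosen tissue.
4. **Overrepresentation test.** Each pool is tested against a pathway
   collection (GMT + hierarchy). For a universe of N annotated proteins, a
   pathway with K members and a submitted pool with n proteins found in the
   universe, the overlap k is scored with the hypergeometric upper tail

   P(X ≥ k) = Σ_{i=k}^{min(n,K)} C(K,i)·C(N−K,n−i) / C(N,n),

   adjusted across hit pathways with the Benjamini–Hochberg step-up rule.
   Pathways pass at FDR ≤ 0.05, disease pathways are excluded, and
   top-level hierarchy terms (depth < 1 from the roots) are pruned.

Group-level tooling compares labelled drug groups by affected-compound
frequency (e.g. pathways hit by ≥ 10% or ≥ 20% of a group), extracts
shared and exclusive pathway sets, exports drug–pathway edge lists, and
scores discovered edges against a reference compound–pathway list.

A seeded synthetic-universe generator emulates all snapshot inputs with
planted drug→pathway signal, so the entire pipeline is testable with no
network access and a known ground truth.

## Worked example

Generate a small synthetic universe, run two drugs through it, then run
the hand-built micro snapshot shipped with the tests:

```sh
drugpath simulate --seed 7 --out scratch/universe
drugpath run --drugs tests/data/micro_snapshot/drugs.txt \
    --snapshots tests/data/micro_snapshot --tissue heart --out scratch/micro
cat scratch/micro/results.csv
```

prints

```
molecule_chembl_id,Names,stIds,fdrs,pValues
CHEMBL1001,Alpha cascade,R-HSA-9000002,0.0357143,0.0178571
```

Reading: drug CHEMBL1001 keeps 3 heart-expressed targets out of a 4-protein
pool; all 3 fall in the 3-member pathway `R-HSA-9000002` within an
8-protein universe, so p = 1/C(8,3) = 0.0178571, and BH over the two hit
pathways doubles it to FDR = 0.0357143 — significant at the 0.05 cutoff.
The second drug's only heart-expressed target gives p = 3/8 (FDR 0.75) and
is correctly reported as non-significant. Per-drug stage counts (raw
records, deduplicated pool, tissue-filtered, found-in-universe,
significant) are in `run_report.json`; full test detail (k, K, n, N) in
`results.json`.

Group comparison over several run outputs:

```sh
drugpath compare --groups groups.tsv --results scratch/micro \
    --min-frac 0.1 --min-frac 0.2 --out scratch/cmp
```

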