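"""Identifier cross-reference table and UniProt protein-status table.

Both are thin, validated wrappers over the snapshot TSVs. The crossref table
is namespace-pair keyed and symmetric (a row ``(chembl, X, drugbank, Y)``
answers lookups in either direction); many-to-many relations are permitted
and fan out to all mapped identifiers.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import SchemaError

__all__ = ["CrossRefTable", "ProteinTable", "read_snapshot_tsv"]

CROSSREF_COLUMNS = ["namespace_a", "id_a", "namespace_b", "id_b"]
PROTEIN_COLUMNS = ["accession", "gene_symbol", "reviewed", "human"]


def read_snapshot_tsv(path: str | Path) -> pd.DataFrame:
    """Read a snapshot TSV (UTF-8, header row, ``#`` comment lines)."""
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def _require_columns(frame: pd.DataFrame, columns: Iterable[str], context: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{context}: missing required column(s): {', '.join(missing)}")


class CrossRefTable:
    """Many-to-many identifier mappings between namespaces."""

    def __init__(self, frame: pd.DataFrame):
        _require_columns(frame, CROSSREF_COLUMNS, "crossref table")
        if frame.duplicated(subset=CROSSREF_COLUMNS).any():
            raise SchemaError("crossref table: duplicate (namespace_a,id_a,namespace_b,id_b) rows")
        self._forward: dict[tuple[str, str, str], set[str]] = defaultdict(set)
        self._pairs: set[tuple[str, str]] = set()
        for ns_a, id_a, ns_b, id_b in frame[CROSSREF_COLUMNS].itertuples(index=False):
            self._forward[(ns_a, id_a, ns_b)].add(id_b)
            self._forward[(ns_b, id_b, ns_a)].add(id_a)
            self._pairs.add((ns_a, ns_b))
            self._pairs.add((ns_b, ns_a))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CrossRefTable":
        return cls(read_snapshot_tsv(path))

    def map(self, ns_from: str, identifier: str, ns_to: str) -> frozenset[str]:
        """All identifiers in *ns_to* mapped from (*ns_from*, *identifier*)."""
        return frozenset(self._forward.get((ns_from, identifier, ns_to), ()))

    def has_namespace_pair(self, ns_a: str, ns_b: str) -> bool:
        """True if at least one row relates the two namespaces."""
        return (ns_a, ns_b) in self._pairs


class ProteinTable:
    """UniProt protein status: review state, organism, gene symbol.

    Gene-symbol lookups are case-insensitive because symbols are cased
    differently across species (human COMT vs rodent Comt) while denoting
    the same gene.
    """

    def __init__(self, frame: pd.DataFrame):
        _require_columns(frame, PROTEIN_COLUMNS, "protein table")
        self._status: dict[str, tuple[bool, bool]] = {}
        self._genes: dict[str, set[str]] = defaultdict(set)
        self._by_gene: dict[str, set[str]] = defaultdict(set)
        for acc, gene, reviewed, human in frame[PROTEIN_COLUMNS].itertuples(index=False):
            rev = str(reviewed).strip().lower() in ("true", "1", "yes")
            hum = str(human).strip().lower() in ("true", "1", "yes")
            self._status[acc] = (rev, hum)
            if gene:
                self._genes[acc].add(gene)
                if rev and hum:
                    self._by_gene[gene.upper()].add(acc)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProteinTable":
        return cls(read_snapshot_tsv(path))

    def is_reviewed_human(self, accession: str) -> bool:
        return self._status.get(accession, (False, False)) == (True, True)

    def known(self, accession: str) -> bool:
        return accession in self._status

    def genes_for(self, accession: str) -> frozenset[str]:
        return frozenset(self._genes.get(accession, ()))

    def reviewed_human_for_gene(self, gene_symbol: str) -> tuple[str, ...]:
        """Reviewed human accessions expressed by *gene_symbol* (sorted)."""
        return tuple(sorted(self._by_gene.get(gene_symbol.upper(), ())))

    def accession_to_genes(self) -> dict[str, frozenset[str]]:
        return {acc: frozenset(genes) for acc, genes in self._genes.items()}
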