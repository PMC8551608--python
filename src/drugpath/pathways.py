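"""Pathway annotations (GMT + sidecar flags) and the pathway hierarchy.

Pathway sets travel as GMT (one pathway per line: stable ID, display name,
member accessions), with a sidecar TSV carrying per-pathway flags
(is_disease, species_tax_id). The hierarchy is a two-column parent/child
relation file in the style of Reactome's pathway-relation export (no
header); depth is the shortest path from any root, so top-level collective
terms sit at depth 0.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .errors import SchemaError

__all__ = [
    "PathwayAnnotation",
    "PathwayHierarchy",
    "parse_gmt",
    "write_gmt",
    "load_annotations",
    "write_flags",
]

HUMAN_TAX_ID = 9606


@dataclass(frozen=True)
class PathwayAnnotation:
    st_id: str
    name: str
    members: frozenset[str]
    is_disease: bool = False
    species_tax_id: int = HUMAN_TAX_ID

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.st_id} has no members")


def parse_gmt(path: str | Path) -> list[tuple[str, str, frozenset[str]]]:
    """Parse a GMT file into (st_id, name, members) triples."""
    triples = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(f"GMT line {lineno}: expected id, name and >=1 member")
            st_id, name, *members = fields
            if st_id in seen:
                raise SchemaError(f"GMT line {lineno}: duplicate pathway id {st_id}")
            seen.add(st_id)
            triples.append((st_id, name, frozenset(m for m in members if m)))
    return triples


def write_gmt(annotations: Iterable[PathwayAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for ann in annotations:
            handle.write("\t".join([ann.st_id, ann.name, *sorted(ann.members)]) + "\n")


def load_annotations(gmt_path: str | Path, flags_path: str | Path) -> list[PathwayAnnotation]:
    """Join a GMT file with its sidecar flag table into PathwayAnnotations."""
    flags = pd.read_csv(flags_path, sep="\t", comment="#", dtype=str)
    for col in ("st_id", "is_disease", "species_tax_id"):
        if col not in flags.columns:
            raise SchemaError(f"pathway flags table: missing required column(s): {col}")
    flag_map = {
        row.st_id: (str(row.is_disease).strip().lower() in ("true", "1", "yes"),
                    int(row.species_tax_id))
        for row in flags.itertuples(index=False)
    }
    annotations = []
    for st_id, name, members in parse_gmt(gmt_path):
        is_disease, tax = flag_map.get(st_id, (False, HUMAN_TAX_ID))
        annotations.append(
            PathwayAnnotation(st_id=st_id, name=name, members=members,
                              is_disease=is_disease, species_tax_id=tax)
        )
    return annotations


def write_flags(annotations: Iterable[PathwayAnnotation], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(a.st_id, str(a.is_disease).lower(), a.species_tax_id) for a in annotations],
        columns=["st_id", "is_disease", "species_tax_id"],
    )
    frame.to_csv(path, sep="\t", index=False)


class PathwayHierarchy:
    """Acyclic parent->child pathway relation with shortest-path depths."""

    def __init__(self, edges: Iterable[tuple[str, str]]):
        self.edges: frozenset[tuple[str, str]] = frozenset(edges)
        graph = nx.DiGraph()
        graph.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(graph):
            raise SchemaError("pathway hierarchy contains a cycle")
        self.roots: frozenset[str] = frozenset(
            n for n in graph.nodes if graph.in_degree(n) == 0
        )
        # multi-source BFS from the roots
        self._depth: dict[str, int] = {r: 0 for r in self.roots}
        queue = deque(self.roots)
        while queue:
            node = queue.popleft()
            for child in graph.successors(node):
                if child not in self._depth:
                    self._depth[child] = self._depth[node] + 1
                    queue.append(child)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PathwayHierarchy":
        edges = []
        with open(path, encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise SchemaError(
                        f"hierarchy line {lineno}: expected parent<TAB>child"
                    )
                edges.append((fields[0], fields[1]))
        return cls(edges)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            for parent, child in sorted(self.edges):
                handle.write(f"{parent}\t{child}\n")

    def depth(self, st_id: str) -> int | None:
        """Shortest-path depth from any root, or None if unknown."""
        return self._depth.get(st_id)

    def prune_high_level(
        self, st_ids: Sequence[str], min_depth: int
    ) -> tuple[list[str], list[str]]:
        """Drop pathways shallower than *min_depth*.

        Returns (kept, unknown): pathways absent from the hierarchy are
        kept — a gap in the relation file should not silently delete
        results — and reported in *unknown* so callers can warn.
        """
        kept, unknown = [], []
        for st_id in st_ids:
            depth = self.depth(st_id)
            if depth is None:
                unknown.append(st_id)
                kept.append(st_id)
            elif depth >= min_depth:
                kept.append(st_id)
        return kept, unknown
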