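"""Restrict target profiles to proteins expressed in a chosen tissue.

Expression evidence is consensus mRNA abundance (nTPM) in long format, one
row per (gene, tissue), as distributed by tissue-atlas resources. A protein
survives the filter when any of its genes reaches the nTPM threshold in the
chosen tissue; "low or no expression" defaults to nTPM < 1, the common
not-detected convention for consensus transcript data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import SchemaError, UnknownTissueError
from .records import TargetProfile

__all__ = ["TissueFilterConfig", "TissueFilterReport", "ExpressionTable", "filter_profile"]


@dataclass(frozen=True)
class TissueFilterConfig:
    tissue: str
    min_ntpm: float = 1.0
    keep_unmeasured: bool = False

    def __post_init__(self) -> None:
        if not self.min_ntpm > 0:
            raise ValueError("min_ntpm must be positive")


@dataclass
class TissueFilterReport:
    """Per-run accounting of why accessions were removed."""

    n_input: int = 0
    n_kept: int = 0
    n_dropped_low_expression: int = 0
    n_dropped_unmeasured: int = 0
    n_kept_unmeasured: int = 0


class ExpressionTable:
    """Long-format consensus expression: (gene_symbol, tissue) -> nTPM."""

    def __init__(self, frame: pd.DataFrame):
        for col in ("gene_symbol", "tissue", "ntpm"):
            if col not in frame.columns:
                raise SchemaError(f"expression table: missing required column(s): {col}")
        if frame.duplicated(subset=["gene_symbol", "tissue"]).any():
            raise SchemaError("expression table: duplicate (gene_symbol, tissue) rows")
        ntpm = pd.to_numeric(frame["ntpm"], errors="raise")
        if (ntpm < 0).any():
            raise SchemaError("expression table: negative nTPM value")
        self._ntpm: dict[tuple[str, str], float] = {
            (g, t): v
            for g, t, v in zip(frame["gene_symbol"], frame["tissue"], ntpm)
        }
        self.tissues: frozenset[str] = frozenset(frame["tissue"])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionTable":
        return cls(
            pd.read_csv(path, sep="\t", comment="#",
                        dtype={"gene_symbol": str, "tissue": str})
        )

    def ntpm(self, gene_symbol: str, tissue: str) -> float | None:
        return self._ntpm.get((gene_symbol, tissue))


def filter_profile(
    profile: TargetProfile,
    expression: ExpressionTable,
    acc2gene: Mapping[str, frozenset[str]],
    cfg: TissueFilterConfig,
) -> tuple[TargetProfile, TissueFilterReport]:
    """Keep accessions whose gene reaches cfg.min_ntpm in cfg.tissue.

    The threshold is inclusive. An accession mapping to several genes is
    kept if ANY mapped gene passes. Accessions with no gene mapping or no
    expression row in the tissue are kept only with ``keep_unmeasured``.
    """
    if cfg.tissue not in expression.tissues:
        raise UnknownTissueError(cfg.tissue, sorted(expression.tissues))

    report = TissueFilterReport(n_input=len(profile.accessions))
    kept: set[str] = set()
    for acc in profile.accessions:
        genes = acc2gene.get(acc, frozenset())
        values = [
            v for v in (expression.ntpm(g, cfg.tissue) for g in genes) if v is not None
        ]
        if not values:
            if cfg.keep_unmeasured:
                kept.add(acc)
                report.n_kept_unmeasured += 1
            else:
                report.n_dropped_unmeasured += 1
            continue
        if max(values) >= cfg.min_ntpm:
            kept.add(acc)
        else:
            report.n_dropped_low_expression += 1

    report.n_kept = len(kept)
    return profile.restrict(frozenset(kept)), report
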