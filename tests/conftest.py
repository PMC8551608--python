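"""Shared fixtures: the hand-built micro snapshot and small table builders."""

from pathlib import Path

import pandas as pd
import pytest

from drugpath.crossref import CrossRefTable, ProteinTable

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def micro_snapshot_dir() -> Path:
    return DATA_DIR / "micro_snapshot"


@pytest.fixture(scope="session")
def expected_micro_csv() -> Path:
    return DATA_DIR / "expected_micro_results.csv"


def make_proteins(rows: list[tuple[str, str, bool, bool]]) -> ProteinTable:
    """Rows of (accession, gene_symbol, reviewed, human)."""
    return ProteinTable(
        pd.DataFrame(
            [(a, g, str(r).lower(), str(h).lower()) for a, g, r, h in rows],
            columns=["accession", "gene_symbol", "reviewed", "human"],
        )
    )


def make_crossrefs(rows: list[tuple[str, str, str, str]]) -> CrossRefTable:
    return CrossRefTable(
        pd.DataFrame(rows, columns=["namespace_a", "id_a", "namespace_b", "id_b"])
    )
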