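"""Pathway overrepresentation analysis (ORA).

A drug's tissue-filtered protein pool is tested against each pathway with
the hypergeometric upper tail: with a universe of N annotated proteins, a
pathway of K members and a submitted pool of n proteins found in the
universe, the p-value is P(X >= k) for X ~ Hypergeometric(N, K, n), where
k is the observed overlap. Overrepresentation means more pathway members
in the pool than chance alone would put there.

Multiplicity is handled with the Benjamini-Hochberg step-up adjustment over
the pathways actually hit (k >= 1); zero-overlap pathways are not tested
and do not count toward m. Reported pathways must pass the FDR cutoff
(default 0.05) and sit at least min_depth below the hierarchy roots, which
removes collective top-level terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .pathways import PathwayAnnotation, PathwayHierarchy
from .records import TargetProfile

__all__ = [
    "hypergeom_upper_tail",
    "bh_adjust",
    "prune_high_level",
    "EnrichmentConfig",
    "EnrichmentResult",
    "OraResult",
    "run_ora",
]


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail probability P(X >= k), X ~ Hypergeometric(N, K, n).

    N is the universe size, K the number of marked items (pathway members),
    n the sample size (submitted proteins found in the universe), k the
    observed overlap. Computed in log space via lgamma so it stays accurate
    deep in the tail.
    """
    for name, value in (("k", k), ("K", K), ("n", n), ("N", N)):
        if not isinstance(value, (int, np.integer)):
            raise ValueError(f"{name} must be an integer, got {value!r}")
    if N <= 0 or K > N or n > N or K < 0 or n < 0:
        raise ValueError(f"invalid population: k={k} K={K} n={n} N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"overlap k={k} outside [0, min(n, K)] for K={K} n={n}")
    if k == 0:
        return 1.0

    def log_comb(a: int, b: int) -> float:
        return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)

    denom = log_comb(N, n)
    log_terms = [
        log_comb(K, i) + log_comb(N - K, n - i) - denom
        for i in range(k, min(n, K) + 1)
        if n - i <= N - K  # term is zero when more non-members needed than exist
    ]
    peak = max(log_terms)
    total = peak + math.log(sum(math.exp(t - peak) for t in log_terms))
    return min(1.0, math.exp(total))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    adj_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    clipped at 1; ties receive equal adjusted values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adjusted = np.empty(m, dtype=float)
    adjusted[order] = adjusted_sorted
    return adjusted


def prune_high_level(
    st_ids: Sequence[str], hierarchy: PathwayHierarchy, min_depth: int
) -> list[str]:
    """Pathways at depth >= min_depth (unknown pathways kept; see hierarchy)."""
    kept, _ = hierarchy.prune_high_level(st_ids, min_depth)
    return kept


@dataclass(frozen=True)
class EnrichmentConfig:
    fdr_cutoff: float = 0.05
    min_depth: int = 1
    exclude_disease: bool = True
    universe_mode: str = "annotated_union"  # or "explicit_list"
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.fdr_cutoff <= 1:
            raise ValueError("fdr_cutoff must be in (0, 1]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if self.universe_mode not in ("annotated_union", "explicit_list"):
            raise ValueError(f"unknown universe_mode {self.universe_mode!r}")
        if self.universe_mode == "explicit_list" and not self.universe:
            raise ValueError("explicit_list universe_mode requires a universe set")


@dataclass(frozen=True)
class EnrichmentResult:
    """One significant (drug, pathway) association with its test detail."""

    drug_id: str
    st_id: str
    name: str
    k: int   # overlap
    K: int   # pathway size within the universe
    n: int   # submitted proteins found in the universe
    N: int   # universe size
    p_value: float
    fdr: float

    def __post_init__(self) -> None:
        if not 1 <= self.k <= min(self.n, self.K):
            raise ValueError("overlap k out of range")
        if not self.fdr >= self.p_value:
            raise ValueError("BH can only raise p-values")


@dataclass
class OraResult:
    """Full outcome of one drug's overrepresentation run."""

    drug_id: str
    status: str                      # "ok" or "no-proteins-found"
    n: int = 0                       # pool proteins found in the universe
    N: int = 0
    n_not_found: int = 0
    n_tested: int = 0                # pathways with k >= 1 (the BH family size)
    results: list[EnrichmentResult] = field(default_factory=list)
    pruned_unknown: list[str] = field(default_factory=list)

    @property
    def significant_st_ids(self) -> frozenset[str]:
        return frozenset(r.st_id for r in self.results)


def run_ora(
    profile: TargetProfile,
    annotations: Iterable[PathwayAnnotation],
    hierarchy: PathwayHierarchy,
    cfg: EnrichmentConfig = EnrichmentConfig(),
) -> OraResult:
    """Overrepresentation test of one drug profile against a pathway collection.

    The universe defaults to the union of all member accessions over the
    (non-disease, if excluded) annotations; profile accessions outside the
    universe are counted as not-found and excluded from the test. Results
    are filtered to fdr <= cutoff and hierarchy depth >= min_depth, sorted
    by (fdr, p, st_id) for byte-stable output.
    """
    anns = [
        a for a in annotations if not (cfg.exclude_disease and a.is_disease)
    ]
    if cfg.universe_mode == "explicit_list":
        universe = frozenset(cfg.universe or ())
    else:
        universe = frozenset().union(*(a.members for a in anns)) if anns else frozenset()

    found = profile.accessions & universe
    n, N = len(found), len(universe)
    not_found = len(profile.accessions) - n
    if n == 0:
        return OraResult(
            drug_id=profile.drug_id, status="no-proteins-found",
            n=0, N=N, n_not_found=not_found,
        )

    tested: list[tuple[PathwayAnnotation, int, int]] = []
    for ann in anns:
        members = ann.members & universe
        k = len(found & members)
        if k >= 1:
            tested.append((ann, k, len(members)))

    p_values = [hypergeom_upper_tail(k, K, n, N) for _, k, K in tested]
    fdrs = bh_adjust(p_values)

    candidates = [
        EnrichmentResult(
            drug_id=profile.drug_id, st_id=ann.st_id, name=ann.name,
            k=k, K=K, n=n, N=N, p_value=p, fdr=float(f),
        )
        for (ann, k, K), p, f in zip(tested, p_values, fdrs)
        if f <= cfg.fdr_cutoff
    ]
    kept_ids, unknown = hierarchy.prune_high_level(
        [c.st_id for c in candidates], cfg.min_depth
    )
    kept_set = set(kept_ids)
    results = sorted(
        (c for c in candidates if c.st_id in kept_set),
        key=lambda r: (r.fdr, r.p_value, r.st_id),
    )
    return OraResult(
        drug_id=profile.drug_id, status="ok", n=n, N=N,
        n_not_found=not_found, n_tested=len(tested),
        results=results, pruned_unknown=sorted(unknown),
    )
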