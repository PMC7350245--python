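"""Hypergeometric over-representation of flagged genes in literature catalogs.

The test asks whether a query list (e.g., the genes hit by flagged SNPs)
contains more catalog genes (e.g., a literature-compiled lipid-gene
list) than a random draw of the same size from the gene universe would.
Only the one-sided upper tail is computed (over-representation).  The
universe is always an explicit input — there is no defensible default
background, and the p-value is meaningless without it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set

import numpy as np
from scipy.special import gammaln, logsumexp


@dataclass
class EnrichmentResult:
    """Outcome of one hypergeometric over-representation test."""

    universe_size: int  # N
    catalog_size: int  # K: catalog genes present in the universe
    query_size: int  # n: query genes present in the universe
    overlap: int  # k: query ∩ catalog
    p_value: float  # upper tail P(X >= k)
    warnings: Dict[str, int] = field(default_factory=dict)


def _log_binom(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n), in log space.

    Σ_{j≥k} C(K,j) C(N−K,n−j) / C(N,n), summed over the support
    j ∈ [max(k, n−(N−K)), min(K, n)].
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if K > N or n > N:
        raise ValueError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K, n)={min(K, n)}")
    if k <= max(0, n - (N - K)):
        return 1.0  # at or below the smallest achievable overlap
    j = np.arange(k, min(K, n) + 1, dtype=float)
    log_pmf = (
        _log_binom(np.float64(K), j)
        + _log_binom(np.float64(N - K), n - j)
        - _log_binom(np.float64(N), np.float64(n))
    )
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def _normalize(genes: Iterable[str]) -> Set[str]:
    """Case-insensitive, whitespace-stripped symbol set."""
    out = set()
    for g in genes:
        s = str(g).strip().upper()
        if s:
            out.add(s)
    return out


def enrich(
    query_genes: Sequence[str],
    catalog_genes: Sequence[str],
    universe_genes: Sequence[str],
) -> EnrichmentResult:
    """Over-representation of a catalog within a query, against a universe.

    Query and catalog genes outside the universe are dropped (counted in
    the warnings) before the tail is evaluated.
    """
    universe = _normalize(universe_genes)
    if not universe:
        raise ValueError("gene universe is empty")
    query = _normalize(query_genes)
    catalog = _normalize(catalog_genes)
    warnings = {
        "query_outside_universe": len(query - universe),
        "catalog_outside_universe": len(catalog - universe),
    }
    query &= universe
    catalog &= universe
    N, K, n = len(universe), len(catalog), len(query)
    k = len(query & catalog)
    return EnrichmentResult(
        universe_size=N,
        catalog_size=K,
        query_size=n,
        overlap=k,
        p_value=hypergeom_upper_tail(N, K, n, k),
        warnings=warnings,
    )


def read_gene_list(path: str) -> List[str]:
    """Plain-text gene list, one symbol per line, # comments allowed."""
    out: List[str] = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                out.append(s)
    return out
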