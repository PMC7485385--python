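"""Over-representation analysis against a gene-set collection.

For a query gene list inside a universe of N genes, a term annotating K
universe genes, and a query of n universe genes with k of them in the
term, the enrichment p-value is the one-sided hypergeometric upper tail
P(X >= k) (Fisher's exact test, enrichment direction).  Raw p-values are
Benjamini-Hochberg adjusted across all tested terms and a term is called
significant at adjusted p below alpha (default 0.05).

The default universe is every gene annotated to at least one term of the
collection, optionally intersected with a user-supplied background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich",
    "top_k",
]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # query genes in term
    K: int  # term size within universe
    n: int  # query size within universe
    N: int  # universe size
    p: float
    p_adj: float
    significant: bool


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got k={k}, K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    # survival function at k-1 gives P(X >= k); scipy works in log space
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """Test every term of the collection for over-representation.

    Results are sorted by (adjusted p, raw p, term id); terms with no
    gene in the universe are not tested.
    """
    annotated = collection.universe()
    eff_universe = annotated if universe is None else annotated & set(universe)
    if not eff_universe:
        raise ValueError("empty universe")
    q = set(query) & eff_universe
    if not q:
        raise ValueError("query has no genes in the universe")
    N, n = len(eff_universe), len(q)

    tested = []
    for term in collection.terms:
        term_genes = term.genes & eff_universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(q & term_genes)
        tested.append((term, k, K, hypergeom_upper_tail(k, K, n, N)))
    p_adj = bh_adjust([t[3] for t in tested])
    results = [
        EnrichmentResult(
            term_id=term.term_id,
            term_name=term.term_name,
            k=k,
            K=K,
            n=n,
            N=N,
            p=p,
            p_adj=pa,
            significant=pa < alpha,
        )
        for (term, k, K, p), pa in zip(tested, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adj, r.p, r.term_id))
    return results


def top_k(results: Sequence[EnrichmentResult], k: int = 20) -> list[EnrichmentResult]:
    """The k best-ranked terms (input already sorted by ``enrich``)."""
    return list(results[:k])
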