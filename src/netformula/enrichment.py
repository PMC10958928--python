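"""Hypergeometric gene-set enrichment with BH-FDR, and shared-term
co-association curves.

Enrichment tests each term of a collection for over-representation in a
query gene list under the hypergeometric model; p-values are adjusted with
Benjamini-Hochberg across the tested (overlapping) terms.

The co-association curve compares two ranked enrichment results: C(n) is
the number of terms shared by the top-n of both lists. The similarity
score is the overlap fraction at the full depth, C(N)/N in [0, 1]; the AUC
is the mean of C(n) over n = 1..N on the unnormalized shared-count curve,
so it can exceed 1 for deeply co-enriched lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import GeneSetCollection

__all__ = [
    "hypergeom_tail",
    "bh_adjust",
    "enrich",
    "shared_term_curve",
    "EnrichmentRow",
    "SharedTermCurve",
]


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size; K: term size; n: query size; k: overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need K,n <= N, got K={K}, n={n}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"need 0 <= k <= min(n, K), got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjustment, input order preserved.

    Monotonicity is enforced and values are capped at 1.
    """
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr <= 0) | (arr > 1)):
        bad = arr[(arr <= 0) | (arr > 1)][0]
        raise ValueError(f"p-values must lie in (0, 1], got {bad}")
    _, adj, _, _ = multipletests(arr, method="fdr_bh")
    return [float(x) for x in adj]


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    description: str
    k: int  # overlap with the query
    K: int  # term size within the universe
    n: int  # query size within the universe
    N: int  # universe size
    pval: float
    fdr: float


def enrich(
    query: Set[str],
    sets: GeneSetCollection,
    universe_override: Optional[Set[str]] = None,
) -> List[EnrichmentRow]:
    """Test every overlapping term for enrichment in the query.

    The query is silently intersected with the universe (dropped genes are
    counted); only terms with overlap k >= 1 are tested and the BH family
    size m is the number of tested terms. Rows are sorted ascending by
    p-value, ties by term id.
    """
    universe = frozenset(universe_override) if universe_override else sets.universe
    q = set(query) & universe
    if not q:
        raise ValueError(
            f"query ({len(query)} genes) has no overlap with the universe "
            f"({len(universe)} genes)"
        )
    N = len(universe)
    n = len(q)
    tested: List[Tuple[str, str, int, int]] = []
    for term, (desc, genes) in sets.sets.items():
        genes = genes & universe
        if not genes:
            continue
        k = len(q & genes)
        if k >= 1:
            tested.append((term, desc, k, len(genes)))
    if not tested:
        return []
    pvals = [hypergeom_tail(k, K, n, N) for _, _, k, K in tested]
    fdrs = bh_adjust(pvals)
    rows = [
        EnrichmentRow(term, desc, k, K, n, N, p, f)
        for (term, desc, k, K), p, f in zip(tested, pvals, fdrs)
    ]
    rows.sort(key=lambda r: (r.pval, r.term_id))
    return rows


@dataclass
class SharedTermCurve:
    """Shared-term counts C(1..N) between two ranked enrichment results."""

    depth: int
    shared: List[int]
    similarity: float  # C(N)/N in [0, 1]
    auc: float  # mean of C(n) over n = 1..N


def shared_term_curve(
    rows_a: Sequence[EnrichmentRow],
    rows_b: Sequence[EnrichmentRow],
    top_n: int = 30,
) -> SharedTermCurve:
    """Co-association curve between two ranked enrichment results.

    The effective depth is min(top_n, len(a), len(b)); C(n) counts term ids
    common to the top-n of both lists.
    """
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    if not rows_a or not rows_b:
        raise ValueError("both enrichment results must be non-empty")
    depth = min(top_n, len(rows_a), len(rows_b))
    terms_a = [r.term_id for r in rows_a[:depth]]
    terms_b = [r.term_id for r in rows_b[:depth]]
    shared: List[int] = []
    seen_a: Set[str] = set()
    seen_b: Set[str] = set()
    for n in range(depth):
        seen_a.add(terms_a[n])
        seen_b.add(terms_b[n])
        shared.append(len(seen_a & seen_b))
    similarity = shared[-1] / depth
    auc = sum(shared) / depth
    return SharedTermCurve(depth=depth, shared=shared, similarity=similarity, auc=auc)
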