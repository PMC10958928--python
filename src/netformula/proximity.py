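"""Network-based relevance between two gene sets on a PPI graph.

Two complementary scores, each with a permutation null:

* KATZ score — walk-counting relevance: overlap + beta*path1 +
  beta^2*path2 + beta^3*path3, where path_l sums the number of length-l
  walks between every pair (a, b), a in A, b in B (entries of adjacency
  powers), and beta geometrically discounts longer walks.
* Network distance score — the symmetric average closest shortest-path
  distance: each node's distance to the nearest member of the other set,
  averaged over both sets.

Nulls draw uniform random node-set pairs of the same sizes; empirical
p-values use the add-one estimator (1 + exceedances) / (1 + n_perm) so
they never reach zero. All randomness flows from the config seed.

Walk counting is implemented with sparse matrix-vector products, and the
distance null with a precomputed BFS distance matrix, so permutation
nulls with thousands of draws stay cheap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .config import AnalysisConfig

__all__ = [
    "katz_components",
    "katz_test",
    "closest_distance",
    "distance_test",
    "seed_subnetwork",
    "KatzResult",
    "DistanceResult",
]


@dataclass
class KatzResult:
    overlap: int
    path1: int
    path2: int
    path3: int
    total: float
    random_median: Optional[float] = None
    random_mean: Optional[float] = None
    pval: Optional[float] = None


@dataclass
class DistanceResult:
    mean_distance: float
    random_mean: Optional[float] = None
    random_sd: Optional[float] = None
    z: Optional[float] = None
    pval: Optional[float] = None
    n_excluded: int = 0  # nodes with no finite cross-set distance


class _GraphContext:
    """Indexed sparse adjacency and (lazy) BFS distance matrix."""

    def __init__(self, graph: nx.Graph):
        self.nodes: List = list(graph.nodes)
        self.index: Dict = {v: i for i, v in enumerate(self.nodes)}
        self.adj = csr_array(
            nx.to_scipy_sparse_array(graph, nodelist=self.nodes, dtype=np.float64)
        )
        self._dist: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def dist(self) -> np.ndarray:
        if self._dist is None:
            self._dist = shortest_path(self.adj, method="D", unweighted=True)
        return self._dist

    def project(self, nodes: Set, label: str) -> np.ndarray:
        present = [self.index[v] for v in nodes if v in self.index]
        dropped = len(nodes) - len(present)
        if dropped:
            warnings.warn(f"{dropped} node(s) of set {label} absent from the graph")
        if not present:
            raise ValueError(f"set {label} has no node in the graph")
        return np.asarray(sorted(present), dtype=np.intp)


def _walk_counts(
    ctx: _GraphContext, ai: np.ndarray, bi: np.ndarray, max_len: int
) -> List[int]:
    """Number of length-l walks between the sets, l = 1..max_len."""
    v = np.zeros(ctx.n)
    v[ai] = 1.0
    counts = []
    for _ in range(max_len):
        v = ctx.adj @ v
        counts.append(int(round(v[bi].sum())))
    return counts


def katz_components(
    graph: nx.Graph,
    set_a: Set,
    set_b: Set,
    beta: float = 0.001,
    max_len: int = 3,
) -> KatzResult:
    """Observed KATZ components (no permutation null).

    total = |A ∩ B| + sum_l beta^l * path_l. Node ids missing from the
    graph are dropped with a warning.
    """
    ctx = _GraphContext(graph)
    return _katz_on_context(ctx, set_a, set_b, beta, max_len)


def _katz_on_context(
    ctx: _GraphContext, set_a: Set, set_b: Set, beta: float, max_len: int
) -> KatzResult:
    ai = ctx.project(set_a, "A")
    bi = ctx.project(set_b, "B")
    overlap = len(np.intersect1d(ai, bi))
    counts = _walk_counts(ctx, ai, bi, max_len)
    counts += [0] * (3 - len(counts))
    total = overlap + sum(beta ** (l + 1) * c for l, c in enumerate(counts))
    return KatzResult(overlap, counts[0], counts[1], counts[2], total)


def katz_test(
    graph: nx.Graph,
    set_a: Set,
    set_b: Set,
    config: Optional[AnalysisConfig] = None,
) -> KatzResult:
    """KATZ score with a permutation null of uniform random set pairs.

    random_median/random_mean summarize the null totals; pval is the
    add-one upper-tail estimate (larger-than-random relevance).
    """
    cfg = config or AnalysisConfig()
    ctx = _GraphContext(graph)
    res = _katz_on_context(ctx, set_a, set_b, cfg.beta, cfg.max_path_len)
    na = len(ctx.project(set_a, "A"))
    nb = len(ctx.project(set_b, "B"))
    if na > ctx.n or nb > ctx.n:
        raise ValueError("set size exceeds node count")
    rng = np.random.default_rng(cfg.seed)

    # batched null: indicator matrices, three sparse mat-mat products
    VA = np.zeros((ctx.n, cfg.n_perm))
    VB = np.zeros((ctx.n, cfg.n_perm))
    for j in range(cfg.n_perm):
        VA[rng.choice(ctx.n, size=na, replace=False), j] = 1.0
        VB[rng.choice(ctx.n, size=nb, replace=False), j] = 1.0
    totals = np.einsum("ij,ij->j", VA, VB)  # overlaps
    W = VA
    for l in range(1, cfg.max_path_len + 1):
        W = ctx.adj @ W
        totals += cfg.beta ** l * np.einsum("ij,ij->j", W, VB)

    res.random_median = float(np.median(totals))
    res.random_mean = float(np.mean(totals))
    res.pval = float((1 + np.count_nonzero(totals >= res.total)) / (1 + cfg.n_perm))
    return res


def _closest_on_dist(
    D: np.ndarray, ai: np.ndarray, bi: np.ndarray
) -> Tuple[float, int]:
    sub = D[np.ix_(ai, bi)]
    parts = np.concatenate([sub.min(axis=1), sub.min(axis=0)])
    finite = np.isfinite(parts)
    if not finite.any():
        raise ValueError("no finite distance between the two sets")
    return float(parts[finite].mean()), int((~finite).sum())


def closest_distance(graph: nx.Graph, set_a: Set, set_b: Set) -> float:
    """Symmetric average closest shortest-path distance between two sets.

    d(A,B) = (sum_a min_b d(a,b) + sum_b min_a d(a,b)) / (|A| + |B|) over
    unweighted shortest paths; nodes with no finite cross-set distance are
    excluded from numerator and denominator.
    """
    ctx = _GraphContext(graph)
    ai = ctx.project(set_a, "A")
    bi = ctx.project(set_b, "B")
    d, _ = _closest_on_dist(ctx.dist, ai, bi)
    return d


def distance_test(
    graph: nx.Graph,
    set_a: Set,
    set_b: Set,
    config: Optional[AnalysisConfig] = None,
) -> DistanceResult:
    """Network distance score with a permutation null.

    pval is the one-sided closer-than-random estimate
    (1 + #{null <= observed}) / (1 + n_perm); z = (observed - mean) / sd of
    the null, reported as NaN when the null is degenerate (sd = 0).
    """
    cfg = config or AnalysisConfig()
    ctx = _GraphContext(graph)
    ai = ctx.project(set_a, "A")
    bi = ctx.project(set_b, "B")
    D = ctx.dist
    observed, n_excl = _closest_on_dist(D, ai, bi)
    rng = np.random.default_rng(cfg.seed)
    null = np.empty(cfg.n_perm)
    for j in range(cfg.n_perm):
        ra = rng.choice(ctx.n, size=len(ai), replace=False)
        rb = rng.choice(ctx.n, size=len(bi), replace=False)
        null[j], _ = _closest_on_dist(D, ra, rb)
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if cfg.n_perm > 1 else 0.0
    z = (observed - mean) / sd if sd > 0 else math.nan
    pval = float((1 + np.count_nonzero(null <= observed)) / (1 + cfg.n_perm))
    return DistanceResult(observed, mean, sd, z, pval, n_excl)


def seed_subnetwork(graph: nx.Graph, seeds: Set, expand: bool = False) -> nx.Graph:
    """Seed-projection subnetwork of a PPI graph.

    With ``expand`` the seed set is extended by connector nodes — non-seed
    nodes adjacent to at least two seeds — before taking the induced
    subgraph. Isolated seeds are retained.
    """
    present = {s for s in seeds if s in graph}
    if not present:
        raise ValueError(
            f"none of the {len(seeds)} seed(s) are present in the graph: "
            f"{sorted(seeds)[:10]}"
        )
    missing = set(seeds) - present
    if missing:
        warnings.warn(f"{len(missing)} seed(s) absent from the graph")
    keep = set(present)
    if expand:
        for v in graph:
            if v not in present:
                if sum(1 for u in graph[v] if u in present) >= 2:
                    keep.add(v)
    sub = graph.subgraph(keep).copy()
    sub.add_nodes_from(present)  # keep isolated seeds
    return sub
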