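"""Core-formula mining from prescription records.

Pipeline: build a weighted herb co-occurrence network (edge weight = number
of prescriptions containing both herbs), binarize it at a co-occurrence
threshold, enumerate maximal cliques with Bron-Kerbosch (pivoting), and
evaluate every candidate clique against the prescription set with two
metrics:

* confidence of a formula F in a prescription R: |F ∩ R| / |F|;
* support S_alpha: the fraction of prescriptions whose confidence is at
  least alpha (alpha defaults to 0.9).

The binarization threshold is chosen adaptively: every distinct edge weight
is scanned and the threshold maximizing the number of qualifying core
formulas wins, ties resolved toward the sparser (larger-threshold) network.
Highly similar formulas can optionally be merged ("Together" = similarity
components collectively; "Step" = most-similar pair at a time, Jaccard
similarity) and patient-level support attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .config import AnalysisConfig
from .datamodel import PrescriptionDataset

__all__ = [
    "build_herb_network",
    "binarize",
    "maximal_cliques",
    "formula_confidence",
    "formula_support",
    "mine_core_formulas",
    "merge_formulas",
    "person_stats",
    "CoreFormula",
    "MiningResult",
]


def build_herb_network(ds: PrescriptionDataset) -> nx.Graph:
    """Weighted undirected herb co-occurrence network.

    Edge (h1, h2) carries weight = number of prescriptions containing both
    herbs. Herbs never co-occurring with another appear as isolated nodes.
    """
    if not ds.records:
        raise ValueError("prescription dataset is empty")
    g = nx.Graph()
    g.add_nodes_from(ds.herbs)
    for rec in ds.records:
        herbs = sorted(rec.herbs)
        for i, h1 in enumerate(herbs):
            for h2 in herbs[i + 1 :]:
                if g.has_edge(h1, h2):
                    g[h1][h2]["weight"] += 1
                else:
                    g.add_edge(h1, h2, weight=1)
    if g.number_of_edges() == 0:
        raise ValueError("every prescription is a singleton; no co-occurrence edges")
    return g


def binarize(net: nx.Graph, threshold: int) -> nx.Graph:
    """Keep edges with weight >= threshold; drop isolated nodes."""
    if threshold < 1:
        raise ValueError(f"threshold must be >= 1, got {threshold}")
    g = nx.Graph()
    for u, v, w in net.edges(data="weight", default=1):
        if w >= threshold:
            g.add_edge(u, v)
    return g


def maximal_cliques(graph: nx.Graph) -> List[FrozenSet]:
    """All maximal cliques of size >= 2, Bron-Kerbosch with pivoting.

    Output is canonically ordered: size descending, then lexicographic
    member list.
    """
    adj = {v: set(graph[v]) for v in graph}
    out: List[FrozenSet] = []

    def bk(r: Set, p: Set, x: Set) -> None:
        if not p and not x:
            if len(r) >= 2:
                out.append(frozenset(r))
            return
        pivot = max(p | x, key=lambda u: len(adj[u] & p))
        for v in list(p - adj[pivot]):
            bk(r | {v}, p & adj[v], x & adj[v])
            p.remove(v)
            x.add(v)

    if adj:
        bk(set(), set(adj), set())
    out.sort(key=lambda c: (-len(c), sorted(c)))
    return out


def formula_confidence(formula: Set[str], prescription: Set[str]) -> float:
    """Fraction of the formula's herbs present in the prescription."""
    if not formula:
        raise ValueError("formula is empty")
    return len(set(formula) & set(prescription)) / len(formula)


@dataclass(frozen=True)
class CoreFormula:
    """A mined herb combination with its support metrics."""

    herbs: FrozenSet[str]
    avg_confidence: float  # mean confidence over all prescriptions
    support: float  # S_alpha
    n_supporting: int
    source_threshold: int
    person_support: Optional[float] = None


@dataclass
class MiningResult:
    formulas: List[CoreFormula]
    chosen_threshold: int
    thresholds_scanned: List[int]
    summary: Dict[int, int]  # threshold -> count of qualifying formulas


class _PrescriptionMatrix:
    """Boolean prescriptions-by-herbs matrix for fast confidence sweeps."""

    def __init__(self, ds: PrescriptionDataset):
        self.ds = ds
        self.herbs = sorted(ds.herbs)
        self.index = {h: i for i, h in enumerate(self.herbs)}
        self.mat = np.zeros((ds.n_prescriptions, len(self.herbs)), dtype=bool)
        for r, rec in enumerate(ds.records):
            for h in rec.herbs:
                self.mat[r, self.index[h]] = True
        self.pids = [rec.pid for rec in ds.records]

    def confidences(self, formula: Set[str]) -> np.ndarray:
        idx = [self.index[h] for h in formula if h in self.index]
        if not idx:
            return np.zeros(self.mat.shape[0])
        return self.mat[:, idx].sum(axis=1) / len(formula)


def formula_support(
    formula: Set[str], ds: PrescriptionDataset, alpha: float = 0.9
) -> Tuple[float, float, int]:
    """(S_alpha, average confidence, supporting-prescription count).

    S_alpha counts prescriptions whose confidence reaches alpha; the
    average confidence runs over all prescriptions.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if not ds.records:
        raise ValueError("prescription dataset is empty")
    conf = _PrescriptionMatrix(ds).confidences(formula)
    return _support_from_conf(conf, alpha)


def _support_from_conf(conf: np.ndarray, alpha: float) -> Tuple[float, float, int]:
    # tiny tolerance so e.g. 9/10 >= 0.9 survives float rounding
    n_sup = int(np.count_nonzero(conf >= alpha - 1e-12))
    return n_sup / conf.size, float(conf.mean()), n_sup


def person_stats(
    formula: Set[str], ds: PrescriptionDataset, alpha: float = 0.9
) -> float:
    """Fraction of patients whose best visit reaches confidence alpha.

    Each patient contributes the maximum confidence over their visits, so a
    patient with many supporting visits counts once.
    """
    pm = _PrescriptionMatrix(ds)
    conf = pm.confidences(formula)
    best: Dict[str, float] = {}
    for pid, c in zip(pm.pids, conf):
        if c > best.get(pid, -1.0):
            best[pid] = float(c)
    n = len(best)
    return sum(1 for c in best.values() if c >= alpha - 1e-12) / n


def _evaluate(
    clique: FrozenSet, pm: _PrescriptionMatrix, alpha: float, threshold: int
) -> CoreFormula:
    s, avg, n_sup = _support_from_conf(pm.confidences(clique), alpha)
    return CoreFormula(clique, avg, s, n_sup, threshold)


def mine_core_formulas(
    ds: PrescriptionDataset, config: Optional[AnalysisConfig] = None
) -> MiningResult:
    """Adaptive-threshold core-formula mining.

    Scans every distinct edge weight of the herb network as a binarization
    threshold (descending), enumerates maximal cliques at each, keeps
    cliques meeting the size constraint with support S_alpha >= s_min, and
    selects the threshold yielding the most qualifying formulas (ties to
    the larger threshold). Optionally merges similar formulas and attaches
    person-based support. No qualifying formula anywhere yields an empty
    result with per-threshold diagnostics, not an exception.
    """
    cfg = config or AnalysisConfig()
    net = build_herb_network(ds)
    pm = _PrescriptionMatrix(ds)
    weights = sorted({w for _, _, w in net.edges(data="weight")}, reverse=True)

    per_threshold: Dict[int, List[CoreFormula]] = {}
    for thr in weights:
        g = binarize(net, thr)
        found: List[CoreFormula] = []
        for clique in maximal_cliques(g):
            if len(clique) < cfg.min_herbs:
                continue
            if (
                cfg.enforce_size
                and cfg.desired_herbs is not None
                and len(clique) != cfg.desired_herbs
            ):
                continue
            cf = _evaluate(clique, pm, cfg.alpha, thr)
            if cf.support >= cfg.s_min:
                found.append(cf)
        per_threshold[thr] = found

    # A qualifying formula that is a proper subset of a qualifying formula
    # found at any scanned threshold is a fragment of it (an over-high
    # threshold splits a true clique into sub-cliques that each qualify) and
    # is not counted or returned.
    all_sets = {cf.herbs for found in per_threshold.values() for cf in found}
    pruned: Dict[int, List[CoreFormula]] = {
        thr: [
            cf
            for cf in found
            if not any(cf.herbs < other for other in all_sets)
        ]
        for thr, found in per_threshold.items()
    }
    summary: Dict[int, int] = {thr: len(found) for thr, found in pruned.items()}
    best_threshold: Optional[int] = None
    best: List[CoreFormula] = []
    for thr in weights:  # descending, strict > keeps the larger threshold
        if pruned[thr] and len(pruned[thr]) > len(best):
            best_threshold = thr
            best = pruned[thr]

    if best_threshold is None:
        return MiningResult([], 0, weights, summary)

    formulas = sorted(
        best, key=lambda f: (-f.support, -f.avg_confidence, sorted(f.herbs))
    )
    if cfg.merge:
        formulas = merge_formulas(formulas, cfg.merge_method, cfg.merge_threshold, ds, cfg.alpha)
    if cfg.person_stats:
        formulas = [
            replace(f, person_support=person_stats(f.herbs, ds, cfg.alpha))
            for f in formulas
        ]
    return MiningResult(formulas, best_threshold, weights, summary)


def _jaccard(a: FrozenSet, b: FrozenSet) -> float:
    return len(a & b) / len(a | b)


def merge_formulas(
    formulas: Sequence[CoreFormula],
    method: str,
    threshold: float,
    ds: PrescriptionDataset,
    alpha: float = 0.9,
) -> List[CoreFormula]:
    """Merge highly similar core formulas (Jaccard >= threshold).

    "Together" merges each connected component of the similarity graph by
    herb-set union in one pass; "Step" repeatedly merges the single most
    similar qualifying pair (ties to the lexicographically smallest union)
    and recomputes similarities until none remain. Metrics are recomputed
    on the dataset after merging; a merged formula keeps the smallest
    source threshold among its parts.
    """
    if method not in ("Together", "Step"):
        raise ValueError(f"unknown merge method {method!r}")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"merge threshold must lie in [0, 1], got {threshold}")
    if len(formulas) <= 1:
        return list(formulas)
    pm = _PrescriptionMatrix(ds)
    sets: List[Tuple[FrozenSet, int]] = [
        (f.herbs, f.source_threshold) for f in formulas
    ]

    if method == "Together":
        sim = nx.Graph()
        sim.add_nodes_from(range(len(sets)))
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if _jaccard(sets[i][0], sets[j][0]) >= threshold:
                    sim.add_edge(i, j)
        merged: List[Tuple[FrozenSet, int]] = []
        for comp in nx.connected_components(sim):
            herbs = frozenset().union(*(sets[i][0] for i in comp))
            thr = min(sets[i][1] for i in comp)
            merged.append((herbs, thr))
    else:  # Step
        merged = list(sets)
        while True:
            cand = []
            for i in range(len(merged)):
                for j in range(i + 1, len(merged)):
                    s = _jaccard(merged[i][0], merged[j][0])
                    if s >= threshold:
                        union = tuple(sorted(merged[i][0] | merged[j][0]))
                        cand.append((-s, union, i, j))
            if not cand:
                break
            _, union, i, j = min(cand)
            thr = min(merged[i][1], merged[j][1])
            merged = [m for k, m in enumerate(merged) if k not in (i, j)]
            merged.append((frozenset(union), thr))

    # dedupe identical herb sets, then re-evaluate on the dataset
    uniq: Dict[FrozenSet, int] = {}
    for herbs, thr in merged:
        uniq[herbs] = min(thr, uniq.get(herbs, thr))
    out = [_evaluate(herbs, pm, alpha, thr) for herbs, thr in uniq.items()]
    out.sort(key=lambda f: (-f.support, -f.avg_confidence, sorted(f.herbs)))
    return out
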