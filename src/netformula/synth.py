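"""Deterministic synthetic-data generators.

Every input shape the analysis modules consume can be generated here with a
planted signal for recovery tests: a preferential-attachment PPI network, a
compound-target table with one enriched target, prescription records with a
planted core formula, and gene-set collections with a planted enriched
term. All generators are pure functions of a :class:`FixtureSpec` — the
RNG is numpy's default PCG64 generator seeded from the spec — so identical
specs give identical outputs.

These fixtures are statistical stand-ins: they emulate the formats and the
signal-vs-background structure of real herb/compound/target data, not the
marginal distributions of any real database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .datamodel import (
    CompoundRecord,
    GeneSetCollection,
    HerbCompoundLink,
    Prescription,
    PrescriptionDataset,
    ScoredLink,
)

__all__ = [
    "FixtureSpec",
    "gen_ppi",
    "gen_compound_target",
    "gen_herb_compound",
    "gen_prescriptions",
    "gen_gene_sets",
    "planted_formula_herbs",
    "formula_compound_ids",
]


@dataclass
class FixtureSpec:
    """Parameters of the synthetic world.

    Defaults describe a small but realistic study: 30 distinct herbs, 500
    compounds, 100 targets, 500 prescriptions from 250 patients with a
    5-herb core formula present intact in 60% of prescriptions, a
    compound-target background density of 2% with one target enriched
    10-fold among the formula's compounds, and gene sets of 10-50 genes
    over a 500-gene universe.
    """

    seed: int = 0
    n_herbs: int = 30
    n_compounds: int = 500
    n_targets: int = 100
    n_genes: int = 500
    n_terms: int = 50
    n_patients: int = 250
    n_prescriptions: int = 500
    planted_formula_size: int = 5
    presence_rate: float = 0.6
    enrichment_factor: float = 10.0
    link_density: float = 0.02
    n_formula_compounds: int = 50
    herbs_per_prescription: Tuple[int, int] = (8, 15)
    n_query: int = 50
    term_size_range: Tuple[int, int] = (10, 50)

    def __post_init__(self) -> None:
        for name in (
            "n_herbs",
            "n_compounds",
            "n_targets",
            "n_genes",
            "n_terms",
            "n_patients",
            "n_prescriptions",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 < self.presence_rate <= 1.0):
            raise ValueError("presence_rate must lie in (0, 1]")
        if not (0.0 < self.link_density < 1.0):
            raise ValueError("link_density must lie in (0, 1)")
        if self.enrichment_factor < 1.0:
            raise ValueError("enrichment_factor must be >= 1")
        if self.planted_formula_size > self.n_herbs:
            raise ValueError("planted formula larger than the herb inventory")
        lo, hi = self.herbs_per_prescription
        if not (1 <= lo <= hi <= self.n_herbs):
            raise ValueError(
                f"herbs_per_prescription range ({lo}, {hi}) infeasible for "
                f"{self.n_herbs} herbs"
            )


def _ids(prefix: str, n: int) -> List[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def planted_formula_herbs(spec: FixtureSpec) -> FrozenSet[str]:
    """The planted core formula: the first herbs of the inventory."""
    return frozenset(_ids("H", spec.n_herbs)[: spec.planted_formula_size])


def formula_compound_ids(spec: FixtureSpec) -> Set[str]:
    """The compound subset acting as the formula's active compounds."""
    return set(_ids("C", spec.n_compounds)[: spec.n_formula_compounds])


PLANTED_TARGET = "T_PLANTED"


def gen_ppi(n_nodes: int, edges_per_node: int, seed: int) -> nx.Graph:
    """Connected preferential-attachment PPI stand-in with gene-id labels."""
    if not (n_nodes > edges_per_node >= 1):
        raise ValueError(
            f"need n_nodes > edges_per_node >= 1, got {n_nodes}, {edges_per_node}"
        )
    g = nx.barabasi_albert_graph(n_nodes, edges_per_node, seed=seed)
    labels = _ids("G", n_nodes)
    return nx.relabel_nodes(g, dict(enumerate(labels)))


def gen_compound_target(
    spec: FixtureSpec,
) -> Tuple[List[CompoundRecord], List[ScoredLink]]:
    """Compound descriptor table plus scored compound-target links.

    Descriptors straddle the Lipinski/Veber/QED decision boundaries.
    Background links are Bernoulli(link_density) with scores uniform on
    150..999. One target (``T_PLANTED``) is additionally linked to the
    formula's compound subset at enrichment_factor x density with scores
    on 400..999 (guaranteed to pass the default threshold); at factor 1 no
    extra links are planted, so the target is pure background — the
    calibration case.
    """
    if spec.link_density * spec.n_compounds < 1:
        raise ValueError(
            "link density too small: expected links per target below 1"
        )
    rng = np.random.default_rng(spec.seed)
    compounds = []
    for cid in _ids("C", spec.n_compounds):
        compounds.append(
            CompoundRecord(
                compound_id=cid,
                MW=float(rng.uniform(100, 700)),
                ALOGP=float(rng.uniform(-2, 7)),
                HBA=int(rng.integers(0, 13)),
                HBD=int(rng.integers(0, 8)),
                PSA=float(rng.uniform(10, 200)),
                ROTB=int(rng.integers(0, 15)),
                AROM=int(rng.integers(0, 5)),
                ALERTS=int(rng.integers(0, 3)),
            )
        )
    targets = _ids("T", spec.n_targets - 1) + [PLANTED_TARGET]
    cids = [c.compound_id for c in compounds]
    links: Dict[Tuple[str, str], int] = {}
    mask = rng.random((len(cids), len(targets))) < spec.link_density
    scores = rng.integers(150, 1000, size=mask.shape)
    for i, cid in enumerate(cids):
        for j in np.nonzero(mask[i])[0]:
            links[(cid, targets[j])] = int(scores[i, j])
    if spec.enrichment_factor > 1.0:
        p_extra = min(1.0, spec.enrichment_factor * spec.link_density)
        for cid in sorted(formula_compound_ids(spec)):
            if rng.random() < p_extra:
                links[(cid, PLANTED_TARGET)] = int(rng.integers(400, 1000))
    return compounds, [ScoredLink(c, t, s) for (c, t), s in sorted(links.items())]


def gen_herb_compound(spec: FixtureSpec) -> List[HerbCompoundLink]:
    """Herb-compound membership links.

    The planted formula's herbs share the formula compound subset (spread
    round-robin); remaining compounds are assigned to random herbs.
    """
    rng = np.random.default_rng(spec.seed + 1)
    herbs = _ids("H", spec.n_herbs)
    planted = sorted(planted_formula_herbs(spec))
    fcids = sorted(formula_compound_ids(spec))
    links = set()
    for i, cid in enumerate(fcids):
        links.add((planted[i % len(planted)], cid))
    rest = [c for c in _ids("C", spec.n_compounds) if c not in set(fcids)]
    for cid in rest:
        links.add((herbs[int(rng.integers(0, len(herbs)))], cid))
    return [HerbCompoundLink(h, c) for h, c in sorted(links)]


def gen_prescriptions(spec: FixtureSpec) -> PrescriptionDataset:
    """Prescription records with a planted intact core formula.

    Each prescription includes the planted formula intact with probability
    presence_rate, then adds noise herbs sampled without replacement until
    reaching a size drawn uniformly from herbs_per_prescription.
    Prescriptions are distributed round-robin over patients, so patients
    can have several visits.
    """
    rng = np.random.default_rng(spec.seed + 2)
    herbs = _ids("H", spec.n_herbs)
    planted = sorted(planted_formula_herbs(spec))
    lo, hi = spec.herbs_per_prescription
    records: List[Prescription] = []
    visit_no: Dict[str, int] = {}
    for i in range(spec.n_prescriptions):
        pid = f"P{(i % spec.n_patients) + 1:04d}"
        visit_no[pid] = visit_no.get(pid, 0) + 1
        size = int(rng.integers(lo, hi + 1))
        chosen: Set[str] = set()
        if rng.random() < spec.presence_rate:
            chosen |= set(planted)
        pool = [h for h in herbs if h not in chosen]
        need = max(0, size - len(chosen))
        if need:
            extra = rng.choice(len(pool), size=min(need, len(pool)), replace=False)
            chosen |= {pool[j] for j in extra}
        records.append(Prescription(pid, f"V{visit_no[pid]}", frozenset(chosen)))
    return PrescriptionDataset(records)


def gen_gene_sets(spec: FixtureSpec) -> Tuple[GeneSetCollection, Set[str]]:
    """Gene-set collection plus a query list enriched for one planted term.

    Random terms draw their members uniformly; the planted term
    (``TERM_PLANTED``) contributes enrichment_factor times the chance
    overlap to the query. At factor 1 the query is drawn uniformly from
    the universe — the calibration case.
    """
    if spec.n_terms < 2:
        raise ValueError("need at least 2 terms")
    lo, hi = spec.term_size_range
    if hi > spec.n_genes:
        raise ValueError("term size exceeds the gene universe")
    rng = np.random.default_rng(spec.seed + 3)
    genes = _ids("g", spec.n_genes)
    sets: Dict[str, Tuple[str, FrozenSet[str]]] = {}
    for term in _ids("TERM", spec.n_terms - 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(spec.n_genes, size=size, replace=False)
        sets[term] = (f"random term {term}", frozenset(genes[j] for j in members))
    k_size = int(rng.integers(lo, hi + 1))
    planted_members = rng.choice(spec.n_genes, size=k_size, replace=False)
    planted_genes = frozenset(genes[j] for j in planted_members)
    sets["TERM_PLANTED"] = ("planted enriched term", planted_genes)

    n_q = min(spec.n_query, spec.n_genes)
    if spec.enrichment_factor > 1.0:
        expected_chance = n_q * k_size / spec.n_genes
        n_hit = int(min(k_size, n_q, round(spec.enrichment_factor * expected_chance)))
        hit = rng.choice(sorted(planted_genes), size=n_hit, replace=False)
        rest_pool = sorted(set(genes) - set(hit))
        fill = rng.choice(len(rest_pool), size=n_q - n_hit, replace=False)
        query = set(hit) | {rest_pool[j] for j in fill}
    else:
        pick = rng.choice(spec.n_genes, size=n_q, replace=False)
        query = {genes[j] for j in pick}
    return GeneSetCollection(sets=sets, universe=frozenset(genes)), query
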