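"""Domain types for formula network analysis.

Plain dataclasses carry the parsed inputs: compound descriptor records,
herb-compound and compound-target link tables, prescription datasets, gene
set collections and protein-protein interaction graphs (held as
``networkx.Graph``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

import networkx as nx

__all__ = [
    "CompoundRecord",
    "HerbCompoundLink",
    "ScoredLink",
    "Prescription",
    "PrescriptionDataset",
    "GeneSetCollection",
    "FormatError",
    "DESCRIPTOR_NAMES",
    "SCORE_SENTINEL",
]

#: Order of the eight QED descriptors throughout the package.
DESCRIPTOR_NAMES = ("MW", "ALOGP", "HBA", "HBD", "PSA", "ROTB", "AROM", "ALERTS")

#: Sentinel score for curated compound-target links that carry no
#: association score; always passes any score threshold.
SCORE_SENTINEL = 9999


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class CompoundRecord:
    """A compound and its eight molecular descriptors.

    ``compound_id`` is an opaque identifier (InChIKey when available).
    Descriptors: molecular weight (Da), octanol-water logP, H-bond
    acceptor/donor counts, polar surface area (A^2), rotatable-bond count,
    aromatic-ring count and structural-alert count.
    """

    compound_id: str
    MW: float
    ALOGP: float
    HBA: int
    HBD: int
    PSA: float
    ROTB: int
    AROM: int
    ALERTS: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.MW <= 0:
            raise ValueError(f"{self.compound_id}: MW must be > 0, got {self.MW}")
        if self.PSA < 0:
            raise ValueError(f"{self.compound_id}: PSA must be >= 0, got {self.PSA}")
        for attr in ("HBA", "HBD", "ROTB", "AROM", "ALERTS"):
            v = getattr(self, attr)
            if v < 0 or int(v) != v:
                raise ValueError(
                    f"{self.compound_id}: {attr} must be a non-negative integer, got {v}"
                )

    @property
    def descriptors(self) -> Tuple[float, ...]:
        """Descriptor vector in canonical order (MW, ALOGP, ..., ALERTS)."""
        return tuple(float(getattr(self, n)) for n in DESCRIPTOR_NAMES)


@dataclass(frozen=True)
class HerbCompoundLink:
    """One herb-to-compound membership link."""

    herb_id: str
    compound_id: str


@dataclass(frozen=True)
class ScoredLink:
    """A compound-target association with a confidence score.

    Scores live on a 0-1000 scale; the sentinel 9999 marks curated links
    lacking a score and passes every threshold.
    """

    compound_id: str
    target: str
    score: int = SCORE_SENTINEL

    def __post_init__(self) -> None:
        if not (0 <= self.score <= 1000 or self.score == SCORE_SENTINEL):
            raise ValueError(
                f"score must be in [0, 1000] or {SCORE_SENTINEL}, got {self.score}"
            )


@dataclass(frozen=True)
class Prescription:
    """One prescription: a patient visit and its herb set."""

    pid: str
    vid: str
    herbs: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.herbs:
            raise ValueError(f"prescription ({self.pid}, {self.vid}) has no herbs")


@dataclass
class PrescriptionDataset:
    """Prescription records keyed by (patient id, visit id)."""

    records: List[Prescription]

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            key = (rec.pid, rec.vid)
            if key in seen:
                raise ValueError(f"duplicate (pid, vid) pair {key}")
            seen.add(key)

    @property
    def n_prescriptions(self) -> int:
        return len(self.records)

    @property
    def n_patients(self) -> int:
        return len({r.pid for r in self.records})

    @property
    def herbs(self) -> Set[str]:
        out: Set[str] = set()
        for r in self.records:
            out |= r.herbs
        return out


@dataclass
class GeneSetCollection:
    """Term -> gene-set mapping with an explicit universe.

    ``sets`` maps a term id to ``(description, frozenset of gene ids)``.
    The universe defaults to the union of all member genes unless overridden.
    """

    sets: Dict[str, Tuple[str, FrozenSet[str]]]
    universe: FrozenSet[str] = field(default_factory=frozenset)
    n_skipped: int = 0

    def __post_init__(self) -> None:
        union: Set[str] = set()
        for term, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"term {term} has an empty gene set")
            union |= genes
        if not self.universe:
            self.universe = frozenset(union)
        elif not union <= self.universe:
            missing = sorted(union - self.universe)[:5]
            raise ValueError(
                f"gene-set members outside the universe, e.g. {missing}"
            )

    def genes(self, term: str) -> FrozenSet[str]:
        return self.sets[term][1]

    def __len__(self) -> int:
        return len(self.sets)


def validate_ppi(graph: nx.Graph) -> nx.Graph:
    """Assert the simple-graph invariants of a PPI network."""
    if any(u == v for u, v in graph.edges):
        raise ValueError("PPI graph contains a self-loop")
    if graph.is_multigraph() or graph.is_directed():
        raise ValueError("PPI graph must be a simple undirected graph")
    return graph
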