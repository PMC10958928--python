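"""Readers and writers for every external format, plus retrieval joins.

All tabular inputs are UTF-8 CSV with a header row; gene sets are GMT;
PPI networks are two-column edge lists. Writers round-trip: writing any
loaded table and re-reading yields the same in-memory value.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Union

import networkx as nx
import pandas as pd

from .datamodel import (
    DESCRIPTOR_NAMES,
    SCORE_SENTINEL,
    CompoundRecord,
    FormatError,
    GeneSetCollection,
    HerbCompoundLink,
    Prescription,
    PrescriptionDataset,
    ScoredLink,
)

__all__ = [
    "read_compound_table",
    "write_compound_table",
    "read_links",
    "write_links",
    "read_prescriptions",
    "write_prescriptions",
    "read_gene_sets",
    "write_gene_sets",
    "read_ppi",
    "write_ppi",
    "write_weighted_network",
    "read_gene_list",
    "normalize_herb",
    "lookup_compound",
    "formula_compounds",
    "FormulaCompounds",
]

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")

_WS_RUN = re.compile(r"\s+")


def normalize_herb(name: str) -> str:
    """Trim and collapse internal whitespace runs; case preserved.

    No synonym resolution is attempted: name dictionaries are data, not
    method.
    """
    return _WS_RUN.sub(" ", name.strip())


# ---------------------------------------------------------------------------
# compound descriptor table
# ---------------------------------------------------------------------------

def read_compound_table(path: Union[str, Path]) -> List[CompoundRecord]:
    """Load a compound descriptor CSV (compound_id + eight descriptors).

    The ``name`` column is optional. Duplicate compound ids are rejected;
    non-numeric descriptors raise a row-level error citing the row number.
    """
    df = pd.read_csv(path, dtype=str, encoding="utf-8")
    required = ["compound_id", *DESCRIPTOR_NAMES]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"compound table missing required column '{col}'")
    records: List[CompoundRecord] = []
    seen: Set[str] = set()
    int_fields = {"HBA", "HBD", "ROTB", "AROM", "ALERTS"}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        row = row._asdict()
        cid = str(row["compound_id"]).strip()
        if cid in seen:
            raise FormatError(f"duplicate compound_id '{cid}'")
        seen.add(cid)
        values = {}
        for col in DESCRIPTOR_NAMES:
            raw = row[col]
            try:
                values[col] = int(raw) if col in int_fields else float(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"row {i}: non-numeric value {raw!r} in column '{col}'"
                ) from None
        name = str(row.get("name", "") or "")
        if name == "nan":
            name = ""
        records.append(CompoundRecord(compound_id=cid, name=name, **values))
    return records


def write_compound_table(records: Sequence[CompoundRecord], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "name": r.name,
                **{c: getattr(r, c) for c in DESCRIPTOR_NAMES},
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# link tables
# ---------------------------------------------------------------------------

def read_links(
    path: Union[str, Path], kind: str
) -> Union[List[HerbCompoundLink], List[ScoredLink]]:
    """Load a two-column herb-compound table or a 2-3 column compound-target
    table.

    Compound-target rows lacking a score receive the 9999 sentinel (curated
    link without a score); duplicate pairs collapse keeping the maximum
    score.
    """
    if kind not in ("herb_compound", "compound_target"):
        raise ValueError(f"unknown link kind {kind!r}")
    df = pd.read_csv(path, dtype=str, encoding="utf-8")
    if df.empty:
        raise FormatError(f"link table {path} contains no rows")
    if kind == "herb_compound":
        if df.shape[1] < 2:
            raise FormatError("herb_compound table needs 2 columns")
        pairs = {
            (normalize_herb(str(h)), str(c).strip())
            for h, c in zip(df.iloc[:, 0], df.iloc[:, 1])
        }
        return [HerbCompoundLink(h, c) for h, c in sorted(pairs)]
    # compound_target
    if df.shape[1] < 2:
        raise FormatError("compound_target table needs 2 or 3 columns")
    best: Dict[tuple, int] = {}
    for row in df.itertuples(index=False):
        cid = str(row[0]).strip()
        tgt = str(row[1]).strip()
        if df.shape[1] >= 3 and not pd.isna(row[2]):
            score = int(float(row[2]))
            if not (0 <= score <= 1000 or score == SCORE_SENTINEL):
                raise FormatError(
                    f"score {score} for ({cid}, {tgt}) outside [0,1000] and not "
                    f"the {SCORE_SENTINEL} sentinel"
                )
        else:
            score = SCORE_SENTINEL
        key = (cid, tgt)
        # sentinel ranks above every numeric score for the keep-max rule
        if key not in best or _score_rank(score) > _score_rank(best[key]):
            best[key] = score
    return [ScoredLink(c, t, s) for (c, t), s in sorted(best.items())]


def _score_rank(score: int) -> int:
    return score if score != SCORE_SENTINEL else 10_000


def write_links(
    links: Sequence[Union[HerbCompoundLink, ScoredLink]], path: Union[str, Path]
) -> None:
    if links and isinstance(links[0], ScoredLink):
        df = pd.DataFrame(
            [(l.compound_id, l.target, l.score) for l in links],
            columns=["compound_id", "target", "score"],
        )
    else:
        df = pd.DataFrame(
            [(l.herb_id, l.compound_id) for l in links],
            columns=["herb_id", "compound_id"],
        )
    df.to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# prescriptions
# ---------------------------------------------------------------------------

def read_prescriptions(
    path: Union[str, Path], delimiter: str = ";"
) -> PrescriptionDataset:
    """Load a prescription CSV with columns Pid, Vid, Herb.

    Accepts long format (one herb per row, grouped by Pid+Vid) or wide
    format (the Herb cell holds a delimiter-separated herb list); the format
    is auto-detected from the presence of the delimiter. Herb names are
    whitespace-normalized and deduplicated within a prescription.
    """
    df = pd.read_csv(path, dtype=str, encoding="utf-8")
    cols = {c.lower(): c for c in df.columns}
    for want in ("pid", "vid", "herb"):
        if want not in cols:
            raise FormatError(f"prescription table missing column '{want.capitalize()}'")
    grouped: Dict[tuple, Set[str]] = {}
    order: List[tuple] = []
    for row in df.itertuples(index=False):
        row = row._asdict()
        pid = str(row[cols["pid"]]).strip()
        vid = str(row[cols["vid"]]).strip()
        cell = str(row[cols["herb"]])
        herbs = (
            cell.split(delimiter) if delimiter in cell else [cell]
        )
        key = (pid, vid)
        if key not in grouped:
            grouped[key] = set()
            order.append(key)
        for h in herbs:
            h = normalize_herb(h)
            if h:
                grouped[key].add(h)
    records = []
    for key in order:
        if not grouped[key]:
            raise FormatError(f"prescription {key} is empty after cleaning")
        records.append(Prescription(key[0], key[1], frozenset(grouped[key])))
    if not records:
        raise FormatError(f"prescription file {path} contains no prescriptions")
    return PrescriptionDataset(records)


def write_prescriptions(
    ds: PrescriptionDataset, path: Union[str, Path], delimiter: str = ";"
) -> None:
    """Write in wide format, herbs sorted for byte-stable output."""
    df = pd.DataFrame(
        [
            (r.pid, r.vid, delimiter.join(sorted(r.herbs)))
            for r in ds.records
        ],
        columns=["Pid", "Vid", "Herb"],
    )
    df.to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# gene sets (GMT) and gene lists
# ---------------------------------------------------------------------------

def read_gene_sets(path: Union[str, Path]) -> GeneSetCollection:
    """Load a GMT file: term_id <tab> description <tab> gene [gene ...].

    Lines with fewer than three fields are skipped; the skip count is kept
    on the returned collection and surfaced as a warning.
    """
    sets: Dict[str, tuple] = {}
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                skipped += 1
                continue
            term, desc, *genes = fields
            sets[term] = (desc, frozenset(g.strip() for g in genes if g.strip()))
    if skipped:
        warnings.warn(f"skipped {skipped} malformed GMT line(s) in {path}")
    if not sets:
        raise FormatError(f"GMT file {path} contains no usable gene sets")
    return GeneSetCollection(sets=sets, n_skipped=skipped)


def write_gene_sets(collection: GeneSetCollection, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(collection.sets):
            desc, genes = collection.sets[term]
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def read_gene_list(path: Union[str, Path]) -> List[str]:
    """Plain text, one gene id per line; blanks ignored, order preserved."""
    out: List[str] = []
    seen: Set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            g = line.strip()
            if g and g not in seen:
                seen.add(g)
                out.append(g)
    if not out:
        raise FormatError(f"gene list {path} is empty")
    return out


# ---------------------------------------------------------------------------
# PPI graph
# ---------------------------------------------------------------------------

def read_ppi(path: Union[str, Path]) -> nx.Graph:
    """Load a PPI edge list (CSV or TSV, first two columns are gene ids).

    Self-loops are dropped; duplicate and reversed-duplicate edges collapse.
    """
    sep = None  # sniff comma vs tab
    with open(path, encoding="utf-8") as fh:
        head = fh.readline()
    sep = "\t" if "\t" in head else ","
    df = pd.read_csv(path, dtype=str, sep=sep, encoding="utf-8")
    if df.shape[1] < 2:
        raise FormatError("PPI edge list needs at least two columns")
    g = nx.Graph()
    for a, b in zip(df.iloc[:, 0], df.iloc[:, 1]):
        a, b = str(a).strip(), str(b).strip()
        if a != b:
            g.add_edge(a, b)
    if g.number_of_edges() < 1:
        raise FormatError(f"PPI file {path} contains no valid edges")
    return g


def write_weighted_network(graph: nx.Graph, path: Union[str, Path]) -> None:
    """Write a weighted network as GraphML or a three-column CSV edge list."""
    path = Path(path)
    if path.suffix == ".graphml":
        nx.write_graphml(graph, path)
        return
    edges = sorted(
        (*sorted((u, v)), w) for u, v, w in graph.edges(data="weight", default=1)
    )
    pd.DataFrame(edges, columns=["node_a", "node_b", "weight"]).to_csv(
        path, index=False, encoding="utf-8"
    )


def write_ppi(graph: nx.Graph, path: Union[str, Path]) -> None:
    """Write as GraphML (.graphml extension) or two-column CSV edge list."""
    path = Path(path)
    if path.suffix == ".graphml":
        nx.write_graphml(graph, path)
        return
    edges = sorted(tuple(sorted(e)) for e in graph.edges)
    pd.DataFrame(edges, columns=["gene_a", "gene_b"]).to_csv(
        path, index=False, encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# retrieval joins ("Formula Compounds" panel)
# ---------------------------------------------------------------------------

def lookup_compound(key: str, hc_links: Sequence[HerbCompoundLink]) -> Set[str]:
    """Return every herb linked to the compound identified by ``key``.

    ``key`` must match the InChIKey 14-10-1 block pattern or be an id
    present in the link table.
    """
    known = {l.compound_id for l in hc_links}
    if not _INCHIKEY_RE.match(key) and key not in known:
        raise ValueError(
            f"{key!r} is neither a valid InChIKey (14-10-1 blocks) nor a known "
            "compound id"
        )
    return {l.herb_id for l in hc_links if l.compound_id == key}


@dataclass
class FormulaCompounds:
    """Result of a formula -> compounds retrieval."""

    compound_ids: Set[str]
    records: List[CompoundRecord]
    unmatched_herbs: List[str]


def formula_compounds(
    herbs: Iterable[str],
    hc_links: Sequence[HerbCompoundLink],
    compounds: Optional[Sequence[CompoundRecord]] = None,
) -> FormulaCompounds:
    """Union of compounds over the listed herbs.

    Unmatched herb names are warned about and reported; if every herb is
    unmatched an error lists them all.
    """
    herbs = [normalize_herb(h) for h in herbs]
    if not herbs:
        raise ValueError("herb list is empty")
    by_herb: Dict[str, Set[str]] = {}
    for l in hc_links:
        by_herb.setdefault(l.herb_id, set()).add(l.compound_id)
    found: Set[str] = set()
    unmatched: List[str] = []
    for h in herbs:
        if h in by_herb:
            found |= by_herb[h]
        else:
            unmatched.append(h)
    if len(unmatched) == len(herbs):
        raise ValueError(f"no herbs matched the link table: {sorted(unmatched)}")
    if unmatched:
        warnings.warn(f"unmatched herb name(s): {sorted(unmatched)}")
    records = [r for r in (compounds or []) if r.compound_id in found]
    return FormulaCompounds(found, records, unmatched)
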