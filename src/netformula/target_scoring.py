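"""Binomial formula-target identification.

For a formula with ``n`` active compounds, a target hit by ``k`` of them is
tested against a binomial null: the probability P(X >= k) that k or more of
n compounds would hit the target by chance, where the per-compound hit
probability p comes from the score-filtered background compound-target
table. Significant targets (P < Psig) are ranked by p-value and scored

    geneScore = -log(P(X >= k)) / rank    (0 when not significant)

and each compound receives a chemScore equal to the arithmetic mean of the
gene scores of its profiled targets. Rank attenuation is the model's own
multiplicity control; no additional correction is applied here.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from scipy import stats

from .config import AnalysisConfig
from .datamodel import SCORE_SENTINEL, ScoredLink

__all__ = [
    "binomial_tail",
    "gene_scores",
    "background_probs",
    "profile_formula",
    "core_targets",
    "TargetProfileEntry",
    "FormulaProfile",
    "filter_links",
]

#: Smallest positive normal float, substituted when a tail probability
#: underflows to zero so that the log score stays finite.
_TINY = sys.float_info.min


def binomial_tail(k: int, n: int, p: float) -> float:
    """Upper tail P(X >= k) for X ~ Binomial(n, p).

    Computed through the survival function for numerical stability; exactly
    1.0 for k = 0.
    """
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def gene_scores(
    pvals: Sequence[float], psig: float = 0.05, log_base: float = 10.0
) -> List[float]:
    """Rank-attenuated significance scores for a list of tail probabilities.

    Significant p-values (p < psig) are ranked ascending (ties keep input
    order) and scored -log(p)/rank; non-significant ones score 0. Returned
    in input order.
    """
    log = math.log10 if log_base in (10, 10.0) else math.log
    order = sorted(
        (i for i, p in enumerate(pvals) if p < psig), key=lambda i: (pvals[i], i)
    )
    scores = [0.0] * len(pvals)
    for rank, i in enumerate(order, start=1):
        scores[i] = -log(pvals[i]) / rank
    return scores


def filter_links(
    ct_links: Iterable[ScoredLink], score_threshold: int
) -> List[ScoredLink]:
    """Keep links with score >= threshold; the 9999 sentinel always passes."""
    return [
        l
        for l in ct_links
        if l.score == SCORE_SENTINEL or l.score >= score_threshold
    ]


def background_probs(
    ct_links: Sequence[ScoredLink], score_threshold: int = 400
) -> Dict[str, float]:
    """Per-target background hit probability from the full link table.

    After score filtering, p_t = (#distinct compounds linked to t) /
    (#distinct compounds in the filtered table). Targets with no surviving
    link are absent from the map.
    """
    if not ct_links:
        raise ValueError("compound-target link table is empty")
    kept = filter_links(ct_links, score_threshold)
    if not kept:
        raise ValueError(
            f"no links survive score threshold {score_threshold}"
        )
    compounds: Set[str] = {l.compound_id for l in kept}
    per_target: Dict[str, Set[str]] = {}
    for l in kept:
        per_target.setdefault(l.target, set()).add(l.compound_id)
    n = len(compounds)
    return {t: len(cs) / n for t, cs in per_target.items()}


@dataclass(frozen=True)
class TargetProfileEntry:
    """One target's row of a formula profile.

    ``rank`` is 1..m over significant targets, 0 for non-significant ones.
    ``underflow`` flags a tail probability that underflowed to zero and was
    clamped to the smallest positive normal float.
    """

    target: str
    k: int
    n: int
    p: float
    pval: float
    rank: int
    gene_score: float
    underflow: bool = False


@dataclass
class FormulaProfile:
    """Per-target binomial profile plus per-compound chem scores."""

    entries: List[TargetProfileEntry]
    chem_scores: Dict[str, float]
    psig: float
    score_threshold: int
    log_base: float


def profile_formula(
    active_compounds: Set[str],
    ct_links: Sequence[ScoredLink],
    background: Dict[str, float],
    config: Optional[AnalysisConfig] = None,
) -> FormulaProfile:
    """Profile every target hit by the formula's active compounds.

    Significant targets (pval < psig) are ranked ascending by p-value, ties
    broken by larger k then target id; gene and chem scores follow the
    model described in the module docstring.
    """
    if not active_compounds:
        raise ValueError("active compound set is empty")
    cfg = config or AnalysisConfig()
    kept = filter_links(ct_links, cfg.score_threshold)
    hits: Dict[str, Set[str]] = {}
    for l in kept:
        if l.compound_id in active_compounds:
            hits.setdefault(l.target, set()).add(l.compound_id)
    n = len(active_compounds)
    log = math.log10 if cfg.log_base in (10, 10.0) else math.log

    raw: List[Tuple[str, int, float, float, bool]] = []
    for target, comps in hits.items():
        if target not in background:
            raise ValueError(f"target {target} missing from background")
        p = background[target]
        k = len(comps)
        pv = binomial_tail(k, n, p)
        under = pv <= 0.0
        if under:
            pv = _TINY
        raw.append((target, k, p, pv, under))

    sig = [r for r in raw if r[3] < cfg.psig]
    # ascending p-value; ties: larger k first, then target id
    sig.sort(key=lambda r: (r[3], -r[1], r[0]))
    nonsig = sorted((r for r in raw if r[3] >= cfg.psig), key=lambda r: (r[3], r[0]))

    entries: List[TargetProfileEntry] = []
    for rank, (target, k, p, pv, under) in enumerate(sig, start=1):
        score = -log(pv) / rank
        entries.append(TargetProfileEntry(target, k, n, p, pv, rank, score, under))
    for target, k, p, pv, under in nonsig:
        entries.append(TargetProfileEntry(target, k, n, p, pv, 0, 0.0, under))

    gene_score = {e.target: e.gene_score for e in entries}
    profiled = set(gene_score)
    chem_scores: Dict[str, float] = {}
    per_compound: Dict[str, List[str]] = {c: [] for c in active_compounds}
    for l in kept:
        if l.compound_id in active_compounds and l.target in profiled:
            per_compound[l.compound_id].append(l.target)
    for c, targets in per_compound.items():
        targets = sorted(set(targets))
        chem_scores[c] = (
            sum(gene_score[t] for t in targets) / len(targets) if targets else 0.0
        )

    return FormulaProfile(
        entries=entries,
        chem_scores=chem_scores,
        psig=cfg.psig,
        score_threshold=cfg.score_threshold,
        log_base=cfg.log_base,
    )


def core_targets(profile: FormulaProfile) -> List[Tuple[str, float]]:
    """Targets with positive gene score, best first.

    Sorted by gene score descending, ties by p-value ascending then target
    id; empty when nothing reaches significance.
    """
    by_target = {e.target: e for e in profile.entries}
    hits = [e for e in profile.entries if e.gene_score > 0]
    hits.sort(key=lambda e: (-e.gene_score, e.pval, e.target))
    return [(e.target, e.gene_score) for e in hits]
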