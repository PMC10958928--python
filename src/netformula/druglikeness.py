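"""Drug-likeness screening: QED, Lipinski rule-of-five, Veber rule.

QED (quantitative estimate of drug-likeness) is the weighted geometric mean
of eight desirability functions — asymmetric double sigmoids (ADS) fitted by
Bickerton et al. to the descriptor distributions of approved oral drugs —
evaluated on molecular weight, ALOGP, H-bond acceptors/donors, polar surface
area, rotatable bonds, aromatic rings and structural alerts. The default
weight vector is the mean-weight scheme (QEDw,mo).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .config import AnalysisConfig
from .datamodel import DESCRIPTOR_NAMES, CompoundRecord

__all__ = [
    "ADS_PARAMS",
    "MEAN_WEIGHTS",
    "ads",
    "qed",
    "lipinski_violations",
    "veber_violations",
    "screen",
    "DruglikenessResult",
]

#: Published ADS parameters (A, B, C, D, E, F, DMAX) per descriptor.
ADS_PARAMS: Dict[str, Tuple[float, ...]] = {
    "MW": (2.817065973, 392.5754953, 290.7489764, 2.419764353, 49.22325677, 65.37051707, 104.9805561),
    "ALOGP": (3.172690585, 137.8624751, 2.534937431, 4.581497897, 0.822739154, 0.576295591, 131.3186604),
    "HBA": (2.948620388, 160.4605972, 3.615294657, 4.435986202, 0.290141953, 1.300669958, 148.7763046),
    "HBD": (1.618662227, 1010.051101, 0.985094388, 0.000000001, 0.713820843, 0.920922555, 258.1632616),
    "PSA": (1.876861559, 125.2232657, 62.90773554, 87.83366614, 12.01999824, 28.51324732, 104.5686167),
    "ROTB": (0.01, 272.4121427, 2.55837997, 1.565547684, 1.271567166, 2.758063707, 105.4420403),
    "AROM": (3.21778897, 957.7374108, 2.274627939, 0.000000001, 1.317690384, 0.375760881, 312.337261),
    "ALERTS": (0.01, 1199.094025, -0.09002883, 0.000000001, 0.185904477, 0.875193782, 417.725314),
}

#: Mean-weight scheme (QEDw,mo), same descriptor order as DESCRIPTOR_NAMES.
MEAN_WEIGHTS: Tuple[float, ...] = (0.66, 0.46, 0.05, 0.61, 0.06, 0.65, 0.48, 0.95)

#: Desirability floor before taking logs, avoiding -inf at extreme inputs.
DESIRABILITY_FLOOR = 1e-6


def ads(x: float, params: Tuple[float, ...]) -> float:
    """Asymmetric double sigmoid desirability, normalized to its maximum."""
    a, b, c, d, e, f, dmax = params
    s1 = 1.0 + math.exp(-(x - c + d / 2.0) / e)
    s2 = 1.0 + math.exp(-(x - c - d / 2.0) / f)
    return (a + b / s1 * (1.0 - 1.0 / s2)) / dmax


def qed(
    descriptors: Sequence[float],
    weights: Optional[Sequence[float]] = None,
) -> float:
    """QED of a descriptor vector (MW, ALOGP, HBA, HBD, PSA, ROTB, AROM,
    ALERTS).

    QED = exp( sum_i w_i * ln d_i(x_i) / sum_i w_i ) with the ADS
    desirabilities floored at a small positive epsilon before the log.
    Returns a value in [0, 1]; 1 is maximally drug-like.
    """
    if len(descriptors) != 8:
        raise ValueError(f"expected 8 descriptors, got {len(descriptors)}")
    w = tuple(weights) if weights is not None else MEAN_WEIGHTS
    if len(w) != 8:
        raise ValueError(f"expected 8 weights, got {len(w)}")
    mw = descriptors[0]
    if mw <= 0:
        raise ValueError(f"MW must be positive, got {mw}")
    for name, x in zip(DESCRIPTOR_NAMES[2:], descriptors[2:]):
        if x < 0:
            raise ValueError(f"{name} must be non-negative, got {x}")
    total = 0.0
    for name, x, wi in zip(DESCRIPTOR_NAMES, descriptors, w):
        d = max(ads(float(x), ADS_PARAMS[name]), DESIRABILITY_FLOOR)
        total += wi * math.log(d)
    return math.exp(total / sum(w))


def lipinski_violations(MW: float, ALOGP: float, HBD: float, HBA: float) -> int:
    """Count rule-of-five violations (0-4); boundaries pass inclusively.

    Violations: HBD > 5, HBA > 10, MW > 500, ALOGP > 5.
    """
    return sum([HBD > 5, HBA > 10, MW > 500, ALOGP > 5])


def veber_violations(ROTB: float, PSA: float, HBD: float, HBA: float) -> int:
    """Count Veber-rule violations (0-2).

    The second criterion is a disjunction: it fails only when PSA > 140 AND
    HBD + HBA > 12.
    """
    return sum([ROTB > 10, PSA > 140 and HBD + HBA > 12])


@dataclass(frozen=True)
class DruglikenessResult:
    compound_id: str
    qed: float
    lipinski_violations: int
    veber_violations: int
    passed: bool


def screen(
    compounds: Sequence[CompoundRecord],
    config: Optional[AnalysisConfig] = None,
) -> List[DruglikenessResult]:
    """Screen compounds by QED, Lipinski and Veber thresholds.

    A compound passes when qed >= qed_min AND lipinski violations <= max AND
    veber violations <= max. Results are sorted by QED descending, ties by
    compound id. An empty pass-set is a valid outcome.
    """
    if not compounds:
        raise ValueError("no compounds to screen")
    cfg = config or AnalysisConfig()
    out: List[DruglikenessResult] = []
    for rec in compounds:
        q = qed(rec.descriptors)
        lip = lipinski_violations(rec.MW, rec.ALOGP, rec.HBD, rec.HBA)
        veb = veber_violations(rec.ROTB, rec.PSA, rec.HBD, rec.HBA)
        passed = (
            q >= cfg.qed_min
            and lip <= cfg.lipinski_max_violations
            and veb <= cfg.veber_max_violations
        )
        out.append(DruglikenessResult(rec.compound_id, q, lip, veb, passed))
    out.sort(key=lambda r: (-r.qed, r.compound_id))
    return out
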