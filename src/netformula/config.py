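"""Analysis configuration shared across modules.

A single dataclass carries every tunable threshold so that CLI flags, YAML
config files and library calls resolve to one validated object.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Tunable parameters for every analysis stage.

    Parameters
    ----------
    qed_min:
        Minimum QED for a compound to pass drug-likeness screening.
    lipinski_max_violations, veber_max_violations:
        Maximum allowed rule violations (the conventional reading is
        "no more than one violation" for each rule).
    score_threshold:
        Minimum compound-target association score (0-1000 scale) for a link
        to count; 400 is the medium-confidence convention. The sentinel 9999
        (curated link without a score) always passes.
    psig:
        Significance threshold on the binomial tail P(X >= k) below which a
        target is called core.
    log_base:
        Base of the logarithm in the gene score numerator (10 or ``math.e``).
    top_n:
        Depth of the shared-term co-association curve.
    beta:
        Walk-attenuation coefficient of the KATZ score.
    max_path_len:
        Longest walk length counted by the KATZ score.
    n_perm:
        Number of random set pairs in the permutation nulls.
    seed:
        Seed for every source of randomness.
    s_min:
        Minimum support S_alpha for a mined core formula.
    alpha:
        Confidence level defining support (fraction of the formula that must
        be present in a prescription for it to count as supporting).
    min_herbs:
        Minimum size of a reported core formula.
    desired_herbs, enforce_size:
        Optional exact-size constraint on mined formulas.
    merge, merge_method, merge_threshold:
        Whether and how to merge highly similar core formulas ("Together"
        merges similarity components collectively; "Step" merges the most
        similar pair at a time).
    person_stats:
        Whether to attach patient-level support to mined formulas.
    """

    qed_min: float = 0.3
    lipinski_max_violations: int = 1
    veber_max_violations: int = 1
    score_threshold: int = 400
    psig: float = 0.05
    log_base: float = 10.0
    top_n: int = 30
    beta: float = 0.001
    max_path_len: int = 3
    n_perm: int = 1000
    seed: int = 0
    s_min: float = 0.1
    alpha: float = 0.9
    min_herbs: int = 3
    desired_herbs: Optional[int] = None
    enforce_size: bool = False
    merge: bool = False
    merge_method: str = "Together"
    merge_threshold: float = 0.6
    person_stats: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.psig < 1.0):
            raise ValueError(f"psig must lie in (0, 1), got {self.psig}")
        if not (0.0 <= self.s_min <= 1.0):
            raise ValueError(f"s_min must lie in [0, 1], got {self.s_min}")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if not (0.0 <= self.merge_threshold <= 1.0):
            raise ValueError(
                f"merge_threshold must lie in [0, 1], got {self.merge_threshold}"
            )
        if self.n_perm < 1:
            raise ValueError(f"n_perm must be >= 1, got {self.n_perm}")
        if self.log_base not in (10, 10.0) and not math.isclose(
            self.log_base, math.e
        ):
            raise ValueError("log_base must be 10 or e")
        if self.min_herbs < 2:
            raise ValueError(f"min_herbs must be >= 2, got {self.min_herbs}")
        if self.merge_method not in ("Together", "Step"):
            raise ValueError(
                f"merge_method must be 'Together' or 'Step', got {self.merge_method!r}"
            )

    def replace(self, **kwargs) -> "AnalysisConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
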