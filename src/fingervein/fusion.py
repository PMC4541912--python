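"""Score-level fusion of several Hamming matching distances.

When several probe images of the same finger are matched against one
enrolled template, the per-comparison distances d_i are combined into one
decision score before thresholding:

    SUM rule:     d_S = Σ_i d_i          (range [0, N])
    PRODUCT rule: d_P = Π_i d_i          (range [0, 1])

The sum is left unnormalized; thresholds are swept per rule during
evaluation, so the scale is immaterial. Note the PRODUCT rule skews the
authentic score distribution away from Gaussian, which makes d-prime an
unreliable accuracy proxy for it (the evaluation module warns about this).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .errors import ContractError, ValidationError


class FusionRule(str, enum.Enum):
    SUM = "sum"
    PRODUCT = "product"


@dataclass(frozen=True)
class FusedScore:
    """A fused decision score plus the rule and score count that produced it."""

    value: float
    rule: FusionRule
    n_scores: int

    def __post_init__(self) -> None:
        upper = self.n_scores if self.rule is FusionRule.SUM else 1.0
        if not 0.0 <= self.value <= upper + 1e-12:
            raise ValidationError(
                f"{self.rule.value} of {self.n_scores} scores must lie in [0, {upper}]"
            )


def fuse(scores, rule: FusionRule | str) -> FusedScore:
    """Combine matching distances in [0, 1] with the SUM or PRODUCT rule."""
    rule = FusionRule(rule)
    values = [s.hd if hasattr(s, "hd") else float(s) for s in scores]
    if len(values) == 0:
        raise ContractError("cannot fuse an empty score list")
    for v in values:
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"matching score {v} outside [0, 1]")
    value = math.fsum(values) if rule is FusionRule.SUM else float(np.prod(values))
    return FusedScore(value, rule, len(values))


def fuse_matrix(score_matrix: np.ndarray, rule: FusionRule | str, axis: int = -1) -> np.ndarray:
    """Vectorized fusion along ``axis`` of an array of distances in [0, 1]."""
    rule = FusionRule(rule)
    arr = np.asarray(score_matrix, dtype=np.float64)
    if arr.size == 0:
        raise ContractError("cannot fuse an empty score array")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValidationError("matching scores must lie in [0, 1]")
    return arr.sum(axis=axis) if rule is FusionRule.SUM else arr.prod(axis=axis)
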