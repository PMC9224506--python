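"""Probabilistic applicability domain via the statistical SMILES defect.

The domain of a trained model is defined by how well a molecule's features
are represented in the two subsets that shaped the model: the active
training set (weights) and the calibration set (overtraining control).
For each non-blocked feature S_k,

    d_k = |P(S_k) − P'(S_k)| / (N(S_k) + N'(S_k))

where P, N (P', N') are the probability and frequency of the feature among
active-training (calibration) compounds — probability and frequency both
counted at the compound level (a compound contributes once however many
times it contains the feature).  A feature absent from both sets has
maximal defect 1.  The molecule's defect is the sum of d_k over its
distinct non-blocked features, and a prediction is considered reliable when

    defect < 2·D̄

with D̄ the mean defect over active-training compounds.  A molecule whose
defect is exactly 0 (every feature perfectly balanced between the two sets)
is in-domain unconditionally; this covers the degenerate threshold D̄ = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .attributes import AttributeKey, AttributeSet

__all__ = [
    "ADStatistics",
    "build_ad_statistics",
    "attribute_defect",
    "smiles_defect",
    "in_domain",
]


@dataclass
class ADStatistics:
    """Feature-distribution statistics backing the applicability domain."""

    p_active: dict[AttributeKey, float]
    p_calib: dict[AttributeKey, float]
    n_active: dict[AttributeKey, int]
    n_calib: dict[AttributeKey, int]
    d_bar: float
    threshold: float  # always exactly 2 * d_bar


def _presence_counts(attr_sets: Sequence[AttributeSet]) -> dict[AttributeKey, int]:
    counts: dict[AttributeKey, int] = {}
    for attrs in attr_sets:
        for key in attrs.counts:
            counts[key] = counts.get(key, 0) + 1
    return counts


def attribute_defect(key: AttributeKey, stats: ADStatistics) -> float:
    """Defect of one feature; 1 for a feature unseen in both reference sets."""
    n = stats.n_active.get(key, 0)
    np_ = stats.n_calib.get(key, 0)
    if n == 0 and np_ == 0:
        return 1.0
    p = stats.p_active.get(key, 0.0)
    pp = stats.p_calib.get(key, 0.0)
    return abs(p - pp) / (n + np_)


def smiles_defect(
    attrs: AttributeSet, stats: ADStatistics, blocked: frozenset | set = frozenset()
) -> float:
    """Sum of attribute defects over the molecule's distinct non-blocked features."""
    return sum(
        attribute_defect(key, stats) for key in attrs.counts if key not in blocked
    )


def in_domain(
    attrs: AttributeSet, stats: ADStatistics, blocked: frozenset | set = frozenset()
) -> bool:
    """Reliability criterion: defect strictly below 2·D̄ (0-defect always inside)."""
    defect = smiles_defect(attrs, stats, blocked)
    if defect == 0.0:
        return True
    return defect < stats.threshold


def build_ad_statistics(
    active_attrs: Sequence[AttributeSet],
    calib_attrs: Sequence[AttributeSet],
    blocked: frozenset | set = frozenset(),
) -> ADStatistics:
    """Build the AD statistics from active-training and calibration features."""
    if not active_attrs or not calib_attrs:
        raise ValueError("both active-training and calibration sets must be non-empty")
    n_active = _presence_counts(active_attrs)
    n_calib = _presence_counts(calib_attrs)
    na, nc = len(active_attrs), len(calib_attrs)
    stats = ADStatistics(
        p_active={k: v / na for k, v in n_active.items()},
        p_calib={k: v / nc for k, v in n_calib.items()},
        n_active=n_active,
        n_calib=n_calib,
        d_bar=0.0,
        threshold=0.0,
    )
    defects = [smiles_defect(attrs, stats, blocked) for attrs in active_attrs]
    stats.d_bar = sum(defects) / len(defects)
    stats.threshold = 2.0 * stats.d_bar
    return stats
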