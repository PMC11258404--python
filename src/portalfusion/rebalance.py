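"""Class-rebalancing strategies applied during training.

Three strategies counter the skewed label distribution typical of
triage corpora (one dominant class, several small ones):

* ``class_weight`` — per-example loss scaling by the inverse-frequency
  weight of the true class (weighted empirical risk),
* ``oversample``   — random oversampling of minority classes up to the
  majority count, inside the training split only,
* ``focal``        — focal loss ``-alpha * (1-p)^gamma * ln(p)``, which
  down-weights well-classified examples so the optimizer concentrates
  on hard ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "RebalanceSpec",
    "inverse_frequency_weights",
    "oversample",
    "focal_loss",
]

_STRATEGIES = ("class_weight", "oversample", "focal", "none")


@dataclass(frozen=True)
class RebalanceSpec:
    """Which rebalancing strategy to apply, with its parameters.

    ``alpha`` is either the string ``"inverse_frequency"`` (weights
    derived from the training-fold class counts) or an explicit
    per-class weight mapping.  ``gamma`` is the focal-loss focusing
    exponent (0 recovers plain cross-entropy).
    """

    strategy: str = "none"
    gamma: float = 2.0
    alpha: str | Mapping[str, float] = "inverse_frequency"

    def __post_init__(self) -> None:
        if self.strategy not in _STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; expected one of {_STRATEGIES}"
            )
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not isinstance(self.alpha, str):
            bad = {c: w for c, w in self.alpha.items() if w <= 0}
            if bad:
                raise ValueError(f"alpha weights must be positive, got {bad}")

    def class_weights(self, counts: Mapping[str, int]) -> dict[str, float]:
        """Resolve alpha to concrete per-class weights for given counts."""
        if isinstance(self.alpha, str):
            if self.alpha != "inverse_frequency":
                raise ValueError(f"unknown alpha spec {self.alpha!r}")
            return inverse_frequency_weights(counts)
        return dict(self.alpha)


def inverse_frequency_weights(counts: Mapping[str, int]) -> dict[str, float]:
    """Balanced class weights ``w_c = N / (K * n_c)``.

    N is the total count and K the number of classes, so the weighted
    class masses satisfy ``sum_c w_c * n_c = N`` and equal counts give
    all-ones.
    """
    zero = [c for c, n in counts.items() if n <= 0]
    if zero:
        raise ValueError(f"classes with zero count: {zero}")
    total = sum(counts.values())
    k = len(counts)
    return {c: total / (k * n) for c, n in counts.items()}


def oversample(
    ids: Sequence[str], labels: Sequence[str], seed: int = 0
) -> list[str]:
    """Random oversampling: equalize every class count to the majority's.

    All original ids are retained; added items are duplicates of
    existing ids of the same class, drawn uniformly with replacement
    from a generator seeded with ``seed``.  Returns the resampled id
    multiset (originals first, in input order).
    """
    if len(ids) == 0:
        raise ValueError("cannot oversample an empty input")
    if len(ids) != len(labels):
        raise ValueError("ids and labels must be aligned")
    by_class: dict[str, list[str]] = {}
    for i, lab in zip(ids, labels):
        by_class.setdefault(lab, []).append(i)
    majority = max(len(v) for v in by_class.values())
    rng = np.random.default_rng(seed)
    out = list(ids)
    for lab in sorted(by_class):  # fixed class order for determinism
        pool = by_class[lab]
        deficit = majority - len(pool)
        if deficit > 0:
            picks = rng.integers(0, len(pool), size=deficit)
            out.extend(pool[p] for p in picks)
    return out


def focal_loss(p_true: float, gamma: float = 2.0, alpha_c: float = 1.0) -> float:
    """Focal loss ``-alpha_c * (1 - p_true)^gamma * ln(p_true)``.

    ``p_true`` is the predicted probability of the true class.  With
    ``gamma=0, alpha_c=1`` this is exactly cross-entropy ``-ln(p)``;
    it is 0 at ``p_true == 1``.  Probabilities must be clamped to
    ``(0, 1]`` by the caller; ``p_true <= 0`` is an error.
    """
    if p_true <= 0:
        raise ValueError(f"p_true must be in (0, 1], got {p_true}")
    return -alpha_c * (1.0 - p_true) ** gamma * math.log(p_true)
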