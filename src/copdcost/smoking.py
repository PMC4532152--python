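"""Smoking-category machinery shared by the simulator and the projection model.

Four categories are tracked: active smokers and three ex-smoker groups by
time since quitting. Quitters are down-weighted when counting "smoker
equivalents" (active and 1-3y quitters count fully, 3-5y quitters 0.75,
5-10y quitters 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

SMOKING_CATEGORIES: tuple[str, ...] = ("active", "quit_1_3", "quit_3_5", "quit_5_10")


@dataclass(frozen=True, slots=True)
class SmokingWeights:
    """Weights turning category headcounts into smoker equivalents."""

    active: float = 1.0
    quit_1_3: float = 1.0
    quit_3_5: float = 0.75
    quit_5_10: float = 0.5

    def __post_init__(self) -> None:
        for cat in SMOKING_CATEGORIES:
            w = getattr(self, cat)
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"weight {cat} must be in [0, 1], got {w}")
            if w > self.active:
                raise ValueError(f"weight {cat}={w} exceeds active weight {self.active}")

    def as_dict(self) -> dict[str, float]:
        return {cat: getattr(self, cat) for cat in SMOKING_CATEGORIES}


DEFAULT_WEIGHTS = SmokingWeights()


def weighted_prevalence(fractions: Mapping[str, float], weights: SmokingWeights = DEFAULT_WEIGHTS) -> float:
    """Weighted sum of category fractions (the per-head equivalent factor)."""
    return sum(float(fractions.get(cat, 0.0)) * getattr(weights, cat) for cat in SMOKING_CATEGORIES)


def cap_fractions(fractions: Mapping[str, float]) -> dict[str, float]:
    """Clamp each category fraction to [0, 1] and cap the four-category sum at 1.

    Any excess above 1 is truncated from the largest category; ties broken
    deterministically by canonical category order.
    """
    capped = {cat: min(1.0, max(0.0, float(fractions.get(cat, 0.0)))) for cat in SMOKING_CATEGORIES}
    # greedy: shave the largest category (repeatedly, if one cannot absorb it all)
    while (excess := sum(capped.values()) - 1.0) > 0.0:
        largest = max(SMOKING_CATEGORIES, key=lambda c: capped[c])
        take = min(excess, capped[largest])
        if take <= 0.0:
            break
        capped[largest] -= take
    return capped
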