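"""Turning a ranked uncertainty list into a training subset, and what it costs.

The selection recipe: drop the top 10% of the descending-ranked list
(outliers — committee disagrees wildly) and the bottom 10% (samples so
easy they carry no training value), then draw a uniform random subset
sized as a fraction of the FULL pool from what remains. Annotation-cost
accounting bounds how much labeling the recipe saves: with a labeled
seed fraction s and a selection budget b, the labeled data actually
needed is the union of the two sets, between max(s, b) (full overlap)
and min(1, s + b) (disjoint), so the saving lies between 1 - (s + b) and
1 - max(s, b). At s = b = 0.30 that is the 40–70% band (mean 55%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .scoring import RankedScoreList


def proportion_to_count(fraction: float, total: int) -> int:
    """Number of samples a pool fraction corresponds to (round half up)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError(f"fraction must be in [0, 1], got {fraction}")
    if total < 1:
        raise ValidationError(f"total must be a positive integer, got {total}")
    return int(math.floor(round(fraction * total, 9) + 0.5))


def _boundary(fraction: float, n: int) -> int:
    # round before floor so 0.29 * 100 lands on 29, not 28
    return int(math.floor(round(fraction * n, 9)))


@dataclass(frozen=True)
class RangeSpec:
    """A slice of the descending-ranked list; 0 is the most-uncertain end."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo < self.hi <= 1.0):
            raise ValidationError(f"invalid range [{self.lo}, {self.hi}): need 0 <= lo < hi <= 1")

    @property
    def width(self) -> float:
        return self.hi - self.lo


@dataclass(frozen=True)
class SelectionPlan:
    """Extreme exclusion plus budget sampling parameters."""

    exclude_top: float = 0.10
    exclude_bottom: float = 0.10
    budget: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.exclude_top < 1.0 and 0.0 <= self.exclude_bottom < 1.0):
            raise ValidationError("exclusion fractions must be in [0, 1)")
        if self.exclude_top + self.exclude_bottom >= 1.0:
            raise ValidationError(
                f"exclusions overlap: {self.exclude_top} + {self.exclude_bottom} >= 1"
            )
        if not 0.0 <= self.budget <= 1.0 - self.exclude_top - self.exclude_bottom:
            raise ValidationError(
                f"budget {self.budget} exceeds retained fraction "
                f"{1.0 - self.exclude_top - self.exclude_bottom:.3f}"
            )


@dataclass(frozen=True)
class CostReport:
    """Annotation-cost bounds implied by a seed fraction and a budget."""

    labeled_fraction: float
    budget_fraction: float
    min_needed: float
    max_needed: float
    min_saving: float
    max_saving: float
    mean_saving: float
    actual_needed: float | None = None

    def __str__(self) -> str:  # CLI-facing summary
        lines = [
            f"labeled seed fraction : {self.labeled_fraction:.0%}",
            f"selection budget      : {self.budget_fraction:.0%}",
            f"labels needed         : {self.min_needed:.0%} – {self.max_needed:.0%}",
            f"annotation saving     : {self.min_saving:.0%} – {self.max_saving:.0%} (mean {self.mean_saving:.0%})",
        ]
        if self.actual_needed is not None:
            lines.append(f"actually needed       : {self.actual_needed:.0%}")
        return "\n".join(lines)


def select_range(ranked: RankedScoreList, range_spec: RangeSpec) -> list[str]:
    """Ids at ranked positions [floor(lo*N), floor(hi*N)) in rank order."""
    n = len(ranked)
    if n == 0:
        raise ValidationError("select_range: empty ranking")
    start, stop = _boundary(range_spec.lo, n), _boundary(range_spec.hi, n)
    if stop <= start:
        raise ValidationError(
            f"range [{range_spec.lo}, {range_spec.hi}) selects no samples from a list of {n}"
        )
    return ranked.sample_ids[start:stop]


def exclude_extremes(ranked: RankedScoreList, exclude_top: float = 0.10,
                     exclude_bottom: float = 0.10) -> list[str]:
    """Drop the most- and least-uncertain tails; keep the informative middle."""
    if not (0.0 <= exclude_top < 1.0 and 0.0 <= exclude_bottom < 1.0):
        raise ValidationError("exclusion fractions must be in [0, 1)")
    if exclude_top + exclude_bottom >= 1.0:
        raise ValidationError(f"exclusions overlap: {exclude_top} + {exclude_bottom} >= 1")
    return select_range(ranked, RangeSpec(exclude_top, 1.0 - exclude_bottom))


def sample_budget(retained_ids: Sequence[str], pool_size: int, budget: float, seed: int) -> list[str]:
    """Uniform subset of the retained ids sized as a fraction of the FULL pool."""
    count = proportion_to_count(budget, pool_size)
    if count > len(retained_ids):
        raise ValidationError(
            f"budget {budget} of pool {pool_size} needs {count} samples "
            f"but only {len(retained_ids)} were retained"
        )
    if count == 0:
        return []
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(retained_ids), size=count, replace=False)
    chosen.sort()  # keep rank order for readability; set content is what matters
    return [retained_ids[i] for i in chosen]


def random_baseline(pool_ids: Sequence[str], budget: float, seed: int) -> list[str]:
    """Uniform subset of the full pool, no exclusions (the comparison arm)."""
    if not pool_ids:
        raise ValidationError("random_baseline: empty pool")
    if not 0.0 < budget <= 1.0:
        raise ValidationError(f"budget must be in (0, 1], got {budget}")
    count = proportion_to_count(budget, len(pool_ids))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool_ids), size=count, replace=False)
    chosen.sort()
    return [pool_ids[i] for i in chosen]


def annotation_cost(
    labeled_fraction: float,
    budget_fraction: float,
    initially_labeled_ids: Sequence[str] | None = None,
    selected_ids: Sequence[str] | None = None,
    pool_size: int | None = None,
) -> CostReport:
    """Bound (and, with id sets, measure) the labeling the recipe requires.

    The saving band follows from set arithmetic on the seed and selected
    subsets; ``actual_needed`` is the measured union size when both id
    sets are known.
    """
    for name, f in (("labeled_fraction", labeled_fraction), ("budget_fraction", budget_fraction)):
        if not 0.0 < f <= 1.0:
            raise ValidationError(f"{name} must be in (0, 1], got {f}")
    min_needed = max(labeled_fraction, budget_fraction)
    max_needed = min(1.0, labeled_fraction + budget_fraction)
    min_saving = 1.0 - max_needed
    max_saving = 1.0 - min_needed
    actual = None
    if initially_labeled_ids is not None or selected_ids is not None:
        if initially_labeled_ids is None or selected_ids is None or pool_size is None:
            raise ValidationError("actual cost needs both id sets and pool_size")
        union = set(initially_labeled_ids) | set(selected_ids)
        actual = len(union) / pool_size
        if not (min_needed - 1e-9 <= actual <= max_needed + 1e-9):
            raise ValidationError(
                f"measured union fraction {actual:.4f} outside bounds [{min_needed:.4f}, {max_needed:.4f}]"
            )
    return CostReport(
        labeled_fraction=labeled_fraction,
        budget_fraction=budget_fraction,
        min_needed=min_needed,
        max_needed=max_needed,
        min_saving=min_saving,
        max_saving=max_saving,
        mean_saving=(min_saving + max_saving) / 2.0,
        actual_needed=actual,
    )
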