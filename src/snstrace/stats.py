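"""Shared statistics and phenotype classifiers.

Wilson score intervals for binomial proportions (the interval used on all
methylation summaries), the flowering-time category partition used for FWA
silencing read-outs, and simple category tallies.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import norm


@dataclass(frozen=True)
class ProportionCI:
    m: int
    n: int
    level: float
    low: float
    high: float

    @property
    def proportion(self) -> float:
        return self.m / self.n


def wilson_interval(m: int, n: int, level: float = 0.95) -> ProportionCI:
    """Wilson score interval for a binomial proportion.

    center = (p + z^2/2n) / (1 + z^2/n),
    half-width = z * sqrt(p(1-p)/n + z^2/4n^2) / (1 + z^2/n),
    with p = m/n and z the standard-normal quantile for the two-sided level.
    The plain score form, no continuity correction; unlike the Wald interval
    it stays inside [0, 1] and behaves sensibly at m = 0 and m = n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= m <= n:
        raise ValueError(f"m must be in [0, n], got m={m}, n={n}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = norm.ppf(0.5 + level / 2)
    p = m / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * ((p * (1 - p) / n + z * z / (4 * n * n)) ** 0.5) / denom
    # endpoints are exact at the boundaries; avoid float residue
    low = 0.0 if m == 0 else max(0.0, center - half)
    high = 1.0 if m == n else min(1.0, center + half)
    return ProportionCI(m=m, n=n, level=level, low=low, high=high)


# Flowering-time partition: leaf count at bolting.
EARLY_MAX = 16
LATE_MIN = 23

CATEGORIES = ("early", "intermediate", "late")


@dataclass(frozen=True)
class FloweringRecord:
    plant_id: str
    leaf_count: int

    @property
    def category(self) -> str:
        return classify_flowering(self.leaf_count)


def classify_flowering(leaf_count: int) -> str:
    """Sort a plant into early (<=16 leaves), intermediate (17-22) or late (>=23).

    Rosette leaf number at bolting is a proxy for flowering time: ectopic FWA
    expression delays flowering, so heritable re-silencing of FWA shows up as
    a shift toward the early category in the progeny.
    """
    if not isinstance(leaf_count, int) or isinstance(leaf_count, bool):
        raise TypeError(f"leaf_count must be an integer, got {leaf_count!r}")
    if leaf_count < 1:
        raise ValueError(f"leaf_count must be >= 1, got {leaf_count}")
    if leaf_count <= EARLY_MAX:
        return "early"
    if leaf_count < LATE_MIN:
        return "intermediate"
    return "late"


def category_proportions(records: list[FloweringRecord] | list[str]) -> pd.DataFrame:
    """Tally category counts and fractions; fractions sum to 1.

    Accepts FloweringRecords (classified from leaf counts) or bare category
    labels (e.g. visually scored silencing categories).
    """
    if not records:
        raise ValueError("no records")
    labels = [
        r.category if isinstance(r, FloweringRecord) else str(r) for r in records
    ]
    order = list(dict.fromkeys(CATEGORIES)) + sorted(
        set(labels) - set(CATEGORIES)
    )
    counts = {lab: labels.count(lab) for lab in order if lab in labels or lab in CATEGORIES}
    n = len(labels)
    return pd.DataFrame(
        [(lab, c, c / n) for lab, c in counts.items()],
        columns=["category", "count", "fraction"],
    )
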