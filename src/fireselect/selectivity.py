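"""Jacobs' selectivity index and per-ownership distribution summaries.

For each footprint and each ownership class available to it, the Jacobs'
index

    D = (o - pi) / (o + pi - 2 * o * pi)

compares the used proportion ``o`` against the available proportion ``pi``:
D = -1 is perfect avoidance (the class is available but none of it burned),
D = 0 indifference (burned in proportion to availability) and D = +1 perfect
preference (the burn confined entirely to the class while more was
available). An ownership is associated with a footprint whenever it occurs
in the footprint's available area (pi > 0), so per-ownership sample sizes
differ across classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import binom

from .classification import FireTypeLabel
from .geometry import ProportionTable

__all__ = [
    "SelectivityRecord",
    "SelectivitySummary",
    "jacobs_index",
    "build_selectivity_table",
    "summarize_selectivity",
    "median_ci",
]


@dataclass(frozen=True)
class SelectivityRecord:
    footprint_id: str
    owner_class: str
    fire_type: str
    o: float
    pi: float
    jacobs: float


@dataclass(frozen=True)
class SelectivitySummary:
    owner_class: str
    fire_type: str
    n: int
    median: float
    q1: float
    q3: float
    median_ci_low: float
    median_ci_high: float
    display: bool


def jacobs_index(o: float, pi: float) -> float:
    """Jacobs' selectivity index D = (o - pi)/(o + pi - 2*o*pi).

    Defined for used proportion ``0 <= o <= 1`` and available proportion
    ``0 < pi <= 1``. Returns 0 when o == pi, including the degenerate
    o = pi = 1 case where the expression is 0/0: a class filling both the
    used and the available area carries no selectivity information.
    """
    if not (0.0 <= o <= 1.0):
        raise ValueError(f"used proportion o={o} outside [0, 1]")
    if not (0.0 < pi <= 1.0):
        raise ValueError(f"available proportion pi={pi} outside (0, 1]")
    if o == pi:
        return 0.0
    if o == 0.0:  # (0 - pi)/(pi) exactly
        return -1.0
    if o == 1.0:  # (1 - pi)/(1 - pi) exactly
        return 1.0
    denom = o + pi - 2.0 * o * pi
    d = (o - pi) / denom
    return min(1.0, max(-1.0, d))  # clamp float round-off at the extremes


def build_selectivity_table(
    proportions: Iterable[ProportionTable],
    labels: Sequence[FireTypeLabel] | Mapping[str, str],
) -> list[SelectivityRecord]:
    """One record per (footprint, ownership class available to it).

    ``labels`` maps footprint ids to fire types; footprints without a label
    (unclassifiable) are skipped.
    """
    if not isinstance(labels, Mapping):
        labels = {lab.footprint_id: lab.fire_type for lab in labels}
    records: list[SelectivityRecord] = []
    for tab in proportions:
        fire_type = labels.get(tab.footprint_id)
        if fire_type is None:
            continue
        for owner_class, o, pi in tab.rows:
            if pi <= 0.0:
                continue
            records.append(
                SelectivityRecord(
                    footprint_id=tab.footprint_id,
                    owner_class=owner_class,
                    fire_type=fire_type,
                    o=float(o),
                    pi=float(pi),
                    jacobs=jacobs_index(float(o), float(pi)),
                )
            )
    return records


def median_ci(values: np.ndarray, confidence: float = 0.95) -> tuple[float, float]:
    """Distribution-free CI for the median from binomial order statistics.

    Uses the largest k with P(X < k) <= (1-confidence)/2 for
    X ~ Binomial(n, 1/2); the interval is [x_(k), x_(n+1-k)]. Falls back to
    the sample range when n is too small for the nominal level.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    alpha = 1.0 - confidence
    # largest k such that cdf(k-1) <= alpha/2, i.e. P(X < k) <= alpha/2
    k = int(binom.ppf(alpha / 2.0, n, 0.5))
    if binom.cdf(k - 1, n, 0.5) > alpha / 2.0:
        k -= 1
    if k < 1:
        return float(x[0]), float(x[-1])
    # order statistics k and n+1-k (1-based): coverage 1 - 2*cdf(k-1) >= conf
    return float(x[k - 1]), float(x[n - k])


def summarize_selectivity(
    records: Sequence[SelectivityRecord],
    display_min_n: int = 25,
) -> list[SelectivitySummary]:
    """Median, quartiles and 95% median CI per (ownership, fire type).

    Quartiles use the linear-interpolation convention. Groups with fewer
    than ``display_min_n`` records are flagged not-for-display; the flag
    affects reporting only, never the statistical test.
    """
    if not records:
        raise ValueError("no records to summarize")
    groups: dict[tuple[str, str], list[float]] = {}
    for r in records:
        groups.setdefault((r.owner_class, r.fire_type), []).append(r.jacobs)
    out: list[SelectivitySummary] = []
    for (owner_class, fire_type), vals in sorted(groups.items()):
        arr = np.asarray(vals, dtype=float)
        q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0])
        lo, hi = median_ci(arr)
        out.append(
            SelectivitySummary(
                owner_class=owner_class,
                fire_type=fire_type,
                n=arr.size,
                median=float(med),
                q1=float(q1),
                q3=float(q3),
                median_ci_low=lo,
                median_ci_high=hi,
                display=arr.size >= display_min_n,
            )
        )
    return out
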