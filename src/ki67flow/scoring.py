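"""Ki-67 scores, median-derived cut-offs and reclassification tables.

A case is scored per method (visual assessment VA, or digital image
analysis DIA) as five positive counts out of 100-cell increments; the
cumulative percentage after k increments is ``100 * sum(n[:k]) /
(100*k)``.  Following the St. Gallen 2015 in-house-median convention,
the cohort median of the 500-cell value defines the cut-offs: Low is
more than 10 percentage points below the median, High more than 10
above, Intermediate in between (boundaries inclusive to Intermediate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

__all__ = [
    "CaseScore",
    "CutoffScheme",
    "TransitionTable",
    "cumulative_percentages",
    "cohort_median",
    "derive_cutoffs",
    "classify_case",
    "transition_table",
    "CATEGORIES",
]

CATEGORIES = ("Low", "Intermediate", "High")


@dataclass
class CaseScore:
    """Per-case, per-method positive counts and cumulative percentages."""

    case_id: str
    method: str  # "VA" | "DIA"
    n_positive: tuple[int, ...]

    def __post_init__(self):
        self.n_positive = tuple(int(n) for n in self.n_positive)
        for n in self.n_positive:
            if not 0 <= n <= 100:
                raise ValueError(
                    f"increment count {n} outside [0, 100]")

    @property
    def cumulative_pct(self) -> tuple[float, ...]:
        return cumulative_percentages(self.n_positive, decimals=None)

    def cumulative_at(self, k: int) -> float:
        """Cumulative percentage after k increments (k in 1..5)."""
        return self.cumulative_pct[k - 1]


def cumulative_percentages(n_positive, decimals: int | None = 1):
    """Cumulative Ki-67 percentages after 1..len(n) increments.

    Exact rational arithmetic; ``decimals`` rounds for reporting
    (``None`` returns unrounded floats).
    """
    counts = [int(n) for n in n_positive]
    for n in counts:
        if not 0 <= n <= 100:
            raise ValueError(f"increment count {n} outside [0, 100]")
    out = []
    total = Fraction(0)
    for k, n in enumerate(counts, start=1):
        total += n
        pct = Fraction(100) * total / (100 * k)
        val = float(pct)
        out.append(round(val, decimals) if decimals is not None else val)
    return tuple(out)


def cohort_median(scores, k: int = 5) -> float:
    """Sample median of the k-increment cumulative percentage."""
    if not scores:
        raise ValueError("no scores")
    vals = [s.cumulative_at(k) for s in scores]
    return float(np.median(vals))


@dataclass(frozen=True)
class CutoffScheme:
    """Median +/- 10 percentage-point Low/Intermediate/High cut-offs."""

    method: str
    median_pct: float
    low_below: float
    high_above: float

    def classify(self, value_pct: float) -> str:
        return classify_case(value_pct, self)


def derive_cutoffs(median_pct: float, method: str = "DIA") -> CutoffScheme:
    """Cut-offs at median - 10 and median + 10 percentage points."""
    if not 10.0 <= median_pct <= 90.0:
        warnings.warn(
            f"median {median_pct:.1f}% outside [10, 90]; cut-offs clipped "
            "to [0, 100] and categories may degenerate", stacklevel=2)
    low = float(np.clip(median_pct - 10.0, 0.0, 100.0))
    high = float(np.clip(median_pct + 10.0, 0.0, 100.0))
    return CutoffScheme(method=method, median_pct=float(median_pct),
                        low_below=low, high_above=high)


def classify_case(value_pct: float, scheme: CutoffScheme) -> str:
    """Low iff value < low cut-off, High iff value > high cut-off."""
    if value_pct < scheme.low_below:
        return "Low"
    if value_pct > scheme.high_above:
        return "High"
    return "Intermediate"


@dataclass
class TransitionTable:
    """3x3 cross-tabulation of categories at two counting depths."""

    counts: pd.DataFrame  # rows: category at k_from; cols: at k_to
    k_from: int
    k_to: int

    @property
    def start_counts(self) -> dict[str, int]:
        return {c: int(self.counts.loc[c].sum()) for c in CATEGORIES}

    @property
    def end_counts(self) -> dict[str, int]:
        return {c: int(self.counts[c].sum()) for c in CATEGORIES}

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @classmethod
    def from_flows(cls, start_counts, flows, k_from: int = 1,
                   k_to: int = 5) -> "TransitionTable":
        """Build from marginal start counts and off-diagonal flows.

        ``start_counts`` maps category -> count at ``k_from``;
        ``flows`` maps (from_category, to_category) -> count.  The
        diagonal is whatever remains of each row.
        """
        m = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES))
        for (a, b), n in flows.items():
            m.loc[a, b] = int(n)
        for c in CATEGORIES:
            moved = int(m.loc[c].sum())
            stay = int(start_counts[c]) - moved
            if stay < 0:
                raise ValueError(
                    f"flows out of {c} exceed its start count")
            m.loc[c, c] = stay
        return cls(counts=m, k_from=k_from, k_to=k_to)


def transition_table(scores, scheme: CutoffScheme, k_from: int = 1,
                     k_to: int = 5) -> TransitionTable:
    """Cross-tabulate case categories at two cumulative depths."""
    m = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES))
    for s in scores:
        a = classify_case(s.cumulative_at(k_from), scheme)
        b = classify_case(s.cumulative_at(k_to), scheme)
        m.loc[a, b] += 1
    return TransitionTable(counts=m, k_from=k_from, k_to=k_to)
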