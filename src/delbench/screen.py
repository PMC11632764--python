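"""Hit calling from DEL sequencing read counts.

Pooled affinity selection of a DEL is read out by counting each
compound's DNA barcode before and after selection.  The normalized fold
number Fn is a conservative enrichment ratio: the lower 95% Poisson
confidence bound on the post-selection read rate divided by the upper
95% bound on the pre-selection rate, both rates normalized by sample
totals.  Compounds with Fn >= 1 are on-DNA hits; alternatively a
minimum-copies rule flags compounds whose raw post-selection read count
reaches a threshold.

Poisson confidence limits are the exact (Garwood) limits from chi-square
quantiles: for k observed events and confidence 1 - alpha,

    lower = chi2.ppf(alpha/2, 2k) / 2        (0 when k = 0)
    upper = chi2.ppf(1 - alpha/2, 2k + 2) / 2
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import chi2

__all__ = [
    "ReadCountRecord",
    "ScreenRecord",
    "normalized_read_count",
    "poisson_ci",
    "compute_fn",
    "classify_hits_fn",
    "classify_hits_readcount",
    "read_counts_csv",
    "write_screen_csv",
]


@dataclass(frozen=True)
class ReadCountRecord:
    """Per-compound sequencing counts in the control and selected samples."""

    compound_id: str
    count_before: int
    count_after: int
    total_before: int
    total_after: int

    def __post_init__(self) -> None:
        if self.total_before <= 0 or self.total_after <= 0:
            raise ValueError(f"{self.compound_id}: sample totals must be positive")
        if not 0 <= self.count_before <= self.total_before:
            raise ValueError(f"{self.compound_id}: count_before out of range")
        if not 0 <= self.count_after <= self.total_after:
            raise ValueError(f"{self.compound_id}: count_after out of range")


@dataclass(frozen=True)
class ScreenRecord:
    """Classified screening result for one compound."""

    compound_id: str
    fn: float | None
    read_count: int | None
    is_hit: bool


def normalized_read_count(count: int, total: int) -> float:
    """Read count divided by the total reads of its sample."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError(f"count {count} out of range [0, {total}]")
    return count / total


def poisson_ci(count: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) two-sided Poisson confidence limits for a count."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    alpha = 1.0 - confidence
    lower = 0.0 if count == 0 else chi2.ppf(alpha / 2, 2 * count) / 2.0
    upper = chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2.0
    return lower, upper


def compute_fn(rec: ReadCountRecord, confidence: float = 0.95) -> float:
    """Normalized fold number: CI lower bound of the after-rate over the
    CI upper bound of the before-rate.

    Zero after-counts give Fn = 0 (the Poisson lower limit at zero
    observations is zero); Fn is monotone non-decreasing in count_after
    and non-increasing in count_before.
    """
    after_lower, _ = poisson_ci(rec.count_after, confidence)
    _, before_upper = poisson_ci(rec.count_before, confidence)
    after_rate = after_lower / rec.total_after
    before_rate = before_upper / rec.total_before
    return float(after_rate / before_rate)


def classify_hits_fn(
    records: Iterable[ReadCountRecord],
    threshold: float = 1.0,
    confidence: float = 0.95,
) -> list[ScreenRecord]:
    """Flag compounds with Fn >= threshold (boundary inclusive) as hits."""
    out = []
    for rec in records:
        fn = compute_fn(rec, confidence)
        out.append(
            ScreenRecord(
                compound_id=rec.compound_id,
                fn=fn,
                read_count=rec.count_after,
                is_hit=bool(fn >= threshold),
            )
        )
    return out


def classify_hits_readcount(
    records: Iterable[ReadCountRecord], min_copies: int
) -> list[ScreenRecord]:
    """Flag compounds whose post-selection read count reaches min_copies."""
    if min_copies < 0:
        raise ValueError("min_copies must be non-negative")
    return [
        ScreenRecord(
            compound_id=rec.compound_id,
            fn=None,
            read_count=rec.count_after,
            is_hit=rec.count_after >= min_copies,
        )
        for rec in records
    ]


def read_counts_csv(path) -> list[ReadCountRecord]:
    """Load compound_id, count_before, count_after (+ optional totals).

    When total columns are absent, totals default to the column sums.
    """
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append(row)
    if not rows:
        return []
    have_totals = "total_before" in rows[0] and "total_after" in rows[0]
    if not have_totals:
        tb = sum(int(r["count_before"]) for r in rows)
        ta = sum(int(r["count_after"]) for r in rows)
    return [
        ReadCountRecord(
            compound_id=r["compound_id"],
            count_before=int(r["count_before"]),
            count_after=int(r["count_after"]),
            total_before=int(r["total_before"]) if have_totals else tb,
            total_after=int(r["total_after"]) if have_totals else ta,
        )
        for r in rows
    ]


def write_screen_csv(records: Sequence[ScreenRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "fn", "read_count", "is_hit"])
        for rec in records:
            w.writerow(
                [
                    rec.compound_id,
                    "" if rec.fn is None else repr(rec.fn),
                    "" if rec.read_count is None else rec.read_count,
                    int(rec.is_hit),
                ]
            )
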