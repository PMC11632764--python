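"""Ranking metrics for virtual-screening recovery of experimental hits.

Compounds are ranked by docking score (lower is better) or by the
virtual-hit-likeness value VHL in [0, 1] (higher is better) and compared
against the experimental hit set through ROC curves, enrichment factors,
and recall/precision/F1.

Two conventions matter throughout:

* Compounds that could not be docked carry no score.  They are excluded
  from the ROC curve but kept in the positive/negative denominators, so
  the curve is truncated — it does not reach (1, 1) — and its trapezoidal
  area is reported as a partial AUC (pAUC) without renormalization.
* The enrichment factor uses the recovered-hit formulation
  EF = (hits_in_top / total_hits) / (selected / population), with the
  population defaulting to the whole library including undocked members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DockRecord",
    "RocResult",
    "EnrichmentResult",
    "BudgetResult",
    "PrecisionRecallF1",
    "rank_records",
    "roc",
    "enrichment_factor",
    "enrichment_factor_from_counts",
    "recall_precision_f1",
    "vhl_filter",
    "deep_docking_budget",
    "score_distribution_summary",
    "random_baseline",
    "read_dock_csv",
    "write_dock_csv",
]


@dataclass(frozen=True)
class DockRecord:
    """Per-compound docking outcome.

    ``score`` is an energy-like quantity (lower = better) and must be
    present exactly when ``docked`` is true.  ``vhl`` is an optional
    virtual-hit-likeness in [0, 1] (higher = more hit-like).
    """

    compound_id: str
    score: float | None = None
    docked: bool = False
    vhl: float | None = None

    def __post_init__(self) -> None:
        if self.docked != (self.score is not None):
            raise ValueError(
                f"{self.compound_id}: score must be present iff docked"
            )
        if self.vhl is not None and not 0.0 <= self.vhl <= 1.0:
            raise ValueError(f"{self.compound_id}: vhl {self.vhl} outside [0, 1]")


@dataclass
class RocResult:
    """A (possibly truncated) ROC curve and its area.

    ``complete`` is true iff the curve reaches (1, 1); otherwise ``area``
    is the unrescaled trapezoidal area of the truncated curve (pAUC).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    area: float
    complete: bool


@dataclass(frozen=True)
class EnrichmentResult:
    selected: int
    hits_in_top: int
    ef: float
    top_fraction: float | None = None


@dataclass(frozen=True)
class BudgetResult:
    docked_count: int
    fraction: float


@dataclass(frozen=True)
class PrecisionRecallF1:
    recall: float
    precision: float
    f1: float


def _rank_key(rec: DockRecord, key: str) -> float | None:
    if key == "score":
        return rec.score
    if key == "vhl":
        return rec.vhl
    raise ValueError(f"unknown ranking key {key!r}; use 'score' or 'vhl'")


def rank_records(
    records: Sequence[DockRecord], key: str = "score"
) -> list[DockRecord]:
    """Order best-first by the chosen key; keyless records go last.

    Score ranks ascending (lower = better), VHL descending.  Ties are
    broken by compound_id so the permutation is deterministic.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot rank an empty record set")
    if all(_rank_key(r, key) is None for r in records):
        raise ValueError(f"no record carries the ranking key {key!r}")
    sign = 1.0 if key == "score" else -1.0

    def sort_key(rec: DockRecord):
        v = _rank_key(rec, key)
        return (v is None, sign * v if v is not None else 0.0, rec.compound_id)

    return sorted(records, key=sort_key)


def roc(
    ranked: Sequence[DockRecord],
    labels: Sequence[bool],
    key: str = "score",
    restrict_to_keyed: bool = True,
) -> RocResult:
    """ROC curve of a ranked deck against experimental hit labels.

    ``ranked`` is the full population in rank order (e.g. from
    :func:`rank_records`) with keyless records trailing; ``labels`` is the
    parallel hit-flag vector.  The positive/negative totals always come
    from the full population.  With ``restrict_to_keyed`` (the default),
    keyless records are dropped from the curve, which then ends short of
    (1, 1) whenever any record was excluded, and ``area`` is the pAUC of
    the truncated curve.  Without it, keyless records form one final tied
    block.  Tied keys are processed as blocks (diagonal segments), which
    makes the complete-curve area identical to the Mann-Whitney U
    statistic normalized by the number of positive-negative pairs.
    """
    ranked = list(ranked)
    labels = [bool(x) for x in labels]
    if len(ranked) != len(labels):
        raise ValueError("ranked and labels must have equal length")
    if not ranked:
        raise ValueError("empty input")
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")

    # group into tie blocks; keyless records are either excluded or one block
    blocks: list[tuple[int, int]] = []  # (tp_increment, fp_increment)
    prev_key: object = object()
    excluded = 0
    for rec, lab in zip(ranked, labels):
        k = _rank_key(rec, key)
        if k is None:
            if restrict_to_keyed:
                excluded += 1
                continue
            k = "__unkeyed__"
        if k != prev_key:
            blocks.append((0, 0))
            prev_key = k
        tp, fp = blocks[-1]
        blocks[-1] = (tp + lab, fp + (not lab))

    fpr = [0.0]
    tpr = [0.0]
    tp = fp = 0
    for d_tp, d_fp in blocks:
        tp += d_tp
        fp += d_fp
        tpr.append(tp / n_pos)
        fpr.append(fp / n_neg)
    fpr_a = np.asarray(fpr)
    tpr_a = np.asarray(tpr)
    area = float(np.trapezoid(tpr_a, fpr_a))
    complete = bool(excluded == 0 and fpr_a[-1] == 1.0 and tpr_a[-1] == 1.0)
    return RocResult(fpr=fpr_a, tpr=tpr_a, area=area, complete=complete)


def enrichment_factor_from_counts(
    hits_in_top: int, total_hits: int, selected: int, population_size: int
) -> float:
    """EF = (hits_in_top/total_hits) / (selected/population_size)."""
    if total_hits <= 0:
        raise ValueError("population contains no hits; EF undefined")
    if not 0 < selected <= population_size:
        raise ValueError(
            f"selected ({selected}) must be in (0, population {population_size}]"
        )
    return (hits_in_top / total_hits) / (selected / population_size)


def enrichment_factor(
    ranked: Sequence[DockRecord],
    labels: Sequence[bool],
    top_fraction: float | None = None,
    top_count: int | None = None,
    population_size: int | None = None,
) -> EnrichmentResult:
    """Enrichment of hits among the top of a ranked deck.

    Exactly one of ``top_fraction`` / ``top_count`` selects the cut.  The
    population defaults to the ranked deck itself but may be larger (the
    full library) when the deck omits undocked compounds.
    """
    if (top_fraction is None) == (top_count is None):
        raise ValueError("give exactly one of top_fraction or top_count")
    labels = [bool(x) for x in labels]
    if len(labels) != len(ranked):
        raise ValueError("ranked and labels must have equal length")
    population = population_size if population_size is not None else len(ranked)
    if top_count is not None:
        selected = top_count
    else:
        if not 0.0 < top_fraction <= 1.0:
            raise ValueError("top_fraction must be in (0, 1]")
        selected = max(1, round(top_fraction * population))
    total_hits = sum(labels)
    hits_in_top = sum(labels[:selected])
    ef = enrichment_factor_from_counts(hits_in_top, total_hits, selected, population)
    return EnrichmentResult(
        selected=selected,
        hits_in_top=hits_in_top,
        ef=ef,
        top_fraction=top_fraction,
    )


def recall_precision_f1(
    predicted_hits: Iterable[str], experimental_hits: Iterable[str]
) -> PrecisionRecallF1:
    """Recall, precision and F1 of a predicted hit set vs the experimental one.

    An empty prediction has precision 0 (with a warning); F1 is 0 when
    precision + recall is 0.
    """
    pred = set(predicted_hits)
    exp = set(experimental_hits)
    if not pred and not exp:
        raise ValueError("both hit sets are empty")
    tp = len(pred & exp)
    recall = tp / len(exp) if exp else 0.0
    if not pred:
        warnings.warn("empty prediction set; precision defined as 0")
        precision = 0.0
    else:
        precision = tp / len(pred)
    f1 = (
        0.0
        if precision + recall == 0
        else 2 * precision * recall / (precision + recall)
    )
    return PrecisionRecallF1(recall=recall, precision=precision, f1=f1)


def vhl_filter(
    records: Iterable[DockRecord], threshold: float = 0.95
) -> list[DockRecord]:
    """Keep records whose VHL value reaches the threshold (inclusive)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"VHL threshold {threshold} outside [0, 1]")
    out = []
    for rec in records:
        if rec.vhl is None:
            raise ValueError(f"{rec.compound_id}: missing vhl value")
        if rec.vhl >= threshold:
            out.append(rec)
    return out


def deep_docking_budget(
    cycles: int, per_cycle: int, library_size: int
) -> BudgetResult:
    """Docking budget of an iterative surrogate-docking workflow.

    Each cycle docks ``per_cycle`` compounds, and the first cycle docks
    three such batches (training, test and validation sets), so the total
    is per_cycle * cycles + 2 * per_cycle.
    """
    if cycles < 1 or per_cycle < 1:
        raise ValueError("cycles and per_cycle must be >= 1")
    docked = per_cycle * cycles + 2 * per_cycle
    if library_size < docked:
        warnings.warn(
            f"budget {docked} exceeds library size {library_size}", stacklevel=2
        )
    return BudgetResult(docked_count=docked, fraction=docked / library_size)


def score_distribution_summary(scores: Sequence[float]) -> dict[str, float]:
    """Five-number summary (min, Q1, median, Q3, max) of a score vector."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("empty score vector")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    return {
        "min": float(arr.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(arr.max()),
    }


def write_dock_csv(records: Sequence[DockRecord], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "score", "docked", "vhl"])
        for rec in records:
            w.writerow(
                [
                    rec.compound_id,
                    "" if rec.score is None else repr(rec.score),
                    int(rec.docked),
                    "" if rec.vhl is None else repr(rec.vhl),
                ]
            )


def read_dock_csv(path) -> list[DockRecord]:
    import csv

    out: list[DockRecord] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                DockRecord(
                    compound_id=row["compound_id"],
                    score=float(row["score"]) if row.get("score") else None,
                    docked=bool(int(row["docked"])),
                    vhl=float(row["vhl"]) if row.get("vhl") else None,
                )
            )
    return out


def random_baseline(
    records: Sequence[DockRecord], n: int, seed: int
) -> list[DockRecord]:
    """Uniform sample of records without replacement, reproducible by seed."""
    if n > len(records):
        raise ValueError(f"cannot sample {n} from {len(records)} records")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(records), size=n, replace=False)
    return [records[i] for i in idx]
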