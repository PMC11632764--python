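"""Per-building-block statistics of a screened combinatorial library.

For a building block fixed at one position, the subset S collects every
library compound containing that block there.  P_bind is the fraction of
S that are hits — a block-level affinity signal under the premise that
building-block identity drives binding.  Because absolute P_bind scales
with the overall hit count, blocks are compared through range-scaled
values, normalized to [0, 1] independently within each position.

The compatible-partner count CP of a fixed block is the number of
distinct partner blocks co-occurring with it among hit compounds, summed
over the non-fixed positions; its maximum is the sum of the non-fixed
position cardinalities.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .library import CompoundRecord

__all__ = [
    "bb_matrix_from_records",
    "p_bind",
    "normalize_p_bind",
    "compatible_partners",
    "top_n_hitset",
    "compute_bb_stats",
    "bb_agreement",
]


def bb_matrix_from_records(records: Iterable[CompoundRecord]) -> np.ndarray:
    """(n_compounds, n_positions) integer matrix of building-block indices."""
    mat = np.asarray([rec.bb_indices for rec in records], dtype=np.int64)
    if mat.ndim != 2:
        raise ValueError("records must share a common number of positions")
    return mat


def _validate(bb: np.ndarray, hits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    bb = np.asarray(bb, dtype=np.int64)
    hits = np.asarray(hits, dtype=bool)
    if bb.ndim != 2:
        raise ValueError("bb matrix must be 2-D (compounds x positions)")
    if hits.shape != (bb.shape[0],):
        raise ValueError("hit-flag vector must align with the compound rows")
    return bb, hits


def p_bind(
    bb: np.ndarray, hits: Sequence[bool], position: int, bb_index: int
) -> float:
    """Fraction of hits among compounds carrying bb_index at position."""
    bb, hits = _validate(bb, np.asarray(hits))
    in_subset = bb[:, position] == bb_index
    n = int(in_subset.sum())
    if n == 0:
        raise ValueError(
            f"no compound contains block {bb_index} at position {position}"
        )
    return float(hits[in_subset].sum() / n)


def normalize_p_bind(values: Sequence[float]) -> np.ndarray:
    """Range-scale a position's P_bind vector to [0, 1].

    A degenerate position (all values equal) maps to all zeros.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("position has no blocks")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def compatible_partners(
    bb: np.ndarray,
    hits: Sequence[bool],
    position: int,
    bb_index: int,
    cardinalities: Sequence[int] | None = None,
) -> tuple[int, int]:
    """Distinct partner blocks among hits containing the fixed block.

    Returns (cp, cp_max): cp sums, over non-fixed positions, the number
    of distinct blocks seen there among hit compounds carrying bb_index
    at the fixed position; cp_max is the sum of non-fixed cardinalities
    (inferred from the library matrix when not given).
    """
    bb, hits = _validate(bb, np.asarray(hits))
    n_positions = bb.shape[1]
    if n_positions < 2:
        raise ValueError("compatible partners need at least two positions")
    if not 0 <= position < n_positions:
        raise ValueError(f"invalid position {position}")
    if cardinalities is None:
        cardinalities = [int(bb[:, p].max()) + 1 for p in range(n_positions)]
    sel = (bb[:, position] == bb_index) & hits
    cp = 0
    cp_max = 0
    for p in range(n_positions):
        if p == position:
            continue
        cp_max += int(cardinalities[p])
        cp += len(np.unique(bb[sel, p]))
    return cp, cp_max


def top_n_hitset(
    ranked_ids: Sequence[str], n: int, universe_ids: Sequence[str]
) -> np.ndarray:
    """Hit-flag vector over the full library flagging the top-n ranked ids.

    Used to feed docking-based "computational hits" into the same
    P_bind/CP machinery as experimental hit calls.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(ranked_ids):
        raise ValueError(f"n={n} exceeds ranked length {len(ranked_ids)}")
    top = set(ranked_ids[:n])
    return np.asarray([cid in top for cid in universe_ids], dtype=bool)


def compute_bb_stats(
    bb: np.ndarray,
    hits: Sequence[bool],
    cardinalities: Sequence[int] | None = None,
    labels: dict[tuple[int, int], str] | None = None,
) -> pd.DataFrame:
    """Full per-block table: subset size, P_bind, normalized P_bind, CP.

    ``cardinalities`` fixes the block count per position; by default each
    position's cardinality is ``max index + 1`` observed in the matrix.
    """
    bb, hits = _validate(bb, np.asarray(hits))
    n_positions = bb.shape[1]
    if cardinalities is None:
        cardinalities = [int(bb[:, p].max()) + 1 for p in range(n_positions)]
    if len(cardinalities) != n_positions:
        raise ValueError("cardinalities must match the number of positions")

    rows = []
    for pos in range(n_positions):
        card = cardinalities[pos]
        subset_sizes = np.bincount(bb[:, pos], minlength=card)
        hit_counts = np.bincount(bb[hits, pos], minlength=card)
        with np.errstate(invalid="ignore"):
            pb = np.where(subset_sizes > 0, hit_counts / subset_sizes, np.nan)
        pb_norm = normalize_p_bind(np.nan_to_num(pb, nan=0.0))
        cp_max_pos = sum(
            int(cardinalities[p]) for p in range(n_positions) if p != pos
        )
        # distinct (fixed block, partner position, partner block) triples among hits
        cp_vec = np.zeros(card, dtype=np.int64)
        hit_rows = bb[hits]
        for p in range(n_positions):
            if p == pos:
                continue
            pairs = np.unique(hit_rows[:, [pos, p]], axis=0)
            if pairs.size:
                cp_vec += np.bincount(pairs[:, 0], minlength=card)
        for i in range(card):
            rows.append(
                {
                    "position": pos,
                    "bb_index": i,
                    "label": (labels or {}).get((pos, i), ""),
                    "subset_size": int(subset_sizes[i]),
                    "p_bind": float(pb[i]) if subset_sizes[i] > 0 else np.nan,
                    "p_bind_norm": float(pb_norm[i]),
                    "cp": int(cp_vec[i]),
                    "cp_max": int(cp_max_pos),
                }
            )
    return pd.DataFrame(rows)


def bb_agreement(
    stats_experimental: pd.DataFrame, stats_computational: pd.DataFrame
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Join experimental vs computational block statistics.

    Returns the per-block paired table and, per position, the Spearman
    rank correlation of the normalized P_bind values.  Both tables must
    describe the same library (identical position/bb_index keys).
    """
    keys = ["position", "bb_index"]
    exp_keys = set(map(tuple, stats_experimental[keys].to_numpy()))
    comp_keys = set(map(tuple, stats_computational[keys].to_numpy()))
    if exp_keys != comp_keys:
        raise ValueError("block statistics describe different libraries")
    joined = stats_experimental.merge(
        stats_computational, on=keys, suffixes=("_exp", "_comp")
    )[
        keys
        + ["p_bind_norm_exp", "p_bind_norm_comp", "cp_exp", "cp_comp"]
    ]
    correlations: dict[int, float] = {}
    for pos, grp in joined.groupby("position"):
        if len(grp) < 2:
            correlations[int(pos)] = float("nan")
            continue
        rho = spearmanr(grp["p_bind_norm_exp"], grp["p_bind_norm_comp"]).statistic
        correlations[int(pos)] = float(rho)
    return joined, correlations
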