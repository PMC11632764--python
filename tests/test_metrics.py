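"""Ranking, ROC/pAUC, enrichment factors and classification metrics."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from delbench.metrics import (
    DockRecord,
    deep_docking_budget,
    enrichment_factor,
    enrichment_factor_from_counts,
    rank_records,
    read_dock_csv,
    recall_precision_f1,
    roc,
    random_baseline,
    score_distribution_summary,
    vhl_filter,
    write_dock_csv,
)


def _deck(scores, vhls=None):
    vhls = vhls or [None] * len(scores)
    return [
        DockRecord(f"c{i:03d}", score=s, docked=s is not None, vhl=v)
        for i, (s, v) in enumerate(zip(scores, vhls))
    ]


# --- ranking ---------------------------------------------------------------

def test_rank_by_score_ascending_with_undocked_last():
    ranked = rank_records(_deck([-7.2, None, -9.1]))
    assert [r.score for r in ranked] == [-9.1, -7.2, None]


def test_rank_by_vhl_descending():
    recs = [
        DockRecord("a", vhl=0.2),
        DockRecord("b", vhl=0.99),
    ]
    assert [r.vhl for r in rank_records(recs, key="vhl")] == [0.99, 0.2]


def test_rank_matches_full_sort_oracle(rng):
    scores = rng.normal(size=100).round(1)  # rounding forces ties
    ranked = rank_records(_deck(list(scores)))
    oracle = sorted(_deck(list(scores)), key=lambda r: (r.score, r.compound_id))
    assert [r.compound_id for r in ranked] == [r.compound_id for r in oracle]


def test_rank_empty_or_keyless_errors():
    with pytest.raises(ValueError):
        rank_records([])
    with pytest.raises(ValueError):
        rank_records([DockRecord("a")], key="score")


def test_score_present_iff_docked():
    with pytest.raises(ValueError):
        DockRecord("a", score=1.0, docked=False)
    with pytest.raises(ValueError):
        DockRecord("a", score=None, docked=True)


# --- ROC -------------------------------------------------------------------

def test_perfect_ranking_gives_complete_auc_one():
    ranked = _deck([-9.0, -8.0, -7.0, -6.0])
    res = roc(ranked, [True, True, False, False])
    assert res.area == 1.0
    assert res.complete


def test_roc_rejects_degenerate_labels():
    ranked = _deck([-9.0, -8.0])
    with pytest.raises(ValueError):
        roc(ranked, [True, True])


def test_auc_equals_mann_whitney_oracle(rng):
    """Complete-curve trapezoid area == normalized Mann-Whitney U."""
    for _ in range(100):
        n = int(rng.integers(20, 80))
        scores = rng.normal(size=n).round(1)  # ties included
        labels = rng.random(n) < 0.3
        if labels.all() or not labels.any():
            continue
        ranked = rank_records(_deck(list(scores)))
        by_id = dict(zip([f"c{i:03d}" for i in range(n)], labels))
        lab = [by_id[r.compound_id] for r in ranked]
        res = roc(ranked, lab)
        # lower score = better, so positives should have low scores;
        # AUC = P(score_pos < score_neg) = U/(n1*n0) with U from -scores of positives
        u = mannwhitneyu(-scores[labels], -scores[~labels]).statistic
        assert res.area == pytest.approx(
            u / (labels.sum() * (~labels).sum()), abs=1e-12
        )


def test_pauc_matches_hand_trapezoid():
    # 6 records, 1 undocked hit; curve over the 5 docked, denominators 3/3
    scores = [-9.0, -8.0, -7.0, -6.0, -5.0, None]
    labels = [True, False, True, False, False, True]
    ranked = _deck(scores)  # already in rank order, undocked last
    res = roc(ranked, labels)
    assert not res.complete
    assert res.area == pytest.approx(5.0 / 9.0, abs=1e-12)
    assert res.tpr[-1] == pytest.approx(2.0 / 3.0)
    assert res.fpr[-1] == 1.0


def test_curve_is_monotone(rng):
    scores = rng.normal(size=200)
    labels = rng.random(200) < 0.2
    labels[0] = True
    labels[1] = False
    res = roc(_deck(list(np.sort(scores))), list(labels))
    assert np.all(np.diff(res.fpr) >= 0)
    assert np.all(np.diff(res.tpr) >= 0)


# --- enrichment ------------------------------------------------------------

def test_ef_reproduces_recovered_hit_worked_example():
    ef = enrichment_factor_from_counts(
        hits_in_top=15, total_hits=1855, selected=1_000_000,
        population_size=7_077_888,
    )
    assert round(ef, 3) == 0.057


def test_ef_at_full_selection_is_one():
    ranked = _deck([-5.0, -4.0, -3.0, -2.0])
    res = enrichment_factor(ranked, [True, False, True, False], top_fraction=1.0)
    assert res.ef == pytest.approx(1.0)


def test_ef_small_case_counting_oracle(rng):
    scores = list(rng.normal(size=20))
    labels = [False] * 20
    for i in rng.choice(20, size=4, replace=False):
        labels[i] = True
    ranked = rank_records(_deck(scores))
    by_id = {f"c{i:03d}": labels[i] for i in range(20)}
    lab = [by_id[r.compound_id] for r in ranked]
    res = enrichment_factor(ranked, lab, top_count=5)
    hits_top = sum(lab[:5])
    assert res.hits_in_top == hits_top
    assert res.ef == pytest.approx((hits_top / 4) / (5 / 20))


def test_ef_requires_hits():
    with pytest.raises(ValueError):
        enrichment_factor_from_counts(0, 0, 5, 20)


# --- recall / precision / F1 ----------------------------------------------

def test_recall_of_14_out_of_18():
    exp = {f"h{i}" for i in range(18)}
    pred = {f"h{i}" for i in range(14)} | {f"x{i}" for i in range(100)}
    prf = recall_precision_f1(pred, exp)
    assert round(100 * prf.recall, 1) == 77.8


def test_identical_sets_are_perfect():
    prf = recall_precision_f1({"a", "b"}, {"a", "b"})
    assert (prf.recall, prf.precision, prf.f1) == (1.0, 1.0, 1.0)


def test_prf_against_set_intersection_oracle(rng):
    universe = [f"c{i}" for i in range(1000)]
    pred = set(rng.choice(universe, size=50, replace=False))
    exp = set(rng.choice(universe, size=50, replace=False))
    prf = recall_precision_f1(pred, exp)
    tp = len(pred & exp)
    assert prf.recall == tp / 50
    assert prf.precision == tp / 50
    if prf.recall + prf.precision:
        assert prf.f1 == pytest.approx(
            2 * prf.recall * prf.precision / (prf.recall + prf.precision)
        )


def test_empty_prediction_warns_and_zeroes():
    with pytest.warns(UserWarning):
        prf = recall_precision_f1(set(), {"a"})
    assert prf.precision == 0.0
    assert prf.f1 == 0.0


def test_both_empty_is_an_error():
    with pytest.raises(ValueError):
        recall_precision_f1(set(), set())


# --- VHL filter ------------------------------------------------------------

def test_vhl_filter_boundary_inclusive():
    recs = [
        DockRecord("a", vhl=0.94),
        DockRecord("b", vhl=0.95),
        DockRecord("c", vhl=0.99),
    ]
    assert [r.compound_id for r in vhl_filter(recs)] == ["b", "c"]
    assert len(vhl_filter(recs, threshold=0.0)) == 3


def test_vhl_filter_matches_brute_force(rng):
    recs = [DockRecord(f"c{i}", vhl=float(v)) for i, v in enumerate(rng.random(10_000))]
    kept = {r.compound_id for r in vhl_filter(recs, 0.9)}
    assert kept == {r.compound_id for r in recs if r.vhl >= 0.9}


def test_vhl_threshold_range_checked():
    with pytest.raises(ValueError):
        vhl_filter([], threshold=1.5)


# --- budget ----------------------------------------------------------------

@pytest.mark.parametrize(
    "cycles, per_cycle, size, docked, pct",
    [
        (11, 10_000, 7_077_888, 130_000, 1.8),
        (11, 1_000_000, 802_160_640, 13_000_000, 1.6),
        (1, 100, 1_000, 300, 30.0),
    ],
)
def test_deep_docking_budget(cycles, per_cycle, size, docked, pct):
    res = deep_docking_budget(cycles, per_cycle, size)
    assert res.docked_count == docked
    assert round(100 * res.fraction, 1) == pct


def test_budget_warns_when_exceeding_library():
    with pytest.warns(UserWarning):
        deep_docking_budget(10, 100, 500)


# --- distribution summary & random baseline --------------------------------

def test_five_number_summary():
    s = score_distribution_summary([1, 2, 3, 4, 5])
    assert (s["min"], s["q1"], s["median"], s["q3"], s["max"]) == (1, 2, 3, 4, 5)
    const = score_distribution_summary([2.5] * 7)
    assert len(set(const.values())) == 1


def test_summary_matches_sorted_array_quantiles(rng):
    x = rng.normal(size=1000)
    s = score_distribution_summary(x)
    assert s["q1"] == pytest.approx(np.quantile(x, 0.25), abs=1e-12)
    assert s["median"] == pytest.approx(np.quantile(x, 0.5), abs=1e-12)
    assert s["q3"] == pytest.approx(np.quantile(x, 0.75), abs=1e-12)


def test_random_baseline_reproducible_and_complete(rng):
    recs = _deck(list(rng.normal(size=50)))
    assert random_baseline(recs, 50, seed=3) is not None
    assert {r.compound_id for r in random_baseline(recs, 50, seed=3)} == {
        r.compound_id for r in recs
    }
    a = random_baseline(recs, 10, seed=5)
    b = random_baseline(recs, 10, seed=5)
    assert [r.compound_id for r in a] == [r.compound_id for r in b]
    with pytest.raises(ValueError):
        random_baseline(recs, 51, seed=0)


def test_dock_csv_round_trip(tmp_path, rng):
    recs = _deck([None, -4.5], vhls=[0.3, None])
    path = tmp_path / "dock.csv"
    write_dock_csv(recs, path)
    assert read_dock_csv(path) == recs
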