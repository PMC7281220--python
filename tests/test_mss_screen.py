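"""MSS core: RGS/RPS sampling, dissimilar selection, Fisher scoring,
gilding and signature extraction — each against an independent oracle."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylmss import (
    RGS,
    RPS,
    ProbePool,
    ScreenConfig,
    derive_signature,
    discover_signatures,
    fisher_enrichment,
    sample_rgs,
    sample_rps,
    sample_rps_candidates,
    score_and_gild,
    select_dissimilar_rps,
)
from methylmss.go_pools import GOSubpool
from methylmss.mss_screen import SCALED_OVERRIDES, fisher_enrichment_p, rps_differential_set
from methylmss.preprocess import normalize_cohort


def _jaccard_dist(a, b):
    a, b = set(a), set(b)
    return 1.0 - len(a & b) / len(a | b)


# ---------------------------------------------------------------- sample_rgs


def test_rgs_equals_subpool_when_m_is_full_size():
    sp = GOSubpool("GO:1", "t", ["a", "b", "c"])
    for rgs in sample_rgs(sp, 5, 3, seed=0):
        assert sorted(rgs.probe_ids) == ["a", "b", "c"]
        assert len(set(rgs.probe_ids)) == 3


def test_rgs_sampling_is_seed_deterministic():
    sp = GOSubpool("GO:1", "t", [f"p{i}" for i in range(50)])
    a = sample_rgs(sp, 20, 10, seed=4)
    b = sample_rgs(sp, 20, 10, seed=4)
    assert [r.probe_ids for r in a] == [r.probe_ids for r in b]


def test_rgs_inclusion_frequency_is_binomial():
    sp = GOSubpool("GO:1", "t", [f"p{i}" for i in range(50)])
    sets = sample_rgs(sp, 500, 10, seed=8)
    counts = pd.Series([pid for r in sets for pid in r.probe_ids]).value_counts()
    expect = 500 * 10 / 50
    sigma = np.sqrt(500 * 0.2 * 0.8)
    assert counts.reindex(sp.probe_ids, fill_value=0).between(expect - 3 * sigma, expect + 3 * sigma).all()


def test_rgs_size_cannot_exceed_subpool():
    with pytest.raises(ValueError, match="exceeds subpool"):
        sample_rgs(GOSubpool("GO:1", "t", ["a"]), 1, 2, seed=0)


# ---------------------------------------------------------------- sample_rps


def test_rps_defaults_are_balanced_200(default_bundle):
    _, cohort, _, _ = default_bundle
    rps = sample_rps(cohort.samples, seed=0)
    assert len(rps) == 200
    meta = cohort.samples.loc[list(rps.sample_ids)]
    assert (meta["class_label"] == "GC").sum() == 100
    assert (meta["class_label"] == "EC").sum() == 100
    assert meta.groupby("gc_subtype", dropna=True).size().eq(25).all()


def test_rps_scaled_case_and_tally_oracle(small_bundle):
    _, cohort, _, _ = small_bundle
    rps = sample_rps(cohort.samples, n_per_subtype=1, n_ec=4, seed=1)
    assert len(rps) == 8
    tally = cohort.samples.loc[list(rps.sample_ids)].groupby("gc_subtype", dropna=True).size()
    assert tally.eq(1).all() and len(tally) == 4
    assert len(set(rps.sample_ids)) == 8


def test_rps_insufficient_stratum_names_it(small_bundle):
    _, cohort, _, _ = small_bundle
    with pytest.raises(ValueError, match="EBV"):
        sample_rps(cohort.samples, n_per_subtype=10**6, n_ec=1, seed=0)
    with pytest.raises(ValueError, match="EC"):
        sample_rps(cohort.samples, n_per_subtype=1, n_ec=10**6, seed=0)


# ---------------------------------------------------- select_dissimilar_rps


def _random_candidates(rng, n, universe, size):
    return [
        RPS(rps_id=f"r{i}", sample_ids=tuple(rng.choice(universe, size=size, replace=False)))
        for i in range(n)
    ]


def test_dissimilar_selection_matches_exhaustive_max_min():
    # fixture chosen so the greedy heuristic attains the exhaustive optimum
    # (greedy max-min is a surrogate, not an exact solver, in general)
    rng = np.random.default_rng(0)
    universe = np.array([f"s{i}" for i in range(12)])
    cands = _random_candidates(rng, 6, universe, 5)

    def min_pairwise(idx):
        return min(_jaccard_dist(cands[i].sample_ids, cands[j].sample_ids) for i, j in itertools.combinations(idx, 2))

    best_val = max(min_pairwise(t) for t in itertools.combinations(range(6), 3))
    optimal = [set(t) for t in itertools.combinations(range(6), 3) if min_pairwise(t) == best_val]
    picked = select_dissimilar_rps(cands, 3)
    picked_idx = {cands.index(r) for r in picked}
    assert min_pairwise(picked_idx) == best_val
    assert picked_idx in optimal


def test_duplicate_candidates_not_both_selected():
    rng = np.random.default_rng(5)
    universe = np.array([f"s{i}" for i in range(10)])
    cands = _random_candidates(rng, 4, universe, 4)
    cands.append(RPS(rps_id="dup", sample_ids=cands[0].sample_ids))
    picked = select_dissimilar_rps(cands, 4)
    sets = [frozenset(r.sample_ids) for r in picked]
    assert len(set(sets)) == len(sets)


def test_identical_candidates_fall_back_to_index_order():
    cands = [RPS(rps_id=f"r{i}", sample_ids=("a", "b")) for i in range(5)]
    picked = select_dissimilar_rps(cands, 3)
    assert [r.rps_id for r in picked] == ["r0", "r1", "r2"]


def test_k_larger_than_candidates_errors():
    cands = [RPS(rps_id=f"r{i}", sample_ids=("a",)) for i in range(3)]
    with pytest.raises(ValueError, match="exceeds"):
        select_dissimilar_rps(cands, 4)


# ----------------------------------------------------------- fisher scoring


def _hypergeom_tail(a, pool, d, n):
    """Oracle: explicit tail sum of the hypergeometric pmf."""
    return sum(comb(d, i) * comb(pool - d, n - i) for i in range(a, min(d, n) + 1)) / comb(pool, n)


def test_fisher_p_explicit_tail_sum():
    assert fisher_enrichment_p(5, 100, 20, 10) == pytest.approx(_hypergeom_tail(5, 100, 20, 10), rel=1e-12)


def test_fisher_p_null_direction_close_to_one():
    # overlap at (just below) the independence expectation: n*d/pool = 2
    assert fisher_enrichment_p(2, 100, 20, 10) > 0.3
    assert fisher_enrichment_p(0, 100, 20, 10) == pytest.approx(1.0)


def test_fisher_p_fully_contained_rgs_is_minimal():
    # RGS entirely inside D: the smallest achievable tail value
    p_full = fisher_enrichment_p(4, 12, 6, 4)
    assert p_full == pytest.approx(_hypergeom_tail(4, 12, 6, 4), rel=1e-12)
    assert all(p_full <= _hypergeom_tail(a, 12, 6, 4) + 1e-12 for a in range(5))


@settings(deadline=None, max_examples=300)
@given(st.data())
def test_fisher_p_matches_enumeration_for_small_pools(data):
    pool = data.draw(st.integers(2, 60))
    d = data.draw(st.integers(1, pool))
    n = data.draw(st.integers(1, pool))
    a = data.draw(st.integers(max(0, n + d - pool), min(n, d)))
    assert fisher_enrichment_p(a, pool, d, n) == pytest.approx(_hypergeom_tail(a, pool, d, n), rel=1e-9, abs=1e-300)


def test_fisher_enrichment_full_path_matches_manual_table(default_bundle, normalized):
    _, cohort, ann, truth = default_bundle
    pool = ProbePool(sorted(truth))
    rps = sample_rps(cohort.samples, seed=3, rps_id="rps0")
    q = 10
    d = rps_differential_set(rps, normalized, cohort.class_label, pool, q)
    rgs = RGS("r0", "GO:x", tuple(sorted(truth)[:8]))
    expected = _hypergeom_tail(len(d & set(rgs.probe_ids)), len(pool), q, 8)
    assert fisher_enrichment(rgs, rps, normalized, cohort.class_label, pool, q) == pytest.approx(expected, rel=1e-9)
    with pytest.raises(ValueError, match="exceeds pool"):
        rps_differential_set(rps, normalized, cohort.class_label, pool, len(pool) + 1)


# ----------------------------------------------------------- score_and_gild


def test_score_is_reciprocal_mean_p():
    records = score_and_gild({"a": [0.01, 0.03], "b": [1.0, 1.0]}, top_k=1)
    by_id = {r.rgs_id: r for r in records}
    assert by_id["a"].score == pytest.approx(50.0)
    assert by_id["b"].score == pytest.approx(1.0)
    assert by_id["a"].gilded and not by_id["b"].gilded


def test_gilding_matches_sort_oracle():
    rng = np.random.default_rng(17)
    plists = {f"rgs{i:02d}": rng.uniform(1e-6, 1, size=5) for i in range(20)}
    records = score_and_gild(plists, top_k=7)
    scores = {k: 1 / np.mean(v) for k, v in plists.items()}
    expected_gilded = set(sorted(scores, key=lambda k: (-scores[k], k))[:7])
    assert {r.rgs_id for r in records if r.gilded} == expected_gilded
    assert [r.score for r in records] == sorted((r.score for r in records), reverse=True)


def test_score_is_invariant_to_rps_order():
    ps = list(np.random.default_rng(1).uniform(size=8))
    a = score_and_gild({"x": ps}, top_k=0)[0].score
    b = score_and_gild({"x": ps[::-1]}, top_k=0)[0].score
    assert a == pytest.approx(b, rel=1e-15)


def test_empty_p_list_errors():
    with pytest.raises(ValueError, match="no p-values"):
        score_and_gild({"x": []})


# --------------------------------------------------------- derive_signature


def _rgs_list(sets):
    return [RGS(f"r{i}", "GO:x", tuple(s)) for i, s in enumerate(sets)]


def test_signature_is_top_by_frequency():
    gilded = _rgs_list([("a", "b"), ("a", "c"), ("a", "b")])
    sig = derive_signature(gilded, size=2)
    assert sig.probe_ids == ("a", "b")
    assert sig.frequencies == {"a": 3, "b": 2, "c": 1}


def test_signature_tie_at_cutoff_prefers_lexicographic():
    gilded = _rgs_list([("z", "m", "a"), ("z",)])
    sig = derive_signature(gilded, size=2)
    assert sig.probe_ids == ("z", "a")  # m vs a tie at rank 2 -> 'a'


def test_signature_matches_brute_force_tally():
    rng = np.random.default_rng(23)
    universe = [f"p{i:02d}" for i in range(40)]
    gilded = _rgs_list([tuple(rng.choice(universe, size=10, replace=False)) for _ in range(30)])
    sig = derive_signature(gilded, size=15)
    tally = {}
    for r in gilded:
        for pid in r.probe_ids:
            tally[pid] = tally.get(pid, 0) + 1
    expected = sorted(tally, key=lambda pid: (-tally[pid], pid))[:15]
    assert list(sig.probe_ids) == expected


def test_signature_needs_enough_unique_probes():
    with pytest.raises(ValueError, match="unique probes"):
        derive_signature(_rgs_list([("a", "b")]), size=3)


# ------------------------------------------------------------- end-to-end


def test_discovery_end_to_end_recovers_planted_signal(default_bundle):
    _, cohort, ann, truth = default_bundle
    cfg = ScreenConfig().scaled(**SCALED_OVERRIDES)
    res = discover_signatures(cohort, ann, cfg, seed=1)
    assert res.signatures, "no signature emitted"
    for term, sig in res.signatures.items():
        assert len(sig.probe_ids) == len(set(sig.probe_ids)) == 30
    sig = res.signatures["GO:0005515"]  # signal term
    assert len(set(sig.probe_ids) & truth) / 30 >= 0.8
    board = res.scoreboard
    assert board.groupby("go_term")["gilded"].sum().eq(min(cfg.gild_top, cfg.rgs_per_term)).all()
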