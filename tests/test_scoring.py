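"""Fit scores, cut-off selection, and discrete classification."""

import numpy as np
import pytest

from ckinome.alignment import AMINO_ACIDS, ProfileAlignment, SequenceRecord
from ckinome.inference import (
    ClusterNode,
    Constraint,
    ConstraintHierarchy,
    ModelError,
)
from ckinome.scoring import (
    UNCLASSIFIED,
    classify,
    score_all,
    score_sequence,
    select_cutoff,
)
from conftest import make_alignment, make_record


def _flat_hierarchy(constraints, n_columns=10):
    nodes = {
        "root": ClusterNode("root", "root", None, []),
        "c": ClusterNode("c", "c", "root", constraints),
    }
    return ConstraintHierarchy(nodes, n_columns)


def test_score_bounds_all_and_none_satisfied():
    constraints = [
        Constraint(i, frozenset("M"), w)
        for i, w in zip(range(5), (0.7, 1.3, 2.9, 4.1, 5.5))
    ]
    h = _flat_hierarchy(constraints)
    all_match = make_record("hit", "MMMMMMMMMM")
    none_match = make_record("miss", "AAAAAAAAAA")
    assert score_sequence(all_match, "c", h) == 1.0
    assert score_sequence(none_match, "c", h) == 0.0


def test_score_is_weighted_fraction():
    h = _flat_hierarchy(
        [Constraint(0, frozenset("M"), 2.0), Constraint(1, frozenset("W"), 2.0)]
    )
    rec = make_record("half", "MAAAAAAAAA")
    assert score_sequence(rec, "c", h) == pytest.approx(0.5)
    h2 = _flat_hierarchy(
        [Constraint(0, frozenset("M"), 3.0), Constraint(1, frozenset("W"), 1.0)]
    )
    assert score_sequence(rec, "c", h2) == pytest.approx(0.75)


def test_gap_and_unknown_never_satisfy():
    h = _flat_hierarchy([Constraint(0, frozenset("M"), 1.0)])
    assert score_sequence(make_record("gap", "-AAAAAAAAA"), "c", h) == 0.0
    assert score_sequence(make_record("unk", "XAAAAAAAAA"), "c", h) == 0.0


def test_score_requires_effective_constraints():
    h = _flat_hierarchy([Constraint(0, frozenset("M"), 1.0)])
    with pytest.raises(ModelError):
        score_sequence(make_record("r", "M" * 10), "root", h)


def test_score_monotone_in_added_constraints():
    """Adding a satisfied constraint never lowers the score; adding an
    unsatisfied one never raises it (checked against brute force)."""
    rng = np.random.default_rng(0)
    aa = list(AMINO_ACIDS)
    for _ in range(50):
        n_cols = 12
        rec = make_record("r", "".join(rng.choice(aa, n_cols)))
        cols = rng.choice(n_cols, size=4, replace=False)
        constraints = [
            Constraint(int(c), frozenset(rng.choice(aa, 2, replace=False)), float(w))
            for c, w in zip(cols[:3], rng.uniform(0.5, 5.0, 3))
        ]
        h = _flat_hierarchy(constraints, n_cols)
        base = score_sequence(rec, "c", h)
        extra_col = int(cols[3])
        sat = Constraint(extra_col, frozenset(rec.match_residues[extra_col]), 2.0)
        unsat_set = frozenset({aa[0] if rec.match_residues[extra_col] != aa[0] else aa[1]})
        unsat = Constraint(extra_col, unsat_set, 2.0)
        h_sat = _flat_hierarchy(constraints + [sat], n_cols)
        h_unsat = _flat_hierarchy(constraints + [unsat], n_cols)
        assert score_sequence(rec, "c", h_sat) >= base
        assert score_sequence(rec, "c", h_unsat) <= base


def test_score_all_shape_and_all_gap_row(preset0):
    h = preset0.truth.hierarchy
    gap_rec = make_record("allgap", "-" * preset0.aln.n_columns)
    aln = ProfileAlignment(
        preset0.aln.records[:3] + (gap_rec,), preset0.aln.n_columns
    )
    table = score_all(aln, h)
    assert table.shape == (4, len(h.cluster_ids()))
    assert ((table >= 0) & (table <= 1)).all().all()
    assert (table.loc["allgap"] == 0).all()


def test_members_score_higher_against_own_cluster(preset0, planted_cls):
    scores = planted_cls.scores
    own = [
        scores.loc[sid, preset0.truth.labels[sid]] for sid in scores.index
    ]
    sg1 = [s for s in scores.index if preset0.truth.labels[s].startswith("sg1")]
    cross = scores.loc[sg1, "sg2.fam1"]
    assert np.mean(own) > cross.mean() + 0.5


# ---------------------------------------------------------------------------
# select_cutoff


def _bimodal_scores(valley=0.55):
    rng = np.random.default_rng(0)
    low = rng.normal(0.2, 0.05, 400).clip(0, 1)
    high = rng.normal(0.9, 0.04, 400).clip(0, 1)
    return np.concatenate([low, high])


def test_select_cutoff_finds_planted_valley():
    scores = _bimodal_scores()
    picked = select_cutoff(scores, bin_width=0.05)
    # brute-force oracle: lowest-count bin between the two tallest modes
    counts, edges = np.histogram(scores, bins=20, range=(0, 1))
    m1 = int(np.argmax(counts))
    rest = [
        j for j in range(20) if abs(edges[j] - edges[m1]) >= 0.2
    ]
    m2 = max(rest, key=lambda j: counts[j])
    lo, hi = sorted((m1, m2))
    vmin = min(counts[lo + 1 : hi])
    lowest = [j for j in range(lo + 1, hi) if counts[j] == vmin]
    valley = lowest[len(lowest) // 2]
    assert not picked.fallback
    assert picked.value == pytest.approx((edges[valley] + edges[valley + 1]) / 2)
    assert abs(picked.value - 0.55) <= 0.1


def test_select_cutoff_unimodal_falls_back_to_paper_default():
    rng = np.random.default_rng(1)
    scores = rng.normal(0.5, 0.05, 500).clip(0, 1)
    picked = select_cutoff(scores)
    assert picked.fallback
    assert float(picked) == 0.7


def test_select_cutoff_input_validation():
    with pytest.raises(ValueError):
        select_cutoff(np.linspace(0, 1, 50))
    with pytest.raises(ValueError):
        select_cutoff(np.linspace(0, 1, 200), bin_width=0.5)


# ---------------------------------------------------------------------------
# classify


def _nested_hierarchy():
    nodes = {
        "root": ClusterNode("root", "root", None, []),
        "super": ClusterNode(
            "super",
            "super",
            "root",
            [Constraint(i, frozenset("M"), 1.0) for i in range(10)],
        ),
        "subA": ClusterNode(
            "subA",
            "subA",
            "super",
            [Constraint(10 + i, frozenset("W"), 1.0) for i in range(10)],
        ),
        "subB": ClusterNode(
            "subB",
            "subB",
            "super",
            [Constraint(20 + i, frozenset("Y"), 1.0) for i in range(10)],
        ),
    }
    return ConstraintHierarchy(nodes, 30)


def test_classify_prefers_deepest_qualifying_cluster():
    h = _nested_hierarchy()
    # satisfies all super, 8/10 subA, 2/10 subB
    rec = make_record("r", "M" * 10 + "W" * 8 + "A" * 2 + "Y" * 2 + "A" * 8)
    aln = ProfileAlignment((rec,), 30)
    result = classify(aln, h, 0.7)
    assert result.assignments["r"] == ("super", "subA")
    assert result.assigned_cluster("r") == "subA"


def test_classify_stops_at_supercluster_when_subs_fail():
    h = _nested_hierarchy()
    rec = make_record("r", "M" * 10 + "A" * 20)
    result = classify(ProfileAlignment((rec,), 30), h, 0.7)
    assert result.assignments["r"] == ("super",)


def test_classify_unclassified_sink():
    h = _nested_hierarchy()
    rec = make_record("r", "A" * 30)
    result = classify(ProfileAlignment((rec,), 30), h, 0.7)
    assert result.assignments["r"] == ()
    assert result.assigned_cluster("r") == UNCLASSIFIED
    assert result.status("r") == UNCLASSIFIED


def test_classify_random_sequences_mostly_unclassified(preset0):
    rng = np.random.default_rng(7)
    aa = np.array(list(AMINO_ACIDS))
    rows = {
        f"rand{i}": "".join(aa[rng.integers(0, 20, preset0.aln.n_columns)])
        for i in range(100)
    }
    aln = make_alignment(rows)
    result = classify(aln, preset0.truth.hierarchy, 0.7)
    unclassified = sum(1 for p in result.assignments.values() if not p)
    assert unclassified >= 95


def test_classify_deterministic_and_idempotent(preset0):
    h = preset0.truth.hierarchy
    r1 = classify(preset0.aln, h, 0.7)
    r2 = classify(preset0.aln, h, 0.7)
    assert r1.assignments == r2.assignments
    assert r1.scores.equals(r2.scores)
    # every assigned node on the path scores >= cutoff
    for sid, path in r1.assignments.items():
        for nid in path:
            assert r1.scores.loc[sid, nid] >= 0.7
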