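"""Constraint contrast, partition sampling, hierarchy inference, LPR."""

import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from ckinome.alignment import AMINO_ACIDS, ProfileAlignment, SequenceRecord
from ckinome.inference import (
    ClusterNode,
    Constraint,
    ConstraintHierarchy,
    InferenceConfig,
    column_contrast,
    consensus_hierarchy,
    infer_hierarchy,
    sample_partition,
    select_pattern,
    total_lpr,
)
from ckinome.synthetic import make_hierarchy, make_sequences
from conftest import deepest_assignment, make_alignment


def _uniform_noise_alignment(n_records, n_columns, seed):
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    rows = {
        f"s{i}": "".join(aa[rng.integers(0, 20, size=n_columns)])
        for i in range(n_records)
    }
    return make_alignment(rows)


# ---------------------------------------------------------------------------
# column_contrast


def test_column_contrast_hand_computed_value():
    # all 10 fg residues in the set, none of 10 bg:
    # q_F = 11/12, q_B = 1/12 -> w = 10 * ln(11)
    fg = np.zeros(20)
    fg[0] = 10
    bg = np.zeros(20)
    bg[5] = 10
    w = column_contrast(fg, bg, {"A"}, pseudocount=1.0)
    assert w == pytest.approx(10 * math.log(11), abs=1e-12)


def test_column_contrast_identical_profiles_near_zero():
    counts = np.full(20, 5.0)
    w = column_contrast(counts, counts, {"A", "C"}, pseudocount=1.0)
    assert abs(w) < 1e-12


def test_column_contrast_full_residue_set_vanishes_with_pseudocount():
    rng = np.random.default_rng(0)
    fg = rng.integers(1, 10, size=20).astype(float)
    bg = rng.integers(1, 10, size=20).astype(float)
    w_small = column_contrast(fg, bg, set(AMINO_ACIDS), pseudocount=1e-9)
    assert abs(w_small) < 1e-6


def test_column_contrast_validates_inputs():
    with pytest.raises(ValueError):
        column_contrast(np.zeros(20), np.ones(20), {"A"}, 1.0)
    with pytest.raises(ValueError):
        column_contrast(np.ones(19), np.ones(20), {"A"}, 1.0)


# ---------------------------------------------------------------------------
# select_pattern


def _planted_column_alignment(seed=0, n=40, n_columns=20, planted_col=7):
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    rows = {}
    for i in range(n):
        seq = list(aa[rng.integers(0, 20, size=n_columns)])
        if i < n // 2:
            seq[planted_col] = "M"
        rows[f"s{i}"] = "".join(seq)
    fg = {f"s{i}" for i in range(n // 2)}
    return make_alignment(rows), fg


def test_select_pattern_finds_planted_column():
    aln, fg = _planted_column_alignment()
    constraints = select_pattern(aln, fg, InferenceConfig())
    assert constraints[0].column == 7
    assert "M" in constraints[0].residue_set
    # sorted by descending weight
    weights = [c.weight for c in constraints]
    assert weights == sorted(weights, reverse=True)
    assert all(c.weight > 0 for c in constraints)


def test_select_pattern_ignores_fg_gap_columns():
    aln, fg = _planted_column_alignment()
    rows = {r.id: r.match_residues for r in aln}
    for sid in fg:
        rows[sid] = "-" + rows[sid][1:]  # column 0 gapped in all fg
    gapped = make_alignment(rows)
    constraints = select_pattern(gapped, fg, InferenceConfig())
    assert all(c.column != 0 for c in constraints)


def test_select_pattern_rejects_degenerate_foreground():
    aln, _ = _planted_column_alignment()
    with pytest.raises(ValueError):
        select_pattern(aln, set(), InferenceConfig())
    with pytest.raises(ValueError):
        select_pattern(aln, set(aln.ids()), InferenceConfig())


# ---------------------------------------------------------------------------
# sample_partition


def test_sample_partition_recovers_planted_groups():
    h = make_hierarchy(
        n_supers=2, subs_per_super=0, constraints_per_node=5, n_columns=50, seed=3
    )
    aln, truth = make_sequences(h, n_per_leaf=50, fidelity=0.95, seed=3)
    res = sample_partition(aln, InferenceConfig(seed=0), init="spectral")
    assert res.accepted
    predicted = [sid in res.fg_ids for sid in aln.ids()]
    actual = [truth.labels[sid] == "sg1" for sid in aln.ids()]
    assert adjusted_rand_score(actual, predicted) >= 0.9


def test_sample_partition_rejects_homogeneous_noise():
    aln = _uniform_noise_alignment(50, 100, seed=42)
    rejected = 0
    for seed in range(20):
        cfg = InferenceConfig(seed=seed, n_sweeps=20, minnat=5)
        if not sample_partition(aln, cfg).accepted:
            rejected += 1
    assert rejected >= 16  # >= 80% of seeds


def test_sample_partition_zero_sweeps_scores_initial_split():
    aln = _uniform_noise_alignment(30, 40, seed=1)
    cfg = InferenceConfig(seed=7, n_sweeps=0)
    first = sample_partition(aln, cfg)
    again = sample_partition(aln, cfg)
    assert first.fg_ids == again.fg_ids
    assert first.net_lpr == again.net_lpr
    fg, constraints = first  # result unpacks per the operation contract
    assert isinstance(fg, frozenset)
    assert isinstance(constraints, list)


def test_sample_partition_needs_four_records():
    aln = _uniform_noise_alignment(3, 10, seed=0)
    with pytest.raises(ValueError):
        sample_partition(aln, InferenceConfig())


# ---------------------------------------------------------------------------
# infer_hierarchy


def test_infer_hierarchy_recovers_planted_topology(preset0, inferred0):
    h = inferred0
    # 1 root + 2 superclusters + 4 families
    assert len(h.nodes) == 7
    root_children = h.children(h.root_id)
    assert len(root_children) == 2
    for child in root_children:
        assert len(h.children(child.id)) == 2
    labels = [preset0.truth.labels[s] for s in preset0.aln.ids()]
    recovered = [deepest_assignment(h, s) for s in preset0.aln.ids()]
    assert adjusted_rand_score(labels, recovered) >= 0.9


def test_infer_hierarchy_constraint_recall(preset0, inferred0):
    """Each recovered node refinds >= 80% of its planted constraint columns."""
    h = inferred0
    planted = preset0.truth.hierarchy
    planted_members = {
        pid: {
            s
            for s, leaf in preset0.truth.labels.items()
            if pid in planted.path_to_root(leaf)
        }
        for pid in planted.cluster_ids()
    }
    for nid in h.cluster_ids():
        members = set(h.memberships[nid])
        match = max(
            planted_members,
            key=lambda pid: len(members & planted_members[pid])
            / len(members | planted_members[pid]),
        )
        planted_cols = {c.column for c in planted.nodes[match].constraints}
        found_cols = {c.column for c in h.nodes[nid].constraints}
        recall = len(planted_cols & found_cols) / len(planted_cols)
        assert recall >= 0.8, (nid, match, recall)


def test_infer_hierarchy_constraints_disjoint_from_ancestors(inferred0):
    for nid in inferred0.cluster_ids():
        own = {c.column for c in inferred0.nodes[nid].constraints}
        for anc in inferred0.path_to_root(nid)[:-1]:
            anc_cols = {c.column for c in inferred0.nodes[anc].constraints}
            assert not own & anc_cols


def test_infer_hierarchy_max_depth_zero(preset0):
    h = infer_hierarchy(preset0.aln, InferenceConfig(seed=0), max_depth=0)
    assert list(h.nodes) == [h.root_id]
    assert h.nodes[h.root_id].constraints == []


def test_infer_hierarchy_identical_sequences_single_node():
    rows = {f"s{i}": "ACDEFGHIKLMNPQRSTVWY" for i in range(10)}
    aln = make_alignment(rows)
    h = infer_hierarchy(aln, InferenceConfig(seed=0, n_sweeps=10), max_depth=3)
    assert list(h.nodes) == [h.root_id]


def test_hierarchy_json_round_trip(inferred0, tmp_path):
    path = tmp_path / "model.json"
    inferred0.save(path)
    back = ConstraintHierarchy.load(path)
    assert set(back.nodes) == set(inferred0.nodes)
    for nid, node in back.nodes.items():
        assert node.constraints == inferred0.nodes[nid].constraints
        assert node.parent_id == inferred0.nodes[nid].parent_id
    assert back.memberships == inferred0.memberships
    assert back.total_lpr == pytest.approx(inferred0.total_lpr)


# ---------------------------------------------------------------------------
# total_lpr


def _two_group_study(seed=5):
    h = make_hierarchy(
        n_supers=2, subs_per_super=0, constraints_per_node=5, n_columns=60, seed=seed
    )
    aln, truth = make_sequences(h, n_per_leaf=30, fidelity=0.95, seed=seed)
    members = {
        nid: tuple(s for s, l in truth.labels.items() if l == nid)
        for nid in ("sg1", "sg2")
    }
    h.memberships = {"root": tuple(aln.ids()), **members}
    return aln, h, truth


def test_total_lpr_single_node_is_zero():
    aln = _uniform_noise_alignment(10, 20, seed=0)
    h = ConstraintHierarchy(
        {"root": ClusterNode("root", "root", None, [])},
        20,
        memberships={"root": tuple(aln.ids())},
    )
    assert total_lpr(h, aln) == 0.0


def test_total_lpr_true_partition_beats_random():
    aln, h, truth = _two_group_study()
    true_lpr = total_lpr(h, aln)
    rng = np.random.default_rng(0)
    ids = np.array(aln.ids())
    for _ in range(20):
        perm = rng.permutation(len(ids))
        shuffled = dict(h.memberships)
        shuffled["sg1"] = tuple(ids[perm[:30]])
        shuffled["sg2"] = tuple(ids[perm[30:]])
        rand_h = ConstraintHierarchy(
            dict(h.nodes), h.n_columns, memberships=shuffled
        )
        assert total_lpr(rand_h, aln) < true_lpr


def test_total_lpr_doubles_with_duplicated_sequences():
    aln, h, truth = _two_group_study()
    base = total_lpr(h, aln)
    doubled_records = list(aln.records) + [
        SequenceRecord(r.id + "_copy", r.match_residues, r.inserts)
        for r in aln.records
    ]
    aln2 = ProfileAlignment(tuple(doubled_records), aln.n_columns)
    memberships2 = {
        nid: members + tuple(m + "_copy" for m in members)
        for nid, members in h.memberships.items()
    }
    h2 = ConstraintHierarchy(dict(h.nodes), h.n_columns, memberships=memberships2)
    ratio = total_lpr(h2, aln2) / base
    assert 1.8 < ratio < 2.3


def test_total_lpr_invariant_under_column_permutation():
    aln, h, truth = _two_group_study()
    base = total_lpr(h, aln)
    rng = np.random.default_rng(1)
    perm = rng.permutation(aln.n_columns)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    permuted = ProfileAlignment(
        tuple(
            SequenceRecord(
                r.id,
                "".join(r.match_residues[inv[c]] for c in range(aln.n_columns)),
                r.inserts,
            )
            for r in aln.records
        ),
        aln.n_columns,
    )
    perm_nodes = {
        nid: ClusterNode(
            node.id,
            node.name,
            node.parent_id,
            [
                Constraint(int(perm[c.column]), c.residue_set, c.weight)
                for c in node.constraints
            ],
        )
        for nid, node in h.nodes.items()
    }
    h_perm = ConstraintHierarchy(perm_nodes, h.n_columns, memberships=h.memberships)
    assert total_lpr(h_perm, permuted) == pytest.approx(base, rel=1e-9)


# ---------------------------------------------------------------------------
# consensus


def test_consensus_of_identical_runs_preserves_topology(preset0, inferred0):
    runs = [inferred0, inferred0, inferred0]
    cons = consensus_hierarchy(runs, 0.5, preset0.aln, InferenceConfig())
    assert len(cons.nodes) == len(inferred0.nodes)
    cons_parts = {
        frozenset(m) for n, m in cons.memberships.items() if n != cons.root_id
    }
    orig_parts = {
        frozenset(m)
        for n, m in inferred0.memberships.items()
        if n != inferred0.root_id
    }
    assert cons_parts == orig_parts


def test_consensus_drops_low_support_cluster(preset0, inferred0):
    spurious = {
        nid: ClusterNode(n.id, n.name, n.parent_id, list(n.constraints))
        for nid, n in inferred0.nodes.items()
    }
    extra_members = inferred0.memberships["c0.c0"][:10]
    spurious["c0.c0.bogus"] = ClusterNode(
        "c0.c0.bogus",
        "c0.c0.bogus",
        "c0.c0",
        [Constraint(199, frozenset("A"), 1.0)],
    )
    memberships = dict(inferred0.memberships)
    memberships["c0.c0.bogus"] = extra_members
    run_with_extra = ConstraintHierarchy(
        spurious, inferred0.n_columns, memberships=memberships
    )
    runs = [inferred0, inferred0, run_with_extra]
    cons = consensus_hierarchy(runs, 0.5, preset0.aln, InferenceConfig())
    cons_parts = [frozenset(m) for m in cons.memberships.values()]
    assert frozenset(extra_members) not in cons_parts
    assert len(cons.nodes) == len(inferred0.nodes)


def test_consensus_rejects_mismatched_id_sets(preset0, inferred0):
    other = ConstraintHierarchy(
        {"root": ClusterNode("root", "root", None, [])},
        preset0.aln.n_columns,
        memberships={"root": ("only", "four", "odd", "ids")},
    )
    with pytest.raises(ValueError):
        consensus_hierarchy(
            [inferred0, other], 0.5, preset0.aln, InferenceConfig()
        )
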