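"""Shared fixtures: synthetic study bundles and small hand-built alignments."""

import numpy as np
import pytest

from ckinome.alignment import ProfileAlignment, SequenceRecord
from ckinome.inference import InferenceConfig, infer_hierarchy
from ckinome.scoring import classify
from ckinome.synthetic import default_preset


def make_record(rec_id, match, inserts=None, organism_id=None):
    """Build a SequenceRecord with empty inserts unless given as a dict
    {slot: segment}."""
    segs = [""] * (len(match) + 1)
    for slot, seg in (inserts or {}).items():
        segs[slot] = seg
    return SequenceRecord(rec_id, match, tuple(segs), organism_id)


def make_alignment(rows, inserts=None, organism_ids=None):
    """Alignment from a dict {id: match_string}."""
    inserts = inserts or {}
    organism_ids = organism_ids or {}
    records = tuple(
        make_record(rid, match, inserts.get(rid), organism_ids.get(rid))
        for rid, match in rows.items()
    )
    return ProfileAlignment(records, len(next(iter(rows.values()))))


@pytest.fixture(scope="session")
def preset0():
    """The study's default synthetic conditions at seed 0."""
    return default_preset(seed=0)


@pytest.fixture(scope="session")
def planted_cls(preset0):
    """Classification of the default preset against its planted hierarchy
    at the optimal cut-off."""
    return classify(preset0.aln, preset0.truth.hierarchy, 0.7)


@pytest.fixture(scope="session")
def inferred0(preset0):
    """Hierarchy inferred from scratch on the default preset, seed 0."""
    return infer_hierarchy(preset0.aln, InferenceConfig(seed=0), max_depth=4)


def deepest_assignment(h, seq_id):
    """Deepest inferred cluster containing a sequence (by membership)."""
    cands = [
        nid
        for nid, members in h.memberships.items()
        if nid != h.root_id and seq_id in members
    ]
    if not cands:
        return "none"
    return max(cands, key=lambda n: (h.depth(n), n))
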