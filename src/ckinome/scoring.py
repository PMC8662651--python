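"""Fit scoring and discrete classification against a constraint hierarchy.

The fit score of a sequence against a cluster is the weight of the
cluster's satisfied constraints divided by the total weight of all its
constraints, giving a value in [0, 1]: a sequence following every
constraint scores exactly 1, one following none scores exactly 0.  A
cluster is scored against its *effective* constraint set — its own plus
all ancestors' — so subcluster members also score highly against their
supercluster.  Gap or unknown residues at a constrained column never
satisfy the constraint.

Discrete classification assigns each sequence the deepest cluster on a
root-to-leaf path whose every cluster scores at or above the cut-off;
sequences qualifying nowhere fall into the "unclassified" sink.  The
default cut-off of 0.7 (relaxed preset: 0.6) sits at the valley of the
empirically bimodal score distribution of member versus non-member
sequence-cluster pairs; :func:`select_cutoff` locates that valley on any
given score sample and falls back to 0.7 when the histogram is not
bimodal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment import ProfileAlignment, SequenceRecord, RESIDUE_CODE
from .inference import ClusterNode, Constraint, ConstraintHierarchy, ModelError

#: named cut-off presets; "relaxed" mirrors the conservation-analysis setting
CUTOFF_PRESETS = {"optimal": 0.7, "relaxed": 0.6}


def _satisfied(rec: SequenceRecord, c: Constraint) -> bool:
    return rec.match_residues[c.column] in c.residue_set


def score_sequence(
    rec: SequenceRecord,
    node: ClusterNode | str,
    h: ConstraintHierarchy,
) -> float:
    """Weighted fraction of a cluster's effective constraints satisfied."""
    node_id = node if isinstance(node, str) else node.id
    eff = h.effective_constraints(node_id)
    if not eff:
        raise ModelError(f"node {node_id!r} has no effective constraints")
    total = sum(c.weight for c in eff)
    hit = sum(c.weight for c in eff if _satisfied(rec, c))
    return hit / total


def score_all(aln: ProfileAlignment, h: ConstraintHierarchy) -> pd.DataFrame:
    """Score every sequence against every cluster.

    Returns a (sequence × cluster) DataFrame of fit scores; clusters are
    all non-root nodes.  Deterministic.
    """
    enc = aln.encoded()
    cluster_ids = h.cluster_ids()
    out = np.zeros((len(aln), len(cluster_ids)))
    for k, cid in enumerate(cluster_ids):
        eff = h.effective_constraints(cid)
        if not eff:
            raise ModelError(f"node {cid!r} has no effective constraints")
        w = np.array([c.weight for c in eff])
        cols = [c.column for c in eff]
        sat = np.zeros((len(aln), len(eff)), dtype=bool)
        for j, c in enumerate(eff):
            codes = np.array(sorted(RESIDUE_CODE[r] for r in c.residue_set))
            sat[:, j] = np.isin(enc[:, cols[j]], codes)
        out[:, k] = (sat @ w) / w.sum()
    return pd.DataFrame(out, index=aln.ids(), columns=cluster_ids)


@dataclass
class CutoffResult:
    """Selected classification cut-off; ``fallback`` marks a non-bimodal
    score distribution where the default 0.7 was adopted instead."""

    value: float
    fallback: bool

    def __float__(self) -> float:
        return self.value


def select_cutoff(
    scores: Sequence[float],
    bin_width: float = 0.01,
    min_separation: float = 0.2,
    default: float = 0.7,
) -> CutoffResult:
    """Locate the valley between the two modes of a score distribution.

    Histograms the scores on [0, 1]; the cut-off is the midpoint of the
    lowest-count bin strictly between the two tallest well-separated
    modes.  If no second mode exists or the valley is not strictly lower
    than both modes, the distribution is deemed unimodal and the default
    is returned with the fallback flag set.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 100:
        raise ValueError("need at least 100 scores to pick a cut-off")
    if not (0 < bin_width <= 0.1):
        raise ValueError("bin_width must be in (0, 0.1]")
    n_bins = int(round(1.0 / bin_width))
    counts, edges = np.histogram(scores, bins=n_bins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    m1 = int(np.argmax(counts))
    apart = np.abs(centers - centers[m1]) >= min_separation
    if not apart.any() or counts[apart].max() == 0:
        return CutoffResult(default, True)
    masked = np.where(apart, counts, -1)
    m2 = int(np.argmax(masked))
    lo, hi = sorted((m1, m2))
    between = counts[lo + 1 : hi]
    if between.size == 0:
        return CutoffResult(default, True)
    vmin = between.min()
    if vmin >= min(counts[m1], counts[m2]):
        return CutoffResult(default, True)
    lowest = [j for j in range(lo + 1, hi) if counts[j] == vmin]
    v = lowest[len(lowest) // 2]  # middle of the flat valley floor
    return CutoffResult(float(centers[v]), False)


UNCLASSIFIED = "unclassified"


@dataclass
class ClassificationResult:
    """Per-sequence fit scores plus discrete assignments.

    ``assignments`` maps each sequence id to its assigned path of
    cluster ids from the shallowest to the deepest qualifying cluster;
    an empty tuple marks an unclassified sequence.
    """

    scores: pd.DataFrame
    assignments: dict[str, tuple[str, ...]] = field(default_factory=dict)
    cutoff: float = 0.7

    def assigned_cluster(self, seq_id: str) -> str:
        path = self.assignments.get(seq_id, ())
        return path[-1] if path else UNCLASSIFIED

    def status(self, seq_id: str) -> str:
        return "classified" if self.assignments.get(seq_id) else UNCLASSIFIED

    def members(self, cluster_id: str) -> list[str]:
        """Sequences whose assigned path contains the cluster."""
        return [s for s, path in self.assignments.items() if cluster_id in path]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Long-format (scores, assignments) tables for TSV export."""
        scores = self.scores.stack().rename_axis(
            ["sequence_id", "cluster_id"]
        ).rename("score").reset_index()
        rows = [
            {
                "sequence_id": s,
                "assigned_path": "/".join(path) if path else UNCLASSIFIED,
                "status": "classified" if path else UNCLASSIFIED,
            }
            for s, path in self.assignments.items()
        ]
        return scores, pd.DataFrame(rows)


def classify(
    aln: ProfileAlignment, h: ConstraintHierarchy, cutoff: float
) -> ClassificationResult:
    """Assign each sequence to the deepest fully-qualifying cluster path.

    A cluster qualifies when the sequence scores >= ``cutoff`` against it
    and against every cluster above it; among the deepest qualifying
    clusters, ties break toward the higher score, then the
    lexicographically smaller cluster id.  Idempotent and deterministic.
    """
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must be in (0, 1)")
    scores = score_all(aln, h)
    paths = {
        cid: [p for p in h.path_to_root(cid) if p != h.root_id]
        for cid in scores.columns
    }
    assignments: dict[str, tuple[str, ...]] = {}
    values = scores.to_numpy()
    col_of = {cid: k for k, cid in enumerate(scores.columns)}
    for i, seq_id in enumerate(scores.index):
        qualifying = [
            cid
            for cid, path in paths.items()
            if all(values[i, col_of[p]] >= cutoff for p in path)
        ]
        if not qualifying:
            assignments[seq_id] = ()
            continue
        best = max(
            qualifying,
            key=lambda cid: (len(paths[cid]), values[i, col_of[cid]], _neg(cid)),
        )
        assignments[seq_id] = tuple(paths[best])
    return ClassificationResult(scores, assignments, cutoff)


class _neg(str):
    """Reverses string comparison so max() prefers the smaller id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):  # pragma: no cover - trivial
        return str.__lt__(self, other)


__all__ = [
    "CUTOFF_PRESETS",
    "UNCLASSIFIED",
    "CutoffResult",
    "ClassificationResult",
    "score_sequence",
    "score_all",
    "select_cutoff",
    "classify",
]
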