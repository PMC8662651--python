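"""Cluster-specific constraint inference over a profile alignment.

A *constraint* is an alignment column plus a small residue set that is
highly conserved inside a cluster of sequences but divergent outside it.
Constraint strength is measured by a binomial log-likelihood-ratio
contrast in nats: for a column with ``n_F`` foreground and ``n_B``
background residues, of which ``n_FR`` / ``n_BR`` fall inside the
residue set,

    w = n_FR * ln(q_F / q_B) + (n_F - n_FR) * ln((1 - q_F) / (1 - q_B))

with pseudocounted frequencies ``q = (n_R + a) / (n + 2a)``.  This is the
log-likelihood gain of explaining the foreground column with its own
match probability instead of the background's, so it is additive in
sequence counts and keeps the "nats" semantics of pattern-based
classification scores.

Partition sampling is a seeded coordinate ascent: starting from a random
split, alternate (i) reselecting the best constraint pattern for the
current foreground with (ii) reassigning each sequence to the foreground
when it satisfies at least half of the pattern's weight.  A candidate
cluster is accepted only if its *penalized* pattern weight clears
``minnat``: each constraint is charged a pattern-complexity prior of
``ln(n_columns) + ln(C(20, |set|))`` nats (the cost of pointing at one
column and one residue set out of all candidates), and only columns
actually conserved in the foreground (set frequency >= ``min_fg_freq``)
count.  Without this penalty a greedy maximum over thousands of candidate
patterns manufactures "clusters" from homogeneous noise.

Hierarchies are built by recursive binary splitting: an accepted
foreground and its complement both become children, each carrying its own
finalized constraints; columns constrained by an ancestor are excluded
from the descendants' searches, so child constraints layer on top of
parent constraints exactly as nested cluster-specific motifs do.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .alignment import (
    AMINO_ACIDS,
    GAP_CODE,
    ProfileAlignment,
    RESIDUE_CODE,
)


class ModelError(ValueError):
    """Raised when a hierarchy cannot support the requested operation."""


# ---------------------------------------------------------------------------
# data model


@dataclass(frozen=True)
class Constraint:
    """One cluster-specific constraint: column, residue set, weight (nats)."""

    column: int
    residue_set: frozenset[str]
    weight: float

    def __post_init__(self) -> None:
        if not self.residue_set:
            raise ValueError("residue_set must be non-empty")
        if self.weight <= 0:
            raise ValueError("constraint weight must be positive")

    @property
    def residues(self) -> str:
        return "".join(sorted(self.residue_set))


@dataclass
class ClusterNode:
    id: str
    name: str
    parent_id: str | None
    constraints: list[Constraint] = field(default_factory=list)

    def __post_init__(self) -> None:
        cols = [c.column for c in self.constraints]
        if len(cols) != len(set(cols)):
            raise ValueError(f"node {self.id!r}: duplicate constraint columns")


@dataclass
class ConstraintHierarchy:
    """A single-rooted tree of clusters with nested constraint semantics.

    The *effective* constraint set of a node is the union of its own
    constraints and those of all its ancestors.  ``memberships``
    optionally records, per node, the ids of the sequences it was
    inferred from (the root holds every sequence).
    """

    nodes: dict[str, ClusterNode]
    n_columns: int
    total_lpr: float | None = None
    memberships: dict[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        roots = [n.id for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise ModelError(f"hierarchy must have exactly one root, got {roots}")
        self._root = roots[0]
        for node in self.nodes.values():
            if node.parent_id is not None and node.parent_id not in self.nodes:
                raise ModelError(f"node {node.id!r} has unknown parent")
        # acyclicity / reachability
        for node in self.nodes.values():
            self.path_to_root(node.id)

    @property
    def root_id(self) -> str:
        return self._root

    def children(self, node_id: str) -> list[ClusterNode]:
        return [n for n in self.nodes.values() if n.parent_id == node_id]

    def path_to_root(self, node_id: str) -> list[str]:
        """Node ids from the root down to ``node_id`` (inclusive)."""
        path = []
        seen = set()
        cur: str | None = node_id
        while cur is not None:
            if cur in seen:
                raise ModelError(f"cycle detected at node {cur!r}")
            seen.add(cur)
            path.append(cur)
            cur = self.nodes[cur].parent_id
        return path[::-1]

    def depth(self, node_id: str) -> int:
        return len(self.path_to_root(node_id)) - 1

    def effective_constraints(self, node_id: str) -> list[Constraint]:
        eff: list[Constraint] = []
        for nid in self.path_to_root(node_id):
            eff.extend(self.nodes[nid].constraints)
        return eff

    def walk(self) -> Iterator[ClusterNode]:
        """Preorder traversal, children in id order."""
        stack = [self._root]
        while stack:
            nid = stack.pop()
            yield self.nodes[nid]
            stack.extend(sorted((c.id for c in self.children(nid)), reverse=True))

    def cluster_ids(self) -> list[str]:
        """All non-root node ids in preorder."""
        return [n.id for n in self.walk() if n.id != self._root]

    def leaves(self) -> list[str]:
        return [n.id for n in self.walk() if not self.children(n.id)]

    # -- serialization ------------------------------------------------------

    def to_json(self) -> dict:
        """JSON model file; constraint columns are written 1-based."""
        nodes = []
        for node in self.walk():
            entry = {
                "id": node.id,
                "name": node.name,
                "parent_id": node.parent_id,
                "constraints": [
                    {
                        "column": c.column + 1,
                        "residues": c.residues,
                        "weight": c.weight,
                    }
                    for c in node.constraints
                ],
            }
            if self.memberships is not None and node.id in self.memberships:
                entry["members"] = sorted(self.memberships[node.id])
            nodes.append(entry)
        return {
            "n_columns": self.n_columns,
            "total_lpr": self.total_lpr,
            "nodes": nodes,
        }

    @classmethod
    def from_json(cls, payload: dict) -> "ConstraintHierarchy":
        nodes: dict[str, ClusterNode] = {}
        memberships: dict[str, tuple[str, ...]] = {}
        for entry in payload["nodes"]:
            constraints = [
                Constraint(
                    column=c["column"] - 1,
                    residue_set=frozenset(c["residues"]),
                    weight=float(c["weight"]),
                )
                for c in entry["constraints"]
            ]
            nodes[entry["id"]] = ClusterNode(
                entry["id"], entry["name"], entry["parent_id"], constraints
            )
            if "members" in entry:
                memberships[entry["id"]] = tuple(entry["members"])
        return cls(
            nodes,
            int(payload["n_columns"]),
            payload.get("total_lpr"),
            memberships or None,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ConstraintHierarchy":
        return cls.from_json(json.loads(Path(path).read_text()))


@dataclass
class InferenceConfig:
    """Tunable parameters of the constraint sampler.

    minnat
        Minimum penalized pattern weight (nats) to accept a cluster.
    pseudocount
        Additive smoothing on set frequencies (per side).
    min_fg_freq
        Minimum foreground residue-set frequency for a constraint to be
        stored on an accepted node; half-conserved columns stay available
        to descendants.
    column_penalty
        Per-constraint complexity charge in nats; ``None`` derives
        ``ln(n_available_columns) + ln(C(20, set_size))`` at run time.
    """

    minnat: float = 5.0
    max_constraints_per_node: int = 20
    pseudocount: float = 1.0
    n_sweeps: int = 50
    seed: int = 0
    max_set_size: int = 4
    min_fg_freq: float = 0.7
    n_restarts: int = 5
    column_penalty: float | None = None

    def __post_init__(self) -> None:
        if self.minnat <= 0:
            raise ValueError("minnat must be positive")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


# ---------------------------------------------------------------------------
# column contrast


def column_contrast(
    fg_counts: Sequence[float],
    bg_counts: Sequence[float],
    residue_set: Iterable[str],
    pseudocount: float,
) -> float:
    """Binomial log-likelihood-ratio contrast of one column, in nats.

    ``fg_counts``/``bg_counts`` are length-20 residue count vectors in
    :data:`~ckinome.alignment.AMINO_ACIDS` order (gaps excluded).  May be
    negative when the set is depleted in the foreground.
    """
    fg = np.asarray(fg_counts, dtype=float)
    bg = np.asarray(bg_counts, dtype=float)
    if fg.shape != (20,) or bg.shape != (20,):
        raise ValueError("count vectors must have length 20")
    if (fg < 0).any() or (bg < 0).any():
        raise ValueError("counts must be nonnegative")
    n_f, n_b = fg.sum(), bg.sum()
    if n_f <= 0 or n_b <= 0:
        raise ValueError("foreground and background totals must be positive")
    idx = [RESIDUE_CODE[r] for r in residue_set]
    if not idx:
        raise ValueError("residue_set must be non-empty")
    n_fr = fg[idx].sum()
    n_br = bg[idx].sum()
    return float(_contrast(n_f, n_fr, n_b, n_br, pseudocount))


def _contrast(n_f, n_fr, n_b, n_br, alpha):
    q_f = (n_fr + alpha) / (n_f + 2.0 * alpha)
    q_b = (n_br + alpha) / (n_b + 2.0 * alpha)
    return n_fr * np.log(q_f / q_b) + (n_f - n_fr) * np.log(
        (1.0 - q_f) / (1.0 - q_b)
    )


def _set_penalty(n_avail: int, size: int) -> float:
    return math.log(max(n_avail, 2)) + math.log(math.comb(20, size))


@dataclass(frozen=True)
class _Candidate:
    column: int
    mask: np.ndarray          # (20,) bool, chosen residue set
    weight: float             # raw contrast, nats
    penalized: float          # weight minus complexity charge
    fg_freq: float            # pseudocounted q_F of the set
    bg_freq: float            # pseudocounted q_B of the set


def _column_counts(enc: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """(n_columns, 20) residue counts for the given record rows."""
    sub = enc[rows]
    counts = np.zeros((enc.shape[1], 20), dtype=float)
    for code in range(20):
        counts[:, code] = (sub == code).sum(axis=0)
    return counts


def _grow_set(cf, cb, alpha, max_size, n_avail):
    """Greedy residue-set growth for one column.

    Grows while the raw contrast improves; among the visited sizes the
    returned candidate carries both the best raw and the best penalized
    variant (the latter may prefer a smaller set).
    """
    n_f, n_b = cf.sum(), cb.sum()
    if n_f <= 0 or n_b <= 0:
        return None
    in_set = np.zeros(20, dtype=bool)
    n_fr = n_br = 0.0
    steps: list[tuple[np.ndarray, float]] = []
    for _ in range(max_size):
        cand = np.flatnonzero(~in_set)
        w = _contrast(n_f, n_fr + cf[cand], n_b, n_br + cb[cand], alpha)
        k = int(np.argmax(w))  # first max -> lowest residue index on ties
        if steps and w[k] <= steps[-1][1]:
            break
        j = int(cand[k])
        in_set[j] = True
        n_fr += cf[j]
        n_br += cb[j]
        steps.append((in_set.copy(), float(w[k])))
    if not steps:
        return None
    raw_mask, raw_w = steps[-1]
    best_pen = -np.inf
    pen_mask = raw_mask
    for size, (mask, w) in enumerate(steps, start=1):
        pen = w - _set_penalty(n_avail, size)
        if pen > best_pen:
            best_pen = pen
            pen_mask = mask
    return raw_mask, raw_w, pen_mask, best_pen


def _set_freqs(cf, cb, mask, alpha):
    q_f = (cf[mask].sum() + alpha) / (cf.sum() + 2.0 * alpha)
    q_b = (cb[mask].sum() + alpha) / (cb.sum() + 2.0 * alpha)
    return float(q_f), float(q_b)


def _scan_columns(enc, fg_rows, bg_rows, cfg, exclude_columns):
    """Raw and penalized best residue sets for every admissible column."""
    cf = _column_counts(enc, fg_rows)
    cb = _column_counts(enc, bg_rows)
    excluded = set(exclude_columns)
    n_avail = enc.shape[1] - len(excluded)
    raw: list[_Candidate] = []
    pen: list[_Candidate] = []
    for col in range(enc.shape[1]):
        if col in excluded:
            continue
        grown = _grow_set(cf[col], cb[col], cfg.pseudocount, cfg.max_set_size, n_avail)
        if grown is None:
            continue
        raw_mask, raw_w, pen_mask, pen_w = grown
        if raw_w > 0:
            q_f, q_b = _set_freqs(cf[col], cb[col], raw_mask, cfg.pseudocount)
            raw.append(_Candidate(col, raw_mask, raw_w, pen_w, q_f, q_b))
        if pen_w > 0:
            w = _contrast(
                cf[col].sum(),
                cf[col][pen_mask].sum(),
                cb[col].sum(),
                cb[col][pen_mask].sum(),
                cfg.pseudocount,
            )
            q_f, q_b = _set_freqs(cf[col], cb[col], pen_mask, cfg.pseudocount)
            pen.append(_Candidate(col, pen_mask, float(w), pen_w, q_f, q_b))
    return raw, pen


def _mask_to_set(mask: np.ndarray) -> frozenset[str]:
    return frozenset(AMINO_ACIDS[i] for i in np.flatnonzero(mask))


def _top(cands: list[_Candidate], limit: int) -> list[_Candidate]:
    return sorted(cands, key=lambda c: (-c.weight, c.column))[:limit]


def select_pattern(
    aln: ProfileAlignment,
    fg_ids: Iterable[str],
    cfg: InferenceConfig,
    exclude_columns: Iterable[int] = (),
) -> list[Constraint]:
    """Best residue-set constraint per column for a foreground subset.

    For every column a residue set of size 1–``max_set_size`` is grown
    greedily to maximize :func:`column_contrast` of the foreground
    against all remaining sequences; columns with positive weight are
    returned sorted by descending weight (ties by column index) and
    truncated at ``max_constraints_per_node``.  Gaps never contribute to
    counts, so a column gapped throughout the foreground is never
    selected.
    """
    fg = set(fg_ids)
    ids = aln.ids()
    if not fg or fg >= set(ids):
        raise ValueError("foreground must be a non-empty proper subset")
    fg_rows = np.array([i for i, x in enumerate(ids) if x in fg])
    bg_rows = np.array([i for i, x in enumerate(ids) if x not in fg])
    raw, _ = _scan_columns(aln.encoded(), fg_rows, bg_rows, cfg, exclude_columns)
    return [
        Constraint(c.column, _mask_to_set(c.mask), c.weight)
        for c in _top(raw, cfg.max_constraints_per_node)
    ]


def _finalized_pattern(enc, fg_rows, bg_rows, cfg, exclude_columns):
    """Penalty- and conservation-filtered pattern plus its net weight."""
    _, pen = _scan_columns(enc, fg_rows, bg_rows, cfg, exclude_columns)
    kept = [c for c in pen if c.fg_freq >= cfg.min_fg_freq]
    kept = _top(kept, cfg.max_constraints_per_node)
    net = float(sum(c.penalized for c in kept))
    constraints = [Constraint(c.column, _mask_to_set(c.mask), c.weight) for c in kept]
    return constraints, net


# ---------------------------------------------------------------------------
# partition sampling


@dataclass
class PartitionResult:
    """Outcome of one partition-sampling run.

    Iterable as ``(fg_ids, constraints)``; a rejected run carries an
    empty foreground and no constraints.
    """

    fg_ids: frozenset[str]
    constraints: list[Constraint]
    net_lpr: float
    accepted: bool

    def __iter__(self):
        yield self.fg_ids
        yield self.constraints


_REJECT = PartitionResult(frozenset(), [], 0.0, False)


def _reassign(enc, rows, cands: list[_Candidate]) -> np.ndarray:
    """Likelihood-ratio membership: a record joins the foreground when
    the summed log-odds of its residues under the foreground versus the
    background pattern frequencies is positive."""
    cols = [c.column for c in cands]
    log_in = np.array([math.log(c.fg_freq / c.bg_freq) for c in cands])
    log_out = np.array(
        [math.log((1.0 - c.fg_freq) / (1.0 - c.bg_freq)) for c in cands]
    )
    sub = enc[rows][:, cols]
    sat = np.zeros(sub.shape, dtype=bool)
    for k, c in enumerate(cands):
        codes = np.flatnonzero(c.mask)
        sat[:, k] = np.isin(sub[:, k], codes)
    odds = sat @ log_in + (~sat) @ log_out
    return odds > 0


def _spectral_split(enc, rows, exclude_columns):
    """Initial split along the top principal component of the one-hot
    encoded columns: the dominant block of correlated residue variation
    (a real cluster boundary, when one exists) separates first."""
    cols = [c for c in range(enc.shape[1]) if c not in set(exclude_columns)]
    sub = enc[rows][:, cols]
    X = np.zeros((len(rows), len(cols) * 20))
    for code in range(20):
        X[:, code::20] = sub == code
    X -= X.mean(axis=0)
    _, vecs = np.linalg.eigh(X @ X.T)
    v = vecs[:, -1]
    fg = v > 0
    if not (2 <= fg.sum() <= len(rows) - 2):
        fg = v > np.median(v)
    return fg


def _sample_partition_rows(enc, rows, ids, cfg, rng, exclude_columns, init="random"):
    n = len(rows)
    if init == "spectral":
        fg = _spectral_split(enc, rows, exclude_columns)
        if not (2 <= fg.sum() <= n - 2):
            return _REJECT
    else:
        fg = rng.random(n) < 0.5
        tries = 0
        while not (2 <= fg.sum() <= n - 2):
            fg = rng.random(n) < 0.5
            tries += 1
            if tries > 100:
                return _REJECT
    for _ in range(cfg.n_sweeps):
        cands, _ = _scan_columns(
            enc, rows[fg], rows[~fg], cfg, exclude_columns
        )
        if not cands:
            return _REJECT
        new_fg = _reassign(enc, rows, cands)
        if not (2 <= new_fg.sum() <= n - 2):
            return _REJECT
        if (new_fg == fg).all():
            break
        fg = new_fg
    constraints, net = _finalized_pattern(
        enc, rows[fg], rows[~fg], cfg, exclude_columns
    )
    if not constraints or net < cfg.minnat:
        return _REJECT
    fg_ids = frozenset(ids[i] for i in rows[fg])
    return PartitionResult(fg_ids, constraints, net, True)


def sample_partition(
    aln: ProfileAlignment,
    cfg: InferenceConfig,
    candidate_ids: Iterable[str] | None = None,
    exclude_columns: Iterable[int] = (),
    rng: np.random.Generator | None = None,
    init: str = "random",
) -> PartitionResult:
    """One seeded coordinate-ascent run splitting off a foreground cluster.

    Starts from a random split of the candidate records (or the
    deterministic spectral split with ``init="spectral"``), alternates
    pattern reselection and membership reassignment for at most
    ``n_sweeps`` sweeps (stopping early at a fixed point), then applies
    the penalized ``minnat`` acceptance test.  ``n_sweeps=0`` scores the
    initial split once.
    """
    ids = np.array(aln.ids())
    if candidate_ids is None:
        rows = np.arange(len(ids))
    else:
        wanted = set(candidate_ids)
        rows = np.array([i for i, x in enumerate(ids) if x in wanted])
    if len(rows) < 4:
        raise ValueError("partition sampling needs at least 4 records")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    return _sample_partition_rows(
        aln.encoded(), rows, ids, cfg, rng, exclude_columns, init=init
    )


# ---------------------------------------------------------------------------
# hierarchy inference


def infer_hierarchy(
    aln: ProfileAlignment, cfg: InferenceConfig, max_depth: int = 4
) -> ConstraintHierarchy:
    """Recursive binary constraint-based clustering of an alignment.

    At each node the best of ``n_restarts`` partition-sampling runs (by
    penalized pattern weight) proposes a split; when both sides pass the
    ``minnat`` test they become children and are split further, down to
    ``max_depth``.  Columns constrained by an ancestor are excluded from
    descendant searches, so each node's constraints are disjoint from its
    ancestors'.
    """
    enc = aln.encoded()
    ids = np.array(aln.ids())
    nodes = {"root": ClusterNode("root", "root", None, [])}
    memberships = {"root": tuple(sorted(ids))}
    serial = 0

    def split(node_id: str, rows: np.ndarray, depth: int, excluded: frozenset[int]):
        nonlocal serial
        if depth >= max_depth or len(rows) < 4:
            return
        serial += 1
        node_serial = serial
        best: PartitionResult | None = None
        for r in range(cfg.n_restarts):
            rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, node_serial, r])
            )
            init = "spectral" if r == 0 else "random"
            res = _sample_partition_rows(
                enc, rows, ids, cfg, rng, excluded, init=init
            )
            if res.accepted and (best is None or res.net_lpr > best.net_lpr):
                best = res
        if best is None:
            return
        in_fg = np.isin(ids[rows], sorted(best.fg_ids))
        fg_rows, bg_rows = rows[in_fg], rows[~in_fg]
        bg_constraints, bg_net = _finalized_pattern(
            enc, bg_rows, fg_rows, cfg, excluded
        )
        if not bg_constraints or bg_net < cfg.minnat:
            # complement indistinct: attach the foreground only
            sides = [(fg_rows, best.constraints)]
        else:
            sides = [(fg_rows, best.constraints), (bg_rows, bg_constraints)]
        prefix = "" if node_id == "root" else node_id + "."
        for i, (side_rows, constraints) in enumerate(sides):
            child_id = f"{prefix}c{i}"
            nodes[child_id] = ClusterNode(child_id, child_id, node_id, constraints)
            memberships[child_id] = tuple(sorted(ids[side_rows]))
            child_excluded = excluded | {c.column for c in constraints}
            split(child_id, side_rows, depth + 1, child_excluded)

    split("root", np.arange(len(ids)), 0, frozenset())
    h = ConstraintHierarchy(nodes, aln.n_columns, memberships=memberships)
    h.total_lpr = total_lpr(h, aln)
    return h


def total_lpr(h: ConstraintHierarchy, aln: ProfileAlignment) -> float:
    """Total pattern-based evidence of a hierarchy, in nats.

    Sums, over every non-root node with recorded members, the stored
    constraints' contrasts recomputed against the node's members versus
    all other sequences; negative column contributions are dropped, so
    the total is nonnegative.
    """
    if h.memberships is None:
        raise ModelError("total_lpr requires node memberships")
    enc = aln.encoded()
    ids = np.array(aln.ids())
    total = 0.0
    for node in h.walk():
        if node.id == h.root_id or not node.constraints:
            continue
        members = set(h.memberships.get(node.id, ()))
        if not members or len(members) == len(ids):
            continue
        fg_rows = np.array([i for i, x in enumerate(ids) if x in members])
        bg_rows = np.array([i for i, x in enumerate(ids) if x not in members])
        cf = _column_counts(enc, fg_rows)
        cb = _column_counts(enc, bg_rows)
        for c in node.constraints:
            if cf[c.column].sum() <= 0 or cb[c.column].sum() <= 0:
                continue
            w = column_contrast(
                cf[c.column], cb[c.column], c.residue_set, 1.0
            )
            if w > 0:
                total += w
    return float(total)


# ---------------------------------------------------------------------------
# consensus across runs


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def consensus_hierarchy(
    runs: Sequence[ConstraintHierarchy],
    min_support: float,
    aln: ProfileAlignment,
    cfg: InferenceConfig,
) -> ConstraintHierarchy:
    """Consensus of several inference runs over the same sequences.

    Clusters are pooled across runs and grouped greedily by best
    membership Jaccard, requiring strictly more than 0.5 (so a
    subcluster covering exactly half its parent is never conflated with
    it; largest clusters seed groups first); groups supported by at least
    ``min_support`` of the runs are kept, nested by membership
    containment, and their constraints are re-estimated on the union
    membership against their consensus siblings.
    """
    if len(runs) < 2:
        raise ValueError("consensus requires at least 2 runs")
    id_sets = []
    for h in runs:
        if h.memberships is None:
            raise ValueError("runs must carry memberships")
        id_sets.append(frozenset(h.memberships[h.root_id]))
    if len(set(id_sets)) != 1:
        raise ValueError("runs cover different sequence id sets")
    all_ids = id_sets[0]

    entries = []
    for r, h in enumerate(runs):
        for nid in h.cluster_ids():
            members = frozenset(h.memberships.get(nid, ()))
            if members:
                entries.append((r, nid, members))
    entries.sort(key=lambda e: (-len(e[2]), e[0], e[1]))

    groups: list[dict] = []
    for r, nid, members in entries:
        best, best_j = None, 0.5
        for g in groups:
            j = _jaccard(members, g["rep"])
            if j > best_j:
                best, best_j = g, j
        if best is not None:
            best["runs"].add(r)
            best["union"] |= members
        else:
            groups.append({"rep": members, "runs": {r}, "union": set(members)})

    kept = [g for g in groups if len(g["runs"]) / len(runs) >= min_support]
    kept.sort(key=lambda g: -len(g["union"]))

    enc = aln.encoded()
    ids = np.array(aln.ids())
    nodes = {"root": ClusterNode("root", "root", None, [])}
    memberships: dict[str, tuple[str, ...]] = {"root": tuple(sorted(all_ids))}
    placed: list[tuple[str, set]] = [("root", set(all_ids))]
    child_count: dict[str, int] = {}

    for g in kept:
        union = g["union"]
        parent_id, parent_members = "root", set(all_ids)
        for pid, pmem in placed:
            if pid == "root":
                continue
            if len(pmem) > len(union) and len(union & pmem) / len(union) >= 0.5:
                if len(pmem) < len(parent_members):
                    parent_id, parent_members = pid, pmem
        idx = child_count.get(parent_id, 0)
        child_count[parent_id] = idx + 1
        prefix = "" if parent_id == "root" else parent_id + "."
        child_id = f"{prefix}c{idx}"
        excluded = frozenset(
            c.column
            for nid in ConstraintHierarchy(
                dict(nodes), aln.n_columns
            ).path_to_root(parent_id)
            for c in nodes[nid].constraints
        )
        bg = parent_members - union
        if not bg:
            bg = all_ids - union
        fg_rows = np.array([i for i, x in enumerate(ids) if x in union])
        bg_rows = np.array([i for i, x in enumerate(ids) if x in bg])
        constraints, _ = _finalized_pattern(enc, fg_rows, bg_rows, cfg, excluded)
        nodes[child_id] = ClusterNode(child_id, child_id, parent_id, constraints)
        memberships[child_id] = tuple(sorted(union))
        placed.append((child_id, set(union)))

    h = ConstraintHierarchy(nodes, aln.n_columns, memberships=memberships)
    h.total_lpr = total_lpr(h, aln)
    return h


__all__ = [
    "Constraint",
    "ClusterNode",
    "ConstraintHierarchy",
    "InferenceConfig",
    "ModelError",
    "PartitionResult",
    "column_contrast",
    "select_pattern",
    "sample_partition",
    "infer_hierarchy",
    "total_lpr",
    "consensus_hierarchy",
]
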