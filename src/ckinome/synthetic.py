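"""Ground-truth-known synthetic data for every pipeline stage.

The generator emulates the statistical structure the analysis assumes: a
hierarchically clustered profile alignment in which each cluster plants
weighted column/residue-set constraints on top of its ancestors'
(members carry a constrained residue with probability ``fidelity``, else
a background draw), organism assignments drawn from each cluster's
taxonomic emergence point, coding-gene exon structures that place shared
introns at known (column, phase) pairs, clade-specific DE-insert length
distributions between the αD and αE helices, and per-clade protein
domain architectures.  Everything is deterministic given a seed, and the
planted truth travels alongside the data so recovery can be measured
exactly.

What this does *not* emulate: phylogenetic sequence evolution (sites are
independent draws, not the outcome of a substitution process on a tree),
alignment error, or compositional biases of real kinase domains
(background is uniform over the 20 amino acids by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import AMINO_ACIDS, ProfileAlignment, SequenceRecord
from .gene_structure import GeneStructure
from .inference import ClusterNode, Constraint, ConstraintHierarchy
from .taxonomy import TaxonomyTable

#: default anchor columns of the 200-column synthetic kinase-domain profile
DEFAULT_ANCHORS = {
    "beta3-K": 15,
    "alphaD-end": 95,
    "alphaE-start": 98,
    "DFG-D": 150,
    "alphaH": 180,
}


@dataclass
class SyntheticTruth:
    """Planted ground truth for one synthetic data set."""

    hierarchy: ConstraintHierarchy
    labels: dict[str, str] = field(default_factory=dict)
    taxa: dict[str, int] = field(default_factory=dict)
    emergence: dict[str, int] = field(default_factory=dict)
    introns: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    loop_model: dict[str, float] = field(default_factory=dict)
    clade_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label in set(self.labels.values()):
            if label not in self.hierarchy.nodes:
                raise ValueError(f"label {label!r} is not a hierarchy node")

    def family_map(self) -> dict[str, str]:
        """sequence id → planted leaf cluster (the 'family')."""
        return dict(self.labels)

    def to_json(self) -> dict:
        return {
            "hierarchy": self.hierarchy.to_json(),
            "labels": self.labels,
            "taxa": self.taxa,
            "emergence": self.emergence,
            "introns": {k: [list(t) for t in v] for k, v in self.introns.items()},
            "loop_model": self.loop_model,
            "clade_map": self.clade_map,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @classmethod
    def from_json(cls, payload: dict) -> "SyntheticTruth":
        return cls(
            hierarchy=ConstraintHierarchy.from_json(payload["hierarchy"]),
            labels=dict(payload["labels"]),
            taxa={k: int(v) for k, v in payload["taxa"].items()},
            emergence={k: int(v) for k, v in payload["emergence"].items()},
            introns={
                k: [tuple(t) for t in v] for k, v in payload["introns"].items()
            },
            loop_model=dict(payload["loop_model"]),
            clade_map=dict(payload["clade_map"]),
        )


# ---------------------------------------------------------------------------
# taxonomy


def make_taxonomy(n_species_per_clade: int = 4) -> TaxonomyTable:
    """A small holozoan-shaped taxonomy with species leaves.

    Internal clades run from the root through Holozoa down to Chordata;
    ``n_species_per_clade`` species hang under each terminal clade
    (Filasterea, Choanoflagellata, Porifera, Cnidaria, Protostomia,
    Chordata).  Node ids are stable small integers, species start at
    1000.
    """
    internal = {
        1: (1, "root"),
        2: (1, "Opisthokonta"),
        3: (2, "Holozoa"),
        4: (3, "Filasterea"),
        5: (3, "Choanoflagellata"),
        6: (3, "Metazoa"),
        7: (6, "Porifera"),
        8: (6, "Cnidaria"),
        9: (6, "Bilateria"),
        10: (9, "Protostomia"),
        11: (9, "Deuterostomia"),
        12: (11, "Chordata"),
    }
    parent = {nid: par for nid, (par, _) in internal.items()}
    name = {nid: nm for nid, (_, nm) in internal.items()}
    rank = {nid: "clade" for nid in internal}
    rank[1] = "no rank"
    species_parents = [4, 5, 7, 8, 10, 12]
    next_id = 1000
    for clade in species_parents:
        for k in range(n_species_per_clade):
            parent[next_id] = clade
            name[next_id] = f"{name[clade]} species {k + 1}"
            rank[next_id] = "species"
            next_id += 1
    return TaxonomyTable(parent, rank, name)


# ---------------------------------------------------------------------------
# hierarchy and sequences


def make_hierarchy(
    n_supers: int = 2,
    subs_per_super: int = 2,
    constraints_per_node: int = 5,
    weight_low: float = 2.0,
    weight_high: float = 6.0,
    n_columns: int = 200,
    seed: int = 0,
) -> ConstraintHierarchy:
    """Plant a nested constraint hierarchy.

    Constraint columns are sampled without replacement across the whole
    tree (so ancestor and descendant constraints never collide); residue
    sets have size 1–2 and weights are uniform in
    [``weight_low``, ``weight_high``].
    """
    n_nodes = n_supers * (1 + subs_per_super)
    needed = n_nodes * constraints_per_node
    if needed > n_columns:
        raise ValueError(
            f"{needed} constrained columns needed but only {n_columns} available"
        )
    rng = np.random.default_rng(seed)
    columns = rng.choice(n_columns, size=needed, replace=False)
    col_iter = iter(int(c) for c in columns)

    def draw_constraints() -> list[Constraint]:
        out = []
        for _ in range(constraints_per_node):
            size = int(rng.integers(1, 3))
            residues = rng.choice(list(AMINO_ACIDS), size=size, replace=False)
            weight = float(rng.uniform(weight_low, weight_high))
            out.append(Constraint(next(col_iter), frozenset(residues), weight))
        return out

    nodes = {"root": ClusterNode("root", "root", None, [])}
    for i in range(1, n_supers + 1):
        sid = f"sg{i}"
        nodes[sid] = ClusterNode(sid, sid, "root", draw_constraints())
        for j in range(1, subs_per_super + 1):
            fid = f"{sid}.fam{j}"
            nodes[fid] = ClusterNode(fid, fid, sid, draw_constraints())
    return ConstraintHierarchy(nodes, n_columns)


def make_sequences(
    h: ConstraintHierarchy,
    n_per_leaf: int = 50,
    fidelity: float = 0.95,
    background: Sequence[float] | str = "uniform",
    seed: int = 0,
) -> tuple[ProfileAlignment, SyntheticTruth]:
    """Draw member sequences for every leaf cluster.

    At each effective-constraint column of its leaf, a sequence carries a
    residue from the constraint's set with probability ``fidelity`` and
    a background draw otherwise; unconstrained columns are pure
    background.  No gaps are generated.
    """
    if not 0.5 < fidelity <= 1.0:
        raise ValueError("fidelity must be in (0.5, 1]")
    if isinstance(background, str):
        if background != "uniform":
            raise ValueError("background must be 'uniform' or a 20-vector")
        bg = np.full(20, 1.0 / 20)
    else:
        bg = np.asarray(background, dtype=float)
        bg = bg / bg.sum()
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    records = []
    labels: dict[str, str] = {}
    for leaf in sorted(h.leaves()):
        eff = h.effective_constraints(leaf)
        constrained = {c.column: sorted(c.residue_set) for c in eff}
        for k in range(n_per_leaf):
            seq = aa[rng.choice(20, size=h.n_columns, p=bg)]
            for col, residues in constrained.items():
                if rng.random() < fidelity:
                    seq[col] = residues[int(rng.integers(len(residues)))]
            seq_id = f"{leaf}_s{k:03d}"
            inserts = tuple([""] * (h.n_columns + 1))
            records.append(SequenceRecord(seq_id, "".join(seq), inserts))
            labels[seq_id] = leaf
    aln = ProfileAlignment(tuple(records), h.n_columns)
    truth = SyntheticTruth(hierarchy=h, labels=labels)
    return aln, truth


# ---------------------------------------------------------------------------
# taxa


def _lca(tax: TaxonomyTable, nodes: Sequence[int]) -> int:
    common = None
    for n in nodes:
        lin = tax.lineage(n)
        common = lin if common is None else [a for a, b in zip(common, lin) if a == b]
    return common[-1]


def make_taxa(
    aln: ProfileAlignment,
    truth: SyntheticTruth,
    taxonomy: TaxonomyTable,
    emergence_map: Mapping[str, int],
    seed: int = 0,
) -> tuple[ProfileAlignment, SyntheticTruth]:
    """Assign organisms according to cluster emergence points.

    Each sequence's taxon is drawn uniformly from the species leaves
    descending from its leaf cluster's emergence node; internal clusters
    get the least common ancestor of their leaves' emergence nodes
    recorded in the returned truth.
    """
    for node in emergence_map.values():
        if node not in taxonomy.parent:
            raise ValueError(f"emergence node {node} not in taxonomy")
    rng = np.random.default_rng(seed)
    leaf_species = {
        cluster: taxonomy.leaves_under(node)
        for cluster, node in emergence_map.items()
    }
    records = []
    taxa: dict[str, int] = {}
    for rec in aln:
        label = truth.labels.get(rec.id)
        if label is None or label not in leaf_species:
            records.append(rec)
            continue
        species = leaf_species[label]
        ox = int(species[int(rng.integers(len(species)))])
        taxa[rec.id] = ox
        records.append(
            SequenceRecord(rec.id, rec.match_residues, rec.inserts, ox)
        )
    emergence = dict(emergence_map)
    h = truth.hierarchy
    for nid in h.cluster_ids():
        if nid in emergence:
            continue
        below = [
            emergence_map[leaf]
            for leaf in h.leaves()
            if nid in h.path_to_root(leaf) and leaf in emergence_map
        ]
        if below:
            emergence[nid] = _lca(taxonomy, below)
    new_truth = SyntheticTruth(
        hierarchy=truth.hierarchy,
        labels=truth.labels,
        taxa=taxa,
        emergence=emergence,
        introns=truth.introns,
        loop_model=truth.loop_model,
        clade_map=truth.clade_map,
    )
    new_aln = ProfileAlignment(tuple(records), aln.n_columns, dict(aln.column_labels))
    return new_aln, new_truth


# ---------------------------------------------------------------------------
# DE inserts and gene structures


def make_de_inserts(
    aln: ProfileAlignment,
    truth: SyntheticTruth,
    d_end: int,
    long_mean: float = 70.0,
    short_mean: float = 4.0,
    seed: int = 0,
) -> tuple[ProfileAlignment, SyntheticTruth]:
    """Add clade-specific DE-insert segments after the αD-end column.

    longDE-clade sequences receive Poisson(``long_mean``)-length inserts,
    shortDE Poisson(``short_mean``); residues are uniform.  A zero mean
    leaves the loop with its match-state residues only.
    """
    rng = np.random.default_rng(seed)
    aa = list(AMINO_ACIDS)
    means = {"longDE": long_mean, "shortDE": short_mean}
    records = []
    for rec in aln:
        clade = truth.clade_map.get(truth.labels.get(rec.id, ""), None)
        if clade not in means:
            records.append(rec)
            continue
        length = int(rng.poisson(means[clade]))
        segment = "".join(aa[int(i)] for i in rng.integers(0, 20, size=length))
        inserts = list(rec.inserts)
        inserts[d_end + 1] = inserts[d_end + 1] + segment
        records.append(
            SequenceRecord(rec.id, rec.match_residues, tuple(inserts), rec.organism_id)
        )
    truth.loop_model = dict(means)
    new_aln = ProfileAlignment(tuple(records), aln.n_columns, dict(aln.column_labels))
    return new_aln, truth


def make_gene_structures(
    aln: ProfileAlignment,
    truth: SyntheticTruth,
    shared_intron_spec: Mapping[str, Sequence[tuple[int, int]]],
    exon_noise: float = 0.0,
    seed: int = 0,
) -> list[GeneStructure]:
    """Plant exon structures so mapped introns hit given (column, phase).

    ``shared_intron_spec`` is keyed by clade label (via the truth's
    clade map); every sequence of a clade receives the clade's planted
    introns, placed at the coding position that makes the intron map
    back to the requested match column with the requested phase.  Random
    extra introns are added at a Poisson(``exon_noise``) rate per
    sequence.  Single-exon genes (no boundaries) simply have no introns.
    """
    rng = np.random.default_rng(seed)
    genes = []
    for rec in aln:
        clade = truth.clade_map.get(truth.labels.get(rec.id, ""), None)
        planted = list(shared_intron_spec.get(clade, ()))
        walk = list(rec.residue_walk())
        col_to_residue = {c: p for p, c in enumerate(walk) if c is not None}
        total_nt = 3 * len(walk)
        cuts = set()
        for column, phase in planted:
            p = col_to_residue.get(column)
            if p is None:
                continue
            cut = 3 * p + phase
            if 0 < cut < total_nt:
                cuts.add(cut)
        for _ in range(int(rng.poisson(exon_noise))):
            cut = int(rng.integers(1, total_nt))
            cuts.add(cut)
        bounds = [0] + sorted(cuts) + [total_nt]
        lengths = tuple(b - a for a, b in zip(bounds[:-1], bounds[1:]))
        genes.append(GeneStructure(rec.id, lengths))
    truth.introns = {k: [tuple(t) for t in v] for k, v in shared_intron_spec.items()}
    return genes


# ---------------------------------------------------------------------------
# domain annotations


def make_domains(
    aln: ProfileAlignment,
    truth: SyntheticTruth,
    arch_map: Mapping[str, Sequence[str]] | None = None,
    rare_domain: tuple[str, float] = ("FN3", 0.02),
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic per-sequence domain annotations (CDD-style TSV rows).

    Default architectures: shortDE clades carry the cytoplasmic
    SH3-SH2-kinase core, longDE clades a receptor-like
    TM + IG×3 + kinase architecture (the repeated IG exercising
    consecutive-repeat compression).  A rare extra domain is inserted at
    a low rate to exercise display-threshold filtering.
    """
    if arch_map is None:
        arch_map = {
            "shortDE": ["SH3", "SH2", "Pkinase_Tyr"],
            "longDE": ["TM", "IG", "IG", "IG", "Pkinase_Tyr"],
        }
    rng = np.random.default_rng(seed)
    rare_name, rare_rate = rare_domain
    rows = []
    for rec in aln:
        clade = truth.clade_map.get(truth.labels.get(rec.id, ""), None)
        arch = list(arch_map.get(clade, ["Pkinase_Tyr"]))
        if clade is not None and rng.random() < rare_rate:
            arch.insert(1, rare_name)
        pos = 1
        for dom in arch:
            rows.append(
                {
                    "sequence_id": rec.id,
                    "domain": dom,
                    "start": pos,
                    "end": pos + 49,
                }
            )
            pos += 50
    return pd.DataFrame(rows, columns=["sequence_id", "domain", "start", "end"])


# ---------------------------------------------------------------------------
# the default preset


#: emergence points cycled over leaf clusters, oldest first
_EMERGENCE_CYCLE = (3, 6, 9, 12)  # Holozoa, Metazoa, Bilateria, Chordata


@dataclass
class PresetBundle:
    """Everything one synthetic study needs, with its planted truth."""

    aln: ProfileAlignment
    truth: SyntheticTruth
    taxonomy: TaxonomyTable
    genes: list[GeneStructure]
    domains: pd.DataFrame
    anchors: dict[str, int]


def default_preset(
    seed: int = 0,
    n_supers: int = 2,
    subs_per_super: int = 2,
    n_per_leaf: int = 50,
    constraints_per_node: int = 5,
    n_columns: int = 200,
    fidelity: float = 0.95,
    long_mean: float = 70.0,
    short_mean: float = 4.0,
    exon_noise: float = 0.5,
    with_artifacts: bool = False,
) -> PresetBundle:
    """The study's default synthetic conditions.

    Two superclusters of two families each, 50 sequences per family at
    fidelity 0.95 over a 200-column profile with 5 constraints per node.
    The first supercluster is the shortDE clade, the second longDE
    (Poisson(4) vs Poisson(70) DE inserts); longDE families share a
    planted phase-2 intron at the αH anchor column.  ``with_artifacts``
    appends fragmentary and duplicate records so the filtering stages
    have work to do.
    """
    anchors = dict(DEFAULT_ANCHORS)
    if n_columns != 200:
        scale = n_columns / 200.0
        anchors = {k: int(v * scale) for k, v in DEFAULT_ANCHORS.items()}
    tax = make_taxonomy()
    h = make_hierarchy(
        n_supers=n_supers,
        subs_per_super=subs_per_super,
        constraints_per_node=constraints_per_node,
        n_columns=n_columns,
        seed=seed,
    )
    aln, truth = make_sequences(
        h, n_per_leaf=n_per_leaf, fidelity=fidelity, seed=seed + 1
    )
    leaves = sorted(h.leaves())
    truth.clade_map = {}
    for nid in h.cluster_ids():
        top = h.path_to_root(nid)[1]
        truth.clade_map[nid] = "shortDE" if top == "sg1" else "longDE"
    aln, truth = make_de_inserts(
        aln,
        truth,
        d_end=anchors["alphaD-end"],
        long_mean=long_mean,
        short_mean=short_mean,
        seed=seed + 2,
    )
    emergence = {
        leaf: _EMERGENCE_CYCLE[i % len(_EMERGENCE_CYCLE)]
        for i, leaf in enumerate(leaves)
    }
    aln, truth = make_taxa(aln, truth, tax, emergence, seed=seed + 3)
    intron_spec = {
        "longDE": [(anchors["alphaH"], 2)],
        "shortDE": [(60, 0)],
    }
    genes = make_gene_structures(
        aln, truth, intron_spec, exon_noise=exon_noise, seed=seed + 4
    )
    domains = make_domains(aln, truth, seed=seed + 5)
    aln.column_labels = {col: label for label, col in anchors.items()}
    if with_artifacts:
        aln = _add_artifacts(aln, anchors, seed=seed + 6)
    return PresetBundle(aln, truth, tax, genes, domains, anchors)


def _add_artifacts(
    aln: ProfileAlignment, anchors: dict[str, int], seed: int
) -> ProfileAlignment:
    """Append two fragmentary records and two near-duplicates."""
    rng = np.random.default_rng(seed)
    records = list(aln.records)
    donors = [records[int(i)] for i in rng.choice(len(records), 4, replace=False)]
    # fragments: gap out everything from the DFG anchor onward
    for k, donor in enumerate(donors[:2]):
        cut = anchors["DFG-D"]
        match = donor.match_residues[:cut] + "-" * (aln.n_columns - cut)
        inserts = list(donor.inserts[: cut + 1]) + [""] * (aln.n_columns - cut)
        records.append(
            SequenceRecord(
                f"frag{k}", match, tuple(inserts), donor.organism_id
            )
        )
    for k, donor in enumerate(donors[2:]):
        records.append(
            SequenceRecord(
                f"dup{k}", donor.match_residues, donor.inserts, donor.organism_id
            )
        )
    return ProfileAlignment(tuple(records), aln.n_columns, dict(aln.column_labels))


__all__ = [
    "DEFAULT_ANCHORS",
    "SyntheticTruth",
    "PresetBundle",
    "make_taxonomy",
    "make_hierarchy",
    "make_sequences",
    "make_taxa",
    "make_de_inserts",
    "make_gene_structures",
    "make_domains",
    "default_preset",
]
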