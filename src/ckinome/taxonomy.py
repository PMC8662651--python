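"""Taxonomy parsing, lineage tracing, and conservation tables.

Reads the NCBI taxdump dialect (fields separated by ``\\t|\\t``, lines
terminated by ``\\t|``), traces organism identifiers (OX) back to the
root along parent pointers, and builds cluster × taxon conservation
matrices: a cell is marked when at least one sequence scoring at or
above the cut-off for the cluster descends from the taxon.  A second,
relaxed cut-off (0.6 against the optimal 0.7) gives a strictly more
permissive matrix, useful for judging borderline ancient family calls.

Also hosts the per-cluster protein-domain frequency table used to survey
domain architectures (IG repeats, SH2/SH3, fibronectin, TM helices, …)
across constraint-defined clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment import ProfileAlignment
from .scoring import ClassificationResult

logger = logging.getLogger("ckinome")


class TaxdumpFormatError(ValueError):
    """Raised on a malformed taxdump line; carries the line number."""


_SEP = "\t|\t"
_TERM = "\t|"


@dataclass
class TaxonomyTable:
    """Parent/rank/name maps keyed by integer taxon node id.

    Follows the NCBI convention that the root is its own parent.
    """

    parent: dict[int, int]
    rank: dict[int, str] = field(default_factory=dict)
    name: dict[int, str] = field(default_factory=dict)

    def lineage(self, ox: int) -> list[int]:
        """Node ids from the root down to ``ox`` (inclusive); cycle-safe."""
        if ox not in self.parent:
            raise KeyError(f"unknown taxon id {ox}")
        path = [ox]
        seen = {ox}
        cur = ox
        while True:
            up = self.parent[cur]
            if up == cur:
                break
            if up in seen:
                raise ValueError(f"cycle in taxonomy at node {up}")
            seen.add(up)
            path.append(up)
            cur = up
        return path[::-1]

    def descendants(self, node: int) -> set[int]:
        """All nodes below ``node``, including itself."""
        children: dict[int, list[int]] = {}
        for child, par in self.parent.items():
            if child != par:
                children.setdefault(par, []).append(child)
        out = set()
        stack = [node]
        while stack:
            cur = stack.pop()
            out.add(cur)
            stack.extend(children.get(cur, []))
        return out

    def leaves_under(self, node: int) -> list[int]:
        desc = self.descendants(node)
        parents = {self.parent[d] for d in desc if self.parent[d] != d}
        return sorted(d for d in desc if d not in parents)


def _split_dmp(line: str, path: str, lineno: int) -> list[str]:
    body = line.rstrip("\n")
    if not body.rstrip().endswith("|"):
        raise TaxdumpFormatError(f"{path}:{lineno}: line not terminated by '\t|'")
    if body.endswith(_TERM):
        body = body[: -len(_TERM)]
    else:
        body = body.rstrip()[:-1].rstrip("\t")
    return body.split(_SEP)


def parse_taxdump(nodes_path: str | Path, names_path: str | Path) -> TaxonomyTable:
    """Parse nodes.dmp / names.dmp into a :class:`TaxonomyTable`.

    Only "scientific name" rows of the names file are used; a node
    without one keeps a null name (with a warning).
    """
    parent: dict[int, int] = {}
    rank: dict[int, str] = {}
    with open(nodes_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = _split_dmp(line, str(nodes_path), lineno)
            if len(fields) < 2:
                raise TaxdumpFormatError(
                    f"{nodes_path}:{lineno}: expected >=2 fields, got {len(fields)}"
                )
            try:
                node_id, parent_id = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise TaxdumpFormatError(
                    f"{nodes_path}:{lineno}: non-integer node ids"
                ) from exc
            parent[node_id] = parent_id
            if len(fields) > 2:
                rank[node_id] = fields[2]
    name: dict[int, str] = {}
    with open(names_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = _split_dmp(line, str(names_path), lineno)
            if len(fields) < 4:
                raise TaxdumpFormatError(
                    f"{names_path}:{lineno}: expected 4 fields, got {len(fields)}"
                )
            if fields[3] != "scientific name":
                continue
            node_id = int(fields[0])
            if node_id in parent:
                name[node_id] = fields[1]
    for node_id in parent:
        if node_id not in name:
            logger.warning("taxon %d has no scientific name", node_id)
    return TaxonomyTable(parent, rank, name)


def write_taxdump(
    tax: TaxonomyTable, nodes_path: str | Path, names_path: str | Path
) -> None:
    """Write a table back out in the taxdump dialect (for synthetic data)."""
    with open(nodes_path, "w") as fh:
        for node_id in sorted(tax.parent):
            rank = tax.rank.get(node_id, "no rank")
            fh.write(f"{node_id}{_SEP}{tax.parent[node_id]}{_SEP}{rank}{_TERM}\n")
    with open(names_path, "w") as fh:
        for node_id in sorted(tax.parent):
            nm = tax.name.get(node_id, f"node {node_id}")
            fh.write(f"{node_id}{_SEP}{nm}{_SEP}{_SEP}scientific name{_TERM}\n")


def lineage(ox: int, tax: TaxonomyTable) -> list[int]:
    """Free-function alias of :meth:`TaxonomyTable.lineage`."""
    return tax.lineage(ox)


@dataclass
class ConservationMatrix:
    """Boolean cluster × taxon presence table at a given cut-off."""

    table: pd.DataFrame
    cutoff: float

    def named(self, tax: TaxonomyTable) -> pd.DataFrame:
        renamed = self.table.copy()
        renamed.columns = [
            tax.name.get(t, str(t)) for t in self.table.columns
        ]
        return renamed


def conservation_matrix(
    result: ClassificationResult,
    aln: ProfileAlignment,
    tax: TaxonomyTable,
    target_taxa: Sequence[int],
    cutoff: float,
) -> ConservationMatrix:
    """Cluster presence/absence across target taxa.

    Entry (cluster, taxon) is True when some sequence scoring >= the
    cut-off for the cluster has the taxon in its lineage.  Sequences
    without an organism id are skipped (their count is logged).
    """
    for t in target_taxa:
        if t not in tax.parent:
            raise KeyError(f"target taxon {t} not in taxonomy")
    lineages: dict[str, set[int]] = {}
    skipped = 0
    for rec in aln:
        if rec.organism_id is None:
            skipped += 1
            continue
        try:
            lineages[rec.id] = set(tax.lineage(rec.organism_id))
        except KeyError:
            skipped += 1
    if skipped:
        logger.info("conservation: %d sequences without usable OX skipped", skipped)
    clusters = list(result.scores.columns)
    table = pd.DataFrame(False, index=clusters, columns=list(target_taxa))
    hits = result.scores >= cutoff
    for seq_id, lin in lineages.items():
        if seq_id not in hits.index:
            continue
        seq_hits = hits.loc[seq_id]
        for taxon in target_taxa:
            if taxon in lin:
                table.loc[seq_hits[seq_hits].index, taxon] = True
    return ConservationMatrix(table, cutoff)


@dataclass
class DomainFrequencies:
    """Full and display (>= min_fraction) per-cluster domain tables."""

    full: pd.DataFrame
    display: pd.DataFrame
    min_fraction: float


def _collapse_repeats(domains: Sequence[str]) -> list[str]:
    out: list[str] = []
    for d in domains:
        if not out or out[-1] != d:
            out.append(d)
    return out


def domain_frequency(
    annotations: pd.DataFrame | str | Path,
    result: ClassificationResult,
    min_fraction: float = 0.03,
    synonyms: Mapping[str, str] | None = None,
) -> DomainFrequencies:
    """Per-cluster domain frequencies from a precomputed annotation table.

    ``annotations`` is a TSV or DataFrame with columns sequence_id,
    domain, start, end.  Consecutive identical domains within one protein
    are compressed to a single occurrence before counting, and a
    user-supplied synonym map is applied first (the full table keeps
    every domain; the display table omits those below ``min_fraction``
    of a cluster's members).
    """
    if not isinstance(annotations, pd.DataFrame):
        annotations = pd.read_csv(annotations, sep="\t", comment="#")
    synonyms = dict(synonyms or {})
    ann = annotations.copy()
    ann["domain"] = ann["domain"].map(lambda d: synonyms.get(d, d))
    per_seq: dict[str, set[str]] = {}
    for seq_id, grp in ann.sort_values(["sequence_id", "start"]).groupby(
        "sequence_id"
    ):
        per_seq[seq_id] = set(_collapse_repeats(list(grp["domain"])))
    rows = []
    for cluster in result.scores.columns:
        members = result.members(cluster)
        if not members:
            continue
        counts: dict[str, int] = {}
        for m in members:
            for d in per_seq.get(m, ()):
                counts[d] = counts.get(d, 0) + 1
        for d, c in sorted(counts.items()):
            rows.append(
                {
                    "cluster_id": cluster,
                    "domain": d,
                    "fraction": c / len(members),
                    "n_members": len(members),
                }
            )
    full = pd.DataFrame(rows, columns=["cluster_id", "domain", "fraction", "n_members"])
    display = full[full["fraction"] >= min_fraction].reset_index(drop=True)
    return DomainFrequencies(full, display, min_fraction)


__all__ = [
    "TaxdumpFormatError",
    "TaxonomyTable",
    "ConservationMatrix",
    "DomainFrequencies",
    "parse_taxdump",
    "write_taxdump",
    "lineage",
    "conservation_matrix",
    "domain_frequency",
]
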