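"""Intron phases from exon lengths, mapped onto alignment columns.

The phase of an intron is the cumulative coding length of the exons
before it, modulo 3 (the codon size): phase 0 lies between codons,
phase 1 after the first nucleotide of a codon, phase 2 after the second.
The number of complete codons before the intron places it on a protein
residue, which a walk along the aligned record's residues converts into
a profile match column (or null, when the intron falls inside an insert
segment or outside the aligned domain).  Introns sharing an identical
(column, phase) pair across families are strong, alignment-independent
evidence of common descent — e.g. a common phase-2 intron at the αH
helix supporting the longDE clade.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment import SequenceRecord


@dataclass(frozen=True)
class GeneStructure:
    """Ordered coding-exon lengths (nt) of one protein's ORF."""

    protein_id: str
    exon_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.exon_lengths:
            raise ValueError("need at least one exon")
        if any(x <= 0 for x in self.exon_lengths):
            raise ValueError("exon lengths must be positive")

    @property
    def partial(self) -> bool:
        """True when the exons do not sum to a whole number of codons."""
        return sum(self.exon_lengths) % 3 != 0


@dataclass(frozen=True)
class IntronRecord:
    """One intron: 0-based index (intron *i* follows exon *i*), phase,
    codon position, and (after mapping) its alignment column."""

    index: int
    phase: int
    codon_position: int
    alignment_column: int | None = None

    @property
    def within_codon_offset(self) -> int:
        return self.phase


def intron_phases(g: GeneStructure) -> list[IntronRecord]:
    """Phases and codon positions of every internal exon boundary.

    phase = (cumulative nt before the intron) mod 3;
    codon_position = floor(cumulative nt / 3), i.e. the 0-based index of
    the residue the intron interrupts (phase 1/2) or precedes (phase 0).
    """
    out = []
    cumulative = 0
    for i, length in enumerate(g.exon_lengths[:-1]):
        cumulative += length
        out.append(IntronRecord(i, cumulative % 3, cumulative // 3))
    return out


def map_intron_to_alignment(
    ir: IntronRecord, rec: SequenceRecord
) -> IntronRecord:
    """Attach the profile match column the intron falls on, if any.

    Walks the record's residues N→C; if the intron's residue lands on a
    match state its column is recorded, otherwise (insert residue, or
    beyond the aligned domain) the column stays null.
    """
    walk = list(rec.residue_walk())
    p = ir.codon_position
    col = walk[p] if p < len(walk) else None
    return replace(ir, alignment_column=col)


def shared_introns(
    records: Iterable[tuple[GeneStructure, SequenceRecord]],
    family_map: Mapping[str, str],
) -> pd.DataFrame:
    """Group mapped introns by identical (alignment column, phase).

    Returns one row per group with the supporting family set and
    sequence count, sorted by family count (then sequence count)
    descending.  Introns that did not map to a match column are
    excluded; their count is reported in the frame's ``attrs``.
    """
    groups: dict[tuple[int, int], dict] = {}
    unmapped = 0
    for gene, rec in records:
        fam = family_map.get(rec.id, "unclassified")
        for ir in intron_phases(gene):
            mapped = map_intron_to_alignment(ir, rec)
            if mapped.alignment_column is None:
                unmapped += 1
                continue
            key = (mapped.alignment_column, mapped.phase)
            g = groups.setdefault(key, {"families": set(), "n_sequences": 0})
            g["families"].add(fam)
            g["n_sequences"] += 1
    rows = [
        {
            "alignment_column": col + 1,
            "phase": phase,
            "families": ",".join(sorted(g["families"])),
            "n_families": len(g["families"]),
            "n_sequences": g["n_sequences"],
        }
        for (col, phase), g in groups.items()
    ]
    frame = pd.DataFrame(
        rows,
        columns=[
            "alignment_column",
            "phase",
            "families",
            "n_families",
            "n_sequences",
        ],
    ).sort_values(
        ["n_families", "n_sequences", "alignment_column"],
        ascending=[False, False, True],
    ).reset_index(drop=True)
    frame.attrs["n_unmapped"] = unmapped
    return frame


# ---------------------------------------------------------------------------
# input readers


def read_exon_table(path: str | Path) -> list[GeneStructure]:
    """Read a TSV of (protein_id, exon_index, length_nt) rows."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for pid, grp in df.groupby("protein_id", sort=True):
        grp = grp.sort_values("exon_index")
        out.append(GeneStructure(str(pid), tuple(int(x) for x in grp["length_nt"])))
    return out


def write_exon_table(genes: Sequence[GeneStructure], path: str | Path) -> None:
    rows = [
        {"protein_id": g.protein_id, "exon_index": i, "length_nt": length}
        for g in genes
        for i, length in enumerate(g.exon_lengths)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gff3_cds(path: str | Path) -> list[GeneStructure]:
    """Extract per-protein CDS segment lengths from a GFF3 file.

    A convenience for when exon tables are not precomputed: CDS features
    (1-based inclusive coordinates) are grouped by their Parent (or ID)
    attribute; minus-strand segments are reversed into ORF order.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    by_parent: dict[str, list] = {}
    for feat in db.features_of_type("CDS"):
        parent = feat.attributes.get("Parent", feat.attributes.get("ID", [feat.id]))[0]
        by_parent.setdefault(parent, []).append(feat)
    out = []
    for parent, feats in sorted(by_parent.items()):
        feats.sort(key=lambda f: f.start)
        if feats[0].strand == "-":
            feats = feats[::-1]
        lengths = tuple(f.end - f.start + 1 for f in feats)
        out.append(GeneStructure(parent, lengths))
    return out


__all__ = [
    "GeneStructure",
    "IntronRecord",
    "intron_phases",
    "map_intron_to_alignment",
    "shared_introns",
    "read_exon_table",
    "write_exon_table",
    "read_gff3_cds",
]
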