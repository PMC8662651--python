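"""Profile-alignment data model and I/O.

The alignment dialect is A2M aligned FASTA: uppercase letters and ``-``
occupy the fixed match columns of the profile (a dash is a deletion
relative to the profile), while lowercase letters are insert-state
residues attached *between* match columns.  ``.`` characters, which some
tools emit to pad insert regions, are ignored on input.  Every record in
an alignment therefore exposes the same number of match columns plus a
ragged set of insert segments, which is the substrate for all downstream
constraint inference, scoring, and loop-length analysis.

Organism identifiers follow the UniProt header convention: an ``OX=<int>``
tag anywhere in the FASTA description.  Columns are 0-based throughout
the library; user-facing tables are written 1-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"

#: integer codes used by :meth:`ProfileAlignment.encoded`
GAP_CODE = 20
UNKNOWN_CODE = 21
RESIDUE_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

_OX_RE = re.compile(r"\bOX=(\d+)\b")


class AlignmentFormatError(ValueError):
    """Raised when an input file violates the A2M profile contract."""


def _encode_char(ch: str) -> int:
    if ch == GAP:
        return GAP_CODE
    return RESIDUE_CODE.get(ch, UNKNOWN_CODE)


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence: fixed match columns plus insert segments.

    ``inserts`` has ``n_columns + 1`` entries: segment *i* holds the
    residues attached before match column *i*; the final entry trails the
    last column.  ``X`` (or any non-standard uppercase letter) is treated
    as unknown: it occupies a match column but never satisfies a
    constraint and never counts as identical during redundancy purging.
    """

    id: str
    match_residues: str
    inserts: tuple[str, ...]
    organism_id: int | None = None

    def __post_init__(self) -> None:
        if len(self.inserts) != len(self.match_residues) + 1:
            raise ValueError(
                f"record {self.id!r}: expected {len(self.match_residues) + 1} "
                f"insert segments, got {len(self.inserts)}"
            )

    @property
    def n_columns(self) -> int:
        return len(self.match_residues)

    @property
    def n_residues(self) -> int:
        """Total residues carried (match non-gaps plus all insert letters)."""
        return sum(ch != GAP for ch in self.match_residues) + sum(
            len(s) for s in self.inserts
        )

    def residue_walk(self) -> Iterator[int | None]:
        """Yield, for each residue in N→C order, its match column or None.

        Insert residues yield ``None``; match-state residues yield their
        0-based column index.  Gap columns are skipped (they carry no
        residue).
        """
        for col in range(self.n_columns):
            for _ in self.inserts[col]:
                yield None
            if self.match_residues[col] != GAP:
                yield col
        for _ in self.inserts[self.n_columns]:
            yield None

    def to_a2m(self) -> str:
        parts = []
        for col in range(self.n_columns):
            parts.append(self.inserts[col].lower())
            parts.append(self.match_residues[col])
        parts.append(self.inserts[self.n_columns].lower())
        return "".join(parts)


@dataclass
class ProfileAlignment:
    """An ordered set of :class:`SequenceRecord` sharing one profile.

    ``column_labels`` optionally maps 0-based column indices to anchor
    names such as ``"beta3-K"`` or ``"alphaD-end"``.
    """

    records: tuple[SequenceRecord, ...]
    n_columns: int
    column_labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.records = tuple(self.records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.n_columns != self.n_columns:
                raise AlignmentFormatError(
                    f"record {rec.id!r} has {rec.n_columns} match columns, "
                    f"expected {self.n_columns}"
                )
            if rec.id in seen:
                raise AlignmentFormatError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
        self._index = {rec.id: i for i, rec in enumerate(self.records)}
        self._encoded: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def get(self, rec_id: str) -> SequenceRecord:
        return self.records[self._index[rec_id]]

    def row(self, rec_id: str) -> int:
        return self._index[rec_id]

    def label_column(self, label: str) -> int:
        """Return the 0-based column carrying an anchor label."""
        for col, name in self.column_labels.items():
            if name == label:
                return col
        raise KeyError(label)

    def encoded(self) -> np.ndarray:
        """(n_records, n_columns) int8 matrix of match-state codes.

        Residues map to 0–19 in :data:`AMINO_ACIDS` order, gaps to
        :data:`GAP_CODE`, unknowns to :data:`UNKNOWN_CODE`.  Cached.
        """
        if self._encoded is None:
            mat = np.empty((len(self.records), self.n_columns), dtype=np.int8)
            for i, rec in enumerate(self.records):
                mat[i] = [_encode_char(ch) for ch in rec.match_residues]
            self._encoded = mat
        return self._encoded

    def subset(self, ids: Iterable[str]) -> "ProfileAlignment":
        """New alignment retaining ``ids`` in their original order."""
        wanted = set(ids)
        kept = tuple(rec for rec in self.records if rec.id in wanted)
        return ProfileAlignment(kept, self.n_columns, dict(self.column_labels))


def _split_a2m(seq: str) -> tuple[str, list[str]]:
    match_chars: list[str] = []
    inserts: list[str] = [""]
    for ch in seq:
        if ch == ".":
            continue
        if ch == GAP or ch.isupper():
            match_chars.append(ch)
            inserts.append("")
        elif ch.islower():
            inserts[-1] += ch.upper()
        else:
            raise AlignmentFormatError(f"illegal alignment character {ch!r}")
    return "".join(match_chars), inserts


def read_a2m(path: str | Path) -> ProfileAlignment:
    """Read an A2M aligned FASTA file into a :class:`ProfileAlignment`.

    The uppercase+dash character count must be identical across records;
    a violation raises :class:`AlignmentFormatError` naming the offending
    record.  ``OX=<int>`` tags are parsed into ``organism_id``.
    """
    records: list[SequenceRecord] = []
    n_columns: int | None = None
    for entry in SeqIO.parse(str(path), "fasta"):
        match, inserts = _split_a2m(str(entry.seq))
        if n_columns is None:
            n_columns = len(match)
        elif len(match) != n_columns:
            raise AlignmentFormatError(
                f"record {entry.id!r} has {len(match)} match columns, "
                f"expected {n_columns}"
            )
        m = _OX_RE.search(entry.description)
        organism_id = int(m.group(1)) if m else None
        records.append(
            SequenceRecord(entry.id, match, tuple(inserts), organism_id)
        )
    if n_columns is None:
        raise AlignmentFormatError(f"no FASTA records in {path}")
    return ProfileAlignment(tuple(records), n_columns)


def write_a2m(aln: ProfileAlignment, path: str | Path) -> None:
    """Write A2M; inverse of :func:`read_a2m` on the data model."""
    with open(path, "w") as fh:
        for rec in aln:
            header = rec.id
            if rec.organism_id is not None:
                header += f" OX={rec.organism_id}"
            fh.write(f">{header}\n{rec.to_a2m()}\n")


def filter_fragments(
    aln: ProfileAlignment, first_required: int, last_required: int
) -> ProfileAlignment:
    """Drop records that do not span the required column range.

    A record is fragmentary unless it carries a non-gap match residue at
    or before ``first_required`` *and* at or after ``last_required``
    (the β3-Lys … DFG-Asp span in the kinase-domain profile).
    """
    if not (0 <= first_required <= last_required < aln.n_columns):
        raise ValueError(
            f"required span [{first_required}, {last_required}] out of range "
            f"for {aln.n_columns} columns"
        )
    enc = aln.encoded()
    nongap = enc != GAP_CODE
    head = nongap[:, : first_required + 1].any(axis=1)
    tail = nongap[:, last_required:].any(axis=1)
    keep = head & tail
    kept = tuple(rec for rec, k in zip(aln.records, keep) if k)
    return ProfileAlignment(kept, aln.n_columns, dict(aln.column_labels))


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Match-column identity over mutually non-gap columns.

    Unknown residues never count as identical.  A pair with zero mutually
    non-gap columns has identity 0.
    """
    ea = np.array([_encode_char(c) for c in a.match_residues])
    eb = np.array([_encode_char(c) for c in b.match_residues])
    both = (ea != GAP_CODE) & (eb != GAP_CODE)
    denom = int(both.sum())
    if denom == 0:
        return 0.0
    same = both & (ea == eb) & (ea < GAP_CODE)
    return float(same.sum()) / denom


def purge_identity(aln: ProfileAlignment, threshold: float) -> ProfileAlignment:
    """Greedy single-pass redundancy purge at a fractional identity.

    Records are scanned in input order; one is dropped when its identity
    to any already-retained record reaches ``threshold``.  The first-seen
    representative of a redundant group is therefore kept, making the
    result a deterministic function of input order.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    if len(aln) == 0:
        return aln
    enc = aln.encoded()
    nongap = enc != GAP_CODE
    residue = enc < GAP_CODE
    retained: list[int] = []
    for i in range(len(aln)):
        redundant = False
        for j in retained:
            both = nongap[i] & nongap[j]
            denom = int(both.sum())
            if denom == 0:
                continue
            same = int((both & (enc[i] == enc[j]) & residue[i]).sum())
            if same / denom >= threshold:
                redundant = True
                break
        if not redundant:
            retained.append(i)
    kept = tuple(aln.records[i] for i in retained)
    return ProfileAlignment(kept, aln.n_columns, dict(aln.column_labels))


__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "UNKNOWN",
    "GAP_CODE",
    "UNKNOWN_CODE",
    "RESIDUE_CODE",
    "AlignmentFormatError",
    "SequenceRecord",
    "ProfileAlignment",
    "read_a2m",
    "write_a2m",
    "filter_fragments",
    "pairwise_identity",
    "purge_identity",
]
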