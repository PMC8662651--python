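"""Cluster-level comparative analyses.

Three views of a classified alignment: the all-versus-all cluster
similarity matrix (mean fit score of cluster A's members against cluster
B's constraints — deliberately non-symmetric, so nested clusters leave a
sub/supercluster signature), comparative sequence-logo data (foreground
versus background residue frequencies with a per-column relative-entropy
divergence), and αD–αE loop lengths (the fast-evolving "DE insert"
between the αD and αE helices whose presence separates the longDE and
shortDE clades of the tyrosine kinome).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from .alignment import AMINO_ACIDS, GAP_CODE, ProfileAlignment
from .inference import ConstraintHierarchy
from .scoring import ClassificationResult, UNCLASSIFIED


def similarity_matrix(
    result: ClassificationResult,
    h: ConstraintHierarchy,
    aln: ProfileAlignment,
) -> pd.DataFrame:
    """All-versus-all cluster similarity.

    Entry (A, B) is the mean fit score against B's effective constraints
    over the sequences classified into A (a sequence belongs to every
    cluster on its assigned path).  Clusters with no classified members
    yield NaN rows.  Because membership requires scoring >= the
    classification cut-off, every diagonal entry of a non-empty row is
    at least the cut-off.
    """
    cluster_ids = list(result.scores.columns)
    mat = pd.DataFrame(np.nan, index=cluster_ids, columns=cluster_ids)
    for a in cluster_ids:
        members = result.members(a)
        if not members:
            continue
        mat.loc[a] = result.scores.loc[members].mean(axis=0)
    return mat


@dataclass
class LogoData:
    """Comparative logo data: per-column fg/bg frequencies + divergence.

    Frequencies are pseudocounted and sum to 1 per column; ``divergence``
    is the relative entropy (nats) of the foreground distribution from
    the background.  ``flagged`` lists columns with no foreground
    residues (all gap), whose divergence is forced to 0.
    """

    columns: list[int]
    fg_freqs: np.ndarray  # (n_cols, 20)
    bg_freqs: np.ndarray  # (n_cols, 20)
    divergence: np.ndarray  # (n_cols,)
    flagged: list[int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, col in enumerate(self.columns):
            for r, aa in enumerate(AMINO_ACIDS):
                rows.append(
                    {
                        "column": col + 1,
                        "residue": aa,
                        "fg_freq": self.fg_freqs[k, r],
                        "bg_freq": self.bg_freqs[k, r],
                        "divergence": self.divergence[k],
                    }
                )
        return pd.DataFrame(rows)


def _freqs(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    """Blend the empirical residue distribution with the uniform one.

    The blend weight depends only on the pseudocount, not on the sample
    size, so two groups with identical empirical compositions always get
    identical smoothed distributions (and hence zero divergence).
    """
    total = counts.sum()
    empirical = counts / total if total > 0 else np.full(20, 1.0 / 20)
    uniform = np.full(20, 1.0 / 20)
    return (empirical + pseudocount * uniform) / (1.0 + pseudocount)


def comparative_logo(
    aln: ProfileAlignment,
    fg_ids: Iterable[str],
    columns: Sequence[int],
    pseudocount: float = 1.0,
) -> LogoData:
    """Foreground-vs-background residue frequencies at chosen columns.

    Gaps and unknowns are excluded from the counts; ``pseudocount``
    controls the uniform-blend smoothing (0 keeps the raw empirical
    distributions).  Divergence is zero exactly when the smoothed
    distributions coincide.
    """
    fg = set(fg_ids)
    ids = aln.ids()
    if not fg or fg >= set(ids):
        raise ValueError("foreground must be a non-empty proper subset")
    enc = aln.encoded()
    fg_rows = np.array([i for i, x in enumerate(ids) if x in fg])
    bg_rows = np.array([i for i, x in enumerate(ids) if x not in fg])
    n = len(columns)
    fg_freqs = np.zeros((n, 20))
    bg_freqs = np.zeros((n, 20))
    div = np.zeros(n)
    flagged: list[int] = []
    for k, col in enumerate(columns):
        cf = np.array([(enc[fg_rows, col] == c).sum() for c in range(20)], float)
        cb = np.array([(enc[bg_rows, col] == c).sum() for c in range(20)], float)
        fg_freqs[k] = _freqs(cf, pseudocount)
        bg_freqs[k] = _freqs(cb, pseudocount)
        if cf.sum() == 0:
            flagged.append(col)
            div[k] = 0.0
        else:
            div[k] = float(rel_entr(fg_freqs[k], bg_freqs[k]).sum())
    return LogoData(list(columns), fg_freqs, bg_freqs, div, flagged)


@dataclass
class LoopStats:
    """Per-family αD–αE loop lengths with an optional clade label."""

    family_id: str
    lengths: np.ndarray
    median_length: float
    clade_label: str = "unassigned"
    display_cap: int = 30

    def display_median(self) -> str:
        if self.median_length > self.display_cap:
            return f">{self.display_cap}"
        return f"{self.median_length:g}"


def de_loop_lengths(
    aln: ProfileAlignment,
    d_end: int,
    e_start: int,
    family_map: Mapping[str, str],
    display_cap: int = 30,
) -> list[LoopStats]:
    """Per-family αD–αE loop lengths.

    The loop length of a sequence is its count of non-gap match residues
    at columns strictly between the αD-end and αE-start anchors, plus
    every insert residue attached between those columns.  Sequences with
    families missing from ``family_map`` are grouped as "unclassified".
    Rendered tables cap the reported median at ``display_cap`` (">30" by
    default), mirroring how extreme DE inserts are usually displayed.
    """
    if not d_end < e_start:
        raise ValueError("d_end must precede e_start")
    enc = aln.encoded()
    by_family: dict[str, list[int]] = {}
    for i, rec in enumerate(aln):
        match_len = int((enc[i, d_end + 1 : e_start] != GAP_CODE).sum())
        insert_len = sum(len(rec.inserts[s]) for s in range(d_end + 1, e_start + 1))
        fam = family_map.get(rec.id, UNCLASSIFIED)
        by_family.setdefault(fam, []).append(match_len + insert_len)
    return [
        LoopStats(
            fam,
            np.array(lengths),
            float(np.median(lengths)),
            display_cap=display_cap,
        )
        for fam, lengths in sorted(by_family.items())
    ]


def label_clades(
    stats: Sequence[LoopStats],
    clade_map: Mapping[str, str] | None = None,
    threshold: float | None = None,
) -> list[LoopStats]:
    """Attach longDE/shortDE clade labels to loop statistics.

    Labels come from a phylogeny-derived clade map when supplied;
    otherwise a median-length threshold is used as a heuristic stand-in
    (families with median loop length above the threshold are longDE).
    Exactly one of the two sources must be given.
    """
    if (clade_map is None) == (threshold is None):
        raise ValueError("provide exactly one of clade_map or threshold")
    out = []
    for s in stats:
        if clade_map is not None:
            label = clade_map.get(s.family_id, "unassigned")
        else:
            label = "longDE" if s.median_length > threshold else "shortDE"
        out.append(replace(s, clade_label=label))
    return out


def loop_stats_frame(stats: Sequence[LoopStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family_id": [s.family_id for s in stats],
            "n_sequences": [len(s.lengths) for s in stats],
            "median_length": [s.median_length for s in stats],
            "display_median": [s.display_median() for s in stats],
            "clade": [s.clade_label for s in stats],
        }
    )


__all__ = [
    "LogoData",
    "LoopStats",
    "similarity_matrix",
    "comparative_logo",
    "de_loop_lengths",
    "label_clades",
    "loop_stats_frame",
]
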