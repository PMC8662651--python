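"""Intron phases, alignment mapping, and shared-intron grouping."""

import numpy as np
import pytest

from ckinome.alignment import ProfileAlignment
from ckinome.gene_structure import (
    GeneStructure,
    IntronRecord,
    intron_phases,
    map_intron_to_alignment,
    read_exon_table,
    read_gff3_cds,
    shared_introns,
    write_exon_table,
)
from ckinome.synthetic import make_gene_structures
from conftest import make_record


def _codon_walk_oracle(exon_lengths):
    """Independent oracle: lay every nucleotide out explicitly, then read
    off each intron's codon context from the nucleotide labels."""
    labels = []  # (codon index, offset within codon) per nucleotide
    i = 0
    for nt in range(sum(exon_lengths)):
        labels.append((nt // 3, nt % 3))
    records = []
    consumed = 0
    for idx, length in enumerate(exon_lengths[:-1]):
        consumed += length
        # the intron sits before nucleotide `consumed`
        if consumed < len(labels):
            codon, offset = labels[consumed]
        else:
            codon, offset = consumed // 3, consumed % 3
        records.append((idx, offset, codon if offset else consumed // 3))
    return records


def test_intron_phase_examples():
    assert intron_phases(GeneStructure("g", (99, 60))) == [IntronRecord(0, 0, 33)]
    assert intron_phases(GeneStructure("g", (100, 50))) == [IntronRecord(0, 1, 33)]
    phases = intron_phases(GeneStructure("g", (101, 49, 30)))
    assert [(p.phase, p.codon_position) for p in phases] == [(2, 33), (0, 50)]


def test_intron_phase_matches_codon_walk_on_random_structures():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        n_exons = int(rng.integers(1, 8))
        lengths = tuple(int(x) for x in rng.integers(1, 400, size=n_exons))
        got = [
            (p.index, p.phase, p.codon_position)
            for p in intron_phases(GeneStructure("g", lengths))
        ]
        expected = [
            (idx, offset, codon)
            for idx, offset, codon in _codon_walk_oracle(lengths)
        ]
        assert got == expected


def test_gene_structure_validation():
    with pytest.raises(ValueError):
        GeneStructure("g", ())
    with pytest.raises(ValueError):
        GeneStructure("g", (10, 0))
    assert GeneStructure("g", (100,)).partial
    assert not GeneStructure("g", (99,)).partial
    assert intron_phases(GeneStructure("g", (99,))) == []


# ---------------------------------------------------------------------------
# mapping to alignment columns


def test_map_intron_boundary_and_overflow():
    rec = make_record("r", "ACDEF")
    first = map_intron_to_alignment(IntronRecord(0, 0, 0), rec)
    assert first.alignment_column == 0
    beyond = map_intron_to_alignment(IntronRecord(0, 2, 40), rec)
    assert beyond.alignment_column is None


def test_map_intron_lands_in_insert_region():
    rec = make_record("r", "ACDEF", {2: "WW"})
    # residues: A C w w D E F -> positions 2 and 3 are insert residues
    assert map_intron_to_alignment(IntronRecord(0, 1, 2), rec).alignment_column is None
    assert map_intron_to_alignment(IntronRecord(0, 1, 4), rec).alignment_column == 2


def test_map_intron_never_lands_on_gap_column():
    rng = np.random.default_rng(1)
    for _ in range(50):
        chars = rng.choice(list("ACDEF-"), size=12)
        rec = make_record("r", "".join(chars))
        for p in range(rec.n_residues):
            mapped = map_intron_to_alignment(IntronRecord(0, 0, p), rec)
            if mapped.alignment_column is not None:
                assert rec.match_residues[mapped.alignment_column] != "-"


def test_map_planted_intron_recovers_column(preset0):
    genes = make_gene_structures(
        preset0.aln, preset0.truth, preset0.truth.introns, exon_noise=0.0, seed=9
    )
    by_id = {g.protein_id: g for g in genes}
    alpha_h = preset0.anchors["alphaH"]
    for rec in preset0.aln.records[:20]:
        clade = preset0.truth.clade_map[preset0.truth.labels[rec.id]]
        mapped = [
            map_intron_to_alignment(p, rec)
            for p in intron_phases(by_id[rec.id])
        ]
        keys = {(m.alignment_column, m.phase) for m in mapped}
        assert keys == set(preset0.truth.introns[clade])
        if clade == "longDE":
            assert (alpha_h, 2) in keys


# ---------------------------------------------------------------------------
# shared introns


def test_shared_intron_group_contains_exactly_planted_families(preset0):
    genes = make_gene_structures(
        preset0.aln, preset0.truth, preset0.truth.introns, exon_noise=0.0, seed=9
    )
    by_id = {g.protein_id: g for g in genes}
    pairs = [(by_id[r.id], r) for r in preset0.aln]
    table = shared_introns(pairs, preset0.truth.family_map())
    alpha_h = preset0.anchors["alphaH"]
    row = table[
        (table["alignment_column"] == alpha_h + 1) & (table["phase"] == 2)
    ].iloc[0]
    long_families = {
        f for f, c in preset0.truth.clade_map.items()
        if c == "longDE" and "." in f
    }
    assert set(row["families"].split(",")) == long_families
    assert row["n_sequences"] == 100


def test_shared_introns_with_noise_keep_planted_groups_on_top(preset0):
    by_id = {g.protein_id: g for g in preset0.genes}  # preset noise 0.5
    pairs = [(by_id[r.id], r) for r in preset0.aln if r.id in by_id]
    table = shared_introns(pairs, preset0.truth.family_map())
    # the two best-supported groups are the planted clade-wide introns
    top2 = table.nlargest(2, "n_sequences")
    keys = {(r.alignment_column - 1, r.phase) for r in top2.itertuples()}
    planted = {
        key for spec in preset0.truth.introns.values() for key in spec
    }
    assert keys == planted
    assert (top2["n_sequences"] >= 90).all()


def test_shared_introns_disjoint_structures_one_family_each():
    recs = [make_record(f"r{i}", "ACDEFGHIKL") for i in range(3)]
    aln = ProfileAlignment(tuple(recs), 10)
    genes = [
        GeneStructure("r0", (9, 21)),
        GeneStructure("r1", (13, 17)),
        GeneStructure("r2", (20, 10)),
    ]
    table = shared_introns(
        zip(genes, aln.records), {"r0": "f0", "r1": "f1", "r2": "f2"}
    )
    assert (table["n_families"] == 1).all()


# ---------------------------------------------------------------------------
# readers


def test_exon_table_round_trip(tmp_path, preset0):
    path = tmp_path / "exons.tsv"
    write_exon_table(preset0.genes[:10], path)
    back = read_exon_table(path)
    assert back == sorted(preset0.genes[:10], key=lambda g: g.protein_id)


GFF = """\
##gff-version 3
chr1\tsrc\tmRNA\t1\t1000\t.\t+\t.\tID=tx1
chr1\tsrc\tCDS\t1\t99\t.\t+\t0\tParent=tx1
chr1\tsrc\tCDS\t200\t259\t.\t+\t0\tParent=tx1
chr1\tsrc\tmRNA\t1\t1000\t.\t-\t.\tID=tx2
chr1\tsrc\tCDS\t500\t559\t.\t-\t0\tParent=tx2
chr1\tsrc\tCDS\t700\t798\t.\t-\t0\tParent=tx2
"""


def test_gff3_cds_reader_orders_by_strand(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(GFF)
    genes = {g.protein_id: g for g in read_gff3_cds(path)}
    assert genes["tx1"].exon_lengths == (99, 60)
    # minus strand: ORF order is reversed genomic order
    assert genes["tx2"].exon_lengths == (99, 60)
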