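"""Genome parsing, intron extraction and partition accounting."""
import pytest

from plastintron.annotation_io import (
    GeneModel, IntronRecord, StructuralError, extract_introns,
    parse_genome_record, partition_stats, reverse_complement_genome,
    table1_partitions, write_gff3,
)
from conftest import make_genome


def toy_two_gene_genome():
    # 100 bp; geneA (+) 2 exons with one 10 bp intron; geneB (-) single exon
    return make_genome(
        [
            ("geneA", "protein", "+", [(10, 28), (38, 50)], [(28, 38)]),
            ("geneB", "protein", "-", [(60, 90)], []),
        ],
        length=100,
    )


class TestPartition:
    def test_toy_partition_is_exact(self):
        g = make_genome(
            [("gA", "protein", "+", [(10, 30), (40, 60)], [(30, 40)])],
            length=100,
        )
        p = partition_stats(g)
        assert (p.gene_bp, p.intron_bp, p.intergenic_bp) == (40, 10, 50)
        assert p.conserves()

    def test_degenerate_genome_all_intergenic(self):
        from plastintron.annotation_io import AnnotatedGenome

        p = partition_stats(AnnotatedGenome(id="e", species_tag="e",
                                            sequence="A" * 50))
        assert p.intergenic_bp == 50 and p.conserves()

    def test_published_partitions_conserve(self):
        parts = {p.species_tag: p for p in table1_partitions()}
        assert len(parts) == 6
        for p in parts.values():
            assert p.conserves()
        assert parts["Maen"].total_bp == 45568 + 13048 + 16130 == 74746
        assert parts["Egra"].total_bp == 62776 + 24712 + 55683 == 143171

    def test_duplicated_genes_counted_once(self):
        g = make_genome(
            [
                ("rrs", "rRNA", "+", [(0, 30)], []),
                ("rrs", "rRNA", "+", [(50, 80)], []),
            ],
            length=100,
        )
        for gene in g.genes:
            gene.duplicate_group = "rrn_operon"
        p = partition_stats(g)
        assert p.counts["total"] == 1
        assert p.gene_bp == 60  # bp is physical: both copies count

    def test_intronic_orf_excluded_from_gene_bp(self):
        # maturase ORF inside the intron: intronic bp, separate count
        g = make_genome(
            [
                ("host", "protein", "+", [(0, 30), (130, 160)], [(30, 130)]),
                ("mat1", "protein", "+", [(40, 100)], []),
            ],
            length=200,
        )
        p = partition_stats(g)
        assert p.intron_bp == 100
        assert p.gene_bp == 60
        assert p.counts["intron_orfs"] == 1
        assert p.counts["total"] == 1

    def test_twintron_counts_one_insertion_site(self):
        g = make_genome(
            [("host", "protein", "+", [(0, 30), (130, 160)], [(30, 130)])],
            length=200,
        )
        parent = g.genes[0].introns[0]
        parent.children.append(
            IntronRecord("host", 0, (50, 90), g.sequence[50:90])
        )
        p = partition_stats(g)
        assert p.counts["insertion_sites"] == 1


class TestExtractIntrons:
    def test_minus_strand_ordinals_follow_transcript(self):
        g = make_genome(
            [("gB", "protein", "-",
              [(10, 22), (30, 42), (50, 62)], [(22, 30), (42, 50)])],
        )
        introns = extract_introns(g)
        # transcript runs right-to-left: ordinal 1 is the genomically last
        by_ordinal = {i.ordinal: i.interval for i in introns}
        assert by_ordinal[1] == (42, 50)
        assert by_ordinal[2] == (22, 30)

    def test_phase_is_coding_offset_mod_3(self):
        g = make_genome(
            [("gA", "protein", "+", [(0, 4), (10, 30)], [(4, 10)])],
        )
        (intron,) = extract_introns(g)
        assert intron.cds_offset == 4
        assert intron.phase == 1

    def test_unflanked_intron_rejected(self):
        g = make_genome(
            [("gA", "protein", "+", [(0, 30)], [])],
        )
        g.genes[0].introns = [IntronRecord("gA", 1, (5, 10), "AAAAA")]
        with pytest.raises(StructuralError):
            extract_introns(g)

    def test_ordinals_stable_under_orientation_flip(self):
        g = make_genome(
            [("gB", "protein", "-",
              [(10, 22), (30, 42), (50, 62)], [(22, 30), (42, 50)])],
        )
        flipped = reverse_complement_genome(g)
        orig = {i.ordinal: i.length for i in extract_introns(g)}
        flip = {i.ordinal: i.length for i in extract_introns(flipped)}
        assert orig == flip


class TestRoundTrip:
    def test_gff3_round_trip_preserves_features(self, tmp_path):
        g = toy_two_gene_genome()
        write_gff3(g, tmp_path / "t.gff3", tmp_path / "t.fa")
        back = parse_genome_record(tmp_path / "t.gff3", "gff3",
                                   fasta=tmp_path / "t.fa", species_tag="Toy")
        assert back.length == g.length
        assert [(x.name, x.kind, x.strand, x.exons) for x in back.genes] == \
               [(x.name, x.kind, x.strand, x.exons) for x in g.genes]
        assert [i.interval for i in extract_introns(back)] == \
               [i.interval for i in extract_introns(g)]

    def test_nested_intron_round_trip(self, tmp_path):
        g = make_genome(
            [("host", "protein", "+", [(0, 30), (130, 160)], [(30, 130)])],
            length=200,
        )
        g.genes[0].introns[0].children.append(
            IntronRecord("host", 0, (50, 90), g.sequence[50:90])
        )
        write_gff3(g, tmp_path / "n.gff3", tmp_path / "n.fa")
        back = parse_genome_record(tmp_path / "n.gff3", "gff3",
                                   fasta=tmp_path / "n.fa")
        (intron,) = extract_introns(back)
        assert len(intron.children) == 1
        assert intron.children[0].interval == (50, 90)

    def test_genbank_parse_derives_introns_from_joins(self, tmp_path):
        gb = tmp_path / "toy.gb"
        gb.write_text(
            "LOCUS       toy                 60 bp    DNA     circular PLN\n"
            "FEATURES             Location/Qualifiers\n"
            "     CDS             join(1..12,23..34)\n"
            '                     /gene="gA"\n'
            "ORIGIN\n"
            "        1 atgaaaaaaa aagggggggg ggcccccccc cctttttttt ttaaaaaaaa"
            " aaaaaaaaaa\n"
            "//\n"
        )
        g = parse_genome_record(gb, "genbank")
        (intron,) = extract_introns(g)
        assert intron.interval == (12, 22)
        assert g.genes[0].kind == "protein"


def test_coding_length_violation_warns_not_raises():
    with pytest.warns(UserWarning, match="not divisible by 3"):
        g = make_genome(
            [("rpoC1", "protein", "+", [(0, 10)], [])],
        )
        from plastintron.annotation_io import _validate

        _validate(g)
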