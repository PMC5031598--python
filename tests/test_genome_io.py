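"""Genome/annotation ingestion: coordinates, phase, splicing, region classes."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from gcxscan import genome_io
from gcxscan.genome_io import (
    CdsSegment,
    GeneModel,
    GenomeSequence,
    RegionClass,
    assemble_coding_sequence,
    classify_position,
    gff3_to_internal,
    internal_to_gff3,
    read_annotation,
    read_genome,
    reverse_complement,
)

from conftest import MINUS_STRAND_CODING, MINUS_STRAND_CONTIG


class TestReadGenome:
    def test_single_record_identity(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1\nACGT\n")
        genome = read_genome(p)
        assert genome["c1"].sequence == "ACGT"

    def test_case_folding(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1\nacgt\n")
        assert read_genome(p)["c1"].sequence == "ACGT"

    def test_two_records_file_order(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1\nAC\n>c2\nGGTT\n")
        genome = read_genome(p)
        assert list(genome) == ["c1", "c2"]
        assert genome["c2"].sequence == "GGTT"

    def test_duplicate_contig_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1\nAC\n>c1\nGG\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_genome(p)

    def test_malformed_header_names_line(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("ACGT\n>c1\nAC\n")
        with pytest.raises(ValueError, match="line 1"):
            read_genome(p)

    def test_alphabet_validated(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            GenomeSequence("c1", "ACGX")
        with pytest.raises(ValueError, match="empty"):
            GenomeSequence("c1", "")


class TestReadAnnotation:
    def test_coordinate_conversion(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c1\t.\tgene\t1\t9\t.\t+\t.\tID=g1\n"
            "c1\t.\tmRNA\t1\t9\t.\t+\t.\tID=t1;Parent=g1\n"
            "c1\t.\tCDS\t1\t9\t.\t+\t0\tParent=t1\n"
        )
        (gene,) = read_annotation(gff)
        seg = gene.cds_segments[0]
        assert (seg.start, seg.end, seg.phase) == (0, 9, 0)

    def test_minus_strand_spliced_coding_sequence(self, minus_strand_toy):
        fasta, gff = minus_strand_toy
        genome = read_genome(fasta)
        (gene,) = read_annotation(gff, genome=genome)
        assert gene.strand == "-"
        # transcription order: the downstream-start segment first
        assert gene.cds_segments[0].start == 10
        assert gene.coding_sequence == MINUS_STRAND_CODING

    def test_representative_transcript_longest_cds(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c1\t.\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "c1\t.\tmRNA\t1\t100\t.\t+\t.\tID=tB;Parent=g1\n"
            "c1\t.\tCDS\t1\t30\t.\t+\t0\tParent=tB\n"
            "c1\t.\tCDS\t41\t70\t.\t+\t0\tParent=tB\n"
            "c1\t.\tmRNA\t1\t100\t.\t+\t.\tID=tA;Parent=g1\n"
            "c1\t.\tCDS\t1\t30\t.\t+\t0\tParent=tA\n"
        )
        (gene,) = read_annotation(gff)
        assert gene.transcript_id == "tB"
        # the CDS interval shared by both isoforms contributes exactly once
        assert gene.cds_length == 60

    def test_shared_interval_tie_breaks_lexicographically(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c1\t.\tgene\t1\t30\t.\t+\t.\tID=g1\n"
            "c1\t.\tmRNA\t1\t30\t.\t+\t.\tID=tB;Parent=g1\n"
            "c1\t.\tCDS\t1\t30\t.\t+\t0\tParent=tB\n"
            "c1\t.\tmRNA\t1\t30\t.\t+\t.\tID=tA;Parent=g1\n"
            "c1\t.\tCDS\t1\t30\t.\t+\t0\tParent=tA\n"
        )
        (gene,) = read_annotation(gff)
        assert gene.transcript_id == "tA"

    def test_missing_phase_inferred_from_lengths(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c1\t.\tgene\t1\t50\t.\t+\t.\tID=g1\n"
            "c1\t.\tmRNA\t1\t50\t.\t+\t.\tID=t1;Parent=g1\n"
            "c1\t.\tCDS\t1\t10\t.\t+\t.\tParent=t1\n"
            "c1\t.\tCDS\t21\t30\t.\t+\t.\tParent=t1\n"
        )
        (gene,) = read_annotation(gff)
        assert [s.phase for s in gene.cds_segments] == [0, 2]

    def test_gene_without_cds_flagged_noncoding(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c1\t.\tgene\t1\t50\t.\t+\t.\tID=g1\n"
            "c1\t.\tmRNA\t1\t50\t.\t+\t.\tID=t1;Parent=g1\n"
            "c1\t.\texon\t1\t50\t.\t+\t.\tParent=t1\n"
        )
        with pytest.warns(UserWarning, match="non-coding"):
            (gene,) = read_annotation(gff)
        assert not gene.is_coding


class TestAssembly:
    def _gene(self, start, end, strand, phase, contig="c1"):
        return GeneModel(
            gene_id="g",
            contig_id=contig,
            strand=strand,
            cds_segments=[CdsSegment(contig, start, end, strand, phase)],
        )

    def test_plus_strand_phase0(self):
        genome = GenomeSequence("c1", "ATGGCC")
        seq, off = assemble_coding_sequence(self._gene(0, 6, "+", 0), genome)
        assert (seq, off) == ("ATGGCC", 0)

    def test_phase1_marks_leading_base(self):
        genome = GenomeSequence("c1", "GATGGC")
        seq, off = assemble_coding_sequence(self._gene(0, 6, "+", 1), genome)
        assert (seq, off) == ("GATGGC", 1)

    def test_minus_strand_reverse_complement(self):
        genome = GenomeSequence("c1", "GGCCAT")
        seq, _ = assemble_coding_sequence(self._gene(0, 6, "-", 0), genome)
        assert seq == "ATGGCC"

    def test_out_of_bounds_segment_errors(self):
        genome = GenomeSequence("c1", "ACGT")
        with pytest.raises(ValueError, match="exceeds contig"):
            assemble_coding_sequence(self._gene(0, 10, "+", 0), genome)

    def test_length_equals_segment_sum(self, small_simulation):
        sim, _ = small_simulation
        for gene in sim.genes[:30]:
            assert len(gene.coding_sequence) == gene.cds_length

    @given(st.integers(20, 200), st.integers(0, 1234))
    def test_strand_mirror_property(self, length, seed):
        """Assembling a gene on the mirrored reverse-complement contig is invariant."""
        import numpy as np

        r = np.random.default_rng(seed)
        contig = "".join(r.choice(list("ACGT"), size=length))
        s, e = sorted(r.choice(length + 1, size=2, replace=False))
        if e - s < 3:
            e = min(length, s + 3)
            if e - s < 3:
                return
        fwd = self._gene(s, e, "+", 0)
        seq_fwd, _ = assemble_coding_sequence(fwd, GenomeSequence("c1", contig))
        mirrored = self._gene(length - e, length - s, "-", 0)
        seq_rev, _ = assemble_coding_sequence(
            mirrored, GenomeSequence("c1", reverse_complement(contig))
        )
        assert seq_fwd == seq_rev


class TestRegions:
    def test_classify_positions(self):
        from conftest import make_two_exon_gene

        gene = make_two_exon_gene()
        # layout: UTR5 [0,10) CDS [10,40) intron [40,60) CDS [60,89) UTR3 [89,99)
        assert classify_position(gene, 15) is RegionClass.CDS
        assert classify_position(gene, 50) is RegionClass.INTRON
        assert classify_position(gene, 5) is RegionClass.UTR5
        assert classify_position(gene, 95) is RegionClass.UTR3
        assert classify_position(gene, 1000) is RegionClass.INTERGENIC

    def test_cds_offset_round_trip(self):
        from conftest import make_two_exon_gene

        gene = make_two_exon_gene()
        for offset in (0, 29, 30, 58):
            pos = gene.genomic_of_cds_offset(offset)
            assert gene.cds_offset_of(pos) == offset
        assert gene.cds_offset_of(45) is None  # intron


@given(st.integers(1, 10**8), st.integers(1, 10**6))
def test_gff3_coordinate_round_trip(start, span):
    """GFF3 -> internal -> GFF3 is the identity."""
    end = start + span
    assert internal_to_gff3(*gff3_to_internal(start, end)) == (start, end)


def test_no_base_counted_twice(small_simulation):
    """After redundancy removal no genomic base enters the coding sequence twice."""
    sim, _ = small_simulation
    for gene in sim.genes:
        segs = sorted((s.start, s.end) for s in gene.cds_segments)
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            assert e1 <= s2


def test_gene_model_table_columns(small_simulation):
    sim, _ = small_simulation
    df = genome_io.gene_model_table(sim.genes)
    assert set(df.columns) >= {"gene_id", "contig", "strand", "n_cds", "cds_len", "phase_offset"}
    assert len(df) == len(sim.genes)
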