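"""PWM construction, scanning, hit localization and frame assignment."""

import numpy as np
import pytest

from gcxscan import motif_scan
from gcxscan.genome_io import RegionClass, reverse_complement
from gcxscan.motif_scan import (
    DEFAULT_CONSENSUS,
    MotifHit,
    assign_codon_frame,
    cds_preference_test,
    consensus_to_pwm,
    histogram_summary,
    localize_hits,
    per_gene_counts,
    scan,
)

from conftest import make_two_exon_gene, random_sequence

BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def naive_scan(seq, model):
    """Independent per-window rescoring oracle."""
    L = len(model)
    out = []
    for i in range(len(seq) - L + 1):
        s = sum(model.score_matrix[j, BASE_IDX.get(seq[i + j], 4)] for j in range(L))
        if s >= model.threshold:
            out.append((i, s / model.max_score))
    return out


@pytest.fixture(scope="module")
def model():
    return consensus_to_pwm()


class TestPwm:
    def test_s_code_probabilities(self):
        m = consensus_to_pwm("S")
        assert m.pwm[0].tolist() == [0.0, 0.5, 0.5, 0.0]

    def test_default_consensus_length(self, model):
        assert len(model) == 19

    def test_invalid_code_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            consensus_to_pwm("GVXG")

    def test_max_score_is_sum_of_position_maxima(self, model):
        assert model.max_score == pytest.approx(model.score_matrix[:, :4].max(axis=1).sum())

    def test_probabilities_sum_to_one(self, model):
        assert np.allclose(model.pwm.sum(axis=1), 1.0)

    def test_all_g_attains_max(self, model):
        # G is allowed at every position of the default consensus
        hits = scan("G" * 19, model, both_strands=False)
        assert len(hits) == 1 and hits[0].score_fraction == pytest.approx(1.0)

    def test_background_validation(self):
        with pytest.raises(ValueError, match="background"):
            consensus_to_pwm("G", background=[0.5, 0.5, 0.0, 0.0])


class TestScan:
    def test_sequence_shorter_than_motif(self, model):
        assert scan("A" * 18, model) == []

    def test_at_only_background_no_hits(self, model, rng):
        seq = random_sequence(rng, 200, alphabet="AT")
        assert scan(seq, model) == []
        assert naive_scan(seq, model) == []

    def test_planted_consensus_max_found_at_offset(self, model, rng):
        background = random_sequence(rng, 120, alphabet="AT")
        planted = model.consensus_max_sequence()
        seq = background[:37] + planted + background[37:]
        hits = scan(seq, model, both_strands=False)
        assert [(h.start, h.score_fraction) for h in hits] == [(37, pytest.approx(1.0))]
        assert hits[0].sequence == planted

    def test_n_scored_neutrally(self, model):
        planted = model.consensus_max_sequence()
        degraded = "N" + planted[1:]
        (hit,) = scan(planted, model, both_strands=False)
        hits_n = scan(degraded, model, both_strands=False)
        if hits_n:  # one neutral position may or may not cross the threshold
            assert hits_n[0].score_fraction < hit.score_fraction

    def test_matches_naive_oracle(self, model, rng):
        for _ in range(50):
            gc = rng.uniform(0.3, 0.9)
            seq = "".join(
                rng.choice(list("GC"), size=150)[i] if rng.random() < gc else
                rng.choice(list("ATN"))
                for i in range(150)
            )
            got = [(h.start, h.score_fraction) for h in scan(seq, model, both_strands=False)]
            expected = naive_scan(seq, model)
            assert [g[0] for g in got] == [e[0] for e in expected]
            for (_, sg), (_, se) in zip(got, expected):
                assert sg == pytest.approx(float(se))

    def test_strand_mirror_property(self, model, rng):
        seq = random_sequence(rng, 300, alphabet="ACGT")
        fwd = scan(seq, model, both_strands=False)
        rev = scan(reverse_complement(seq), model, both_strands=False)
        mirrored = sorted(len(seq) - 19 - h.start for h in rev)
        both = scan(seq, model, both_strands=True)
        assert sorted(h.start for h in both if h.strand == "-") == mirrored
        assert sorted(h.start for h in both if h.strand == "+") == sorted(
            h.start for h in fwd
        )

    def test_minmax_anchor_is_more_permissive(self):
        strict = consensus_to_pwm(stringency=0.8, threshold_anchor="max")
        loose = consensus_to_pwm(stringency=0.8, threshold_anchor="minmax")
        assert loose.threshold < strict.threshold


class TestLocalization:
    def _hit(self, start, seq="G" * 19):
        return MotifHit("c1", start, "+", 1.0, seq)

    def _gene_with_sequence(self):
        gene = make_two_exon_gene()
        # deterministic coding sequence: 59 coding bases
        gene.coding_sequence = ("ACG" * 20)[:59]
        return gene

    def test_hit_inside_single_cds_segment(self):
        gene = self._gene_with_sequence()
        (hit,) = localize_hits([self._hit(12)], [gene])
        assert hit.region is RegionClass.CDS
        assert hit.cds_offset == 2
        assert hit.codon_frame == 3
        assert hit.coding_sequence == gene.coding_sequence[2:21]

    def test_hit_crossing_intron_flagged_split(self):
        gene = self._gene_with_sequence()
        (hit,) = localize_hits([self._hit(30)], [gene])  # CDS1 ends at 40
        assert hit.region is RegionClass.CDS
        assert hit.cds_offset is None
        assert hit.codon_frame is None
        assert "split" in hit.flags

    def test_hit_in_utr5(self):
        gene = self._gene_with_sequence()
        (hit,) = localize_hits([self._hit(2)], [gene])
        assert hit.region is RegionClass.UTR5
        assert hit.codon_frame is None

    def test_hit_in_intron(self):
        gene = self._gene_with_sequence()
        (hit,) = localize_hits([self._hit(41)], [gene])
        assert hit.region is RegionClass.INTRON

    def test_hit_outside_any_gene(self):
        gene = self._gene_with_sequence()
        (hit,) = localize_hits([self._hit(500)], [gene])
        assert hit.region is RegionClass.INTERGENIC
        assert hit.gene_id is None

    def test_overlapping_genes_both_assigned(self):
        g1 = self._gene_with_sequence()
        g2 = self._gene_with_sequence()
        g2.gene_id = "gY"
        hits = localize_hits([self._hit(12)], [g1, g2])
        assert {h.gene_id for h in hits} == {"gX", "gY"}
        assert all("multi_gene" in h.flags for h in hits)


class TestFrames:
    @pytest.mark.parametrize(
        "cds_offset,phase,expected",
        [(0, 0, 1), (4, 0, 2), (2, 0, 3), (1, 1, 1), (3, 0, 1), (5, 2, 1)],
    )
    def test_frame_formula(self, cds_offset, phase, expected):
        gene = make_two_exon_gene()
        gene.coding_phase_offset = phase
        hit = MotifHit("c1", 0, "+", 1.0, "G" * 19, cds_offset=cds_offset)
        assert assign_codon_frame(hit, gene) == expected

    def test_undefined_offset_undefined_frame(self):
        gene = make_two_exon_gene()
        hit = MotifHit("c1", 0, "+", 1.0, "G" * 19)
        assert assign_codon_frame(hit, gene) is None

    def test_minus_strand_frame_from_coding_orientation(self, small_simulation):
        """Planted frames on minus-strand genes are recovered exactly from the scan."""
        sim, _ = small_simulation
        model = consensus_to_pwm()
        hits = motif_scan.localize_hits(
            motif_scan.scan_genome(
                {c: type("S", (), {"sequence": s})() for c, s in sim.contigs.items()}, model
            ),
            sim.genes,
        )
        found = {(h.gene_id, h.cds_offset): h.codon_frame for h in hits if h.cds_offset is not None}
        minus = [m for m in sim.planted if m.strand == "-"]
        assert minus, "expected minus-strand plantings in the fixture"
        for m in minus:
            assert found.get((m.gene_id, m.cds_offset)) == m.codon_frame


class TestPerGeneCounts:
    def test_single_gene_three_hits(self):
        hits = [MotifHit("c", i, "+", 1.0, "G" * 19, gene_id="g1") for i in range(3)]
        res = per_gene_counts(hits)
        assert res.per_gene == {"g1": 3}
        assert res.histogram.set_index("motifs_per_gene").loc[3, "n_genes"] == 1
        assert res.total_motifs == 3
        assert res.fraction_multi == 1.0

    def test_frame_conservation(self, small_simulation):
        """Sum of frame counts equals the number of frame-defined hits."""
        sim, _ = small_simulation
        model = consensus_to_pwm()
        raw = []
        for cid, s in sim.contigs.items():
            raw.extend(scan(s, model, contig_id=cid))
        hits = localize_hits(raw, sim.genes)
        framed = [h for h in hits if h.codon_frame is not None]
        counts = {k: sum(1 for h in framed if h.codon_frame == k) for k in (1, 2, 3)}
        assert sum(counts.values()) == len(framed)


class TestCdsPreference:
    def test_proportional_split_p_one(self):
        res = cds_preference_test(100, 50, 1000, 500)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_reversed_preference_significant(self):
        res = cds_preference_test(0, 100, 1000, 1000)
        assert res.p < 1e-10
        assert res.observed[0] < res.expected[0]

    def test_zero_bases_rejected(self):
        with pytest.raises(ValueError):
            cds_preference_test(1, 1, 0, 100)


def test_histogram_summary():
    total, frac = histogram_summary({1: 2, 3: 1, 5: 1})
    assert total == 2 + 3 + 5
    assert frac == pytest.approx(0.5)
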