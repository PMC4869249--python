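"""Meta-profile aggregation, window construction, BED parsing, motif scan."""

import io

import numpy as np
import pytest

from structprobe import GenomicInterval, ScoreTrack
from structprobe.aggregate import (
    RegionSet,
    aggregate_mean,
    extract_oriented_profile,
    make_feature_windows,
    motif_scan,
    read_bed,
)

from conftest import make_store


def track(chrom, strand, scores, offset=0, method="dsss"):
    return ScoreTrack(chrom=chrom, strand=strand, method=method,
                      scores=np.asarray(scores, dtype=float), offset=offset)


class TestReadBed:
    def test_bed6_strand_honored(self):
        rs = read_bed(io.StringIO("chr1\t100\t121\tx\t0\t-\n"))
        assert rs.regions == [GenomicInterval("chr1", 100, 121, "-")]

    def test_bed3_defaults_to_plus(self):
        rs = read_bed(io.StringIO("chr1\t100\t121\n"))
        assert rs.regions[0].strand == "+"

    def test_mixed_lengths_rejected_with_lines(self):
        bed = "chr1\t0\t21\nchr1\t50\t70\n"
        with pytest.raises(ValueError, match="mixed lengths"):
            read_bed(io.StringIO(bed))

    def test_empty_file_rejected(self):
        with pytest.raises(ValueError, match="no regions"):
            read_bed(io.StringIO("# only a comment\n"))


class TestOrientedExtraction:
    def test_plus_strand_identity(self):
        store = make_store(track("chr1", "+", [1.0, 2.0, 3.0], offset=100))
        iv = GenomicInterval("chr1", 100, 103, "+")
        assert list(extract_oriented_profile(store, iv, "dsss")) == [1.0, 2.0, 3.0]

    def test_minus_strand_reversed_to_transcript_order(self):
        # minus-strand regions read 5'->3' right to left in the genome
        store = make_store(track("chr1", "-", [1.0, 2.0, 3.0], offset=100))
        iv = GenomicInterval("chr1", 100, 103, "-")
        assert list(extract_oriented_profile(store, iv, "dsss")) == [3.0, 2.0, 1.0]

    def test_unscored_region_is_all_missing(self):
        store = make_store(track("chr1", "+", [1.0], offset=0))
        iv = GenomicInterval("chr9", 0, 5, "+")
        assert np.isnan(extract_oriented_profile(store, iv, "dsss")).all()


class TestAggregateMean:
    def test_hand_arithmetic(self):
        store = make_store(track("chr1", "+", [1.0, 2.0, 3.0], offset=0),
                           track("chr2", "+", [3.0, 2.0, 1.0], offset=0))
        rs = RegionSet([GenomicInterval("chr1", 0, 3, "+"),
                        GenomicInterval("chr2", 0, 3, "+")])
        prof = aggregate_mean(store, rs, "dsss")
        assert list(prof.mean_score) == [2.0, 2.0, 2.0]
        assert list(prof.n_contrib) == [2, 2, 2]

    def test_missing_excluded_from_numerator_and_denominator(self):
        store = make_store(track("chr1", "+", [4.0, np.nan], offset=0),
                           track("chr2", "+", [2.0, 6.0], offset=0))
        rs = RegionSet([GenomicInterval("chr1", 0, 2, "+"),
                        GenomicInterval("chr2", 0, 2, "+")])
        prof = aggregate_mean(store, rs, "dsss")
        assert prof.mean_score[0] == 3.0 and prof.n_contrib[0] == 2
        assert prof.mean_score[1] == 6.0 and prof.n_contrib[1] == 1

    def test_all_missing_offset(self):
        store = make_store(track("chr1", "+", [1.0], offset=0))
        rs = RegionSet([GenomicInterval("chr1", 0, 2, "+")])
        prof = aggregate_mean(store, rs, "dsss")
        assert np.isnan(prof.mean_score[1]) and prof.n_contrib[1] == 0

    def test_duplication_leaves_mean_doubles_count(self):
        store = make_store(track("chr1", "+", [1.0, 5.0], offset=0),
                           track("chr2", "+", [3.0, 1.0], offset=0))
        regions = [GenomicInterval("chr1", 0, 2, "+"),
                   GenomicInterval("chr2", 0, 2, "+")]
        once = aggregate_mean(store, RegionSet(regions), "dsss")
        twice = aggregate_mean(store, RegionSet(regions * 2), "dsss")
        assert np.allclose(once.mean_score, twice.mean_score)
        assert (twice.n_contrib == 2 * once.n_contrib).all()

    def test_single_region_equals_oriented_extraction(self):
        store = make_store(track("chr1", "-", [1.0, np.nan, 3.0], offset=10))
        iv = GenomicInterval("chr1", 10, 13, "-")
        prof = aggregate_mean(store, RegionSet([iv]), "dsss")
        extracted = extract_oriented_profile(store, iv, "dsss")
        assert np.array_equal(prof.mean_score, extracted, equal_nan=True)

    def test_strand_coherence_on_mirrored_fixtures(self):
        """A minus-strand profile equals the plus-strand profile built on
        mirror-image coordinates with reversed scores."""
        scores = [1.0, 2.0, 3.0, 4.0, 5.0]
        plus = make_store(track("chr1", "+", scores, offset=0))
        minus = make_store(track("chr1", "-", scores[::-1], offset=0))
        p_prof = aggregate_mean(
            plus, RegionSet([GenomicInterval("chr1", 0, 5, "+")]), "dsss")
        m_prof = aggregate_mean(
            minus, RegionSet([GenomicInterval("chr1", 0, 5, "-")]), "dsss")
        assert np.array_equal(p_prof.mean_score, m_prof.mean_score)


class TestFeatureWindows:
    def test_codon_window_offsets(self):
        # 3-nt codon with 9-nt flanks: 21-nt window, codon at offsets 9-11
        anchors = [GenomicInterval("chr1", 100, 103, "+")]
        rs = make_feature_windows(anchors, up=9, down=9)
        assert rs.length == 21
        win = rs.regions[0]
        assert (win.start, win.end) == (91, 112)
        assert win.start + 9 == 100 and win.start + 12 == 103

    def test_heptamer_window_offsets(self):
        # 7-nt motif with 21-nt flanks: 49-nt window, motif at offsets 21-27
        anchors = [GenomicInterval("chr1", 500, 507, "+")]
        rs = make_feature_windows(anchors, up=21, down=21)
        assert rs.length == 49
        win = rs.regions[0]
        assert win.start + 21 == 500 and win.start + 28 == 507

    def test_zero_flanks_identity(self):
        anchors = [GenomicInterval("chr1", 5, 8, "+")]
        rs = make_feature_windows(anchors, up=0, down=0)
        assert rs.regions == anchors

    def test_minus_strand_flanks_are_transcript_oriented(self):
        """For a minus-strand anchor the 5' flank extends to higher
        genomic coordinates, so oriented extraction still puts the
        feature at the same offsets."""
        anchors = [GenomicInterval("chr1", 100, 103, "-")]
        rs = make_feature_windows(anchors, up=9, down=9)
        win = rs.regions[0]
        assert (win.start, win.end) == (91, 112)
        # oriented offset 9 is genomic position end-1-9 = 102: codon's 5' base
        assert win.end - 1 - 9 == 102

    def test_asymmetric_flanks_respect_strand(self):
        plus = make_feature_windows([GenomicInterval("chr1", 100, 103, "+")],
                                    up=5, down=2).regions[0]
        minus = make_feature_windows([GenomicInterval("chr1", 100, 103, "-")],
                                     up=5, down=2).regions[0]
        assert (plus.start, plus.end) == (95, 105)
        assert (minus.start, minus.end) == (98, 108)

    def test_out_of_bounds_window_dropped(self):
        anchors = [GenomicInterval("chr1", 2, 5, "+"),
                   GenomicInterval("chr1", 100, 103, "+")]
        rs = make_feature_windows(anchors, up=9, down=9)
        assert len(rs) == 1 and rs.regions[0].start == 91


class TestMotifScan:
    def test_plus_strand_hit(self):
        hits = motif_scan({"s": "GAAAAAAAG"}, "AAAAAAA")
        plus = [h for h in hits if h.strand == "+"]
        assert plus == [GenomicInterval("s", 1, 8, "+")]

    def test_minus_strand_hit_via_reverse_complement(self):
        hits = motif_scan({"s": "GTTTTTTTG"}, "AAAAAAA")
        assert hits == [GenomicInterval("s", 1, 8, "-")]

    def test_motif_longer_than_sequence(self):
        assert motif_scan({"s": "ACG"}, "AAAAAAA") == []

    def test_iupac_degeneracy_and_rna_alphabet(self):
        hits = motif_scan({"s": "ATGCA"}, "AUGY")
        assert GenomicInterval("s", 0, 4, "+") in hits

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            motif_scan({"s": "ACGT"}, "AXG")

    def test_overlapping_matches_all_reported(self):
        hits = motif_scan({"s": "AAAA"}, "AA")
        assert len([h for h in hits if h.strand == "+"]) == 3

    def test_palindromic_motif_hits_both_strands(self):
        hits = motif_scan({"s": "GAATTCG"}, "GAATTC")
        strands = {h.strand for h in hits}
        assert strands == {"+", "-"}

    def test_fasta_input(self, tmp_path):
        fasta = tmp_path / "toy.fa"
        fasta.write_text(">s\nGAAAAAAAG\n")
        hits = motif_scan(fasta, "AAAAAAA")
        assert GenomicInterval("s", 1, 8, "+") in hits
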