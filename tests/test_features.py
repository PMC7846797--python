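"""Read extension, clustering, window densities and profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sacs.core_io import GeneModel, GenomicInterval
from sacs.epigenomic_features import (
    MarkTrack,
    PwmScorer,
    build_clusters,
    build_feature_matrix,
    event_windows,
    extend_reads,
    normalize_against_input,
    reference_point_profile,
    region_coverage,
    splice_site_strength,
    window_density,
)
from sacs.splicing_quantification import extract_cassette_events


def _iv(s, e, strand="+", chrom="chr1"):
    return GenomicInterval(chrom, s, e, strand)


def _track(intervals, mark="m"):
    return MarkTrack.from_intervals(mark, intervals)


def _event(strand="+", exon_len=100, intron=1000, chrom="chr1"):
    flags = [True, True, False, True, True]
    exons = []
    pos = 5000
    for i in range(5):
        length = exon_len if i == 2 else 150
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length + intron
    if strand == "-":
        exons = exons[::-1]
    model = GeneModel("g", "g.t", exons, "protein_coding", flags)
    (ev,) = extract_cassette_events([model])
    return ev


class TestExtendReads:
    def test_plus_strand_keeps_start(self):
        (out,) = extend_reads([_iv(100, 136, "+")])
        assert (out.start, out.end) == (100, 300)

    def test_minus_strand_clipped_at_zero(self):
        (out,) = extend_reads([_iv(100, 136, "-")])
        assert (out.start, out.end) == (0, 136)

    def test_extension_equal_to_read_length_is_identity(self):
        (out,) = extend_reads([_iv(100, 136, "+")], length=36)
        assert (out.start, out.end) == (100, 136)

    def test_read_longer_than_extension_rejected(self):
        with pytest.raises(ValueError):
            extend_reads([_iv(0, 300, "+")])


class TestBuildClusters:
    def test_overlapping_pair_kept_singleton_dropped(self):
        clusters = build_clusters([_iv(0, 200), _iv(150, 350), _iv(500, 700)])
        assert len(clusters) == 1
        assert (clusters[0].interval.start, clusters[0].interval.end) == (0, 350)
        assert clusters[0].n_reads == 2

    def test_no_overlap_gives_empty(self):
        assert build_clusters([_iv(0, 200), _iv(200, 400)]) == []

    def test_transitive_chain(self):
        clusters = build_clusters([_iv(0, 200), _iv(100, 300), _iv(250, 450)])
        assert len(clusters) == 1
        assert (clusters[0].interval.start, clusters[0].interval.end) == (0, 450)
        assert clusters[0].n_reads == 3

    def test_reads_partition_into_disjoint_clusters(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 20_000, 400)
        reads = [_iv(int(s), int(s) + 200) for s in starts]
        clusters = build_clusters(reads)
        ivs = sorted((c.interval.start, c.interval.end) for c in clusters)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2
        # every retained read lies in exactly one cluster
        n_in = sum(c.n_reads for c in clusters)
        singles = len(build_clusters(reads)) and None
        covered = 0
        for r in reads:
            hits = [c for c in clusters if c.interval.overlaps(r)]
            assert len(hits) <= 1
            covered += bool(hits)
        assert covered == n_in


class TestNormalizeAgainstInput:
    def test_fold_filter(self):
        clusters = build_clusters([_iv(0, 200), _iv(100, 300)])
        strong_input = _track([_iv(0, 300)] * 2)
        weak_input = _track([_iv(5000, 5200)])
        assert normalize_against_input(clusters, strong_input) == []  # 2 vs 2 scaled
        kept = normalize_against_input(clusters, weak_input)
        assert len(kept) == 1 and kept[0].above_input

    def test_no_input_keeps_everything(self):
        clusters = build_clusters([_iv(0, 200), _iv(100, 300)])
        assert len(normalize_against_input(clusters, None)) == 1


class TestWindowDensity:
    @pytest.mark.parametrize(
        "n_reads,library,expected",
        [(10, 1_000_000, 100.0), (0, 1_000_000, 0.0), (10, 2_000_000, 50.0)],
    )
    def test_rpkm_arithmetic(self, n_reads, library, expected):
        track = _track([_iv(10, 50)] * n_reads)
        track.library_size = library
        win = _iv(0, 100)
        assert window_density(track, win) == pytest.approx(expected)

    def test_zero_library_rejected(self):
        track = _track([])
        with pytest.raises(ValueError):
            window_density(track, _iv(0, 100))

    @given(
        st.integers(min_value=1, max_value=50),
        st.integers(min_value=1, max_value=20),
    )
    @settings(max_examples=30, deadline=None)
    def test_linear_in_count_inverse_in_library(self, n, scale):
        reads = [_iv(10, 60)] * n
        t1 = _track(reads)
        t1.library_size = 1_000_000
        t2 = _track(reads * scale)
        t2.library_size = 1_000_000
        t3 = _track(reads)
        t3.library_size = 1_000_000 * scale
        win = _iv(0, 100)
        d1 = window_density(t1, win)
        assert window_density(t2, win) == pytest.approx(scale * d1)
        assert window_density(t3, win) == pytest.approx(d1 / scale)


class TestFeatureMatrix:
    def test_dimensions(self, small_dataset):
        events = small_dataset.events[:100]
        tracks = [
            MarkTrack.from_intervals(m, small_dataset.mark_reads[m])
            for m in list(small_dataset.mark_reads)[:2]
        ]
        mat = build_feature_matrix(events, tracks)
        assert mat.shape == (100, 8)
        assert len(set(mat.columns)) == 8
        assert (mat.to_numpy() >= 0).all()

    def test_minus_strand_windows_mirror(self):
        ev = _event(strand="-")
        wins = event_windows(ev)
        # 3'ss of a minus-strand exon is its genomic end
        assert wins["3ss@intronic_100"].start == ev.alt_exon.end
        assert wins["3ss@exonic_100"].end == ev.alt_exon.end
        assert wins["5ss@intronic_100"].end == ev.alt_exon.start

    def test_short_exon_truncates_exonic_window(self):
        ev = _event(exon_len=60)
        wins = event_windows(ev)
        assert len(wins["3ss@exonic_100"]) == 60
        # density normalised by the truncated length: 3 reads / 0.06 kb / 1M
        track = _track([_iv(ev.alt_exon.start, ev.alt_exon.start + 10)] * 3)
        track.library_size = 1_000_000
        assert window_density(track, wins["3ss@exonic_100"]) == pytest.approx(3 / 0.06)

    def test_translation_invariance(self):
        ev = _event()
        reads = [_iv(ev.alt_exon.start - 50, ev.alt_exon.start + 150)] * 4
        shift = 10_000
        moved_reads = [_iv(r.start + shift, r.end + shift) for r in reads]
        ev_shift = type(ev)(
            event_id=ev.event_id,
            gene_id=ev.gene_id,
            upstream_exon=ev.upstream_exon.shifted(shift),
            alt_exon=ev.alt_exon.shifted(shift),
            downstream_exon=ev.downstream_exon.shifted(shift),
            exon_index_in_transcript=ev.exon_index_in_transcript,
            strand=ev.strand,
        )
        m1 = build_feature_matrix([ev], [_track(reads)])
        m2 = build_feature_matrix([ev_shift], [_track(moved_reads)])
        np.testing.assert_allclose(m1.to_numpy(), m2.to_numpy())


class TestRegionCoverage:
    def test_uniform_reads_give_near_equal_densities(self):
        # reads much shorter than the regions, so edge effects stay small
        ev = _event(exon_len=1000, intron=1000)
        rng = np.random.default_rng(0)
        lo, hi = ev.upstream_exon.end - 20, ev.downstream_exon.start + 20
        reads = [_iv(int(s), int(s) + 20) for s in rng.integers(lo, hi, 20_000)]
        cov = region_coverage(_track(reads), [ev]).iloc[0]
        vals = [cov["upstream_intron"], cov["exon"], cov["downstream_intron"]]
        assert max(vals) / min(vals) < 1.1

    def test_exon_only_reads(self):
        ev = _event()
        reads = [_iv(ev.alt_exon.start + 5, ev.alt_exon.start + 15)] * 3
        cov = region_coverage(_track(reads), [ev]).iloc[0]
        assert cov["upstream_intron"] == 0 and cov["downstream_intron"] == 0
        assert cov["exon"] > 0

    def test_empty_track_is_zero(self):
        ev = _event()
        t = _track([_iv(0, 10)])  # far away
        cov = region_coverage(t, [ev]).iloc[0]
        assert cov["exon"] == 0


class TestReferencePointProfile:
    def test_bin_count(self):
        ev = _event()
        prof = reference_point_profile(_track([_iv(0, 10)]), [ev], ["g1"])
        assert (prof["group"] == "g1").sum() == 50  # 2*250/10

    def test_planted_band_peaks_only_in_its_group(self):
        ev_a, ev_b = _event(), _event(chrom="chr2")
        point = ev_a.alt_exon.start
        reads = [_iv(point + 100, point + 150)] * 20
        prof = reference_point_profile(_track(reads), [ev_a, ev_b], ["A", "B"])
        peak_a = prof[(prof.group == "A") & (prof.bin_start == 100)]["mean"].iloc[0]
        assert peak_a > 0
        assert (prof[prof.group == "B"]["mean"] == 0).all()
        far_a = prof[(prof.group == "A") & (prof.bin_start == -200)]["mean"].iloc[0]
        assert far_a == 0

    def test_flank_must_divide_by_bin(self):
        with pytest.raises(ValueError):
            reference_point_profile(_track([_iv(0, 10)]), [_event()], ["g"], flank_nt=255)


class TestSpliceSiteStrength:
    def test_uniform_pwm_scores_zero(self):
        s3 = PwmScorer(np.full((23, 4), 0.25))
        s5 = PwmScorer(np.full((9, 4), 0.25))
        a, b = splice_site_strength("A" * 23, "C" * 9, s3, s5)
        assert a == pytest.approx(0.0) and b == pytest.approx(0.0)

    def test_consensus_is_maximal(self):
        rng = np.random.default_rng(0)
        pwm = rng.dirichlet(np.ones(4), size=9)
        scorer = PwmScorer(pwm)
        consensus = "".join("ACGT"[i] for i in pwm.argmax(axis=1))
        best = scorer.score(consensus)
        for _ in range(50):
            other = "".join(rng.choice(list("ACGT"), 9))
            assert scorer.score(other) <= best + 1e-9

    def test_hand_computed_toy_pwm(self):
        pwm = np.array(
            [[0.7, 0.1, 0.1, 0.1], [0.1, 0.7, 0.1, 0.1], [0.25, 0.25, 0.25, 0.25]]
        )
        scorer = PwmScorer(pwm)
        expected = np.log2(0.7 / 0.25) + np.log2(0.1 / 0.25) + np.log2(0.25 / 0.25)
        assert scorer.score("AGT") == pytest.approx(expected)

    def test_wrong_window_length_rejected(self):
        s3 = PwmScorer(np.full((23, 4), 0.25))
        s5 = PwmScorer(np.full((9, 4), 0.25))
        with pytest.raises(ValueError):
            splice_site_strength("A" * 22, "C" * 9, s3, s5)

    def test_scorer_estimated_from_sequences(self):
        seqs = ["ACG", "ACG", "ACT"]
        scorer = PwmScorer.from_sequences(seqs, pseudocount=0.0)
        assert scorer.score("ACG") > scorer.score("TGA")
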