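"""Contingency tests, interval overlaps, genetic features, rank tests."""

import itertools

import numpy as np
import pytest
from scipy import stats

from sacs.core_io import GenomicInterval
from sacs.comparative_stats import (
    fisher_exact_2x2,
    genetic_features,
    interval_overlap_counts,
    maintenance_analysis,
    splice_site_window_seqs,
    wilcoxon_compare,
)


def enumeration_fisher_p(a, b, c, d):
    """Two-sided Fisher p by explicit hypergeometric enumeration."""
    n1, k, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, k - (n - n1)), min(n1, k)
    pmf = {x: stats.hypergeom.pmf(x, n, n1, k) for x in range(lo, hi + 1)}
    p_obs = pmf[a]
    return min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9)))


class TestFisherExact:
    def test_in_text_maintenance_table_is_significant(self):
        # 16/33 excluded exons keep the signature vs 3/19 included
        res = fisher_exact_2x2([[16, 17], [3, 16]])
        assert res.p_two_sided < 0.05
        assert res.p_two_sided == pytest.approx(
            enumeration_fisher_p(16, 17, 3, 16), rel=1e-9
        )

    def test_symmetric_table(self):
        res = fisher_exact_2x2([[5, 5], [5, 5]])
        assert res.p_two_sided == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_zero_cell_odds_ratio_is_finite(self):
        res = fisher_exact_2x2([[10, 0], [2, 8]])
        assert np.isfinite(res.odds_ratio)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [0, 0]])

    def test_matches_enumeration_on_small_tables(self):
        for a, b, c, d in itertools.product(range(6), repeat=4):
            if a + b + c + d == 0:
                continue
            res = fisher_exact_2x2([[a, b], [c, d]])
            assert res.p_two_sided == pytest.approx(
                enumeration_fisher_p(a, b, c, d), rel=1e-7, abs=1e-12
            )


class TestIntervalOverlap:
    def test_half_open_adjacency(self):
        q = [GenomicInterval("c", 0, 100)]
        assert interval_overlap_counts(q, [GenomicInterval("c", 99, 150)]) == (1, 1)
        assert interval_overlap_counts(q, [GenomicInterval("c", 100, 150)]) == (0, 1)

    def test_disjoint(self):
        q = [GenomicInterval("c", i * 10, i * 10 + 5) for i in range(5)]
        assert interval_overlap_counts(q, [GenomicInterval("c", 1000, 1010)]) == (0, 5)

    def test_pair_intersections_symmetric(self):
        rng = np.random.default_rng(0)
        A = [GenomicInterval("c", int(s), int(s) + 30) for s in rng.integers(0, 2000, 40)]
        B = [GenomicInterval("c", int(s), int(s) + 50) for s in rng.integers(0, 2000, 30)]
        pairs_ab = sum(a.overlaps(b) for a in A for b in B)
        pairs_ba = sum(b.overlaps(a) for b in B for a in A)
        assert pairs_ab == pairs_ba


class TestMaintenance:
    def test_identical_condition_keeps_every_member(self, planted_dataset):
        from sacs.pipeline import peaks_from_tracks, prepare_tracks
        from sacs.sacs_discovery import (
            RegionSet, SacsSignature, _event_region, assign_members,
        )
        from sacs.splicing_quantification import quantify_events

        ds = planted_dataset
        peaks = peaks_from_tracks(prepare_tracks(ds.mark_reads))
        members_truth = [
            ev for ev, s in zip(ds.events, ds.truth["signature_id"]) if s
        ]
        regions = RegionSet(
            "exon_body", "excluded",
            [_event_region(ev, "exon_body", 200) for ev in members_truth],
            [ev.event_id for ev in members_truth],
        )
        sig = SacsSignature(
            "s", frozenset(("H4K20me1", "H3K79me2")), "exon_body", "excluded"
        )
        sig, _ = assign_members(sig, peaks, regions)
        psi_same = quantify_events(ds.events, ds.junctions)
        table = maintenance_analysis(sig, ds.events, psi_same, peaks)
        assert table.cells["lost"].sum() == 0
        assert table.cells["kept"].sum() == sig.n_members

    def test_shifted_condition_loses_marks_and_is_significant(self, planted_dataset):
        from sacs.pipeline import peaks_from_tracks, prepare_tracks
        from sacs.sacs_discovery import (
            RegionSet, SacsSignature, _event_region, assign_members,
        )
        from sacs.splicing_quantification import quantify_events
        from sacs.synthetic_data import simulate_shifted_condition

        ds = planted_dataset
        ds2 = simulate_shifted_condition(ds, shift_fraction=0.5, seed=3)
        peaks_a = peaks_from_tracks(prepare_tracks(ds.mark_reads))
        members_truth = [
            ev for ev, s in zip(ds.events, ds.truth["signature_id"]) if s
        ]
        regions = RegionSet(
            "exon_body", "excluded",
            [_event_region(ev, "exon_body", 200) for ev in members_truth],
            [ev.event_id for ev in members_truth],
        )
        sig = SacsSignature(
            "s", frozenset(("H4K20me1", "H3K79me2")), "exon_body", "excluded"
        )
        sig, _ = assign_members(sig, peaks_a, regions)
        psi_b = quantify_events(ds.events, ds2.junctions, condition="B")
        peaks_b = peaks_from_tracks(prepare_tracks(ds2.mark_reads))
        table = maintenance_analysis(sig, ds.events, psi_b, peaks_b)
        assert table.test is not None
        assert table.test.p_two_sided < 0.05
        kept_in_group = table.cells.loc["excluded", "kept"]
        lost_in_group = table.cells.loc["excluded", "lost"]
        assert kept_in_group > lost_in_group

    def test_no_shared_events_gives_empty_table(self, planted_dataset):
        from sacs.pipeline import peaks_from_tracks, prepare_tracks
        from sacs.sacs_discovery import SacsSignature

        ds = planted_dataset
        peaks = peaks_from_tracks(prepare_tracks(ds.mark_reads))
        sig = SacsSignature(
            "s", frozenset(("H4K20me1", "H3K79me2")), "exon_body", "excluded",
            member_events={"missing"}, n_members=1,
        )
        table = maintenance_analysis(sig, ds.events, [], peaks)
        assert table.test is None and table.cells.empty


class TestGeneticFeatures:
    def test_gc_ratio_and_tss_distance(self):
        from sacs.core_io import GeneModel
        from sacs.splicing_quantification import extract_cassette_events

        # exon GC 100%, introns GC 50% -> log2 ratio 1
        exon_len, intron = 100, 400
        flags = [True, True, False, True, True]
        exons, pos = [], 1000
        for i in range(5):
            exons.append(GenomicInterval("c", pos, pos + exon_len, "+"))
            pos += exon_len + intron
        model = GeneModel("g", "t", exons, "protein_coding", flags)
        (ev,) = extract_cassette_events([model])
        seq = ["A"] * 10_000
        for e in exons:
            for i in range(e.start, e.end):
                seq[i] = "G"
        for iv in (ev.upstream_intron, ev.downstream_intron):
            for i in range(iv.start, iv.end):
                seq[i] = "G" if (i % 2) else "A"
        genome = {"c": "".join(seq)}
        gf = genetic_features([ev], genome, [model], {"g": 100.0})
        row = gf.iloc[0]
        assert row.gc_log2_ratio_up == pytest.approx(1.0)
        assert row.gc_log2_ratio_down == pytest.approx(1.0)
        assert row.distance_to_tss_kb == pytest.approx((ev.alt_exon.start - 1000) / 1000)
        assert row.log_tpm == pytest.approx(2.0)
        assert row.exon_length == exon_len
        assert row.n_exons_in_gene == 5

    def test_splice_site_windows_have_canonical_dinucleotides(self, small_dataset):
        ds = small_dataset
        hits = 0
        for ev in ds.events[:20]:
            s3, s5 = splice_site_window_seqs(ev, ds.genome)
            assert len(s3) == 23 and len(s5) == 9
            hits += s3[18:20] == "AG" and s5[3:5] == "GT"
        assert hits == 20


class TestWilcoxon:
    def test_identical_samples_not_significant(self):
        out = wilcoxon_compare(
            {"a": [1, 2, 3, 4, 5], "ref": [1, 2, 3, 4, 5]}, ["ref"]
        )
        assert out.iloc[0].p_raw > 0.9

    def test_separated_normals_significant_after_correction(self):
        rng = np.random.default_rng(0)
        out = wilcoxon_compare(
            {
                "a": rng.normal(3, 1, 100),
                "b": rng.normal(0, 1, 100),
                "ref": rng.normal(0, 1, 100),
            },
            ["ref"],
        )
        pa = out[out.group == "a"].iloc[0]
        pb = out[out.group == "b"].iloc[0]
        assert pa.p_corrected < 0.001
        assert pb.p_corrected > 0.05

    def test_single_comparison_unchanged_by_bonferroni(self):
        out = wilcoxon_compare({"a": [1, 2, 9, 10], "ref": [3, 4, 5, 6]}, ["ref"])
        assert out.iloc[0].p_corrected == pytest.approx(
            min(1.0, out.iloc[0].p_raw), rel=1e-12
        )

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_compare({"a": [1.0], "ref": [1, 2]}, ["ref"])
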