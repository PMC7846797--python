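"""Region sets, block-bootstrap co-enrichment, reciprocity, uniqueness."""

import math

import numpy as np
import pytest

from sacs.core_io import GeneModel, GenomicInterval
from sacs.epigenomic_features import PeakCluster
from sacs.sacs_discovery import (
    CoEnrichmentResult,
    RegionSet,
    assign_members,
    block_bootstrap_z,
    co_enrichment,
    co_enrichment_scan,
    make_region_sets,
    permutation_oracle_z,
    randomize_group_labels,
    reciprocity_filter,
    uniqueness_filter,
)
from sacs.splicing_quantification import extract_cassette_events


def _event(start=5000, strand="+", chrom="chr1", exon_len=100, intron=1000):
    """Exon triplet whose alternative exon starts at ``start``."""
    flags = [True, True, False, True, True]
    exons = []
    pos = start - 2 * (150 + intron)
    for i in range(5):
        length = exon_len if i == 2 else 150
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length + intron
    if strand == "-":
        exons = exons[::-1]
    model = GeneModel(f"g{chrom}{start}", "t", exons, "protein_coding", flags)
    (ev,) = extract_cassette_events([model])
    return ev


def _cluster(s, e, chrom="chr1"):
    return PeakCluster(GenomicInterval(chrom, s, e, "."), 2)


def _regions(n, length=200, gap=2000, seed=None):
    ivs = [GenomicInterval("chr1", i * gap, i * gap + length, "+") for i in range(n)]
    return RegionSet("exon_body", "excluded", ivs, [f"e{i}" for i in range(n)])


class TestMakeRegionSets:
    def test_plus_strand_arithmetic(self):
        ev = _event(strand="+")
        sets = make_region_sets([ev], ["excluded"])
        by_kind = {s.region_kind: s.intervals[0] for s in sets}
        alt = ev.alt_exon
        assert (by_kind["upstream_200"].start, by_kind["upstream_200"].end) == (
            alt.start - 200, alt.start)
        assert (by_kind["exon_body"].start, by_kind["exon_body"].end) == (
            alt.start, alt.end)
        assert (by_kind["downstream_200"].start, by_kind["downstream_200"].end) == (
            alt.end, alt.end + 200)

    def test_minus_strand_upstream_is_genomic_right(self):
        ev = _event(strand="-")
        sets = make_region_sets([ev], ["excluded"])
        by_kind = {s.region_kind: s.intervals[0] for s in sets}
        alt = ev.alt_exon
        assert (by_kind["upstream_200"].start, by_kind["upstream_200"].end) == (
            alt.end, alt.end + 200)
        assert (by_kind["downstream_200"].end) == alt.start

    def test_short_intron_clips_flank(self):
        ev = _event(intron=120)
        sets = make_region_sets([ev], ["excluded"])
        up = next(s for s in sets if s.region_kind == "upstream_200")
        assert len(up.intervals[0]) == 120

    def test_constitutive_control_capped_at_600(self):
        events = [
            _event(chrom=f"c{i}") for i in range(5)
        ]  # few events, many controls
        controls = [_event(chrom=f"k{i}") for i in range(700)]
        sets = make_region_sets(
            [events[0]], ["excluded"], constitutive_events=controls, seed=1
        )
        const = [s for s in sets if s.group == "constitutive"]
        assert all(len(s.intervals) == 600 for s in const)


class TestBlockBootstrapZ:
    def test_planted_co_occurrence_is_significant(self):
        rng = np.random.default_rng(0)
        regions = _regions(200)
        peaks_a, peaks_b = [], []
        members = rng.random(200) < 0.5
        for i, iv in enumerate(regions.intervals):
            if members[i]:  # both marks present at members
                peaks_a.append(_cluster(iv.start + 10, iv.start + 60))
                peaks_b.append(_cluster(iv.start + 20, iv.start + 80))
            elif rng.random() < 0.1:  # sparse background, one mark
                peaks_a.append(_cluster(iv.start + 10, iv.start + 60))
        res = co_enrichment(peaks_a, peaks_b, regions, seed=1)
        assert res.z_ab > 5 and res.z_ba > 5
        assert res.reciprocal

    def test_independent_placements_are_null(self):
        extreme = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            regions = _regions(150)
            pa = [
                _cluster(iv.start + 5, iv.start + 40)
                for iv, keep in zip(regions.intervals, rng.random(150) < 0.4)
                if keep
            ]
            pb = [
                _cluster(iv.start + 50, iv.start + 90)
                for iv, keep in zip(regions.intervals, rng.random(150) < 0.4)
                if keep
            ]
            res = block_bootstrap_z(pa, pb, regions, seed=seed)
            if abs(res.z_ab) > 3:
                extreme += 1
        assert extreme <= 1

    def test_degenerate_null_gives_zero(self):
        regions = _regions(50)
        peaks = [_cluster(iv.start, iv.end) for iv in regions.intervals]
        res = block_bootstrap_z(peaks, peaks, regions, seed=0)
        # presence everywhere: every permutation gives the same count
        assert res.z_ab == 0.0

    def test_parameter_validation(self):
        regions = _regions(10)
        with pytest.raises(ValueError):
            block_bootstrap_z([], [], regions, r=1.5)
        with pytest.raises(ValueError):
            block_bootstrap_z([], [], regions, n=10)
        with pytest.raises(ValueError):
            block_bootstrap_z([], [], RegionSet("exon_body", "excluded", [], []))


class TestPermutationOracle:
    def test_agrees_with_bootstrap_on_planted_and_null(self):
        agree_sig = 0
        n_inst = 12
        for seed in range(n_inst):
            rng = np.random.default_rng(seed)
            regions = _regions(120)
            planted = seed % 2 == 0
            pa, pb = [], []
            for iv, m, ba, bb in zip(
                regions.intervals,
                rng.random(120) < 0.5,
                rng.random(120) < 0.15,
                rng.random(120) < 0.15,
            ):
                if planted and m:
                    pa.append(_cluster(iv.start + 10, iv.start + 50))
                    pb.append(_cluster(iv.start + 30, iv.start + 70))
                else:
                    if ba:
                        pa.append(_cluster(iv.start + 10, iv.start + 50))
                    if bb:
                        pb.append(_cluster(iv.start + 30, iv.start + 70))
            zb = block_bootstrap_z(pa, pb, regions, seed=seed).z_ab
            zo = permutation_oracle_z(pa, pb, regions, n_perm=400, seed=seed)
            agree_sig += (zb >= 3) == (zo >= 3)
            if max(abs(zb), abs(zo)) > 3:
                assert math.copysign(1, zb) == math.copysign(1, zo)
        assert agree_sig >= n_inst - 1

    def test_no_peaks_is_undefined(self):
        regions = _regions(20)
        assert math.isnan(permutation_oracle_z([], [], regions, n_perm=50, seed=0))


def _result(pair, region, group, z_ab, z_ba):
    a, b = pair
    res = CoEnrichmentResult(a, b, region, group, z_ab, z_ba, 10, 5.0, 1.0, 100, 0.1)
    res.reciprocal = res.significant = z_ab >= 3 and z_ba >= 3
    return res


class TestReciprocityFilter:
    def test_one_sided_enrichment_dropped(self):
        kept = reciprocity_filter(
            [_result(("A", "B"), "exon_body", "excluded", 6.0, 1.0)]
        )
        assert kept == []

    def test_reciprocal_kept_and_flagged(self):
        (res,) = reciprocity_filter(
            [_result(("A", "B"), "exon_body", "excluded", 5.0, 5.0)]
        )
        assert res.reciprocal and res.significant

    def test_empty(self):
        assert reciprocity_filter([]) == []

    def test_missing_direction_dropped(self):
        res = _result(("A", "B"), "exon_body", "excluded", 6.0, float("nan"))
        assert reciprocity_filter([res]) == []


class TestUniquenessFilter:
    def test_multi_group_combo_discarded(self):
        results = [
            _result(("A", "B"), "exon_body", "excluded", 5, 5),
            _result(("A", "B"), "exon_body", "included", 5, 5),
        ]
        assert uniqueness_filter(results) == []

    def test_single_group_combo_emitted(self):
        results = [
            _result(("A", "B"), "upstream_200", "mid_excluded", 5, 5),
            _result(("A", "B"), "upstream_200", "included", 1, 1),
        ]
        (sig,) = uniqueness_filter(results)
        assert sig.group == "mid_excluded"
        assert sig.mark_pair == frozenset(("A", "B"))

    def test_constitutive_control_hit_discards(self):
        results = [
            _result(("A", "B"), "exon_body", "excluded", 5, 5),
            _result(("A", "B"), "exon_body", "constitutive", 5, 5),
        ]
        assert uniqueness_filter(results) == []


class TestAssignMembers:
    def test_breakdown_partitions_the_group(self):
        regions = _regions(30)
        pa = [_cluster(iv.start, iv.start + 50) for iv in regions.intervals[:20]]
        pb = [_cluster(iv.start + 5, iv.start + 60) for iv in regions.intervals[10:25]]
        from sacs.sacs_discovery import SacsSignature

        sig = SacsSignature("s", frozenset(("A", "B")), "exon_body", "excluded")
        sig, breakdown = assign_members(sig, {"A": pa, "B": pb}, regions)
        assert breakdown["both"] == 10 and sig.n_members == 10
        assert breakdown["both"] + breakdown["one"] + breakdown["none"] == 30


class TestScanProperties:
    def test_mark_label_swap_leaves_signatures_invariant(self, planted_dataset):
        from sacs.pipeline import peaks_from_tracks, prepare_tracks

        ds = planted_dataset
        tracks = prepare_tracks(ds.mark_reads)
        peaks = peaks_from_tracks(tracks)
        sets = make_region_sets(
            ds.events, ds.groups, constitutive_events=ds.constitutive_events, seed=0
        )
        use = {m: peaks[m] for m in ("H4K20me1", "H3K79me2", "H3K9me3")}
        res1 = co_enrichment_scan(use, sets, n_boot=300, seed=4)
        swapped = dict(use)
        swapped["H4K20me1"], swapped["H3K79me2"] = use["H3K79me2"], use["H4K20me1"]
        res2 = co_enrichment_scan(swapped, sets, n_boot=300, seed=4)
        sigs1 = {(s.mark_pair, s.region_kind, s.group) for s in uniqueness_filter(reciprocity_filter(res1))}
        swap = {"H4K20me1": "H3K79me2", "H3K79me2": "H4K20me1"}
        sigs2 = {
            (frozenset(swap.get(m, m) for m in s.mark_pair), s.region_kind, s.group)
            for s in uniqueness_filter(reciprocity_filter(res2))
        }
        assert sigs1 == sigs2
        assert any(s[0] == frozenset(("H4K20me1", "H3K79me2")) for s in sigs1)


def test_randomize_group_labels_is_a_permutation():
    groups = ["a"] * 5 + ["b"] * 3
    out = randomize_group_labels(groups, seed=3)
    assert sorted(out) == sorted(groups)
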