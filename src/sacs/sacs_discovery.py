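"""Calling splicing-associated chromatin signatures (SACS).

A SACS is an unordered pair of chromatin marks reciprocally co-enriched
at one of three exon-anchored regions (upstream 200-nt intronic, exon
body, downstream 200-nt intronic) uniquely in one splicing group.  The
co-occurrence statistic is the number of regions of a group overlapped
by peaks of *both* marks; its null distribution comes from a moving-block
bootstrap of one mark's per-region presence indicator (blocks of a
fraction ``r`` of the regions, in genomic order, resampled with
replacement), yielding a z-score per direction.  Reciprocity requires
both directions to exceed the threshold; uniqueness requires the
(pair, region) co-enrichment in exactly one splicing group and in no
control set (constitutive exons from the same genes).  An independent
permutation oracle (uniform re-placement of peaks inside the concatenated
region space) guards the bootstrap's calibration.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import GenomicInterval
from .epigenomic_features import MarkTrack, PeakCluster
from .splicing_quantification import GROUPS, CassetteEvent

logger = logging.getLogger(__name__)

REGION_KINDS = ("upstream_200", "exon_body", "downstream_200")

#: Default z threshold for a significant co-enrichment direction
#: (roughly two-sided p < 0.003 under a normal null).
DEFAULT_Z_MIN = 3.0

#: Control exon sets are capped at this many sampled regions.
CONTROL_CAP = 600


@dataclass
class RegionSet:
    """One region kind for one splicing group (or control set).

    ``intervals`` are transcription-order-oriented, one per event, sorted
    by genomic position (the order the block bootstrap resamples in);
    ``event_ids`` stays aligned with ``intervals``.
    """

    region_kind: str
    group: str  # splicing group, "constitutive" or "randomized"
    intervals: list[GenomicInterval]
    event_ids: list[str]

    def __post_init__(self) -> None:
        order = sorted(
            range(len(self.intervals)),
            key=lambda i: (self.intervals[i].chrom, self.intervals[i].start),
        )
        self.intervals = [self.intervals[i] for i in order]
        self.event_ids = [self.event_ids[i] for i in order]


@dataclass
class CoEnrichmentResult:
    mark_a: str
    mark_b: str
    region_kind: str
    group: str
    z_ab: float
    z_ba: float
    observed_overlap: int
    boot_mean: float
    boot_sd: float
    n_boot: int
    r_fraction: float
    significant: bool = False
    reciprocal: bool = False


@dataclass
class SacsSignature:
    signature_id: str
    mark_pair: frozenset
    region_kind: str
    group: str
    member_events: set = field(default_factory=set)
    n_members: int = 0


# ---------------------------------------------------------------------------
# Region construction
# ---------------------------------------------------------------------------

def _event_region(event: CassetteEvent, kind: str, flank_nt: int) -> GenomicInterval:
    """The region of ``kind`` for one event, clipped at the flanking exon."""
    alt = event.alt_exon
    if kind == "exon_body":
        return alt
    if kind == "upstream_200":
        intron = event.upstream_intron
        w = min(flank_nt, len(intron))
        if w < flank_nt:
            logger.debug("upstream flank of %s clipped to %d nt", event.event_id, w)
        # slice of the upstream intron adjacent to the exon (3'ss side)
        if event.strand == "+":
            return GenomicInterval(alt.chrom, intron.end - w, intron.end, "+")
        return GenomicInterval(alt.chrom, intron.start, intron.start + w, "-")
    if kind == "downstream_200":
        intron = event.downstream_intron
        w = min(flank_nt, len(intron))
        if event.strand == "+":
            return GenomicInterval(alt.chrom, intron.start, intron.start + w, "+")
        return GenomicInterval(alt.chrom, intron.end - w, intron.end, "-")
    raise ValueError(f"unknown region kind {kind!r}")


def make_region_sets(
    events: Sequence[CassetteEvent],
    groups: Sequence[str],
    flank_nt: int = 200,
    constitutive_events: Sequence[CassetteEvent] | None = None,
    control_cap: int = CONTROL_CAP,
    seed: int = 0,
) -> list[RegionSet]:
    """Build the three exon-anchored region sets per splicing group.

    ``constitutive_events`` (exon triplets centred on constitutive exons
    from the same genes) yield the constitutive control sets, sampled
    without replacement down to ``control_cap`` regions.
    """
    rng = np.random.default_rng(seed)
    sets: list[RegionSet] = []
    by_group: dict[str, list[CassetteEvent]] = {g: [] for g in GROUPS}
    for ev, grp in zip(events, groups):
        if grp in by_group:
            by_group[grp].append(ev)

    pools: list[tuple[str, list[CassetteEvent]]] = [
        (g, evs) for g, evs in by_group.items() if evs
    ]
    if constitutive_events:
        const = list(constitutive_events)
        if len(const) > control_cap:
            idx = rng.choice(len(const), size=control_cap, replace=False)
            const = [const[i] for i in sorted(idx)]
        pools.append(("constitutive", const))

    for group, evs in pools:
        for kind in REGION_KINDS:
            sets.append(
                RegionSet(
                    region_kind=kind,
                    group=group,
                    intervals=[_event_region(ev, kind, flank_nt) for ev in evs],
                    event_ids=[ev.event_id for ev in evs],
                )
            )
    return sets


def randomize_group_labels(groups: Sequence[str], seed: int) -> list[str]:
    """Shuffled copy of the group labels (the randomised-inclusion control)."""
    rng = np.random.default_rng(seed)
    out = list(groups)
    return [out[i] for i in rng.permutation(len(out))]


# ---------------------------------------------------------------------------
# Presence vectors and the block bootstrap
# ---------------------------------------------------------------------------

def presence_vector(
    peaks: Sequence[PeakCluster] | MarkTrack, regions: RegionSet
) -> np.ndarray:
    """Boolean vector: does any peak overlap each region."""
    if isinstance(peaks, MarkTrack):
        track = peaks
    else:
        track = MarkTrack.from_intervals(
            "peaks", [p.interval for p in peaks]
        )
    out = np.zeros(len(regions.intervals), dtype=bool)
    for i, iv in enumerate(regions.intervals):
        out[i] = track.count(iv.chrom, iv.start, iv.end) > 0
    return out


def _block_bootstrap_counts(
    fixed: np.ndarray,
    resampled: np.ndarray,
    r: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Co-occurrence counts with ``resampled`` block-bootstrapped.

    Blocks are runs of ``ceil(r * N)`` consecutive regions (genomic
    order); each replicate concatenates uniformly drawn blocks (with
    replacement) to length N.
    """
    N = fixed.size
    block = max(1, int(math.ceil(r * N)))
    n_blocks = int(math.ceil(N / block))
    starts = rng.integers(0, N - block + 1, size=(n, n_blocks))
    idx = (starts[:, :, None] + np.arange(block)[None, None, :]).reshape(n, -1)[:, :N]
    return (fixed[None, :] & resampled[idx]).sum(axis=1)


def block_bootstrap_z(
    peaks_a: Sequence[PeakCluster] | MarkTrack,
    peaks_b: Sequence[PeakCluster] | MarkTrack,
    regions: RegionSet,
    r: float = 0.1,
    n: int = 1000,
    seed: int = 0,
    mark_a: str = "A",
    mark_b: str = "B",
) -> CoEnrichmentResult:
    """z-score of the observed A∧B region co-occurrence versus the
    block-bootstrap null (direction a→b: B's presence is resampled).

    Returns a CoEnrichmentResult with ``z_ab`` filled; ``z_ba`` is NaN
    (compute it by swapping the arguments, or use ``co_enrichment``).
    """
    if not 0 < r < 1:
        raise ValueError("r must be in (0, 1)")
    if n < 100:
        raise ValueError("need >= 100 bootstrap replicates")
    if not regions.intervals:
        raise ValueError("empty region set")
    a = presence_vector(peaks_a, regions)
    b = presence_vector(peaks_b, regions)
    rng = np.random.default_rng(seed)
    observed = int((a & b).sum())
    counts = _block_bootstrap_counts(a, b, r, n, rng)
    mean, sd = float(counts.mean()), float(counts.std(ddof=1))
    if sd == 0:
        z = 0.0 if observed == mean else math.inf * np.sign(observed - mean)
        if not math.isfinite(z):
            logger.warning(
                "degenerate bootstrap null for %s/%s in %s:%s",
                mark_a, mark_b, regions.group, regions.region_kind,
            )
    else:
        z = (observed - mean) / sd
    return CoEnrichmentResult(
        mark_a=mark_a,
        mark_b=mark_b,
        region_kind=regions.region_kind,
        group=regions.group,
        z_ab=float(z),
        z_ba=float("nan"),
        observed_overlap=observed,
        boot_mean=mean,
        boot_sd=sd,
        n_boot=n,
        r_fraction=r,
    )


def co_enrichment(
    peaks_a: Sequence[PeakCluster] | MarkTrack,
    peaks_b: Sequence[PeakCluster] | MarkTrack,
    regions: RegionSet,
    r: float = 0.1,
    n: int = 1000,
    seed: int = 0,
    mark_a: str = "A",
    mark_b: str = "B",
    z_min: float = DEFAULT_Z_MIN,
) -> CoEnrichmentResult:
    """Both bootstrap directions for one mark pair in one region set."""
    res_ab = block_bootstrap_z(peaks_a, peaks_b, regions, r, n, seed, mark_a, mark_b)
    res_ba = block_bootstrap_z(peaks_b, peaks_a, regions, r, n, seed + 1, mark_b, mark_a)
    res_ab.z_ba = res_ba.z_ab
    res_ab.significant = res_ab.z_ab >= z_min and res_ab.z_ba >= z_min
    res_ab.reciprocal = res_ab.significant
    return res_ab


def co_enrichment_scan(
    peaks_by_mark: Mapping[str, Sequence[PeakCluster]],
    region_sets: Sequence[RegionSet],
    r: float = 0.1,
    n_boot: int = 1000,
    z_min: float = DEFAULT_Z_MIN,
    seed: int = 0,
) -> list[CoEnrichmentResult]:
    """All mark pairs x all region sets, with shared presence caching."""
    marks = sorted(peaks_by_mark)
    tracks = {
        m: MarkTrack.from_intervals(m, [p.interval for p in peaks_by_mark[m]])
        for m in marks
    }
    results: list[CoEnrichmentResult] = []
    for si, regions in enumerate(region_sets):
        presence = {m: presence_vector(tracks[m], regions) for m in marks}
        N = len(regions.intervals)
        if N == 0:
            continue
        rng = np.random.default_rng([seed, si])
        for mark_a, mark_b in itertools.combinations(marks, 2):
            a, b = presence[mark_a], presence[mark_b]
            observed = int((a & b).sum())
            zs = []
            for fixed, moved in ((a, b), (b, a)):
                counts = _block_bootstrap_counts(fixed, moved, r, n_boot, rng)
                mean, sd = float(counts.mean()), float(counts.std(ddof=1))
                if sd == 0:
                    z = 0.0 if observed == mean else math.inf * np.sign(observed - mean)
                else:
                    z = (observed - mean) / sd
                zs.append((float(z), mean, sd))
            res = CoEnrichmentResult(
                mark_a=mark_a,
                mark_b=mark_b,
                region_kind=regions.region_kind,
                group=regions.group,
                z_ab=zs[0][0],
                z_ba=zs[1][0],
                observed_overlap=observed,
                boot_mean=zs[0][1],
                boot_sd=zs[0][2],
                n_boot=n_boot,
                r_fraction=r,
            )
            res.significant = res.z_ab >= z_min and res.z_ba >= z_min
            res.reciprocal = res.significant
            results.append(res)
    return results


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def reciprocity_filter(
    results: Sequence[CoEnrichmentResult], z_min: float = DEFAULT_Z_MIN
) -> list[CoEnrichmentResult]:
    """Keep pairs significant in both directions (A→B and B→A)."""
    kept = []
    for res in results:
        if math.isnan(res.z_ab) or math.isnan(res.z_ba):
            logger.warning(
                "pair %s/%s missing a direction; dropped", res.mark_a, res.mark_b
            )
            continue
        if res.z_ab >= z_min and res.z_ba >= z_min:
            res.significant = True
            res.reciprocal = True
            kept.append(res)
    return kept


def uniqueness_filter(
    results: Sequence[CoEnrichmentResult],
    control_kinds: tuple[str, ...] = ("constitutive",),
) -> list[SacsSignature]:
    """Keep (pair, region) combinations reciprocally significant in exactly
    one splicing group and in no control set."""
    by_combo: dict[tuple[frozenset, str], dict[str, bool]] = {}
    for res in results:
        key = (frozenset((res.mark_a, res.mark_b)), res.region_kind)
        by_combo.setdefault(key, {})[res.group] = bool(res.reciprocal)
    signatures: list[SacsSignature] = []
    for (pair, kind), flags in sorted(
        by_combo.items(), key=lambda kv: (sorted(kv[0][0]), kv[0][1])
    ):
        sig_groups = [g for g, ok in flags.items() if ok and g in GROUPS]
        ctrl_hit = any(flags.get(c, False) for c in control_kinds)
        if len(sig_groups) == 1 and not ctrl_hit:
            group = sig_groups[0]
            signatures.append(
                SacsSignature(
                    signature_id=f"SACS:{'+'.join(sorted(pair))}:{kind}:{group}",
                    mark_pair=pair,
                    region_kind=kind,
                    group=group,
                )
            )
    return signatures


def _midpoint_track(peaks: Sequence[PeakCluster]) -> MarkTrack:
    mids = [
        GenomicInterval(
            p.interval.chrom,
            (p.interval.start + p.interval.end) // 2,
            (p.interval.start + p.interval.end) // 2 + 1,
            ".",
        )
        for p in peaks
    ]
    return MarkTrack.from_intervals("mid", mids)


def localize_signatures(
    signatures: Sequence[SacsSignature],
    results: Sequence[CoEnrichmentResult],
    peaks_by_mark: Mapping[str, Sequence[PeakCluster]] | None = None,
    region_sets: Sequence[RegionSet] | None = None,
) -> list[SacsSignature]:
    """Keep one region per (mark pair, group): the signature's position.

    Read extension (200 nt) blurs a localised co-enrichment into the
    adjacent exon-anchored regions, so a single physical signature can
    reach the reciprocity threshold at two neighbouring positions; since
    a merged cluster usually crosses a region boundary by a few bases,
    any-overlap counts cannot break the tie.  The position is therefore
    the region where most events carry the *midpoints* of clusters of
    both marks (each midpoint falls in exactly one region); without peak
    data the region with the largest min(z_ab, z_ba) is kept.
    """
    z_strength: dict[tuple[frozenset, str, str], float] = {}
    for res in results:
        key = (frozenset((res.mark_a, res.mark_b)), res.region_kind, res.group)
        z_strength[key] = min(res.z_ab, res.z_ba)

    mid_tracks: dict[str, MarkTrack] = {}
    region_by_key: dict[tuple[str, str], RegionSet] = {}
    if peaks_by_mark is not None and region_sets is not None:
        mid_tracks = {m: _midpoint_track(p) for m, p in peaks_by_mark.items()}
        region_by_key = {(s.group, s.region_kind): s for s in region_sets}

    def score(sig: SacsSignature) -> tuple[float, float]:
        z = z_strength.get((sig.mark_pair, sig.region_kind, sig.group), float("-inf"))
        mid_cooc = float("-inf")
        regions = region_by_key.get((sig.group, sig.region_kind))
        if regions is not None:
            a, b = sorted(sig.mark_pair)
            pa = presence_vector(mid_tracks[a], regions)
            pb = presence_vector(mid_tracks[b], regions)
            mid_cooc = float((pa & pb).sum())
        return (mid_cooc, z)

    best: dict[tuple[frozenset, str], tuple[tuple[float, float], SacsSignature]] = {}
    for sig in signatures:
        key = (sig.mark_pair, sig.group)
        s = score(sig)
        if key not in best or s > best[key][0]:
            best[key] = (s, sig)
    return sorted((sig for _, sig in best.values()), key=lambda s: s.signature_id)


def assign_members(
    signature: SacsSignature,
    peaks_by_mark: Mapping[str, Sequence[PeakCluster]],
    regions: RegionSet,
) -> tuple[SacsSignature, dict[str, int]]:
    """Fill member events (defining region overlaps peaks of BOTH marks).

    Also returns the both / one-mark-only / neither breakdown of the
    group's events; the three counts partition the group.
    """
    mark_a, mark_b = sorted(signature.mark_pair)
    pa = presence_vector(list(peaks_by_mark[mark_a]), regions)
    pb = presence_vector(list(peaks_by_mark[mark_b]), regions)
    both = pa & pb
    one = (pa | pb) & ~both
    members = {eid for eid, hit in zip(regions.event_ids, both) if hit}
    signature.member_events = members
    signature.n_members = len(members)
    breakdown = {
        "both": int(both.sum()),
        "one": int(one.sum()),
        "none": int((~(pa | pb)).sum()),
    }
    return signature, breakdown


# ---------------------------------------------------------------------------
# Independent permutation oracle
# ---------------------------------------------------------------------------

def _concat_presence(
    starts: np.ndarray, widths: np.ndarray, boundaries: np.ndarray
) -> np.ndarray:
    """Region presence for peaks placed on the concatenated region line."""
    n_regions = boundaries.size - 1
    ends = starts + widths
    lo = np.searchsorted(boundaries, starts, side="right") - 1
    hi = np.searchsorted(boundaries, ends, side="left") - 1
    lo = np.clip(lo, 0, n_regions - 1)
    hi = np.clip(hi, 0, n_regions - 1)
    diff = np.zeros(n_regions + 1, dtype=int)
    np.add.at(diff, lo, 1)
    np.add.at(diff, hi + 1, -1)
    return np.cumsum(diff[:-1]) > 0


def permutation_oracle_z(
    peaks_a: Sequence[PeakCluster],
    peaks_b: Sequence[PeakCluster],
    regions: RegionSet,
    n_perm: int = 500,
    seed: int = 0,
) -> float:
    """z of the observed co-occurrence against uniform re-placement of the
    peaks inside the concatenated region space.

    An independent null for small instances (<= a few hundred regions):
    every peak overlapping the region space is re-placed, preserving its
    length, uniformly on the concatenated coordinate line; both marks are
    re-placed independently.  Returns NaN when either mark has no peak in
    the region space.
    """
    lengths = np.array([len(iv) for iv in regions.intervals], dtype=int)
    boundaries = np.concatenate([[0], np.cumsum(lengths)])
    total = int(boundaries[-1])

    track = MarkTrack.from_intervals("r", regions.intervals)

    def in_space(peaks: Sequence[PeakCluster]) -> np.ndarray:
        widths = [
            min(len(p.interval), total)
            for p in peaks
            if track.count(p.interval.chrom, p.interval.start, p.interval.end) > 0
        ]
        return np.asarray(widths, dtype=int)

    widths_a, widths_b = in_space(peaks_a), in_space(peaks_b)
    if widths_a.size == 0 or widths_b.size == 0:
        logger.warning("permutation oracle undefined: a mark has no peaks in space")
        return float("nan")

    pa = presence_vector(list(peaks_a), regions)
    pb = presence_vector(list(peaks_b), regions)
    observed = int((pa & pb).sum())

    rng = np.random.default_rng(seed)
    counts = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        sa = rng.integers(0, total - widths_a + 1)
        sb = rng.integers(0, total - widths_b + 1)
        qa = _concat_presence(sa, widths_a, boundaries)
        qb = _concat_presence(sb, widths_b, boundaries)
        counts[i] = int((qa & qb).sum())
    mean, sd = counts.mean(), counts.std(ddof=1)
    if sd == 0:
        return 0.0 if observed == mean else math.inf * np.sign(observed - mean)
    return float((observed - mean) / sd)
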