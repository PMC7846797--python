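"""Chromatin read tracks, peak clusters and splice-site-anchored features.

Aligned ChIP/MeDIP reads (BED intervals) are extended to 200 nt in the 5'
to 3' direction, optionally merged into clusters of >= 2 overlapping
reads and filtered against an input track, and summarised as normalised
read densities (reads per kilobase of region per million mapped reads,
RPKM-like) in 100-nt windows on either side of the 3' and 5' splice
sites of each cassette exon.  These densities are the epigenetic feature
matrix consumed by the shadow-feature selection step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core_io import PWM_PROB_FLOOR, GenomicInterval
from .splicing_quantification import CassetteEvent

logger = logging.getLogger(__name__)

FEATURE_SITES = ("3ss", "5ss")
FEATURE_SIDES = ("intronic_100", "exonic_100")


# ---------------------------------------------------------------------------
# Read tracks
# ---------------------------------------------------------------------------

@dataclass
class MarkTrack:
    """A chromatin mark's read placements with O(log n) overlap counting.

    Interval starts and ends are kept as independently sorted arrays per
    chromosome so the number of reads overlapping a window [s, e) is
    ``n - #(starts >= e) - #(ends <= s)`` (the two excluded sets are
    disjoint for half-open intervals with s < e).
    """

    mark: str
    library_size: int
    input_track: "MarkTrack | None" = None
    _starts: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _ends: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _intervals: list[GenomicInterval] = field(default_factory=list, repr=False)

    @classmethod
    def from_intervals(
        cls,
        mark: str,
        intervals: Sequence[GenomicInterval],
        input_track: "MarkTrack | None" = None,
    ) -> "MarkTrack":
        track = cls(mark=mark, library_size=len(intervals), input_track=input_track)
        track._intervals = list(intervals)
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, pairs in by_chrom.items():
            arr = np.asarray(pairs, dtype=np.int64)
            track._starts[chrom] = np.sort(arr[:, 0])
            track._ends[chrom] = np.sort(arr[:, 1])
        return track

    @property
    def reads(self) -> list[GenomicInterval]:
        return self._intervals

    def count(self, chrom: str, start: int, end: int) -> int:
        """Number of reads overlapping [start, end) on ``chrom``."""
        starts = self._starts.get(chrom)
        if starts is None:
            return 0
        ends = self._ends[chrom]
        n = starts.size
        return int(
            n
            - (n - np.searchsorted(starts, end, side="left"))
            - np.searchsorted(ends, start, side="right")
        )

    def count_windows(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorised ``count`` over parallel window arrays."""
        s = self._starts.get(chrom)
        if s is None:
            return np.zeros(len(starts), dtype=np.int64)
        e = self._ends[chrom]
        n = s.size
        return (
            n
            - (n - np.searchsorted(s, ends, side="left"))
            - np.searchsorted(e, starts, side="right")
        )


@dataclass
class PeakCluster:
    """A merged run of >= 2 transitively overlapping extended reads."""

    interval: GenomicInterval
    n_reads: int
    above_input: bool = True

    def __post_init__(self) -> None:
        if self.n_reads < 2:
            raise ValueError("clusters of a single read are discarded")


def extend_reads(
    reads: Sequence[GenomicInterval], length: int = 200
) -> list[GenomicInterval]:
    """Extend each read to ``length`` nt in its 5'->3' direction.

    Plus-strand (and strandless, with a warning) reads keep their start;
    minus-strand reads keep their end.  Extension past the contig start is
    clipped at 0 and counted.
    """
    out: list[GenomicInterval] = []
    clipped = 0
    strandless = 0
    for iv in reads:
        if len(iv) > length:
            raise ValueError(f"extension length {length} shorter than read {iv}")
        if iv.strand == "-":
            start = iv.end - length
            if start < 0:
                start = 0
                clipped += 1
            out.append(GenomicInterval(iv.chrom, start, iv.end, "-"))
        else:
            if iv.strand == ".":
                strandless += 1
            out.append(GenomicInterval(iv.chrom, iv.start, iv.start + length, iv.strand))
    if strandless:
        logger.warning("%d strandless reads extended as plus-strand", strandless)
    if clipped:
        logger.info("%d reads clipped at contig start during extension", clipped)
    return out


def build_clusters(reads: Sequence[GenomicInterval]) -> list[PeakCluster]:
    """Merge transitively overlapping reads; drop single-read clusters."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in reads:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    clusters: list[PeakCluster] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end, n = ivs[0].start, ivs[0].end, 1
        for iv in ivs[1:]:
            if iv.start < cur_end:  # strict: touching intervals do not overlap
                cur_end = max(cur_end, iv.end)
                n += 1
            else:
                if n >= 2:
                    clusters.append(
                        PeakCluster(GenomicInterval(chrom, cur_start, cur_end, "."), n)
                    )
                cur_start, cur_end, n = iv.start, iv.end, 1
        if n >= 2:
            clusters.append(
                PeakCluster(GenomicInterval(chrom, cur_start, cur_end, "."), n)
            )
    return clusters


def normalize_against_input(
    clusters: Sequence[PeakCluster],
    input_track: MarkTrack | None,
    track_library_size: int | None = None,
    min_fold: float = 2.0,
) -> list[PeakCluster]:
    """Keep clusters whose read density exceeds the library-size-scaled
    input density over the same interval by >= ``min_fold``.

    With no input track every cluster passes (with a logged notice), as
    input samples are not always available.
    """
    if input_track is None:
        logger.info("no input track supplied; all %d clusters retained", len(clusters))
        return [
            PeakCluster(c.interval, c.n_reads, above_input=True) for c in clusters
        ]
    if input_track.library_size <= 0:
        raise ValueError("input track has zero library size")
    kept: list[PeakCluster] = []
    # scale input counts to the ChIP library size
    scale = (
        (track_library_size / input_track.library_size)
        if track_library_size
        else 1.0
    )
    for c in clusters:
        iv = c.interval
        if len(iv) == 0:
            raise ValueError("zero-length cluster interval")
        input_count = input_track.count(iv.chrom, iv.start, iv.end) * scale
        fold = c.n_reads / input_count if input_count > 0 else math.inf
        if fold >= min_fold:
            kept.append(PeakCluster(iv, c.n_reads, above_input=True))
    return kept


# ---------------------------------------------------------------------------
# Densities and the feature matrix
# ---------------------------------------------------------------------------

def window_density(track: MarkTrack, window: GenomicInterval) -> float:
    """RPKM-like density: overlapping reads per kb of window per million
    mapped reads."""
    if len(window) <= 0:
        raise ValueError("window length must be positive")
    if track.library_size <= 0:
        raise ValueError("track library_size must be positive")
    count = track.count(window.chrom, window.start, window.end)
    return count / (len(window) / 1000.0) / (track.library_size / 1e6)


def event_windows(
    event: CassetteEvent, window_nt: int = 100
) -> dict[str, GenomicInterval]:
    """The four splice-site windows of an event, transcription-oriented.

    3ss = exon start in transcription order (acceptor), 5ss = exon end
    (donor).  Exonic windows are truncated to the exon when it is shorter
    than ``window_nt``; intronic windows are truncated at the flanking
    exon boundary.
    """
    alt = event.alt_exon
    chrom = alt.chrom
    exon_w = min(window_nt, len(alt))
    if event.strand == "+":
        acceptor, donor = alt.start, alt.end
        up_limit = event.upstream_exon.end
        down_limit = event.downstream_exon.start
        wins = {
            "3ss@intronic_100": (max(acceptor - window_nt, up_limit), acceptor),
            "3ss@exonic_100": (acceptor, acceptor + exon_w),
            "5ss@exonic_100": (donor - exon_w, donor),
            "5ss@intronic_100": (donor, min(donor + window_nt, down_limit)),
        }
    else:
        acceptor, donor = alt.end, alt.start  # genomic right is transcription start
        up_limit = event.upstream_exon.start
        down_limit = event.downstream_exon.end
        wins = {
            "3ss@intronic_100": (acceptor, min(acceptor + window_nt, up_limit)),
            "3ss@exonic_100": (acceptor - exon_w, acceptor),
            "5ss@exonic_100": (donor, donor + exon_w),
            "5ss@intronic_100": (max(donor - window_nt, down_limit), donor),
        }
    return {
        key: GenomicInterval(chrom, s, e, event.strand) for key, (s, e) in wins.items()
    }


def build_feature_matrix(
    events: Sequence[CassetteEvent],
    tracks: Sequence[MarkTrack],
    window_nt: int = 100,
    group_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Events x (mark@site@side) matrix of normalised window densities.

    Column names follow ``mark@3ss@intronic_100`` etc.  If
    ``group_labels`` is given it is attached as a ``group`` column (kept
    separate from feature columns by downstream consumers).
    """
    index = [ev.event_id for ev in events]
    data: dict[str, np.ndarray] = {}
    win_cache = [event_windows(ev, window_nt) for ev in events]
    for track in tracks:
        lib_m = track.library_size / 1e6
        for site in FEATURE_SITES:
            for side in FEATURE_SIDES:
                key = f"{site}@{side}"
                col = np.empty(len(events))
                for i, wins in enumerate(win_cache):
                    w = wins[key]
                    col[i] = track.count(w.chrom, w.start, w.end) / (
                        len(w) / 1000.0
                    ) / lib_m
                data[f"{track.mark}@{key}"] = col
    frame = pd.DataFrame(data, index=index)
    if group_labels is not None:
        frame["group"] = list(group_labels)
    return frame


def region_coverage(
    track: MarkTrack, events: Sequence[CassetteEvent]
) -> pd.DataFrame:
    """Normalised coverage over the upstream intron, exon and downstream
    intron of each event (full extents, transcription order)."""
    rows = []
    for ev in events:
        rows.append(
            {
                "event_id": ev.event_id,
                "upstream_intron": window_density(track, ev.upstream_intron),
                "exon": window_density(track, ev.alt_exon),
                "downstream_intron": window_density(track, ev.downstream_intron),
            }
        )
    return pd.DataFrame(rows)


def reference_point_profile(
    track: MarkTrack,
    events: Sequence[CassetteEvent],
    groups: Sequence[str],
    flank_nt: int = 250,
    bin_nt: int = 10,
    anchor: str = "3ss",
) -> pd.DataFrame:
    """Average read count (+/- SEM) per bin around a splice site, per group.

    Bins span ``+/- flank_nt`` around the anchor splice site in
    transcription orientation (negative offsets are intronic for the 3'ss
    anchor).  Returns a tidy frame (group, bin_start, mean, sem, n_events).
    """
    if flank_nt % bin_nt != 0:
        raise ValueError("flank_nt must be divisible by bin_nt")
    if anchor not in FEATURE_SITES:
        raise ValueError(f"anchor must be one of {FEATURE_SITES}")
    n_bins = 2 * flank_nt // bin_nt
    offsets = np.arange(-flank_nt, flank_nt, bin_nt)

    per_group: dict[str, list[np.ndarray]] = {}
    for ev, grp in zip(events, groups):
        alt = ev.alt_exon
        if ev.strand == "+":
            point = alt.start if anchor == "3ss" else alt.end
            starts = point + offsets
            ends = starts + bin_nt
        else:
            point = alt.end if anchor == "3ss" else alt.start
            ends = point - offsets
            starts = ends - bin_nt
        counts = track.count_windows(
            alt.chrom, np.maximum(starts, 0), np.maximum(ends, 1)
        ).astype(float)
        per_group.setdefault(grp, []).append(counts)

    rows = []
    for grp in sorted(per_group):
        stack = np.vstack(per_group[grp])
        mean = stack.mean(axis=0)
        sem = (
            stack.std(axis=0, ddof=1) / math.sqrt(stack.shape[0])
            if stack.shape[0] > 1
            else np.zeros(n_bins)
        )
        for b in range(n_bins):
            rows.append(
                {
                    "group": grp,
                    "bin_start": int(offsets[b]),
                    "mean": mean[b],
                    "sem": sem[b],
                    "n_events": stack.shape[0],
                }
            )
    empty = set(groups) - set(per_group)
    for grp in empty:
        logger.warning("group %s has no events; omitted from profile", grp)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Splice-site strength
# ---------------------------------------------------------------------------

#: Context lengths around the splice sites used for strength scoring:
#: 23 nt at the 3'ss (20 intronic + 3 exonic) and 9 nt at the 5'ss
#: (3 exonic + 6 intronic), the standard MaxEnt window shapes.
SS3_WINDOW = 23
SS5_WINDOW = 9

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


class PwmScorer:
    """Log-odds scorer of a fixed-length sequence against uniform background.

    The default splice-site strength model: probabilities are floored at
    PWM_PROB_FLOOR before taking log2 odds against 0.25 per base.  Any
    object with a compatible ``score(seq)`` (e.g. an external MaxEnt
    implementation) can be used in its place.
    """

    def __init__(self, pwm: np.ndarray):
        pwm = np.asarray(pwm, dtype=float)
        if pwm.ndim != 2 or pwm.shape[1] != 4:
            raise ValueError("PWM must be (width, 4)")
        self.width = pwm.shape[0]
        self.log_odds = np.log2(np.maximum(pwm, PWM_PROB_FLOOR) / 0.25)

    @classmethod
    def from_sequences(cls, seqs: Sequence[str], pseudocount: float = 0.5) -> "PwmScorer":
        """Estimate the PWM from aligned equal-length training sequences."""
        if not seqs:
            raise ValueError("no training sequences")
        width = len(seqs[0])
        counts = np.full((width, 4), pseudocount)
        for s in seqs:
            if len(s) != width:
                raise ValueError("training sequences must have equal length")
            for i, base in enumerate(s.upper()):
                counts[i, _BASE_INDEX[base]] += 1
        return cls(counts / counts.sum(axis=1, keepdims=True))

    def score(self, seq: str) -> float:
        if len(seq) != self.width:
            raise ValueError(f"expected a {self.width}-nt window, got {len(seq)}")
        idx = [_BASE_INDEX[b] for b in seq.upper()]
        return float(self.log_odds[np.arange(self.width), idx].sum())


def splice_site_strength(
    seq_3ss: str,
    seq_5ss: str,
    scorer_3ss: Callable[[str], float] | PwmScorer,
    scorer_5ss: Callable[[str], float] | PwmScorer,
) -> tuple[float, float]:
    """Score the acceptor (23-nt) and donor (9-nt) context windows.

    Scorers are pluggable; the PWM log-odds default is provided by
    ``PwmScorer``.
    """
    if len(seq_3ss) != SS3_WINDOW:
        raise ValueError(f"3'ss window must be {SS3_WINDOW} nt")
    if len(seq_5ss) != SS5_WINDOW:
        raise ValueError(f"5'ss window must be {SS5_WINDOW} nt")
    s3 = scorer_3ss.score(seq_3ss) if hasattr(scorer_3ss, "score") else scorer_3ss(seq_3ss)
    s5 = scorer_5ss.score(seq_5ss) if hasattr(scorer_5ss, "score") else scorer_5ss(seq_5ss)
    return s3, s5
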