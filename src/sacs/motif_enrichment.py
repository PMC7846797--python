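"""RNA-motif and 5-mer enrichment at chromatin-marked exons.

Member exons of a signature, plus trimmed flanking intronic sequence
(at most 250 nt per side, with 9 nt removed at donor sites and 30 nt at
acceptor sites to avoid splice-site, branch-point and polypyrimidine
signals; introns under 60 nt contribute no flank), are scanned for
overlapping 5-mers and for PWM motif matches.  Enrichment against
non-marked alternatively spliced control events is an odds ratio of
per-sequence motif densities (log2, pseudocounted) with a two-sided
Fisher exact test on sequence-level presence/absence, Benjamini-Hochberg
adjusted across all motif x region records.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import PWM_PROB_FLOOR, GenomicInterval
from .splicing_quantification import CassetteEvent

logger = logging.getLogger(__name__)

MOTIF_REGIONS = ("upstream_intron", "exon", "downstream_intron")

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class MotifRegionSeqs:
    """Sense-strand sequences of one event's exon and trimmed flanks."""

    event_id: str
    exon_seq: str
    upstream_flank_seq: str | None
    downstream_flank_seq: str | None
    trims_applied: dict = field(default_factory=dict)

    def region(self, kind: str) -> str | None:
        return {
            "upstream_intron": self.upstream_flank_seq,
            "exon": self.exon_seq,
            "downstream_intron": self.downstream_flank_seq,
        }[kind]


@dataclass
class MotifEnrichmentRecord:
    motif_id: str
    region: str
    log2_fc: float
    p: float
    p_adj: float
    fdr_pass: bool
    occurrences_test: int
    seqs_test: int
    occurrences_ctrl: int
    seqs_ctrl: int


# ---------------------------------------------------------------------------
# Sequence extraction
# ---------------------------------------------------------------------------

def _slice(genome: dict[str, str], iv: GenomicInterval) -> str:
    contig = genome[iv.chrom]
    if iv.end > len(contig):
        raise KeyError(f"{iv.chrom}:{iv.start}-{iv.end} beyond contig end")
    return contig[iv.start : iv.end]


def extract_motif_regions(
    events: Sequence[CassetteEvent],
    genome: dict[str, str],
    max_flank: int = 250,
    donor_trim: int = 9,
    acceptor_trim: int = 30,
    min_intron: int = 60,
) -> list[MotifRegionSeqs]:
    """Sense-strand exon and flank sequences per event.

    Minus-strand events are reverse-complemented so every output reads in
    transcription direction (DNA alphabet, T for U).  The upstream flank
    is the end of the upstream intron nearest the exon's acceptor
    (acceptor trim applied there, donor trim at its far end); the
    downstream flank mirrors this at the donor side.
    """
    out = []
    for ev in events:
        try:
            exon_seq = _slice(genome, ev.alt_exon)
        except KeyError as exc:
            logger.warning("event %s skipped: %s", ev.event_id, exc)
            continue
        minus = ev.strand == "-"
        if minus:
            exon_seq = reverse_complement(exon_seq)

        def flank(intron: GenomicInterval, exon_side: str) -> str | None:
            """exon_side: which intron end abuts the alt exon (acceptor for
            the upstream intron, donor for the downstream one)."""
            if len(intron) < min_intron:
                return None
            near_trim = acceptor_trim if exon_side == "acceptor" else donor_trim
            far_trim = donor_trim if exon_side == "acceptor" else acceptor_trim
            usable = len(intron) - near_trim - far_trim
            if usable <= 0:
                return None
            take = min(max_flank, usable)
            # the exon-adjacent intron end in genomic coordinates
            if (ev.strand == "+") == (exon_side == "acceptor"):
                # exon-adjacent end is the genomic end of the intron
                end = intron.end - near_trim
                piece = _slice(genome, GenomicInterval(intron.chrom, end - take, end))
            else:
                start = intron.start + near_trim
                piece = _slice(
                    genome, GenomicInterval(intron.chrom, start, start + take)
                )
            return reverse_complement(piece) if minus else piece

        up = flank(ev.upstream_intron, "acceptor")
        down = flank(ev.downstream_intron, "donor")
        out.append(
            MotifRegionSeqs(
                event_id=ev.event_id,
                exon_seq=exon_seq,
                upstream_flank_seq=up,
                downstream_flank_seq=down,
                trims_applied={
                    "donor_trim": donor_trim,
                    "acceptor_trim": acceptor_trim,
                    "max_flank": max_flank,
                    "min_intron": min_intron,
                },
            )
        )
    return out


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def count_kmers(seq: str, k: int = 5) -> dict[str, int]:
    """Overlapping k-mer counts."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return dict(Counter(seq[i : i + k] for i in range(len(seq) - k + 1)))


def pwm_log_odds(pwm: np.ndarray) -> np.ndarray:
    """Per-position log2 odds against uniform background, floored."""
    return np.log2(np.maximum(np.asarray(pwm, float), PWM_PROB_FLOOR) / 0.25)


def pwm_score_threshold(
    pwm: np.ndarray, score_quantile: float = 0.9, resolution: float = 0.01
) -> float:
    """Score at ``score_quantile`` of the null (uniform-sequence) score
    distribution, computed analytically by convolving the per-position
    score distributions on a discretised grid."""
    lo = pwm_log_odds(pwm)
    offset = lo.min(axis=1)  # shift each position to non-negative support
    dist = np.array([1.0])
    for row in lo - offset[:, None]:
        step = np.zeros(int(round(row.max() / resolution)) + 1)
        for v in row:
            step[int(round(v / resolution))] += 0.25
        dist = np.convolve(dist, step)
    cdf = np.cumsum(dist)
    idx = int(np.searchsorted(cdf, score_quantile, side="left"))
    return idx * resolution + offset.sum()


_BASE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def scan_pwm(
    seq: str,
    pwm: np.ndarray,
    score_quantile: float = 0.9,
    threshold: float | None = None,
) -> int:
    """Number of positions scoring at or above the PWM's match threshold.

    The threshold defaults to the ``score_quantile`` point of the null
    score distribution (precompute it with ``pwm_score_threshold`` when
    scanning many sequences).
    """
    lo = pwm_log_odds(pwm)
    width = lo.shape[0]
    if len(seq) < width:
        return 0
    if threshold is None:
        threshold = pwm_score_threshold(pwm, score_quantile)
    idx = np.array([_BASE.get(b, 0) for b in seq.upper()])
    n_win = len(seq) - width + 1
    scores = np.zeros(n_win)
    for j in range(width):
        scores += lo[j, idx[j : j + n_win]]
    return int((scores >= threshold - 1e-9).sum())


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------

def motif_odds_ratio(
    occ_test: int,
    seqs_test: int,
    occ_ctrl: int,
    seqs_ctrl: int,
    pseudocount: float = 0.5,
    present_test: int | None = None,
    present_ctrl: int | None = None,
    method: str = "fisher",
) -> tuple[float, float]:
    """Per-sequence density log2 ratio and its p-value.

    The p-value comes from a two-sided Fisher exact test on the 2x2 table
    of sequences with >= 1 occurrence vs without (presence counts default
    to min(occurrences, sequences) when not given), or, with
    ``method="binomial"``, from a two-sided binomial test of the
    occurrence split against the sequence-count proportion.
    """
    from scipy import stats

    if seqs_test < 1 or seqs_ctrl < 1:
        raise ValueError("need at least one sequence per side")
    density_test = occ_test / seqs_test
    density_ctrl = occ_ctrl / seqs_ctrl
    log2_fc = float(
        np.log2(
            (density_test + pseudocount / seqs_test)
            / (density_ctrl + pseudocount / seqs_ctrl)
        )
    )
    if method == "binomial":
        n = occ_test + occ_ctrl
        if n == 0:
            return log2_fc, 1.0
        p_expect = seqs_test / (seqs_test + seqs_ctrl)
        p = float(stats.binomtest(occ_test, n, p_expect).pvalue)
        return log2_fc, p
    if method != "fisher":
        raise ValueError(f"unknown method {method!r}")
    a = present_test if present_test is not None else min(occ_test, seqs_test)
    c = present_ctrl if present_ctrl is not None else min(occ_ctrl, seqs_ctrl)
    table = [[a, seqs_test - a], [c, seqs_ctrl - c]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return log2_fc, p


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _region_counts(
    region_seqs: Sequence[str],
    motifs: Sequence[tuple[str, np.ndarray]],
    thresholds: dict[str, float],
    k: int,
) -> tuple[Counter, Counter, int]:
    """Occurrences and presence per motif/k-mer over a sequence set."""
    occurrences: Counter = Counter()
    presence: Counter = Counter()
    for seq in region_seqs:
        counts = count_kmers(seq, k)
        for kmer, c in counts.items():
            occurrences[kmer] += c
            presence[kmer] += 1
        for motif_id, pwm in motifs:
            c = scan_pwm(seq, pwm, threshold=thresholds[motif_id])
            if c:
                occurrences[motif_id] += c
                presence[motif_id] += 1
    return occurrences, presence, len(region_seqs)


def enrichment_table(
    test_regions: Sequence[MotifRegionSeqs],
    ctrl_regions: Sequence[MotifRegionSeqs],
    motifs: Sequence[tuple[str, np.ndarray]] = (),
    kmers_k: int = 5,
    fdr: float = 0.05,
    alpha: float = 0.01,
    score_quantile: float = 0.9,
    pseudocount: float = 0.5,
) -> list[MotifEnrichmentRecord]:
    """One record per motif/5-mer per region kind.

    ``fdr_pass`` requires the BH-adjusted p below both ``alpha`` and
    ``fdr``.  Every 4^k k-mer is reported per region (count 0 where
    absent); PWM motifs use a per-motif match threshold at
    ``score_quantile`` of their null score distribution.
    """
    if not ctrl_regions:
        raise ValueError("control set must be non-empty")
    from itertools import product

    thresholds = {
        mid: pwm_score_threshold(pwm, score_quantile) for mid, pwm in motifs
    }
    all_kmers = ["".join(p) for p in product("ACGT", repeat=kmers_k)]
    motif_ids = [mid for mid, _ in motifs] + all_kmers

    records: list[MotifEnrichmentRecord] = []
    pvals: list[float] = []
    for region in MOTIF_REGIONS:
        test_seqs = [s for r in test_regions if (s := r.region(region)) is not None]
        ctrl_seqs = [s for r in ctrl_regions if (s := r.region(region)) is not None]
        if not test_seqs or not ctrl_seqs:
            logger.warning("region %s empty on one side; skipped", region)
            continue
        occ_t, pres_t, n_t = _region_counts(test_seqs, motifs, thresholds, kmers_k)
        occ_c, pres_c, n_c = _region_counts(ctrl_seqs, motifs, thresholds, kmers_k)
        for mid in motif_ids:
            log2_fc, p = motif_odds_ratio(
                occ_t[mid],
                n_t,
                occ_c[mid],
                n_c,
                pseudocount=pseudocount,
                present_test=pres_t[mid],
                present_ctrl=pres_c[mid],
            )
            records.append(
                MotifEnrichmentRecord(
                    motif_id=mid,
                    region=region,
                    log2_fc=log2_fc,
                    p=p,
                    p_adj=np.nan,
                    fdr_pass=False,
                    occurrences_test=occ_t[mid],
                    seqs_test=n_t,
                    occurrences_ctrl=occ_c[mid],
                    seqs_ctrl=n_c,
                )
            )
            pvals.append(p)
    adjusted = bh_fdr(pvals)
    for rec, p_adj in zip(records, adjusted):
        rec.p_adj = float(p_adj)
        rec.fdr_pass = bool(p_adj < alpha and p_adj < fdr)
    return records


def records_frame(records: Sequence[MotifEnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
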