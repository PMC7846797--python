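"""Statistics for SACS characterisation and cross-condition validation.

Covers the contingency layer (Fisher exact tests on signature
maintenance and binding-site overlap), group-wise Wilcoxon rank
comparisons of genetic features with Bonferroni correction, interval
overlap counting for eCLIP-style peak sets, and the per-event genetic
feature table (exon/intron lengths, splice-site strengths, TSS distance,
GC log-ratios, expression).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneModel, GenomicInterval
from .epigenomic_features import (
    SS3_WINDOW,
    SS5_WINDOW,
    MarkTrack,
    PeakCluster,
    PwmScorer,
)
from .motif_enrichment import reverse_complement
from .sacs_discovery import RegionSet, SacsSignature, _event_region, presence_vector
from .splicing_quantification import CassetteEvent, PsiRecord

logger = logging.getLogger(__name__)


@dataclass
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_two_sided: float


@dataclass
class MaintenanceTable:
    signature_id: str
    condition_pair: tuple[str, str]
    cells: pd.DataFrame  # rows: group in other condition; cols: kept, lost
    test: ContingencyResult | None


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> ContingencyResult:
    """Two-sided Fisher exact test (hypergeometric-tail summation).

    The odds ratio is reported with the Haldane-Anscombe 0.5 correction
    when a cell is zero; the test itself uses the raw counts.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return ContingencyResult(((a, b), (c, d)), float(odds), float(p))


# ---------------------------------------------------------------------------
# Interval overlap
# ---------------------------------------------------------------------------

def interval_overlap_counts(
    query: Sequence[GenomicInterval], peaks: Sequence[GenomicInterval]
) -> tuple[int, int]:
    """(number of query intervals overlapping any peak, total queries).

    Overlap is any shared base under half-open coordinates (adjacent
    intervals do not overlap).
    """
    if not query:
        return 0, 0
    track = MarkTrack.from_intervals("peaks", peaks)
    n_hit = sum(
        1 for q in query if track.count(q.chrom, q.start, q.end) > 0
    )
    return n_hit, len(query)


# ---------------------------------------------------------------------------
# Signature maintenance across conditions
# ---------------------------------------------------------------------------

def maintenance_analysis(
    signature: SacsSignature,
    events: Sequence[CassetteEvent],
    psi_other: Sequence[PsiRecord],
    peaks_other: Mapping[str, Sequence[PeakCluster]],
    condition_pair: tuple[str, str] = ("reference", "other"),
    flank_nt: int = 200,
    min_events: int = 5,
    require_both_marks: bool = True,
) -> MaintenanceTable:
    """Cross-classify a signature's member exons in another condition.

    Shared (expressed) member events are classified by their splicing
    group in the other condition and by whether the signature is kept
    (both marks — or either, per flag — still overlap the defining
    region).  A Fisher test compares kept vs lost between events that
    stay in the signature's group and events that shift group.
    """
    psi_by_id = {r.event_id: r for r in psi_other}
    members = [
        ev
        for ev in events
        if ev.event_id in signature.member_events
        and ev.event_id in psi_by_id
        and psi_by_id[ev.event_id].group != "NA"
    ]
    if not members:
        logger.info("no shared events for %s", signature.signature_id)
        empty = pd.DataFrame(columns=["kept", "lost"])
        return MaintenanceTable(signature.signature_id, condition_pair, empty, None)

    regions = RegionSet(
        region_kind=signature.region_kind,
        group=signature.group,
        intervals=[_event_region(ev, signature.region_kind, flank_nt) for ev in members],
        event_ids=[ev.event_id for ev in members],
    )
    mark_a, mark_b = sorted(signature.mark_pair)
    pa = presence_vector(list(peaks_other[mark_a]), regions)
    pb = presence_vector(list(peaks_other[mark_b]), regions)
    kept_vec = (pa & pb) if require_both_marks else (pa | pb)
    kept_by_id = dict(zip(regions.event_ids, kept_vec))

    rows: dict[str, dict[str, int]] = {}
    for ev in members:
        grp = psi_by_id[ev.event_id].group
        cell = rows.setdefault(grp, {"kept": 0, "lost": 0})
        cell["kept" if kept_by_id[ev.event_id] else "lost"] += 1
    cells = pd.DataFrame(rows).T.fillna(0).astype(int)
    cells = cells.reindex(columns=["kept", "lost"], fill_value=0)

    test = None
    if len(members) >= min_events:
        same = cells.loc[[g for g in cells.index if g == signature.group]].sum()
        shifted = cells.loc[[g for g in cells.index if g != signature.group]].sum()
        table = [
            [int(same.get("kept", 0)), int(same.get("lost", 0))],
            [int(shifted.get("kept", 0)), int(shifted.get("lost", 0))],
        ]
        if sum(table[0]) + sum(table[1]) > 0:
            test = fisher_exact_2x2(table)
    else:
        logger.info(
            "%s: only %d shared events; maintenance test skipped",
            signature.signature_id,
            len(members),
        )
    return MaintenanceTable(signature.signature_id, condition_pair, cells, test)


# ---------------------------------------------------------------------------
# Genetic features
# ---------------------------------------------------------------------------

def _gc_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / len(seq)


def genetic_features(
    events: Sequence[CassetteEvent],
    genome: dict[str, str] | None,
    models: Sequence[GeneModel],
    tpm: Mapping[str, float],
    scorer_3ss: PwmScorer | None = None,
    scorer_5ss: PwmScorer | None = None,
    log_base: int = 10,
) -> pd.DataFrame:
    """Per-event genetic feature table.

    Lengths in nt, TSS distance in kb, GC ratios as log2(exon GC% /
    intron GC%), expression as log(TPM) (base configurable, default 10).
    Splice-site strengths are filled when a genome and scorers are given.
    """
    tx_by_gene: dict[str, GeneModel] = {}
    for m in models:
        tx_by_gene.setdefault(m.gene_id, m)
    rows = []
    for ev in events:
        model = tx_by_gene.get(ev.gene_id)
        tss = None
        n_exons = None
        if model is not None and model.exons:
            first = model.exons[0]
            tss = first.start if model.strand == "+" else first.end
            n_exons = len(model.exons)
        alt = ev.alt_exon
        if tss is not None:
            alt_start_tx = alt.start if ev.strand == "+" else alt.end
            dist_kb = abs(alt_start_tx - tss) / 1000.0
        else:
            dist_kb = float("nan")
        row = {
            "event_id": ev.event_id,
            "exon_length": len(alt),
            "upstream_intron_length": len(ev.upstream_intron),
            "downstream_intron_length": len(ev.downstream_intron),
            "distance_to_tss_kb": dist_kb,
            "exon_position": ev.exon_index_in_transcript,
            "n_exons_in_gene": n_exons,
            "log_tpm": (
                math.log(tpm[ev.gene_id], log_base)
                if ev.gene_id in tpm and tpm[ev.gene_id] > 0
                else float("nan")
            ),
            "ss3_score": float("nan"),
            "ss5_score": float("nan"),
            "gc_log2_ratio_up": float("nan"),
            "gc_log2_ratio_down": float("nan"),
        }
        if genome is not None:
            contig = genome[alt.chrom]
            exon_seq = contig[alt.start : alt.end]
            up_iv, down_iv = ev.upstream_intron, ev.downstream_intron
            up_seq = contig[up_iv.start : up_iv.end]
            down_seq = contig[down_iv.start : down_iv.end]
            gc_e = _gc_fraction(exon_seq)
            for key, seq in (("gc_log2_ratio_up", up_seq), ("gc_log2_ratio_down", down_seq)):
                gc_i = _gc_fraction(seq)
                if gc_e > 0 and gc_i > 0:
                    row[key] = math.log2(gc_e / gc_i)
            if scorer_3ss is not None and scorer_5ss is not None:
                row["ss3_score"], row["ss5_score"] = splice_site_windows_scores(
                    ev, genome, scorer_3ss, scorer_5ss
                )
        rows.append(row)
    return pd.DataFrame(rows)


def splice_site_windows_scores(
    ev: CassetteEvent,
    genome: dict[str, str],
    scorer_3ss: PwmScorer,
    scorer_5ss: PwmScorer,
) -> tuple[float, float]:
    """Score the standard acceptor (20 intronic + 3 exonic nt) and donor
    (3 exonic + 6 intronic nt) windows of the alternative exon."""
    s3, s5 = splice_site_window_seqs(ev, genome)
    return scorer_3ss.score(s3), scorer_5ss.score(s5)


def splice_site_window_seqs(
    ev: CassetteEvent, genome: dict[str, str]
) -> tuple[str, str]:
    contig = genome[ev.alt_exon.chrom]
    alt = ev.alt_exon
    if ev.strand == "+":
        s3 = contig[alt.start - (SS3_WINDOW - 3) : alt.start + 3]
        s5 = contig[alt.end - 3 : alt.end + (SS5_WINDOW - 3)]
    else:
        s3 = reverse_complement(contig[alt.end - 3 : alt.end + (SS3_WINDOW - 3)])
        s5 = reverse_complement(contig[alt.start - (SS5_WINDOW - 3) : alt.start + 3])
    return s3, s5


# ---------------------------------------------------------------------------
# Wilcoxon comparisons
# ---------------------------------------------------------------------------

def wilcoxon_compare(
    groups: Mapping[str, Sequence[float]],
    reference_labels: Sequence[str],
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Two-sided rank-sum tests of each group against each reference.

    Returns a tidy frame (group, reference, p_raw, p_corrected) with the
    Bonferroni factor equal to the number of comparisons performed.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    comparisons = [
        (g, ref)
        for g in groups
        for ref in reference_labels
        if g != ref and ref in groups
    ]
    n_comp = len(comparisons)
    rows = []
    for g, ref in comparisons:
        x, y = np.asarray(groups[g], float), np.asarray(groups[ref], float)
        if x.size < 2 or y.size < 2:
            raise ValueError("each group needs >= 2 values")
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        p_corr = min(1.0, p * n_comp) if correction == "bonferroni" else p
        rows.append({"group": g, "reference": ref, "p_raw": p, "p_corrected": p_corr})
    return pd.DataFrame(rows)
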