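"""Cassette-exon extraction, PSI computation and splicing-group assignment.

The percent-spliced-in (PSI) of a cassette exon is estimated from unique
splice-junction reads: inclusion reads are averaged over the acceptor and
donor junctions (both report the included isoform) and divided by the sum
of that average and the exclusion-junction reads,

    PSI = mean(inc_acceptor, inc_donor) / (mean(inc) + exc).

Events are binned into four splicing groups by PSI: excluded [0, 0.2),
mid-excluded [0.2, 0.4), mid-included [0.4, 0.8) and included [0.8, 1.0].
The source intervals are open at the boundaries; a half-open convention
(with 1.0 folded into "included") is adopted so the groups partition
[0, 1] — see docs/methods.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .core_io import GeneModel, GenomicInterval, JunctionRecord

logger = logging.getLogger(__name__)

GROUPS = ("excluded", "mid_excluded", "mid_included", "included")

#: Half-open PSI bin edges for the four splicing groups.
GROUP_EDGES = (0.0, 0.2, 0.4, 0.8)

#: Biotypes retained when extracting cassette events.
ALLOWED_BIOTYPES = frozenset(
    {"protein_coding", "lncRNA", "lincRNA", "noncoding_rna", "ncRNA"}
)


@dataclass(frozen=True)
class CassetteEvent:
    """An exon triplet: constitutive — alternative — constitutive.

    Exons are in transcription order; ``exon_index_in_transcript`` is the
    1-based position of the alternative exon in its transcript and is at
    least 3 (first and second exons are discarded to avoid promoter
    effects).
    """

    event_id: str
    gene_id: str
    upstream_exon: GenomicInterval
    alt_exon: GenomicInterval
    downstream_exon: GenomicInterval
    exon_index_in_transcript: int
    strand: str

    def __post_init__(self) -> None:
        if self.exon_index_in_transcript < 3:
            raise ValueError("alternative exon must be the 3rd exon or later")
        if self.strand not in ("+", "-"):
            raise ValueError("cassette events require a known strand")
        trio = (self.upstream_exon, self.alt_exon, self.downstream_exon)
        coords = [(e.start, e.end) for e in trio]
        if self.strand == "-":
            coords = coords[::-1]
        for (s1, e1), (s2, e2) in zip(coords, coords[1:]):
            if e1 > s2:
                raise ValueError(f"exons of {self.event_id} overlap or are unordered")

    @property
    def upstream_intron(self) -> GenomicInterval:
        """Intron between the upstream and alternative exon (transcription order)."""
        if self.strand == "+":
            return GenomicInterval(
                self.alt_exon.chrom, self.upstream_exon.end, self.alt_exon.start, "+"
            )
        return GenomicInterval(
            self.alt_exon.chrom, self.alt_exon.end, self.upstream_exon.start, "-"
        )

    @property
    def downstream_intron(self) -> GenomicInterval:
        if self.strand == "+":
            return GenomicInterval(
                self.alt_exon.chrom, self.alt_exon.end, self.downstream_exon.start, "+"
            )
        return GenomicInterval(
            self.alt_exon.chrom, self.downstream_exon.end, self.alt_exon.start, "-"
        )

    @property
    def acceptor_junction(self) -> GenomicInterval:
        """Inclusion junction spanning the upstream intron (reaches the 3'ss)."""
        iv = self.upstream_intron
        return GenomicInterval(iv.chrom, iv.start, iv.end, self.strand)

    @property
    def donor_junction(self) -> GenomicInterval:
        iv = self.downstream_intron
        return GenomicInterval(iv.chrom, iv.start, iv.end, self.strand)

    @property
    def exclusion_junction(self) -> GenomicInterval:
        if self.strand == "+":
            return GenomicInterval(
                self.alt_exon.chrom,
                self.upstream_exon.end,
                self.downstream_exon.start,
                "+",
            )
        return GenomicInterval(
            self.alt_exon.chrom,
            self.downstream_exon.end,
            self.upstream_exon.start,
            "-",
        )


@dataclass
class PsiRecord:
    event_id: str
    condition: str
    inc_acceptor: int
    inc_donor: int
    exc: int
    psi: float | None
    group: str  # one of GROUPS or "NA"


@dataclass
class ConstitutiveCall:
    exon: GenomicInterval
    n_conditions: int
    n_high_inclusion: int
    annotated_constitutive: bool
    is_constitutive: bool


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def filter_junctions(
    junctions: Sequence[JunctionRecord], min_reads: int = 5
) -> list[JunctionRecord]:
    """Keep junctions supported by at least ``min_reads`` unique reads."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    return [j for j in junctions if j.unique_reads >= min_reads]


def compute_psi(inc_acceptor: int, inc_donor: int, exc: int) -> float | None:
    """PSI = mean(inclusion reads) / (mean(inclusion) + exclusion).

    Returns None (undefined) when no reads support either isoform.
    """
    if min(inc_acceptor, inc_donor, exc) < 0:
        raise ValueError("junction read counts must be non-negative")
    inc = (inc_acceptor + inc_donor) / 2.0
    denom = inc + exc
    if denom == 0:
        return None
    return inc / denom


def assign_group(psi: float) -> str:
    """Map a defined PSI in [0, 1] to its splicing group."""
    if not 0.0 <= psi <= 1.0:
        raise ValueError(f"psi {psi} outside [0, 1]")
    if psi < GROUP_EDGES[1]:
        return "excluded"
    if psi < GROUP_EDGES[2]:
        return "mid_excluded"
    if psi < GROUP_EDGES[3]:
        return "mid_included"
    return "included"


def call_constitutive(
    psi_by_condition: Mapping[str, float | None],
    annotated: bool,
    exon: GenomicInterval | None = None,
    psi_min: float = 0.95,
    frac_min: float = 0.75,
) -> ConstitutiveCall:
    """An exon is constitutive if annotated so and its PSI exceeds
    ``psi_min`` in more than ``frac_min`` of the conditions."""
    defined = {k: v for k, v in psi_by_condition.items() if v is not None}
    n_cond = len(psi_by_condition)
    n_high = sum(1 for v in defined.values() if v > psi_min)
    if not defined:
        logger.warning("constitutive call with no defined PSI in any condition")
        is_const = False
    else:
        is_const = annotated and (n_high / n_cond) > frac_min
    return ConstitutiveCall(
        exon=exon if exon is not None else GenomicInterval("NA", 0, 1, "."),
        n_conditions=n_cond,
        n_high_inclusion=n_high,
        annotated_constitutive=annotated,
        is_constitutive=is_const,
    )


def extract_cassette_events(
    models: Sequence[GeneModel],
    constitutive: Sequence[ConstitutiveCall] | None = None,
    allowed_biotypes: frozenset[str] = ALLOWED_BIOTYPES,
) -> list[CassetteEvent]:
    """Extract exon triplets in which an alternative exon is flanked by two
    constitutive exons.

    Constitutive status comes from the transcript's annotation flags,
    optionally overridden by explicit ``ConstitutiveCall`` results (keyed
    by exon coordinates).  Events whose alternative exon is the 1st or 2nd
    exon of the transcript are dropped; duplicate events (same alternative
    exon from several transcripts) are deduplicated.
    """
    const_map: dict[tuple[str, int, int], bool] = {}
    if constitutive:
        for call in constitutive:
            key = (call.exon.chrom, call.exon.start, call.exon.end)
            const_map[key] = call.is_constitutive

    events: list[CassetteEvent] = []
    seen: set[tuple[str, int, int]] = set()
    for model in models:
        if model.biotype not in allowed_biotypes:
            continue
        if len(model.exons) < 3:
            logger.debug("transcript %s has <3 exons; skipped", model.transcript_id)
            continue

        def is_const(i: int) -> bool:
            exon = model.exons[i]
            key = (exon.chrom, exon.start, exon.end)
            return const_map.get(key, model.constitutive_flags[i])

        for i in range(1, len(model.exons) - 1):
            index_1based = i + 1
            if index_1based < 3:
                continue  # 1st/2nd exon: promoter-proximal, discarded
            if is_const(i) or not (is_const(i - 1) and is_const(i + 1)):
                continue
            alt = model.exons[i]
            key = (alt.chrom, alt.start, alt.end)
            if key in seen:
                continue
            seen.add(key)
            events.append(
                CassetteEvent(
                    event_id=f"{model.gene_id}:{alt.chrom}:{alt.start}-{alt.end}",
                    gene_id=model.gene_id,
                    upstream_exon=model.exons[i - 1],
                    alt_exon=alt,
                    downstream_exon=model.exons[i + 1],
                    exon_index_in_transcript=index_1based,
                    strand=model.strand,
                )
            )
    return events


def quantify_events(
    events: Sequence[CassetteEvent],
    junctions: Sequence[JunctionRecord],
    condition: str = "cond",
    min_reads: int = 5,
) -> list[PsiRecord]:
    """Compute a PsiRecord for every event from a junction count table.

    Junctions are first filtered at ``min_reads``; a junction absent after
    filtering counts as 0 reads, but PSI is left undefined unless at least
    one of the event's junctions passed the filter.
    """
    counts: dict[tuple[str, int, int], int] = {}
    for j in filter_junctions(junctions, min_reads):
        iv = j.interval
        counts[(iv.chrom, iv.start, iv.end)] = j.unique_reads

    def lookup(iv: GenomicInterval) -> int:
        return counts.get((iv.chrom, iv.start, iv.end), 0)

    records = []
    for ev in events:
        ia = lookup(ev.acceptor_junction)
        idn = lookup(ev.donor_junction)
        ex = lookup(ev.exclusion_junction)
        psi = compute_psi(ia, idn, ex)
        group = assign_group(psi) if psi is not None else "NA"
        records.append(PsiRecord(ev.event_id, condition, ia, idn, ex, psi, group))
    return records


def filter_expression(
    events: Sequence[CassetteEvent],
    tpm: Mapping[str, float],
    min_tpm: float = 10.0,
) -> list[CassetteEvent]:
    """Keep events whose gene has TPM >= ``min_tpm``.

    Genes missing from the TPM table are dropped with a warning count.
    """
    missing = sum(1 for ev in events if ev.gene_id not in tpm)
    if missing:
        logger.warning("%d events from genes absent in the TPM table dropped", missing)
    return [ev for ev in events if tpm.get(ev.gene_id, -1.0) >= min_tpm]
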