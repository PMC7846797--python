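"""Coupled synthetic datasets with planted chromatin co-enrichments.

The generator emulates the statistical structure the pipeline consumes:
genes with one cassette exon each, group-structured true PSI, junction
counts with binomial sampling noise, per-mark 36-nt read placements with
a uniform genomic background plus Poisson-planted position- and
group-specific mark-pair co-enrichments, an i.i.d. genome with
configurable GC and canonical GT..AG intron boundaries, TPM tables, and
truth tables for every planted quantity.  It does not model nucleosome
positioning, fragment-size distributions or sequencing errors.

Randomness is split into one stream per output (annotation/PSI,
junctions, expression, genome, motifs, and one per mark, keyed by the
mark's name) so that, for a fixed master seed, adding a mark or changing
the genome leaves junction counts byte-identical.

Junction-count accounting: with per-event depth ``d`` and true inclusion
``psi``, the included-transcript count is N ~ Binomial(d, psi); each
included transcript contributes one acceptor and one donor read
(inc_acceptor ~ Binomial(2N, 1/2), inc_donor = 2N - inc_acceptor) and
each excluded transcript one exclusion read (exc = d - N), so
inc_acceptor + inc_donor + 2*exc == 2*d exactly and the PSI estimator
N/d is unbiased.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import GeneModel, GenomicInterval, JunctionRecord
from .sacs_discovery import REGION_KINDS, _event_region
from .splicing_quantification import (
    GROUP_EDGES,
    GROUPS,
    CassetteEvent,
    extract_cassette_events,
)

CHROM = "chrS"

#: Group PSI intervals, half-open except "included" which reaches 1.0.
GROUP_INTERVALS = {
    "excluded": (0.0, 0.2),
    "mid_excluded": (0.2, 0.4),
    "mid_included": (0.4, 0.8),
    "included": (0.8, 1.0),
}

#: Default group proportions, the relative sizes of the four splicing
#: groups among H1 cassette exons (950 : 332 : 634 : 675).
DEFAULT_PROPORTIONS = (0.3667, 0.1281, 0.2447, 0.2605)

DEFAULT_MARKS = ("H3K4me1", "H3K4me2", "H3K79me2", "H4K20me1", "H4K91ac", "H3K9me3")


@dataclass(frozen=True)
class PlantedSignature:
    """A mark pair co-planted in one region kind of one splicing group.

    Both marks receive extra reads at the *same* random subset
    (``member_fraction``) of the group's events: chromatin signatures
    mark a subset of a splicing group, and it is exactly this shared
    membership that makes the two marks' presence co-occur above the
    product of their marginals.
    """

    mark_a: str
    mark_b: str
    region: str  # one of REGION_KINDS
    group: str  # one of GROUPS
    enrichment_fold: float
    member_fraction: float = 0.5

    @property
    def signature_id(self) -> str:
        return f"{self.mark_a}+{self.mark_b}:{self.region}:{self.group}"

    def __post_init__(self) -> None:
        if self.mark_a == self.mark_b:
            raise ValueError("a signature needs two distinct marks")
        if self.enrichment_fold <= 1:
            raise ValueError("enrichment_fold must be > 1 for a plant")
        if self.region not in REGION_KINDS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not 0 < self.member_fraction <= 1:
            raise ValueError("member_fraction must be in (0, 1]")


@dataclass(frozen=True)
class MotifPlant:
    motif_id: str
    consensus: str
    rate: float  # expected insertions per target sequence
    target_ids: tuple[str, ...] | None = None  # None = all sequences


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 600
    exons_per_gene: tuple[int, int] = (5, 9)
    exon_length: tuple[int, int] = (60, 300)
    intron_length: tuple[int, int] = (300, 1500)
    group_proportions: tuple[float, float, float, float] = DEFAULT_PROPORTIONS
    junction_depth: int = 200
    marks: tuple[str, ...] = DEFAULT_MARKS
    planted_signatures: list[PlantedSignature] = field(default_factory=list)
    background_rate: float = 2.0  # reads per kb of genome
    plant_footprint_nt: int = 200  # extension footprint used to calibrate plants
    motif_plants: list[MotifPlant] = field(default_factory=list)
    read_length: int = 36
    psi_margin: float = 0.02  # keeps true PSI off the bin boundaries
    exon_gc: float = 0.5
    intron_gc: float = 0.5
    tpm_log10_mean: float = 1.7
    tpm_log10_sd: float = 0.5
    intergenic_nt: int = 1000
    make_genome: bool = True

    def __post_init__(self) -> None:
        total = sum(self.group_proportions)
        if abs(total - 1.0) > 1e-6:
            raise ValueError("group_proportions must sum to 1")
        if self.junction_depth <= 0 or self.background_rate <= 0:
            raise ValueError("depths and rates must be positive")
        for g, (lo, hi) in GROUP_INTERVALS.items():
            if lo + self.psi_margin >= hi - self.psi_margin:
                raise ValueError(f"group interval {g} empty at this psi_margin")


@dataclass
class SimulatedDataset:
    """In-memory bundle of one simulated condition plus truth tables."""

    config: SimulationConfig
    models: list[GeneModel]
    events: list[CassetteEvent]
    constitutive_events: list[CassetteEvent]
    truth: pd.DataFrame  # event_id, group, true_psi, depth, signature_id, counts
    junctions: list[JunctionRecord]
    tpm: dict[str, float]
    mark_reads: dict[str, list[GenomicInterval]]
    genome: dict[str, str] | None
    condition: str = "simA"

    @property
    def groups(self) -> list[str]:
        by_id = dict(zip(self.truth["event_id"], self.truth["group"]))
        return [by_id[ev.event_id] for ev in self.events]


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named RNG stream derived from the master seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _build_annotation(config: SimulationConfig):
    rng = _stream(config.seed, "annotation")
    models: list[GeneModel] = []
    alt_index: dict[str, int] = {}  # gene -> transcription-order alt index (0-based)
    cursor = config.intergenic_nt
    for gi in range(config.n_genes):
        gene = f"gene{gi:05d}"
        strand = "+" if gi % 2 == 0 else "-"
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, n_exons)
        intron_lens = rng.integers(
            config.intron_length[0], config.intron_length[1] + 1, n_exons - 1
        )
        starts = []
        pos = cursor
        for k in range(n_exons):
            starts.append(pos)
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        cursor = pos + config.intergenic_nt
        exons_genomic = [
            GenomicInterval(CHROM, s, s + int(l), strand)
            for s, l in zip(starts, exon_lens)
        ]
        exons_tx = exons_genomic if strand == "+" else exons_genomic[::-1]
        # alternative exon: transcription-order index >= 3 (1-based), internal
        alt_i = int(rng.integers(2, n_exons - 1))  # 0-based, so 3rd..(n-1)th exon
        flags = [True] * n_exons
        flags[alt_i] = False
        models.append(
            GeneModel(
                gene_id=gene,
                transcript_id=f"{gene}.t1",
                exons=exons_tx,
                biotype="protein_coding",
                constitutive_flags=flags,
            )
        )
        alt_index[gene] = alt_i
    return models, alt_index


def _constitutive_triplets(
    models: Sequence[GeneModel], alt_index: dict[str, int]
) -> list[CassetteEvent]:
    """Exon triplets centred on a constitutive exon of the same genes,
    away from the alternative exon and promoter-proximal positions."""
    out = []
    for m in models:
        alt_i = alt_index[m.gene_id]
        for i in range(2, len(m.exons) - 1):
            if abs(i - alt_i) < 2:
                continue
            alt = m.exons[i]
            out.append(
                CassetteEvent(
                    event_id=f"{m.gene_id}:const:{alt.chrom}:{alt.start}-{alt.end}",
                    gene_id=m.gene_id,
                    upstream_exon=m.exons[i - 1],
                    alt_exon=alt,
                    downstream_exon=m.exons[i + 1],
                    exon_index_in_transcript=i + 1,
                    strand=m.strand,
                )
            )
            break  # one control triplet per gene
    return out


# ---------------------------------------------------------------------------
# PSI, junctions, expression
# ---------------------------------------------------------------------------

def _draw_groups_and_psi(config: SimulationConfig, n: int, rng: np.random.Generator):
    groups = rng.choice(len(GROUPS), size=n, p=np.asarray(config.group_proportions))
    psis = np.empty(n)
    for i, g in enumerate(groups):
        lo, hi = GROUP_INTERVALS[GROUPS[g]]
        psis[i] = rng.uniform(lo + config.psi_margin, hi - config.psi_margin)
    return [GROUPS[g] for g in groups], psis


def _junctions_for_condition(
    models: Sequence[GeneModel],
    events: Sequence[CassetteEvent],
    psis: Sequence[float],
    depth: int,
    rng: np.random.Generator,
) -> tuple[list[JunctionRecord], pd.DataFrame]:
    """Junction counts for one condition; also returns per-event counts."""
    alt_of = {ev.gene_id: ev for ev in events}
    counts: dict[tuple[str, int, int, str], int] = {}

    def add(iv: GenomicInterval, c: int) -> None:
        key = (iv.chrom, iv.start, iv.end, iv.strand)
        counts[key] = counts.get(key, 0) + c

    rows = []
    for ev, psi in zip(events, psis):
        n_inc = int(rng.binomial(depth, psi))
        n_exc = depth - n_inc
        inc_a = int(rng.binomial(2 * n_inc, 0.5)) if n_inc else 0
        inc_d = 2 * n_inc - inc_a
        add(ev.acceptor_junction, inc_a)
        add(ev.donor_junction, inc_d)
        add(ev.exclusion_junction, n_exc)
        rows.append(
            {"event_id": ev.event_id, "inc_acceptor": inc_a, "inc_donor": inc_d,
             "exc": n_exc, "depth": depth, "n_inc": n_inc}
        )
    # constitutive introns: full-depth support
    for m in models:
        ev = alt_of.get(m.gene_id)
        skip = set()
        if ev is not None:
            for j in (ev.acceptor_junction, ev.donor_junction):
                skip.add((j.start, j.end))
        for a, b in zip(m.exons, m.exons[1:]):
            if m.strand == "+":
                s, e = a.end, b.start
            else:
                s, e = b.end, a.start
            if (s, e) in skip:
                continue
            add(GenomicInterval(m.exons[0].chrom, s, e, m.strand), depth)
    junctions = [
        JunctionRecord(GenomicInterval(c, s, e, st), n)
        for (c, s, e, st), n in sorted(counts.items())
    ]
    return junctions, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGT", "TGCA")


def _gc_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def _build_genome(
    config: SimulationConfig, models: Sequence[GeneModel], length: int
) -> dict[str, str]:
    rng = _stream(config.seed, "genome")
    seq = _gc_bases(rng, length, config.intron_gc)
    for m in models:
        for exon in m.exons:
            seq[exon.start : exon.end] = _gc_bases(rng, len(exon), config.exon_gc)
    # canonical GT..AG intron boundaries (strand-aware)
    for m in models:
        genomic = sorted(m.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            s, e = a.end, b.start  # intron in genomic coordinates
            if m.strand == "+":
                seq[s : s + 2] = np.frombuffer(b"GT", dtype="S1")
                seq[e - 2 : e] = np.frombuffer(b"AG", dtype="S1")
            else:
                seq[e - 2 : e] = np.frombuffer(b"AC", dtype="S1")
                seq[s : s + 2] = np.frombuffer(b"CT", dtype="S1")
    return {CHROM: seq.tobytes().decode()}


# ---------------------------------------------------------------------------
# Mark reads
# ---------------------------------------------------------------------------

def _mark_reads(
    config: SimulationConfig,
    genome_len: int,
    mark: str,
    plants: list[tuple[GenomicInterval, float]],
) -> list[GenomicInterval]:
    rng = _stream(config.seed, f"mark:{mark}")
    L, w = genome_len, config.read_length
    n_bg = int(rng.poisson(config.background_rate * L / 1000.0))
    starts = rng.integers(0, L - w, size=n_bg)
    strands = rng.choice(np.array(["+", "-"]), size=n_bg)
    reads = [
        GenomicInterval(CHROM, int(s), int(s) + w, str(st))
        for s, st in zip(starts, strands)
    ]
    ext = config.plant_footprint_nt
    for region, fold in plants:
        # fold is relative to the background reads whose extended
        # footprint overlaps the region, not just those starting in it
        span = len(region) + ext
        lam = fold * config.background_rate * span / 1000.0
        n = int(rng.poisson(lam))
        # point-source placement: the extended (5'->3', ext nt) footprint
        # of a planted plus-strand read is centred in the middle half of
        # the region, as for fragments piling on a positioned nucleosome
        quarter = max(1, len(region) // 4)
        mids = rng.integers(
            region.start + quarter, max(region.start + quarter + 1, region.end - quarter),
            size=n,
        )
        for mid in mids:
            s = max(0, int(mid) - ext // 2)
            reads.append(GenomicInterval(CHROM, s, s + w, "+"))
    return reads


# ---------------------------------------------------------------------------
# Top-level simulation
# ---------------------------------------------------------------------------

def _plant_assignments(
    config: SimulationConfig,
    events: Sequence[CassetteEvent],
    groups: Sequence[str],
    seed: int,
    prev_members: dict[str, set[str]] | None = None,
    prev_groups: dict[str, str] | None = None,
) -> tuple[dict[str, list[tuple[GenomicInterval, float]]], dict[str, list[str]]]:
    """Per-mark plant regions and per-event signature membership.

    Membership is a seeded ``member_fraction`` draw among the group's
    events.  With a reference condition's membership (``prev_members``
    keyed by signature, ``prev_groups`` per event), events that stayed
    in the group keep their status and only events newly entering the
    group are drawn fresh — the structure the maintenance analysis
    tests.
    """
    plants_by_mark: dict[str, list[tuple[GenomicInterval, float]]] = {
        m: [] for m in config.marks
    }
    sig_of_event: dict[str, list[str]] = {}
    for sig in config.planted_signatures:
        rng = _stream(seed, f"members:{sig.signature_id}")
        prev = prev_members.get(sig.signature_id, set()) if prev_members else None
        for ev, grp in zip(events, groups):
            if grp != sig.group:
                continue
            if prev is not None and ev.event_id in prev:
                member = True
            elif (
                prev is not None
                and prev_groups is not None
                and prev_groups.get(ev.event_id) == sig.group
            ):
                member = False  # was in the group before and not a member
            else:
                member = rng.random() < sig.member_fraction
            if not member:
                continue
            region = _event_region(ev, sig.region, 200)
            for mark in (sig.mark_a, sig.mark_b):
                if mark not in plants_by_mark:
                    raise ValueError(f"planted mark {mark!r} not in config.marks")
                plants_by_mark[mark].append((region, sig.enrichment_fold))
            sig_of_event.setdefault(ev.event_id, []).append(sig.signature_id)
    return plants_by_mark, sig_of_event


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one condition: annotation, PSI/junctions, TPM, genome and
    per-mark reads with the configured planted signatures."""
    models, alt_index = _build_annotation(config)
    events = extract_cassette_events(models)
    events.sort(key=lambda ev: ev.gene_id)
    const_events = _constitutive_triplets(models, alt_index)

    psi_rng = _stream(config.seed, "psi")
    groups, psis = _draw_groups_and_psi(config, len(events), psi_rng)

    jn_rng = _stream(config.seed, "junctions")
    junctions, count_rows = _junctions_for_condition(
        models, events, psis, config.junction_depth, jn_rng
    )

    tpm_rng = _stream(config.seed, "expression")
    tpm = {
        m.gene_id: float(
            10 ** tpm_rng.normal(config.tpm_log10_mean, config.tpm_log10_sd)
        )
        for m in models
    }

    genome_len = max(m.exons[-1].end if m.strand == "+" else m.exons[0].end for m in models)
    genome_len += config.intergenic_nt
    genome = _build_genome(config, models, genome_len) if config.make_genome else None

    plants_by_mark, sig_of_event = _plant_assignments(
        config, events, groups, config.seed
    )

    mark_reads = {
        mark: _mark_reads(config, genome_len, mark, plants_by_mark[mark])
        for mark in config.marks
    }

    truth = count_rows.copy()
    truth.insert(1, "gene_id", [ev.gene_id for ev in events])
    truth.insert(2, "group", groups)
    truth.insert(3, "true_psi", psis)
    truth["signature_id"] = [
        ";".join(sig_of_event.get(ev.event_id, [])) for ev in events
    ]
    return SimulatedDataset(
        config=config,
        models=models,
        events=events,
        constitutive_events=const_events,
        truth=truth,
        junctions=junctions,
        tpm=tpm,
        mark_reads=mark_reads,
        genome=genome,
    )


def simulate_shifted_condition(
    ds: SimulatedDataset, shift_fraction: float = 0.5, seed: int = 1,
    condition: str = "simB",
) -> SimulatedDataset:
    """A second condition in which a fraction of events change group.

    Shifted events draw a new PSI from a uniformly chosen *different*
    group; planted signature reads follow the new labels (events leaving
    a signature's group lose its reads), which is the structure the
    maintenance analysis tests.
    """
    rng = _stream(seed, f"shift:{condition}")
    groups = list(ds.groups)
    psis = np.asarray(ds.truth["true_psi"], dtype=float).copy()
    config = ds.config
    shifted = rng.random(len(groups)) < shift_fraction
    for i in np.where(shifted)[0]:
        others = [g for g in GROUPS if g != groups[i]]
        new_g = others[int(rng.integers(len(others)))]
        lo, hi = GROUP_INTERVALS[new_g]
        groups[i] = new_g
        psis[i] = rng.uniform(lo + config.psi_margin, hi - config.psi_margin)

    jn_rng = _stream(seed, f"junctions:{condition}")
    junctions, count_rows = _junctions_for_condition(
        ds.models, ds.events, psis, config.junction_depth, jn_rng
    )

    shifted_config = replace(config, seed=(config.seed + 7919 + seed) & 0x7FFFFFFF)
    prev_members: dict[str, set[str]] = {}
    for eid, sigs in zip(ds.truth["event_id"], ds.truth["signature_id"]):
        for sig_id in str(sigs).split(";"):
            if sig_id and sig_id != "nan":
                prev_members.setdefault(sig_id, set()).add(eid)
    prev_groups = dict(zip(ds.truth["event_id"], ds.truth["group"]))
    plants_by_mark, sig_of_event = _plant_assignments(
        config,
        ds.events,
        groups,
        shifted_config.seed,
        prev_members=prev_members,
        prev_groups=prev_groups,
    )

    genome_len = (
        max(m.exons[-1].end if m.strand == "+" else m.exons[0].end for m in ds.models)
        + config.intergenic_nt
    )
    mark_reads = {
        mark: _mark_reads(shifted_config, genome_len, mark, plants_by_mark[mark])
        for mark in config.marks
    }
    truth = count_rows.copy()
    truth.insert(1, "gene_id", [ev.gene_id for ev in ds.events])
    truth.insert(2, "group", groups)
    truth.insert(3, "true_psi", psis)
    truth["signature_id"] = [
        ";".join(sig_of_event.get(ev.event_id, [])) for ev in ds.events
    ]
    return SimulatedDataset(
        config=config,
        models=ds.models,
        events=ds.events,
        constitutive_events=ds.constitutive_events,
        truth=truth,
        junctions=junctions,
        tpm=ds.tpm,
        mark_reads=mark_reads,
        genome=ds.genome,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# Motif planting
# ---------------------------------------------------------------------------

def plant_motifs(
    sequences: dict[str, str],
    plants: Sequence[MotifPlant],
    seed: int,
) -> tuple[dict[str, str], pd.DataFrame, int]:
    """Insert motif consensus occurrences into sequences.

    Insertion replaces bases at a uniform random offset (no shifting);
    the number of insertions per sequence is Poisson(rate), capped so
    insertions fit.  Returns (new sequences, truth log, n skipped because
    the sequence is shorter than the motif).
    """
    rng = _stream(seed, "motifs")
    out = dict(sequences)
    log_rows = []
    skipped = 0
    for plant in plants:
        width = len(plant.consensus)
        targets = plant.target_ids if plant.target_ids is not None else tuple(out)
        for sid in targets:
            seq = out[sid]
            if len(seq) < width:
                skipped += 1
                continue
            n_ins = int(rng.poisson(plant.rate)) if plant.rate > 0 else 0
            for _ in range(n_ins):
                off = int(rng.integers(0, len(seq) - width + 1))
                seq = seq[:off] + plant.consensus + seq[off + width :]
                log_rows.append(
                    {"seq_id": sid, "motif_id": plant.motif_id, "offset": off}
                )
            out[sid] = seq
    log = pd.DataFrame(log_rows, columns=["seq_id", "motif_id", "offset"])
    return out, log, skipped


# ---------------------------------------------------------------------------
# On-disk bundle
# ---------------------------------------------------------------------------

def write_dataset(ds: SimulatedDataset, outdir: str) -> dict[str, str]:
    """Write the bundle in the pipeline's input formats; returns paths."""
    import os

    from . import core_io

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    paths["annotation"] = os.path.join(outdir, "annotation.gtf")
    core_io.write_gene_models_gtf(paths["annotation"], ds.models)
    paths["junctions"] = os.path.join(outdir, "junctions.tsv")
    core_io.write_junction_table(paths["junctions"], ds.junctions)
    paths["tpm"] = os.path.join(outdir, "tpm.tsv")
    tpm_frame = pd.DataFrame(
        sorted(ds.tpm.items()), columns=["gene_id", "tpm"]
    )
    core_io.write_table(paths["tpm"], tpm_frame, "tpm")
    if ds.genome is not None:
        paths["genome"] = os.path.join(outdir, "genome.fa")
        core_io.write_fasta(paths["genome"], ds.genome)
    for mark, reads in ds.mark_reads.items():
        p = os.path.join(outdir, f"reads_{mark}.bed")
        core_io.write_bed(p, reads)
        paths[f"reads:{mark}"] = p
    paths["truth"] = os.path.join(outdir, "truth.tsv")
    core_io.write_table(paths["truth"], ds.truth, "truth")
    return paths
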