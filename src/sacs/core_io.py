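"""Input/output layer and the genomic coordinate contract.

Every coordinate handed between modules is 0-based, half-open (BED
convention).  1-based formats (STAR ``SJ.out.tab``, GTF) are converted at
the boundary, in this module only.  Strand-aware vocabulary used
throughout the package: *upstream*/*downstream*, the 3'ss (exon start in
transcription order, the acceptor) and the 5'ss (exon end, the donor) are
defined in transcription order and therefore mirror on the minus strand.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

STRANDS = ("+", "-", ".")

#: Floor applied to PWM probabilities before taking log-odds, to keep
#: scores finite for zero-probability cells.
PWM_PROB_FLOOR = 1e-4

#: Comment-header prefix written at the top of every output table.
TABLE_COMMENT = "#"

__version__ = "0.1.0"


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


class ConfigurationError(ValueError):
    """An invalid option (unknown dialect, bad parameter value)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``start`` is inclusive, ``end`` exclusive; ``strand`` is ``+``, ``-``
    or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(
            self.chrom, self.start + offset, self.end + offset, self.strand
        )


@dataclass(frozen=True)
class JunctionRecord:
    """A splice junction: intron coordinates plus unique read support."""

    interval: GenomicInterval
    unique_reads: int

    def __post_init__(self) -> None:
        if self.unique_reads < 0:
            raise ValueError("unique_reads must be >= 0")


@dataclass
class GeneModel:
    """One transcript of one gene, as an ordered exon chain.

    ``exons`` are sorted in transcription order (genomically descending on
    the minus strand); ``constitutive_flags`` aligns with ``exons``.
    """

    gene_id: str
    transcript_id: str
    exons: list[GenomicInterval]
    biotype: str = "protein_coding"
    constitutive_flags: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.constitutive_flags:
            self.constitutive_flags = [False] * len(self.exons)
        if len(self.constitutive_flags) != len(self.exons):
            raise ValueError("constitutive_flags must align with exons")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )

    @property
    def strand(self) -> str:
        return self.exons[0].strand if self.exons else "."


# ---------------------------------------------------------------------------
# Junction tables
# ---------------------------------------------------------------------------

def read_junction_table(path: str, dialect: str = "star_sj") -> list[JunctionRecord]:
    """Read a splice-junction count table.

    ``star_sj``: the 9-column STAR ``SJ.out.tab`` layout, whose intron
    coordinates are 1-based inclusive; they are converted to the internal
    0-based half-open contract here.  ``tsv``: a headered tab-separated
    equivalent (chrom, start, end, strand, unique_reads) already 0-based
    half-open.
    """
    if dialect not in ("star_sj", "tsv"):
        raise ConfigurationError(f"unknown junction dialect {dialect!r}")
    records: list[JunctionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(TABLE_COMMENT):
                continue
            fields = line.split()
            try:
                if dialect == "star_sj":
                    if len(fields) < 7:
                        raise ValueError("expected >= 7 columns")
                    chrom = fields[0]
                    start1, end1 = int(fields[1]), int(fields[2])
                    strand_code = int(fields[3])
                    strand = {0: ".", 1: "+", 2: "-"}[strand_code]
                    count = int(fields[6])
                    interval = GenomicInterval(chrom, start1 - 1, end1, strand)
                else:
                    if fields[0] in ("chrom", "chr"):  # header row
                        continue
                    chrom = fields[0]
                    interval = GenomicInterval(
                        chrom, int(fields[1]), int(fields[2]), fields[3]
                    )
                    count = int(fields[4])
                records.append(JunctionRecord(interval, count))
            except (ValueError, KeyError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_junction_table(path: str, records: Sequence[JunctionRecord]) -> None:
    """Write junctions in the internal ``tsv`` dialect (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write(_comment_header("junctions"))
        fh.write("chrom\tstart\tend\tstrand\tunique_reads\n")
        for rec in records:
            iv = rec.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{rec.unique_reads}\n"
            )


# ---------------------------------------------------------------------------
# BED intervals (reads, peaks, eCLIP)
# ---------------------------------------------------------------------------

def read_reads_bed(path: str) -> list[GenomicInterval]:
    """Read a BED3/BED6 interval file; BED3 lines get strand ``.``."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                out.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(path: str, intervals: Iterable[GenomicInterval], names: Iterable[str] | None = None) -> None:
    """Write intervals as BED6 (score column fixed at 0)."""
    with open(path, "w") as fh:
        if names is None:
            names = (f"iv{i}" for i in range(10**12))
        for iv, name in zip(intervals, names):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Gene models (GTF)
# ---------------------------------------------------------------------------

def read_gene_models(path: str) -> list[GeneModel]:
    """Read transcripts from a GTF file (exon features only are required).

    Recognised attributes: ``gene_id``, ``transcript_id``,
    ``gene_biotype`` (default protein_coding) and the per-exon flag
    ``constitutive_exon`` ("1"/"0").  Uses gffutils for parsing.
    """
    import gffutils

    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    by_tx: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        tx = exon.attributes["transcript_id"][0]
        entry = by_tx.setdefault(
            tx,
            {
                "gene_id": exon.attributes["gene_id"][0],
                "biotype": exon.attributes.get("gene_biotype", ["protein_coding"])[0],
                "exons": [],
            },
        )
        const = exon.attributes.get("constitutive_exon", ["0"])[0] == "1"
        entry["exons"].append(
            (
                GenomicInterval(exon.seqid, exon.start - 1, exon.end, exon.strand),
                const,
            )
        )
    models = []
    for tx, entry in by_tx.items():
        exons = sorted(entry["exons"], key=lambda p: p[0].start)
        if exons and exons[0][0].strand == "-":
            exons = exons[::-1]  # transcription order
        models.append(
            GeneModel(
                gene_id=entry["gene_id"],
                transcript_id=tx,
                exons=[e for e, _ in exons],
                biotype=entry["biotype"],
                constitutive_flags=[c for _, c in exons],
            )
        )
    models.sort(key=lambda m: m.transcript_id)
    return models


def write_gene_models_gtf(path: str, models: Sequence[GeneModel]) -> None:
    """Write transcripts as GTF exon lines (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        for m in models:
            for i, (exon, const) in enumerate(zip(m.exons, m.constitutive_flags), 1):
                attrs = (
                    f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                    f'gene_biotype "{m.biotype}"; exon_number "{i}"; '
                    f'constitutive_exon "{int(const)}";'
                )
                fh.write(
                    f"{exon.chrom}\tsim\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{exon.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into a dict of upper-case sequences."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path: str, sequences: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PWMs (CISBP-style position probability matrices)
# ---------------------------------------------------------------------------

def read_pwm_set(path: str, tolerance: float = 1e-3) -> list[tuple[str, np.ndarray]]:
    """Read position probability matrices.

    Format: ``>motif_id`` header lines, each followed by one row per
    position with 4 whitespace-separated probabilities (A, C, G, U/T; U is
    mapped to T by column position).  Rows must sum to 1 within
    ``tolerance`` and are renormalised to sum exactly 1.
    """
    motifs: list[tuple[str, np.ndarray]] = []
    name: str | None = None
    rows: list[list[float]] = []

    def _flush(lineno: int) -> None:
        nonlocal name, rows
        if name is None:
            return
        if not rows:
            raise ParseError(f"{path}:{lineno}: empty motif {name!r}")
        mat = np.asarray(rows, dtype=float)
        sums = mat.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > tolerance)[0]
        if bad.size:
            raise ParseError(
                f"{path}: motif {name!r} row {bad[0] + 1} sums to {sums[bad[0]]:.4g}"
            )
        motifs.append((name, mat / sums[:, None]))
        name, rows = None, []

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                _flush(lineno)
                name = line[1:].split()[0]
                continue
            fields = line.replace(",", " ").split()
            if fields[0].lower() in ("pos", "position"):
                continue
            if name is None:
                raise ParseError(f"{path}:{lineno}: matrix row before a motif header")
            # CISBP dumps often lead with a position index column
            if len(fields) == 5:
                fields = fields[1:]
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 probabilities")
            try:
                rows.append([float(x) for x in fields])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
        _flush(lineno + 1)
    return motifs


def write_pwm_set(path: str, motifs: Sequence[tuple[str, np.ndarray]]) -> None:
    with open(path, "w") as fh:
        for name, mat in motifs:
            fh.write(f">{name}\n")
            for row in mat:
                fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# Output tables
# ---------------------------------------------------------------------------

def _comment_header(kind: str, params: dict | None = None) -> str:
    parts = [f"{TABLE_COMMENT} sacs v{__version__} {kind}"]
    if params:
        parts.append(
            TABLE_COMMENT
            + " "
            + " ".join(f"{k}={v}" for k, v in sorted(params.items()))
        )
    return "\n".join(parts) + "\n"


def write_table(path: str, frame, kind: str, params: dict | None = None) -> None:
    """Write a DataFrame as a commented, tab-separated UTF-8 table."""
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_comment_header(kind, params))
        frame.to_csv(fh, sep="\t", index=False)


def read_table(path: str):
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment=TABLE_COMMENT)
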