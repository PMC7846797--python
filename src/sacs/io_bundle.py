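"""Load a dataset directory (the layout written by ``write_dataset``)
back into the in-memory bundle the pipeline consumes."""

from __future__ import annotations

import glob
import os

from . import core_io
from .splicing_quantification import extract_cassette_events
from .synthetic_data import (
    SimulatedDataset,
    SimulationConfig,
    _constitutive_triplets,
)


def load_dataset_dir(path: str) -> SimulatedDataset:
    models = core_io.read_gene_models(os.path.join(path, "annotation.gtf"))
    events = extract_cassette_events(models)
    events.sort(key=lambda ev: ev.gene_id)
    alt_index = {}
    for m in models:
        for i, const in enumerate(m.constitutive_flags):
            if not const:
                alt_index[m.gene_id] = i
                break
    junctions = core_io.read_junction_table(
        os.path.join(path, "junctions.tsv"), dialect="tsv"
    )
    tpm_frame = core_io.read_table(os.path.join(path, "tpm.tsv"))
    tpm = dict(zip(tpm_frame["gene_id"], tpm_frame["tpm"]))
    mark_reads = {}
    for bed in sorted(glob.glob(os.path.join(path, "reads_*.bed"))):
        mark = os.path.basename(bed)[len("reads_") : -len(".bed")]
        mark_reads[mark] = core_io.read_reads_bed(bed)
    genome = None
    fasta = os.path.join(path, "genome.fa")
    if os.path.exists(fasta):
        genome = core_io.read_fasta(fasta)
    truth_path = os.path.join(path, "truth.tsv")
    truth = core_io.read_table(truth_path) if os.path.exists(truth_path) else None
    return SimulatedDataset(
        config=SimulationConfig(marks=tuple(sorted(mark_reads))),
        models=models,
        events=events,
        constitutive_events=_constitutive_triplets(models, alt_index),
        truth=truth,
        junctions=junctions,
        tpm=tpm,
        mark_reads=mark_reads,
        genome=genome,
    )
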