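"""End-to-end orchestration: junctions -> PSI -> features -> selection ->
co-enrichment -> signatures.

`run_discovery` chains the full method on one condition's inputs (as
produced by `synthetic_data.simulate_dataset` or loaded from files) and
returns every intermediate product, so callers can inspect any stage or
re-run a single one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .epigenomic_features import (
    MarkTrack,
    PeakCluster,
    build_clusters,
    build_feature_matrix,
    extend_reads,
    normalize_against_input,
)
from .feature_selection import (
    SelectionConfig,
    SelectionReport,
    run_all_pairwise,
    selected_marks,
)
from .sacs_discovery import (
    DEFAULT_Z_MIN,
    CoEnrichmentResult,
    SacsSignature,
    assign_members,
    co_enrichment_scan,
    localize_signatures,
    make_region_sets,
    randomize_group_labels,
    reciprocity_filter,
    uniqueness_filter,
)
from .splicing_quantification import (
    CassetteEvent,
    PsiRecord,
    filter_expression,
    quantify_events,
)
from .synthetic_data import SimulatedDataset

logger = logging.getLogger(__name__)


@dataclass
class DiscoveryResult:
    events: list[CassetteEvent]
    psi_records: list[PsiRecord]
    feature_matrix: pd.DataFrame
    selection_reports: list[SelectionReport]
    selected_marks: list[str]
    coenrichment: list[CoEnrichmentResult]
    signatures: list[SacsSignature]
    breakdowns: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def groups(self) -> list[str]:
        return [r.group for r in self.psi_records]

    @property
    def n_marked(self) -> int:
        return len({e for s in self.signatures for e in s.member_events})

    @property
    def marked_fraction(self) -> float:
        return self.n_marked / len(self.events) if self.events else 0.0

    def signatures_frame(self) -> pd.DataFrame:
        rows = []
        for sig in self.signatures:
            a, b = sorted(sig.mark_pair)
            rows.append(
                {
                    "signature_id": sig.signature_id,
                    "mark_a": a,
                    "mark_b": b,
                    "region": sig.region_kind,
                    "group": sig.group,
                    "n_members": sig.n_members,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["signature_id", "mark_a", "mark_b", "region", "group", "n_members"],
        )


def prepare_tracks(
    mark_reads: Mapping[str, Sequence], extension_nt: int = 200
) -> dict[str, MarkTrack]:
    """Extend raw reads 5'->3' and index them as MarkTracks."""
    return {
        mark: MarkTrack.from_intervals(mark, extend_reads(list(reads), extension_nt))
        for mark, reads in mark_reads.items()
    }


def peaks_from_tracks(
    tracks: Mapping[str, MarkTrack],
    input_tracks: Mapping[str, MarkTrack] | None = None,
    min_fold: float = 2.0,
) -> dict[str, list[PeakCluster]]:
    """Cluster extended reads and filter against inputs where available."""
    peaks = {}
    for mark, track in tracks.items():
        clusters = build_clusters(track.reads)
        inp = input_tracks.get(mark) if input_tracks else None
        peaks[mark] = normalize_against_input(
            clusters, inp, track_library_size=track.library_size, min_fold=min_fold
        )
    return peaks


def run_discovery(
    ds: SimulatedDataset,
    selection_config: SelectionConfig | None = None,
    min_junction_reads: int = 5,
    min_tpm: float = 10.0,
    extension_nt: int = 200,
    r: float = 0.1,
    n_boot: int = 1000,
    z_min: float = DEFAULT_Z_MIN,
    seed: int = 0,
    skip_selection: bool = False,
    randomize_labels: bool = False,
) -> DiscoveryResult:
    """Run the full signature-discovery method on one condition.

    With ``randomize_labels`` the splicing-group labels are shuffled
    before selection and co-enrichment: the overfitting control, which
    should yield no signatures.  ``skip_selection`` admits every mark to
    the pairwise co-enrichment scan (used when the mark panel is fixed
    upstream).
    """
    events = filter_expression(ds.events, ds.tpm, min_tpm=min_tpm)
    psi_records = quantify_events(
        events, ds.junctions, condition=ds.condition, min_reads=min_junction_reads
    )
    defined = [
        (ev, rec) for ev, rec in zip(events, psi_records) if rec.group != "NA"
    ]
    events = [ev for ev, _ in defined]
    psi_records = [rec for _, rec in defined]
    groups = [rec.group for rec in psi_records]
    if randomize_labels:
        groups = randomize_group_labels(groups, seed=seed + 17)

    tracks = prepare_tracks(ds.mark_reads, extension_nt)
    matrix = build_feature_matrix(events, list(tracks.values()))

    if skip_selection:
        reports: list[SelectionReport] = []
        marks = sorted(tracks)
    else:
        config = selection_config or SelectionConfig(seed=seed)
        reports = run_all_pairwise(matrix, groups, config)
        confirmed = sorted({f for rep in reports for f in rep.confirmed})
        marks = selected_marks(confirmed)
        logger.info("selection kept %d marks: %s", len(marks), marks)

    signatures: list[SacsSignature] = []
    breakdowns: dict[str, dict[str, int]] = {}
    results: list[CoEnrichmentResult] = []
    if len(marks) >= 2:
        peaks = peaks_from_tracks({m: tracks[m] for m in marks})
        region_sets = make_region_sets(
            events,
            groups,
            constitutive_events=ds.constitutive_events,
            seed=seed,
        )
        results = co_enrichment_scan(
            peaks, region_sets, r=r, n_boot=n_boot, z_min=z_min, seed=seed
        )
        reciprocal = reciprocity_filter(results, z_min=z_min)
        signatures = uniqueness_filter(reciprocal)
        signatures = localize_signatures(
            signatures, results, peaks_by_mark=peaks, region_sets=region_sets
        )
        region_by_key = {(s.group, s.region_kind): s for s in region_sets}
        for sig in signatures:
            regions = region_by_key[(sig.group, sig.region_kind)]
            _, breakdown = assign_members(sig, peaks, regions)
            breakdowns[sig.signature_id] = breakdown
    return DiscoveryResult(
        events=events,
        psi_records=psi_records,
        feature_matrix=matrix,
        selection_reports=reports,
        selected_marks=marks,
        coenrichment=results,
        signatures=signatures,
        breakdowns=breakdowns,
    )
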