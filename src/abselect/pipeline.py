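"""End-to-end campaign analysis: filter -> demultiplex -> annotate -> cluster.

Convenience layer tying the stage modules together for a whole campaign;
each stage remains individually usable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .abscan import AbScanClusterer, ClusterAssignment
from .annotation import AnnotatedClone, ScaffoldRef, annotate_reads, roi_string
from .io_ngs import BarcodeSpec, FilterConfig, SeqRead, demultiplex, quality_filter
from .quantify import relative_frequency, roi_counts


@dataclass
class PipelineResult:
    clones: list[AnnotatedClone]
    rejects: list[tuple[str, str]]
    unassigned: list[SeqRead]
    n_quality_rejected: int
    assignments: list[ClusterAssignment]
    clusterer: AbScanClusterer
    roi: str
    read_to_clone: dict[str, str] = field(repr=False)

    def cluster_of(self) -> dict[str, int]:
        """ROI value -> cluster id for every non-discarded value."""
        return {a.roi_value: a.cluster_id for a in self.assignments
                if a.cluster_id is not None}

    def read_to_cluster(self) -> dict[str, int]:
        """Read id -> cluster id over annotated, non-discarded reads."""
        clone_by_id = {c.clone_id: c for c in self.clones}
        cluster_of = self.cluster_of()
        out = {}
        for rid, cid in self.read_to_clone.items():
            cluster = cluster_of.get(roi_string(clone_by_id[cid], self.roi))
            if cluster is not None:
                out[rid] = cluster
        return out

    def population_frequencies(self, population: str) -> dict[str, float]:
        return relative_frequency(roi_counts(self.clones, self.roi, population))


def run_pipeline(
    reads: Sequence[SeqRead],
    barcodes: Sequence[BarcodeSpec],
    scaffolds: Sequence[ScaffoldRef],
    roi: str = "HCDR3",
    filter_cfg: FilterConfig = FilterConfig(),
    clusterer: AbScanClusterer | None = None,
) -> PipelineResult:
    """Run the full analysis on raw barcoded reads (pooled clustering mode)."""
    kept = quality_filter(reads, filter_cfg)
    assigned, unassigned = demultiplex(kept, barcodes)
    clones, rejects, read_to_clone = annotate_reads(assigned, scaffolds)
    clusterer = clusterer or AbScanClusterer()
    values, counts = [], []
    pooled: dict[str, int] = {}
    for clone in clones:
        v = roi_string(clone, roi)
        pooled[v] = pooled.get(v, 0) + clone.total_count
    for v in sorted(pooled, key=lambda v: (-pooled[v], v)):
        values.append(v)
        counts.append(pooled[v])
    if values:
        clusterer.fit(values, counts=counts)
        assignments = clusterer.assignments_
    else:
        assignments = []
    return PipelineResult(
        clones=clones,
        rejects=rejects,
        unassigned=unassigned,
        n_quality_rejected=len(reads) - len(kept),
        assignments=assignments,
        clusterer=clusterer,
        roi=roi,
        read_to_clone=read_to_clone,
    )
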