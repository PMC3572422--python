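"""End-to-end successive-refinement mapping pipeline.

Ties the stages together: suffix-array anchoring -> window chaining and
ranking -> candidate intervals -> SDP chains -> guided banded alignment ->
mapping quality.  The unit of work is one read; reads are processed in input
order and results are deterministic for a fixed configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .anchoring import find_anchors
from .banded_alignment import (
    AlignmentResult,
    BandError,
    GuideBand,
    banded_align,
    build_guide_band,
)
from .clustering import AnchorCluster, cluster_anchors, rank_clusters
from .config import MapperConfig
from .map_quality import AnchorBasesMoments, cluster_significance, compute_mapqv
from .ref_index import ReferenceIndex, build_index
from .refinement import SdpChain, candidate_interval, sdp_refine
from .seq_io import SeqRecord

__all__ = ["Mapper"]

logger = logging.getLogger(__name__)


@dataclass
class Mapper:
    """Maps reads against a reference genome.

    Parameters
    ----------
    genome:
        Reference records; an index is built on construction (or pass a
        prebuilt ``index``).
    cfg:
        Mapper configuration; defaults follow the standard parameterization.
    """

    genome: Sequence[SeqRecord]
    cfg: MapperConfig = field(default_factory=MapperConfig)
    index: Optional[ReferenceIndex] = None

    def __post_init__(self) -> None:
        if self.index is None:
            self.index = build_index(self.genome)
        self.moments = AnchorBasesMoments(seed=self.cfg.seed)

    def map_read(self, read: SeqRecord) -> AlignmentResult:
        """Map one read; returns an unmapped result when no candidate
        survives."""
        cfg = self.cfg
        idx = self.index
        R = len(read.seq)
        if R < cfg.K:
            logger.info("read %s shorter than K; unmapped", read.id)
            return AlignmentResult.unmapped(read)
        anchors = find_anchors(read, idx, cfg)
        if not anchors:
            return AlignmentResult.unmapped(read)
        clusters = cluster_anchors(anchors, R)
        ranked = rank_clusters(clusters, cfg, idx.size)
        candidates: list[AlignmentResult] = []
        for cluster in ranked:
            result = self._align_candidate(read, cluster)
            if result is not None:
                candidates.append(result)
        if not candidates:
            return AlignmentResult.unmapped(read)
        candidates.sort(key=lambda r: (r.cost, r.ref_start, r.strand))
        best = candidates[0]
        n_sig = cluster_significance(
            clusters, R, best.accuracy, cfg.K, self.moments
        )
        qv = compute_mapqv([c.cost for c in candidates], n_sig, cfg)
        best.mapq = qv.Q
        return best

    def map_reads(self, reads: Sequence[SeqRecord]) -> list[AlignmentResult]:
        return [self.map_read(r) for r in reads]

    # ------------------------------------------------------------------

    def _align_candidate(
        self, read: SeqRecord, cluster: AnchorCluster
    ) -> Optional[AlignmentResult]:
        cfg = self.cfg
        idx = self.index
        R = len(read.seq)
        ci = candidate_interval(cluster, R, idx.size, cfg)
        # keep the interval inside the record holding the cluster
        rec_start, rec_end = idx.record_bounds(cluster.a_first.genome_pos)
        s = max(ci.s, rec_start)
        f = min(ci.f, rec_end)
        if f - s < cfg.k_sdp:
            return None
        interval_seq = idx.text[s:f].decode("ascii")
        oriented = read if cluster.strand == "+" else read.reverse_complement()
        chain = sdp_refine(oriented.seq, interval_seq, cfg)
        band = build_guide_band(chain, R, f - s, cfg)
        try:
            result = banded_align(oriented, interval_seq, band, cfg)
        except BandError:
            if not chain.matches:
                return None
            # widen once to the full matrix, then give up on the candidate
            full = build_guide_band(SdpChain(matches=[], k=cfg.k_sdp), R, f - s, cfg)
            try:
                result = banded_align(oriented, interval_seq, full, cfg)
            except BandError:
                return None
        rec_idx, local = idx.record_at(s + result.ref_start)
        result.ref_id = idx.names[rec_idx]
        result.strand = cluster.strand
        result.ref_start = local
        result.ref_end = local + sum(
            length for op, length in result.cigar if op in ("M", "D")
        )
        return result
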