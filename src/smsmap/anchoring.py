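"""Anchor generation: exact matches between a read and the genome.

For every read position the longest common prefix of the read suffix with
the genome is located through the suffix array; matches are deliberately
shortened by ``lcp_shorten`` bases (never below the minimum anchor length K)
because an LCP tends to end in a sequencing error.  Positions whose LCP
occurs more than ``max_count`` times, or is shorter than K, contribute
nothing.  The same scan runs on the reverse complement of the read; minus
strand anchors keep their genome coordinates on the forward strand and
their read coordinates on the reverse-complemented read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .config import MapperConfig
from .ref_index import ReferenceIndex, count_lcp, count_occurrences
from .seq_io import SeqRecord, revcomp

__all__ = ["Anchor", "find_anchors"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Anchor:
    """Exact match triplet: read offset, genome offset (global text
    coordinates), match length; plus strand and the genome-wide frequency of
    the matched sequence."""

    read_pos: int
    genome_pos: int
    length: int
    strand: str  # '+' or '-'
    freq: int = 1

    @property
    def read_end(self) -> int:
        return self.read_pos + self.length

    @property
    def genome_end(self) -> int:
        return self.genome_pos + self.length


def _scan_strand(
    seq: str, strand: str, idx: ReferenceIndex, cfg: MapperConfig
) -> list[Anchor]:
    anchors: list[Anchor] = []
    R = len(seq)
    seqb = seq.encode("ascii")
    freq_cache: dict[bytes, int] = {}
    for i in range(R - cfg.K + 1):
        c, l, hits = count_lcp(seqb[i:], idx, max_hits=cfg.max_count)
        if l < cfg.K or c > cfg.max_count:
            continue
        length = max(l - cfg.lcp_shorten, cfg.K)
        frag = seqb[i : i + length]
        if b"N" in frag:
            continue  # poly-N anchors are spurious
        freq = freq_cache.get(frag)
        if freq is None:
            freq = count_occurrences(frag, idx) if length < l else c
            freq_cache[frag] = freq
        for pos in hits.tolist():
            anchors.append(Anchor(i, pos, length, strand, max(freq, 1)))
    return anchors


def find_anchors(read: SeqRecord, idx: ReferenceIndex, cfg: MapperConfig) -> list[Anchor]:
    """All anchors of the read against the genome, on both strands.

    Reads shorter than K yield an empty list (logged).  Every emitted anchor
    is a verbatim exact match of its (possibly shortened) sequence.
    """
    if len(read.seq) < cfg.K:
        logger.info("read %s shorter than K=%d; skipped", read.id, cfg.K)
        return []
    anchors = _scan_strand(read.seq, "+", idx, cfg)
    anchors += _scan_strand(revcomp(read.seq), "-", idx, cfg)
    return anchors
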