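"""Anchor clustering: global chaining inside read-length genome windows.

Each anchor seeds a window of genome span equal to the read length; the
anchors falling in a window are chained (maximum total anchor bases, strictly
colinear and non-overlapping in read and genome).  Identical or contained
chains are deduplicated, and the survivors are ranked by a frequency-weighted
score sum(log(1/freq(a))) where freq(a) = Freq(a)/G is the *relative*
genomic frequency of the anchor's sequence: every anchor contributes
log(G/Freq(a)) > 0, so rare anchors count for more and a chain of many
unique anchors outranks any accidental single match, while anchors from deep
repeat families are discounted.  Only the top ``max_candidates`` clusters
proceed to refinement, but the full pre-truncation list is kept by the
caller for mapping-quality significance counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .anchoring import Anchor
from .config import MapperConfig

__all__ = ["AnchorCluster", "cluster_anchors", "rank_clusters"]


@dataclass
class AnchorCluster:
    """A chained, scored set of anchors on one strand."""

    anchors: list[Anchor]
    strand: str
    rank: Optional[int] = None
    fw_score: float = 0.0
    anchor_bases: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ValueError("a cluster must contain at least one anchor")
        self.anchor_bases = sum(a.length for a in self.anchors)

    def score(self, genome_size: int) -> float:
        """Frequency-weighted score: sum of log(1/freq) over the chain with
        freq the anchor sequence's relative genomic frequency Freq/G."""
        return sum(math.log(genome_size / a.freq) for a in self.anchors)

    @property
    def a_first(self) -> Anchor:
        return self.anchors[0]

    @property
    def a_last(self) -> Anchor:
        return self.anchors[-1]


def _chain(window: list[Anchor]) -> list[Anchor]:
    """Maximum-anchor-bases colinear chain (O(n^2) dynamic programming).

    Chained anchors must not overlap: each successor starts at or after the
    predecessor's end in both read and genome.
    """
    order = sorted(range(len(window)), key=lambda i: (window[i].read_pos, window[i].genome_pos))
    anchors = [window[i] for i in order]
    n = len(anchors)
    score = [a.length for a in anchors]
    pred = [-1] * n
    for j in range(n):
        aj = anchors[j]
        for k in range(j):
            ak = anchors[k]
            if ak.read_end <= aj.read_pos and ak.genome_end <= aj.genome_pos:
                cand = score[k] + aj.length
                if cand > score[j]:
                    score[j] = cand
                    pred[j] = k
    best = max(range(n), key=lambda j: (score[j], -anchors[j].genome_pos))
    chain: list[Anchor] = []
    while best != -1:
        chain.append(anchors[best])
        best = pred[best]
    chain.reverse()
    return chain


def cluster_anchors(anchors: list[Anchor], R: int) -> list[AnchorCluster]:
    """Chain anchors within read-length windows into clusters.

    For every anchor ``a_i`` the window holds all anchors ``a_j`` with
    ``0 <= Genome(a_j) + l(a_j) - Genome(a_i) <= R``; each window is chained
    independently and duplicate or contained chains are dropped so that every
    surviving cluster is maximal.  Strands never mix within a cluster.
    """
    clusters: list[AnchorCluster] = []
    for strand in "+-":
        group = sorted(
            (a for a in anchors if a.strand == strand),
            key=lambda a: (a.genome_pos, a.read_pos),
        )
        if not group:
            continue
        ends = [a.genome_end for a in group]
        chains: dict[tuple, list[Anchor]] = {}
        seen_windows: set[tuple[int, ...]] = set()
        for a_i in group:
            member_idx = tuple(
                j for j, e in enumerate(ends) if 0 <= e - a_i.genome_pos <= R
            )
            if not member_idx or member_idx in seen_windows:
                continue
            seen_windows.add(member_idx)
            chain = _chain([group[j] for j in member_idx])
            key = tuple((a.read_pos, a.genome_pos, a.length) for a in chain)
            chains[key] = chain
        # drop duplicate chains and chains whose genome span lies inside a
        # better chain's span (suffix chains of the same locus)
        def span(chain: list[Anchor]) -> tuple[int, int]:
            return chain[0].genome_pos, chain[-1].genome_end

        order = sorted(
            chains.values(), key=lambda ch: sum(a.length for a in ch), reverse=True
        )
        kept_spans: list[tuple[int, int]] = []
        for chain in order:
            s, e = span(chain)
            if any(ks <= s and e <= ke for ks, ke in kept_spans):
                continue
            kept_spans.append((s, e))
            clusters.append(AnchorCluster(anchors=chain, strand=strand))
    return clusters


def rank_clusters(
    clusters: list[AnchorCluster], cfg: MapperConfig, genome_size: int
) -> list[AnchorCluster]:
    """Sort clusters by frequency-weighted score and keep the best.

    Ties break by anchor bases, then by leftmost genome start, for
    determinism.  Ranks are 1-based; at most ``cfg.max_candidates`` clusters
    are returned (callers keep the pre-truncation list for significance).
    """
    for c in clusters:
        c.fw_score = c.score(genome_size)
    ranked = sorted(
        clusters,
        key=lambda c: (-c.fw_score, -c.anchor_bases, c.a_first.genome_pos, c.strand),
    )
    top = ranked[: cfg.max_candidates]
    for i, c in enumerate(top, 1):
        c.rank = i
    return top
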