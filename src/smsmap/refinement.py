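"""Candidate intervals and sparse dynamic programming refinement.

A ranked cluster defines a genome interval that should contain the whole
read: the chained anchors are extended outwards by the unanchored read
prefix/suffix scaled by (1 + delta), delta being the assumed maximum
insertion rate.  Inside that interval a fine-grained chain of short
fixed-length (k_sdp) exact matches is computed by sparse dynamic
programming; the chain later guides the banded alignment.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass

from .clustering import AnchorCluster
from .config import MapperConfig

__all__ = ["CandidateInterval", "SdpChain", "candidate_interval", "sdp_refine"]

# above this many matches the drift-minimizing quadratic pass is skipped and
# pure patience chaining (O(n log n)) is used
_EXACT_TIEBREAK_LIMIT = 1500


@dataclass(frozen=True)
class CandidateInterval:
    """Genome interval [s, f) (global text coordinates) for one cluster."""

    s: int
    f: int
    strand: str

    @property
    def length(self) -> int:
        return self.f - self.s


@dataclass
class SdpChain:
    """Ordered chain of (read_pos, interval_pos) matches of fixed length."""

    matches: list[tuple[int, int]]
    k: int

    def __len__(self) -> int:
        return len(self.matches)


def candidate_interval(
    cluster: AnchorCluster, R: int, G: int, cfg: MapperConfig
) -> CandidateInterval:
    """Interval [s, f) containing the cluster plus (1+delta)-scaled flanks.

    s = Genome(a_first) - (1+delta) * Read(a_first) and
    f = Genome(a_last) + (1+delta) * (R - Read(a_last) - l(a_last)), rounded
    outward and clamped to the genome.
    """
    first, last = cluster.a_first, cluster.a_last
    s = math.floor(first.genome_pos - (1.0 + cfg.delta) * first.read_pos)
    f = math.ceil(last.genome_end + (1.0 + cfg.delta) * (R - last.read_end))
    return CandidateInterval(s=max(s, 0), f=min(f, G), strand=cluster.strand)


def _kmer_matches(read: str, interval: str, k: int) -> list[tuple[int, int]]:
    index: dict[str, list[int]] = {}
    for j in range(len(interval) - k + 1):
        index.setdefault(interval[j : j + k], []).append(j)
    out = [
        (i, j)
        for i in range(len(read) - k + 1)
        for j in index.get(read[i : i + k], ())
    ]
    out.sort()
    return out


def _lis_patience(matches: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Maximum chain strictly increasing in both coordinates, O(n log n)."""
    # sort by read asc, interval desc so equal read positions cannot co-chain
    order = sorted(matches, key=lambda m: (m[0], -m[1]))
    tails: list[int] = []  # smallest chain-tail interval coordinate per length
    tail_idx: list[int] = []
    pred = [-1] * len(order)
    for m, (_, j) in enumerate(order):
        p = bisect.bisect_left(tails, j)
        if p == len(tails):
            tails.append(j)
            tail_idx.append(m)
        else:
            tails[p] = j
            tail_idx[p] = m
        pred[m] = tail_idx[p - 1] if p else -1
    chain: list[tuple[int, int]] = []
    at = tail_idx[-1]
    while at != -1:
        chain.append(order[at])
        at = pred[at]
    chain.reverse()
    return chain


def _lis_exact(matches: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Maximum chain with ties broken toward minimal total diagonal drift."""
    order = sorted(matches)
    n = len(order)
    best_len = [1] * n
    best_drift = [0] * n
    pred = [-1] * n
    for m in range(n):
        rm, jm = order[m]
        for k in range(m):
            rk, jk = order[k]
            if rk < rm and jk < jm:
                drift = best_drift[k] + abs((jm - rm) - (jk - rk))
                cand = (best_len[k] + 1, -drift)
                if cand > (best_len[m], -best_drift[m]):
                    best_len[m] = best_len[k] + 1
                    best_drift[m] = drift
                    pred[m] = k
    at = max(range(n), key=lambda m: (best_len[m], -best_drift[m], -m))
    chain: list[tuple[int, int]] = []
    while at != -1:
        chain.append(order[at])
        at = pred[at]
    chain.reverse()
    return chain


def sdp_refine(read_seq: str, interval_seq: str, cfg: MapperConfig) -> SdpChain:
    """Sparse dynamic programming chain of k_sdp-mer exact matches.

    Enumerates all exact k_sdp-length matches between read and interval and
    returns a maximum-cardinality subset strictly increasing in both
    coordinates.  Among equal-cardinality chains the one with the smallest
    total diagonal drift is preferred (exactly for modest match sets, by
    patience chaining beyond that).  An empty chain signals the caller to
    demote the candidate.
    """
    k = cfg.k_sdp
    if len(interval_seq) < k:
        raise ValueError("interval shorter than k_sdp")
    matches = _kmer_matches(read_seq, interval_seq, k)
    if not matches:
        return SdpChain(matches=[], k=k)
    if len(matches) <= _EXACT_TIEBREAK_LIMIT:
        chain = _lis_exact(matches)
    else:
        chain = _lis_patience(matches)
    return SdpChain(matches=chain, k=k)
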