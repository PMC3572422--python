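"""Anchor similarity: repeat structure as seen by an anchor-based mapper.

Percent identity is a poor predictor of whether two sequences confound
anchor-based seeding; what matters is how many long exact matches they share,
in a layout compatible with an indel-dominated error process.  The
*anchor similarity* S of two sequences is the maximum number of fixed-length
(K), non-overlapping, ordered shared anchors such that every consecutive pair
of chained anchors at starts (a, b) in one sequence and (a', b') in the other
keeps its gap ratio within the indel rate: 1 - delta <= (b-a)/(b'-a') <=
1 + delta.  Two sequences with anchor similarity S are called S-similar.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SimilarityParams", "anchor_similarity", "shared_kmer_matches"]


@dataclass(frozen=True)
class SimilarityParams:
    """Fixed anchor length ``K`` and indel rate ``delta`` bounding the
    ratio of gap lengths between consecutive chained anchors."""

    K: int
    delta: float

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0.0 <= self.delta < 1.0:
            raise ValueError("delta must lie in [0, 1)")


def shared_kmer_matches(seq1: str, seq2: str, K: int) -> list[tuple[int, int]]:
    """All (pos1, pos2) pairs where seq1 and seq2 share an exact K-mer."""
    index: dict[str, list[int]] = {}
    for j in range(len(seq2) - K + 1):
        index.setdefault(seq2[j : j + K], []).append(j)
    matches = [
        (i, j)
        for i in range(len(seq1) - K + 1)
        for j in index.get(seq1[i : i + K], ())
    ]
    matches.sort()
    return matches


def anchor_similarity(seq1: str, seq2: str, params: SimilarityParams) -> int:
    """Anchor similarity S of two sequences.

    Chaining dynamic programming over the shared K-mer match set: a match may
    follow another if both coordinates advance by at least K (ordered,
    non-overlapping) and the gap ratio satisfies the delta bound.  Returns the
    length of the longest admissible chain (0 when no K-mer is shared).
    """
    K, delta = params.K, params.delta
    if len(seq1) < K or len(seq2) < K:
        raise ValueError("both sequences must be at least K long")
    matches = shared_kmer_matches(seq1, seq2, K)
    if not matches:
        return 0
    # gaps are >= K > 0, so the ratio is always well-defined
    lo, hi = 1.0 - delta, 1.0 + delta
    best = [1] * len(matches)
    for m, (b, b2) in enumerate(matches):
        for k in range(m):
            a, a2 = matches[k]
            if a + K <= b and a2 + K <= b2 and lo <= (b - a) / (b2 - a2) <= hi:
                if best[k] + 1 > best[m]:
                    best[m] = best[k] + 1
    return max(best)
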