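"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive each contract from first principles
(naive sorting, exhaustive enumeration, full-matrix dynamic programming) and
never call into the implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from smsmap.config import MapperConfig
from smsmap.seq_io import SeqRecord

_BASES = "ACGT"


@pytest.fixture
def cfg() -> MapperConfig:
    return MapperConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20120919)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


# ---------------------------------------------------------------------------
# independent oracles


def naive_suffix_array(text: bytes) -> list[int]:
    return sorted(range(len(text)), key=lambda i: text[i:])


def naive_count_lcp(q: str, text: str) -> tuple[int, int, list[int]]:
    """Longest prefix of q occurring in text, by scanning all substrings."""
    for l in range(len(q), 0, -1):
        prefix = q[:l]
        hits = [
            i for i in range(len(text) - l + 1) if text[i : i + l] == prefix
        ]
        if hits:
            return len(hits), l, hits
    return 0, 0, []


def full_dp_cost(read: SeqRecord, interval: str, cfg: MapperConfig) -> float:
    """Unbanded minimum alignment cost, read-global / interval-free ends.

    An independent re-derivation of the scoring recurrence over the full
    matrix (no band, no vectorization): diagonal costs 0 on match, the
    substitution QV when the alternative call equals the genome base, else
    the mismatch prior; vertical costs the insertion QV; horizontal costs
    the deletion QV when the deletion alternative call equals the deleted
    genome base, else the deletion prior.
    """
    R, L = len(read.seq), len(interval)
    qv = read.qv
    INF = float("inf")
    prev_row = [0.0] * (L + 1)
    for i in range(1, R + 1):
        ri = read.seq[i - 1]
        if qv is None:
            ins_c = float(cfg.flat_insertion)
        else:
            ins_c = float(qv.ins[i - 1])
        row = [prev_row[0] + ins_c] + [INF] * L
        for j in range(1, L + 1):
            gj = interval[j - 1]
            if qv is None:
                diag_c = 0.0 if ri == gj else float(cfg.flat_mismatch)
                del_c = float(cfg.flat_deletion)
            else:
                if ri == gj:
                    diag_c = 0.0
                elif qv.sub_alt[i - 1] == gj:
                    diag_c = float(qv.sub[i - 1])
                else:
                    diag_c = float(cfg.mismatch_prior)
                if qv.del_alt[i - 1] == gj:
                    del_c = float(qv.del_[i - 1])
                else:
                    del_c = float(cfg.deletion_prior)
            row[j] = min(
                prev_row[j - 1] + diag_c,
                prev_row[j] + ins_c,
                row[j - 1] + del_c,
            )
        prev_row = row
    return min(prev_row)


def brute_force_best_chain(anchors) -> int:
    """Maximum total anchor bases over all valid colinear chains, by trying
    every subset (anchors must not overlap in read or genome)."""
    import itertools

    best = 0
    for r in range(1, len(anchors) + 1):
        for combo in itertools.combinations(anchors, r):
            chain = sorted(combo, key=lambda a: (a.read_pos, a.genome_pos))
            ok = all(
                chain[k].read_pos + chain[k].length <= chain[k + 1].read_pos
                and chain[k].genome_pos + chain[k].length <= chain[k + 1].genome_pos
                for k in range(len(chain) - 1)
            )
            if ok:
                best = max(best, sum(a.length for a in chain))
    return best


def quadratic_lis(matches: list[tuple[int, int]]) -> int:
    """Length of the longest chain strictly increasing in both coordinates,
    O(n^2)."""
    if not matches:
        return 0
    pts = sorted(matches)
    best = [1] * len(pts)
    for m in range(len(pts)):
        for k in range(m):
            if pts[k][0] < pts[m][0] and pts[k][1] < pts[m][1]:
                best[m] = max(best[m], best[k] + 1)
    return max(best)


def brute_force_similarity(matches: list[tuple[int, int]], K: int, delta: float) -> int:
    """Longest admissible anchor chain by depth-first search over all
    chains (for small match sets)."""
    best = 0

    def extend(last: tuple[int, int] | None, remaining: list[tuple[int, int]], depth: int) -> None:
        nonlocal best
        best = max(best, depth)
        for t, m in enumerate(remaining):
            if last is not None:
                b, b2 = m
                a, a2 = last
                if not (a + K <= b and a2 + K <= b2):
                    continue
                ratio = (b - a) / (b2 - a2)
                if not (1 - delta <= ratio <= 1 + delta):
                    continue
            extend(m, remaining[t + 1 :], depth + 1)

    extend(None, sorted(matches), 0)
    return best
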