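"""Suffix-array index over a (multi-)FASTA genome with count/locate/LCP
queries.

The genome's records are concatenated with a ``#`` separator byte that
matches no nucleotide, so no query match ever spans two records.  The suffix
array is built by numpy prefix doubling (O(n log^2 n)); only the query
contract matters downstream, not the construction algorithm.

The central query is :func:`count_lcp`: for a query ``q`` it reports the
length ``l`` of the longest prefix of ``q`` occurring anywhere in the text,
the number ``c`` of its occurrences, and (unless ``c`` exceeds a caller
cap) the occurrence positions.  The search walks the suffix array in
64-byte windows so that long queries never force long comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .seq_io import SeqRecord

__all__ = ["ReferenceIndex", "build_index", "count_lcp", "count_occurrences"]

_SEP = b"#"
_CACHE_VERSION = 1


@dataclass
class ReferenceIndex:
    """Concatenated genome text plus its suffix array and record layout."""

    text: bytes
    sa: np.ndarray
    names: list[str]
    starts: np.ndarray  # start offset of each record in text
    lengths: np.ndarray

    @property
    def size(self) -> int:
        return len(self.text)

    def record_at(self, pos: int) -> tuple[int, int]:
        """Map a global text position to (record index, local offset)."""
        i = int(np.searchsorted(self.starts, pos, side="right")) - 1
        local = pos - int(self.starts[i])
        if local >= int(self.lengths[i]):
            raise ValueError(f"position {pos} falls on a record separator")
        return i, local

    def record_bounds(self, pos: int) -> tuple[int, int]:
        """Global [start, end) of the record containing ``pos``."""
        i, _ = self.record_at(pos)
        s = int(self.starts[i])
        return s, s + int(self.lengths[i])


def _suffix_array(data: np.ndarray) -> np.ndarray:
    """Prefix-doubling suffix array of a uint8 sequence."""
    n = data.size
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = data.astype(np.int64)
    k = 1
    while True:
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        order = np.lexsort((second, rank))
        r_o, s_o = rank[order], second[order]
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        np.cumsum((r_o[1:] != r_o[:-1]) | (s_o[1:] != s_o[:-1]), out=changed[1:])
        rank = np.empty(n, dtype=np.int64)
        rank[order] = changed
        if changed[-1] == n - 1:
            return order
        k *= 2


def build_index(genome: Sequence[SeqRecord], cache: Optional[str] = None) -> ReferenceIndex:
    """Build (or load from ``cache``) the suffix-array index of a genome.

    Construction is deterministic.  A stale or unreadable cache is silently
    ignored and rebuilt.
    """
    if not genome or sum(len(r.seq) for r in genome) < 1:
        raise ValueError("cannot index an empty genome")
    text = _SEP.join(r.seq.upper().encode("ascii") for r in genome)
    names = [r.id for r in genome]
    lengths = np.array([len(r.seq) for r in genome], dtype=np.int64)
    starts = np.concatenate(([0], np.cumsum(lengths[:-1] + 1)))
    if cache is not None:
        idx = _load_cache(cache, text)
        if idx is not None:
            return ReferenceIndex(text, idx, names, starts, lengths)
    sa = _suffix_array(np.frombuffer(text, dtype=np.uint8))
    if cache is not None:
        np.savez(cache, version=_CACHE_VERSION, text_len=len(text), sa=sa)
    return ReferenceIndex(text, sa, names, starts, lengths)


def _load_cache(cache: str, text: bytes) -> Optional[np.ndarray]:
    try:
        with np.load(cache) as blob:
            if int(blob["version"]) != _CACHE_VERSION or int(blob["text_len"]) != len(text):
                return None
            return blob["sa"]
    except (OSError, KeyError, ValueError):
        return None


def _window(text: bytes, pos: int, off: int, width: int) -> bytes:
    start = pos + off
    return text[start : start + width]


def _bisect(text: bytes, sa: np.ndarray, lo: int, hi: int, off: int, seg: bytes, strict: bool) -> int:
    """Leftmost index in [lo, hi) whose suffix window at ``off`` compares
    ``> seg`` (strict) or ``>= seg``."""
    w = len(seg)
    while lo < hi:
        mid = (lo + hi) // 2
        win = _window(text, int(sa[mid]), off, w)
        if (win <= seg) if strict else (win < seg):
            lo = mid + 1
        else:
            hi = mid
    return lo


def _common_prefix(a: bytes, b: bytes) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def count_lcp(
    q: str | bytes,
    idx: ReferenceIndex,
    max_hits: Optional[int] = None,
) -> tuple[int, int, np.ndarray]:
    """Count and locate the longest common prefix of ``q`` with the text.

    Returns ``(c, l, hits)``: ``l`` is the length of the longest prefix of
    ``q`` occurring in the text, ``c`` its occurrence count, and ``hits`` the
    sorted global start positions — empty (withheld) when ``max_hits`` is
    given and ``c`` exceeds it.  A query whose first character is absent
    yields ``(0, 0, [])``.
    """
    qb = q.encode("ascii") if isinstance(q, str) else q
    if not qb:
        raise ValueError("query must be nonempty")
    text, sa = idx.text, idx.sa
    lo, hi = 0, len(sa)
    off = 0
    while off < len(qb):
        seg = qb[off : off + 64]
        left = _bisect(text, sa, lo, hi, off, seg, strict=False)
        right = _bisect(text, sa, left, hi, off, seg, strict=True)
        if left < right:
            lo, hi = left, right
            off += len(seg)
            continue
        # seg matched nowhere in full; find the longest partial match
        best = 0
        for cand in (left - 1, left):
            if lo <= cand < hi:
                win = _window(text, int(sa[cand]), off, len(seg))
                best = max(best, _common_prefix(win, seg))
        if best == 0:
            break
        part = seg[:best]
        lo = _bisect(text, sa, lo, hi, off, part, strict=False)
        hi = _bisect(text, sa, lo, hi, off, part, strict=True)
        off += best
        break
    l = off
    if l == 0:
        return 0, 0, np.empty(0, dtype=np.int64)
    c = hi - lo
    if max_hits is not None and c > max_hits:
        return c, l, np.empty(0, dtype=np.int64)
    hits = np.sort(sa[lo:hi].astype(np.int64))
    return c, l, hits


def count_occurrences(q: str | bytes, idx: ReferenceIndex) -> int:
    """Number of exact full occurrences of ``q`` in the text."""
    qb = q.encode("ascii") if isinstance(q, str) else q
    c, l, _ = count_lcp(qb, idx, max_hits=0)
    return c if l == len(qb) else 0
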