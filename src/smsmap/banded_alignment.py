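"""Quality-aware banded alignment guided by the SDP chain.

The final base-level alignment minimizes a phred-scaled cost over a dynamic
programming matrix restricted to a band that follows the SDP chain's
diagonals.  Moves into cell (i, j) cost:

* diagonal (consume read base r_i and genome base g_j): 0 on match; the
  substitution quality S_i when the alternative call explains g_j; otherwise
  the global MISMATCHPRIOR;
* vertical (read insertion): the insertion quality I_i;
* horizontal (genome deletion): the deletion quality D_i when the deletion
  alternative call matches the deleted genome base g_j; otherwise
  DELETIONPRIOR.

Reads without quality tracks fall back to flat penalties.  The alignment is
global in the read and free at both interval ends (the interval already
carries (1+delta) flanks).  All costs are small integers, so the float
arithmetic is exact and traceback can re-derive moves by equality, preferring
diagonal, then deletion, then insertion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import MapperConfig
from .refinement import SdpChain
from .seq_io import QualityArrays, SeqRecord

__all__ = ["GuideBand", "AlignmentResult", "BandError", "build_guide_band", "banded_align", "path_cost"]

_INF = np.inf


class BandError(RuntimeError):
    """The band excludes every complete alignment path."""


@dataclass
class GuideBand:
    """Admissible column range [lo_i, hi_i] for each DP row i = 0..R."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=np.int64)
        self.hi = np.asarray(self.hi, dtype=np.int64)
        if np.any(self.hi < self.lo):
            raise ValueError("empty band row")
        if np.any(np.diff(self.lo) < 0) or np.any(np.diff(self.hi) < 0):
            raise ValueError("band endpoints must be non-decreasing")
        if np.any(self.lo[1:] > self.hi[:-1] + 1):
            raise ValueError("consecutive band rows must overlap or be adjacent")


@dataclass
class AlignmentResult:
    """A base-level alignment of a read to a reference interval.

    Coordinates are 0-based half-open.  ``ref_start``/``ref_end`` are local
    to the named reference sequence once the pipeline fills them in; the
    aligner itself reports interval-local coordinates.  ``cigar`` is a list
    of (op, length) with ops M/I/D in read order (already reference-forward
    for minus-strand alignments, whose ``read_seq`` is the
    reverse-complemented read).
    """

    read_id: str
    read_seq: str
    mapped: bool
    ref_id: Optional[str] = None
    strand: str = "+"
    ref_start: int = 0
    ref_end: int = 0
    cigar: list = field(default_factory=list)
    cost: float = _INF
    n_match: int = 0
    n_mismatch: int = 0
    n_ins: int = 0
    n_del: int = 0
    mapq: Optional[int] = None

    @classmethod
    def unmapped(cls, read: SeqRecord) -> "AlignmentResult":
        return cls(read_id=read.id, read_seq=read.seq, mapped=False)

    @property
    def n_columns(self) -> int:
        return self.n_match + self.n_mismatch + self.n_ins + self.n_del

    @property
    def accuracy(self) -> float:
        cols = self.n_columns
        return self.n_match / cols if cols else 0.0


def build_guide_band(chain: SdpChain, R: int, l_C: int, cfg: MapperConfig) -> GuideBand:
    """Band following the SDP chain: half-width ``b_sdp`` on anchor
    diagonals, widened by the inter-anchor diagonal drift between chain
    matches, extending the nearest diagonal before the first and after the
    last match.  An empty chain yields the full matrix."""
    b = cfg.b_sdp
    lo = np.empty(R + 1, dtype=np.int64)
    hi = np.empty(R + 1, dtype=np.int64)
    if not chain.matches:
        lo[:] = 0
        hi[:] = l_C
        return GuideBand(lo=lo, hi=hi)
    # rows i consume read base i-1; a match at (r, j) spans rows r+1..r+k
    segments = []  # (row_start, row_end inclusive, diag, half_width)
    first_r, first_j = chain.matches[0]
    d_prev = first_j - first_r
    end_prev = 0
    segments.append((0, first_r, d_prev, b))
    for r, j in chain.matches:
        d = j - r
        start = r + 1
        if start > end_prev + 1:
            drift = abs(d - d_prev) + b
            segments.append((end_prev + 1, start - 1, d_prev, drift))
        segments.append((start, r + chain.k, d, b))
        d_prev = d
        end_prev = r + chain.k
    if end_prev < R:
        segments.append((end_prev + 1, R, d_prev, b))
    for start, end, diag, width in segments:
        start = max(start, 0)
        end = min(end, R)
        if start > end:
            continue
        rows = np.arange(start, end + 1)
        lo[rows] = rows + diag - width
        hi[rows] = rows + diag + width
    # minimal widening to restore monotone, overlapping rows
    lo = np.minimum.accumulate(lo[::-1])[::-1]
    hi = np.maximum.accumulate(hi)
    for i in range(1, R + 1):
        if lo[i] > hi[i - 1] + 1:
            lo[i] = hi[i - 1] + 1
    np.clip(lo, 0, l_C, out=lo)
    np.clip(hi, 0, l_C, out=hi)
    return GuideBand(lo=lo, hi=hi)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def banded_align(
    read: SeqRecord,
    interval_seq: str,
    band: GuideBand,
    cfg: MapperConfig,
) -> AlignmentResult:
    """Minimum-cost alignment of the whole read to (part of) the interval.

    Raises :class:`BandError` when the band admits no complete path; the
    caller is expected to retry once with a full band, then demote the
    candidate.  The returned coordinates are interval-local.
    """
    R = len(read.seq)
    l_C = len(interval_seq)
    if len(band.lo) != R + 1:
        raise ValueError("band does not match read length")
    r_enc = _encode(read.seq)
    g_enc = _encode(interval_seq)
    qv = read.qv
    if qv is not None:
        ins_q = qv.ins.astype(np.float64)
        sub_q = qv.sub.astype(np.float64)
        del_q = qv.del_.astype(np.float64)
        sub_alt = _encode(qv.sub_alt)
        del_alt = _encode(qv.del_alt)
    lo, hi = band.lo, band.hi

    S = np.full((R + 1, l_C + 1), _INF)
    S[0, lo[0] : hi[0] + 1] = 0.0
    for i in range(1, R + 1):
        l, h = int(lo[i]), int(hi[i])
        width = h - l + 1
        prev = S[i - 1]
        ri = r_enc[i - 1]
        if qv is not None:
            ins_cost = ins_q[i - 1]
        else:
            ins_cost = float(cfg.flat_insertion)
        # vertical candidates
        row = prev[l : h + 1] + ins_cost
        # diagonal candidates (j >= 1 consumes g_{j})
        js = max(l, 1)
        if js <= h:
            g_seg = g_enc[js - 1 : h]  # genome bases consumed at j = js..h
            if qv is not None:
                diag_cost = np.where(
                    g_seg == ri,
                    0.0,
                    np.where(g_seg == sub_alt[i - 1], sub_q[i - 1], float(cfg.mismatch_prior)),
                )
            else:
                diag_cost = np.where(g_seg == ri, 0.0, float(cfg.flat_mismatch))
            off = js - l
            np.minimum(row[off:], prev[js - 1 : h] + diag_cost, out=row[off:])
        # horizontal moves (deletion chains within the row)
        if width > 1:
            del_cost = _deletion_costs(i, l + 1, h, g_enc, qv, cfg,
                                       del_q if qv is not None else None,
                                       del_alt if qv is not None else None)
            cum = np.concatenate(([0.0], np.cumsum(del_cost)))
            running = np.minimum.accumulate(row - cum)
            row = running + cum
        S[i, l : h + 1] = row

    last_l, last_h = int(lo[R]), int(hi[R])
    final = S[R, last_l : last_h + 1]
    j_best = int(np.argmin(final)) + last_l
    cost = float(S[R, j_best])
    if not np.isfinite(cost):
        raise BandError("band excludes every complete alignment path")
    return _traceback(S, j_best, read, _Scorer(read, interval_seq, cfg), band)


def _deletion_costs(i, j_from, j_to, g_enc, qv, cfg, del_q, del_alt):
    """Cost of a deletion move into each j in [j_from, j_to].

    The deletion quality D_i applies when the read's deletion alternative
    call matches the consumed genome base g_j; otherwise the DELETIONPRIOR.
    """
    if qv is None:
        return np.full(j_to - j_from + 1, float(cfg.flat_deletion))
    consumed = g_enc[j_from - 1 : j_to]  # base deleted by the move into j
    return np.where(
        consumed == del_alt[i - 1], del_q[i - 1], float(cfg.deletion_prior)
    ).astype(np.float64)


class _Scorer:
    """Per-cell move costs with encodings precomputed once."""

    def __init__(self, read: SeqRecord, interval_seq: str, cfg: MapperConfig):
        self.r_enc = _encode(read.seq)
        self.g_enc = _encode(interval_seq)
        self.cfg = cfg
        qv = read.qv
        self.qv = qv
        if qv is not None:
            self.sub_alt = _encode(qv.sub_alt)
            self.del_alt = _encode(qv.del_alt)

    def move_costs(self, i: int, j: int) -> tuple[float, float, float]:
        """(diag, del, ins) costs for moves into cell (i, j)."""
        cfg = self.cfg
        ri = self.r_enc[i - 1]
        gj = self.g_enc[j - 1] if j >= 1 else None
        if self.qv is None:
            diag = 0.0 if gj == ri else float(cfg.flat_mismatch)
            return diag, float(cfg.flat_deletion), float(cfg.flat_insertion)
        qv = self.qv
        if gj == ri:
            diag = 0.0
        elif gj is not None and gj == self.sub_alt[i - 1]:
            diag = float(qv.sub[i - 1])
        else:
            diag = float(cfg.mismatch_prior)
        if gj is not None and gj == self.del_alt[i - 1]:
            dele = float(qv.del_[i - 1])
        else:
            dele = float(cfg.deletion_prior)
        return diag, dele, float(qv.ins[i - 1])


def _traceback(S, j_end, read, scorer: "_Scorer", band) -> AlignmentResult:
    ops: list[str] = []
    i, j = len(read.seq), j_end
    n_match = n_mismatch = n_ins = n_del = 0
    r_enc, g_enc = scorer.r_enc, scorer.g_enc
    lo, hi = band.lo, band.hi
    while i > 0:
        diag, dele, ins = scorer.move_costs(i, j)
        here = S[i, j]
        if j >= 1 and lo[i - 1] <= j - 1 <= hi[i - 1] and here == S[i - 1, j - 1] + diag:
            ops.append("M")
            if r_enc[i - 1] == g_enc[j - 1]:
                n_match += 1
            else:
                n_mismatch += 1
            i -= 1
            j -= 1
        elif j >= 1 and lo[i] <= j - 1 and here == S[i, j - 1] + dele:
            ops.append("D")
            n_del += 1
            j -= 1
        elif lo[i - 1] <= j <= hi[i - 1] and here == S[i - 1, j] + ins:
            ops.append("I")
            n_ins += 1
            i -= 1
        else:  # pragma: no cover - would indicate an internal inconsistency
            raise BandError("traceback failed inside the band")
    ops.reverse()
    cigar: list[tuple[str, int]] = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return AlignmentResult(
        read_id=read.id,
        read_seq=read.seq,
        mapped=True,
        ref_start=j,
        ref_end=j_end,
        cigar=cigar,
        cost=float(S[len(read.seq), j_end]),
        n_match=n_match,
        n_mismatch=n_mismatch,
        n_ins=n_ins,
        n_del=n_del,
    )


def path_cost(result: AlignmentResult, read: SeqRecord, interval_seq: str, cfg: MapperConfig) -> float:
    """Recompute the cost of an alignment path from its CIGAR (invariant
    check: must equal ``result.cost``)."""
    scorer = _Scorer(read, interval_seq, cfg)
    i, j = 0, result.ref_start
    total = 0.0
    for op, length in result.cigar:
        for _ in range(length):
            if op == "M":
                i += 1
                j += 1
                total += scorer.move_costs(i, j)[0]
            elif op == "D":
                j += 1
                total += scorer.move_costs(i, j)[1]
            else:
                i += 1
                total += scorer.move_costs(i, j)[2]
    return total
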