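"""Mapping quality: posterior probability that the reported interval is
correct, with significance-based scaling.

The posterior over the mapped position m is
``Pr(m | r, g) = Pr(r | g_m..) Pr(m) / sum_i Pr(r | g_i..) Pr(i)`` with a
uniform prior on positions; ``Pr(r | g interval)`` is approximated by the
phred-scaled Viterbi cost of the banded alignment, ``10^(-cost/10)``.  The
denominator sums only the top ``max_candidates`` alignments.  Because a read
from a deep repeat family may have more plausible locations than were ever
aligned, the denominator is scaled by ``nu = n_sig / max_candidates``
whenever the number of *significant* clusters exceeds ``max_candidates``.

A cluster is significant when its anchor-bases total exceeds ``mu - 2 sigma``
of the anchor-bases distribution expected at the read's true location — a
genome-independent quantity depending only on read length, accuracy and the
minimum anchor length, precomputed per bin (exact mean; seeded Monte Carlo
variance).  The accuracy of the best alignment serves as a proxy for the
read's true accuracy.

The phred quality is ``Q = round(-10 log10(1 - posterior))`` capped at 254
(255 is reserved in SAM for "unavailable").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .clustering import AnchorCluster
from .config import MapperConfig

__all__ = [
    "MapQvResult",
    "AnchorBasesMoments",
    "anchor_bases_moments",
    "cluster_significance",
    "compute_mapqv",
    "exact_anchor_bases_mean",
]

logger = logging.getLogger(__name__)

MAX_QV = 254

ACCURACY_GRID = np.round(np.arange(0.60, 1.0001, 0.01), 2)
# quarter-octave log-spaced read-length bins, ~50..185k bases
LENGTH_GRID = np.unique(np.round(2 ** (np.arange(23, 71) / 4.0)).astype(int))


def _comb0(n: int, k: int) -> int:
    if k < 0 or n < 0 or n < k:
        return 0
    return math.comb(n, k)


def exact_anchor_bases_mean(L: int, M: int, K: int) -> float:
    """Exact expected total anchor bases for a read of length L with M
    errors and minimum anchor length K.

    A part of size v > K contributes v - 1 error-free bases; summing the
    marginal distribution of a single part over all M + 1 parts gives
    ``(M+1) sum_{v>K} (v-1) C(L-v, M-1) / C(L, M)``.
    """
    if M == 0:
        return float(L) if L >= K else 0.0
    if M >= L:
        return 0.0
    total = math.comb(L, M)
    num = sum((v - 1) * _comb0(L - v, M - 1) for v in range(K + 1, L + 2))
    return (M + 1) * num / total


def _mc_anchor_bases_var(L: int, M: int, K: int, seed: int, n_draws: int) -> float:
    """Monte Carlo variance of total anchor bases over uniform error
    placements (equivalently uniform compositions of L+1 into M+1 parts)."""
    rng = np.random.default_rng(seed)
    totals = np.empty(n_draws)
    for t in range(n_draws):
        errors = rng.choice(L, size=M, replace=False)
        errors.sort()
        parts = np.diff(np.concatenate(([0], errors + 1, [L + 1])))
        runs = parts - 1
        totals[t] = runs[runs >= K].sum()
    return float(totals.var())


@dataclass
class AnchorBasesMoments:
    """Lazy per-bin table of anchor-bases mean and standard deviation.

    Keys are (length bin, accuracy bin, K); bins are filled on first use with
    a seed derived deterministically from the key, so results do not depend
    on query order.
    """

    seed: int = 0
    n_draws: int = 10_000
    table: dict = field(default_factory=dict)

    def get(self, L: int, accuracy: float, K: int) -> tuple[float, float]:
        L_bin = self._bin_length(L)
        acc_bin = self._bin_accuracy(accuracy)
        key = (L_bin, acc_bin, K)
        if key not in self.table:
            M = int(round((1.0 - acc_bin) * L_bin))
            if M >= L_bin:
                self.table[key] = (0.0, 0.0)
            else:
                mu = exact_anchor_bases_mean(L_bin, M, K)
                sub_seed = (self.seed * 1_000_003 + hash(key)) % (2**31)
                var = (
                    _mc_anchor_bases_var(L_bin, M, K, sub_seed, self.n_draws)
                    if M > 0
                    else 0.0
                )
                self.table[key] = (mu, math.sqrt(var))
        return self.table[key]

    @staticmethod
    def _bin_length(L: int) -> int:
        grid = LENGTH_GRID
        if L <= grid[0] or L >= grid[-1]:
            if not grid[0] <= L <= grid[-1]:
                logger.warning("read length %d outside moment grid; clamped", L)
            return int(np.clip(L, grid[0], grid[-1]))
        return int(grid[np.argmin(np.abs(np.log(grid) - np.log(L)))])

    @staticmethod
    def _bin_accuracy(accuracy: float) -> float:
        grid = ACCURACY_GRID
        if not grid[0] <= accuracy <= grid[-1]:
            logger.warning("accuracy %.3f outside moment grid; clamped", accuracy)
        return float(grid[np.argmin(np.abs(grid - accuracy))])


def anchor_bases_moments(
    lengths: Sequence[int],
    K: int,
    seed: int = 0,
    accuracies: Sequence[float] = tuple(ACCURACY_GRID),
    n_draws: int = 10_000,
) -> AnchorBasesMoments:
    """Precompute the anchor-bases moment table over a (length, accuracy)
    grid for one minimum anchor length."""
    table = AnchorBasesMoments(seed=seed, n_draws=n_draws)
    for L in lengths:
        for acc in accuracies:
            table.get(int(L), float(acc), K)
    return table


def cluster_significance(
    clusters: Sequence[AnchorCluster],
    read_length: int,
    accuracy: float,
    K: int,
    table: AnchorBasesMoments,
) -> int:
    """Number of clusters whose anchor-bases total exceeds mu - 2 sigma.

    ``clusters`` must be the full pre-truncation cluster list; ``accuracy``
    is the best alignment's matches per alignment column.
    """
    mu, sigma = table.get(read_length, accuracy, K)
    threshold = mu - 2.0 * sigma
    return sum(1 for c in clusters if c.anchor_bases > threshold)


@dataclass
class MapQvResult:
    posterior: float
    Q: int
    n_sig: int
    nu: float


def compute_mapqv(costs: Sequence[float], n_sig: int, cfg: MapperConfig) -> MapQvResult:
    """Mapping quality of the best of several candidate alignment costs.

    ``costs`` are phred-scaled alignment costs (lower is better); only the
    top ``max_candidates`` enter the denominator.  ``nu`` scales the
    denominator when more significant clusters exist than candidates were
    aligned; with ``n_sig <= max_candidates`` (including the degenerate 0)
    it stays 1.
    """
    finite = sorted(c for c in costs if math.isfinite(c))
    if not finite:
        raise ValueError("mapping quality requires at least one finite cost")
    top = finite[: cfg.max_candidates]
    best = top[0]
    denom = sum(10.0 ** (-(c - best) / 10.0) for c in top)
    nu = n_sig / cfg.max_candidates if n_sig > cfg.max_candidates else 1.0
    posterior = 1.0 / (denom * nu)
    miss = 1.0 - posterior
    if miss <= 0.0:
        q = MAX_QV
    else:
        q = min(MAX_QV, int(round(-10.0 * math.log10(miss))))
    return MapQvResult(posterior=posterior, Q=q, n_sig=n_sig, nu=nu)
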