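"""Combinatorics of alignment anchors in error-corrupted reads.

A read of length ``L`` sequenced with ``M`` single-base errors is split by the
error positions into ``M + 1`` parts; the part sizes form a strict composition
of ``L + 1`` into ``M + 1`` positive integers.  Parts larger than ``K`` are
*anchors*: maximal error-free words of length >= K usable to seed an
alignment.  This module computes, exactly and asymptotically, the distribution
of the number of anchors ``N``:

* ``compositions_poly`` / ``compositions_closed`` -- the exact count
  ``c_{M,N,K}(L)`` of error arrangements yielding exactly ``N`` anchors, by
  truncated generating-function polynomial arithmetic and by an alternating
  closed-form sum (the latter with big-integer term diagnostics, since its
  terms vastly exceed the result in magnitude).
* ``num_configurations`` -- the survival count of arrangements with at least
  ``N`` anchors, and the corresponding probability.
* ``composition_moments`` -- exact mean and variance of ``N`` under the
  uniform distribution on compositions.
* ``normal_approx`` -- the central-limit normal approximation to the pmf and
  survival function of ``N``.
* ``waiting_length`` -- under the geometric run model (error-free word length
  ``W`` with ``Pr{W >= K} = (1-rho)^K``), the number of words / bases one must
  sequence before an anchor of length >= K appears with probability
  ``1 - epsilon``.
* ``enumerate_oracle`` -- brute-force enumeration of every error placement,
  for validation at small sizes.

All exact routines use unbounded Python integers (and exact rationals for the
moments); floating point enters only in the avowedly approximate operations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction

from scipy.stats import norm

__all__ = [
    "RunModelParams",
    "CompositionQuery",
    "AnchorCountTable",
    "AnchorMoments",
    "ClosedFormResult",
    "waiting_length",
    "compositions_poly",
    "compositions_closed",
    "num_configurations",
    "composition_moments",
    "normal_approx",
    "enumerate_oracle",
    "anchors_first_compositions",
    "anchor_count_table",
    "mean_run_length",
    "run_length_sf",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class RunModelParams:
    """Geometric run model parameters: per-base error rate ``rho``, minimum
    anchor length ``K`` and admissible failure probability ``epsilon``."""

    rho: float
    K: int
    epsilon: float

    def __post_init__(self) -> None:
        if not 0.0 < self.rho < 1.0:
            raise ValueError(f"rho must lie in (0, 1), got {self.rho}")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError(f"epsilon must lie in (0, 1), got {self.epsilon}")
        if self.K < 1:
            raise ValueError(f"K must be a positive integer, got {self.K}")


@dataclass(frozen=True)
class CompositionQuery:
    """Parameters (M errors, N anchors, threshold K, read length L) of a
    composition count, with the derived quantities D and imax recomputed on
    access rather than stored."""

    M: int
    N: int
    K: int
    L: int

    def __post_init__(self) -> None:
        if self.L < 1 or self.M < 0 or self.N < 0 or self.K < 0:
            raise ValueError(f"invalid composition query {self}")
        if self.M > self.L:
            raise ValueError(f"more errors than read positions: {self}")

    @property
    def D(self) -> int:
        return self.L - self.N * self.K - self.M

    @property
    def imax(self) -> int:
        return min(-(-self.D // self.K) if self.K else 0, self.M + 1 - self.N)


@dataclass
class ClosedFormResult:
    """Exact closed-form count plus diagnostics of the alternating sum.

    ``n_nonzero`` counts the terms C(M+1-N, i) * C(M+D-iK, M) that are
    nonzero; ``max_abs``/``min_abs`` are the extreme magnitudes among them
    (before the (-1)^i sign and the leading C(M+1, N) prefactor).
    """

    value: int
    n_nonzero: int
    max_abs: int
    min_abs: int

    @property
    def sum_abs(self) -> int:
        """Magnitude of the bare alternating sum (without C(M+1,N))."""
        return self._sum_abs

    _sum_abs: int = field(default=0, repr=False)


@dataclass
class AnchorCountTable:
    """Exact counts c_{M,N,K}(L) for N = 0..M+1 and their suffix sums."""

    M: int
    K: int
    L: int
    counts: list  # counts[N] = c_{M,N,K}(L)

    @property
    def total(self) -> int:
        return math.comb(self.L, self.M)

    def survival(self, N: int) -> int:
        """NumConfigurations(M, N, K, L) = sum of counts over N' >= N."""
        return sum(self.counts[max(N, 0) :])


@dataclass(frozen=True)
class AnchorMoments:
    """Exact mean and variance of the anchor count N (as rationals)."""

    mu: Fraction
    sigma2: Fraction


# ---------------------------------------------------------------------------
# geometric run model


def mean_run_length(rho: float) -> float:
    """Mean length of an error-free run at per-base error rate ``rho``."""
    if not 0.0 < rho <= 1.0:
        raise ValueError("rho must lie in (0, 1]")
    return 1.0 / rho - 1.0


def run_length_sf(length: int, accuracy: float) -> float:
    """Pr{W >= length} for an error-free word under geometric parameter
    ``accuracy`` = 1 - rho (probability a base is read correctly)."""
    if not 0.0 <= accuracy < 1.0:
        raise ValueError("accuracy must lie in [0, 1)")
    return accuracy**length


def waiting_length(params: RunModelParams) -> tuple[float, float]:
    """Words and expected bases to sequence before an error-free word of
    length >= K appears with probability 1 - epsilon.

    Returns ``(t, bases)`` where ``t = log(eps) / log(1 - (1-rho)^K)`` and
    ``bases = t * (1/rho - K (1-rho)^K / (1 - (1-rho)^K))``.
    """
    rho, K, eps = params.rho, params.K, params.epsilon
    p_anchor = (1.0 - rho) ** K
    t = math.log(eps) / math.log(1.0 - p_anchor)
    bases = t * (1.0 / rho - K * p_anchor / (1.0 - p_anchor))
    return t, bases


# ---------------------------------------------------------------------------
# exact counts


def _comb0(n: int, k: int) -> int:
    """Binomial coefficient extended with C(n, k) = 0 for n < k or n < 0."""
    if k < 0 or n < 0 or n < k:
        return 0
    return math.comb(n, k)


def _poly_mul_trunc(a: list[int], b: list[int], deg: int) -> list[int]:
    """Product of integer polynomials truncated to degree <= deg."""
    out = [0] * (min(len(a) + len(b) - 1, deg + 1))
    for i, ai in enumerate(a):
        if ai == 0 or i > deg:
            continue
        jmax = min(len(b), deg + 1 - i)
        for j in range(jmax):
            out[i + j] += ai * b[j]
    return out


def _poly_pow_trunc(p: list[int], n: int, deg: int) -> list[int]:
    result = [1]
    base = p[: deg + 1]
    while n:
        if n & 1:
            result = _poly_mul_trunc(result, base, deg)
        n >>= 1
        if n:
            base = _poly_mul_trunc(base, base, deg)
    return result


def compositions_poly(q: CompositionQuery) -> int:
    """c_{M,N,K}(L) by truncated polynomial multiplication.

    The count is the coefficient of t^(L+1) in
    C(M+1, N) * A(t)^N * S(t)^(M+1-N), with short-part generating function
    S(t) = t + t^2 + ... + t^K and anchor generating function
    A(t) = t^(K+1) + t^(K+2) + ...  (truncated at degree L+1).  Every
    intermediate value is a nonnegative integer bounded by the result's total,
    so no precision is ever lost.
    """
    M, N, K, L = q.M, q.N, q.K, q.L
    if N > M + 1:
        return 0
    deg = L + 1
    if K == 0:
        # no short parts exist: all M+1 parts are anchors
        return math.comb(L, M) if N == M + 1 else 0
    short = [0] + [1] * K  # t + ... + t^K
    anchor = [0] * (K + 1) + [1] * max(deg - K, 0)  # t^(K+1) + ... + t^deg
    poly = _poly_mul_trunc(
        _poly_pow_trunc(anchor, N, deg), _poly_pow_trunc(short, M + 1 - N, deg), deg
    )
    coeff = poly[deg] if len(poly) > deg else 0
    return math.comb(M + 1, N) * coeff


def compositions_closed(q: CompositionQuery) -> ClosedFormResult:
    """c_{M,N,K}(L) by the exact alternating closed-form sum.

    Evaluates C(M+1,N) * sum_{i=0}^{imax} (-1)^i C(M+1-N, i) C(M+D-iK, M)
    with D = L - NK - M, in exact integer arithmetic.  The diagnostics record
    how many of the unprefixed terms are nonzero and their extreme magnitudes:
    the terms can exceed the result by hundreds of bits, which is why this
    route demands big integers.
    """
    M, N, K, L = q.M, q.N, q.K, q.L
    if N > M + 1:
        return ClosedFormResult(0, 0, 0, 0)
    if K == 0:
        # every part is an anchor; the proof of the closed form gives C(L, M)
        # compositions, all with N = M + 1 anchors
        val = math.comb(L, M) if N == M + 1 else 0
        return ClosedFormResult(val, 1 if val else 0, val, val, _sum_abs=val)
    D = q.D
    imax = q.imax
    if D < 0 or imax < 0:
        return ClosedFormResult(0, 0, 0, 0)
    total = 0
    n_nonzero = 0
    max_abs = 0
    min_abs = 0
    for i in range(imax + 1):
        term = _comb0(M + 1 - N, i) * _comb0(M + D - i * K, M)
        if term:
            n_nonzero += 1
            max_abs = max(max_abs, term)
            min_abs = term if min_abs == 0 else min(min_abs, term)
        total += -term if i & 1 else term
    return ClosedFormResult(
        math.comb(M + 1, N) * total, n_nonzero, max_abs, min_abs, _sum_abs=abs(total)
    )


def num_configurations(M: int, N: int, K: int, L: int) -> tuple[int, Fraction]:
    """NumConfigurations(M,N,K,L): arrangements with at least N anchors.

    Returns the exact count (suffix sum of c_{M,N',K}(L) over N' >= N) and the
    probability count / C(L, M).
    """
    count = sum(
        compositions_closed(CompositionQuery(M, Np, K, L)).value
        for Np in range(max(N, 0), M + 2)
    )
    return count, Fraction(count, math.comb(L, M))


def anchor_count_table(M: int, K: int, L: int) -> AnchorCountTable:
    """Exact table of c_{M,N,K}(L) for all N, via the closed form."""
    counts = [
        compositions_closed(CompositionQuery(M, N, K, L)).value for N in range(M + 2)
    ]
    return AnchorCountTable(M=M, K=K, L=L, counts=counts)


def anchors_first_compositions(M: int, N: int, K: int, L: int) -> list[tuple[int, ...]]:
    """All compositions of L+1 into M+1 parts with the N anchors first.

    The first N parts exceed K and the remaining M+1-N parts are at most K;
    the returned list enumerates c'_{M,N,K}(L) explicitly (c = C(M+1,N) c').
    Intended for small parameters (tests, worked examples).
    """
    target = L + 1
    out: list[tuple[int, ...]] = []

    def extend(prefix: list[int], remaining: int) -> None:
        idx = len(prefix)
        if idx == M + 1:
            if remaining == 0:
                out.append(tuple(prefix))
            return
        lo, hi = (K + 1, remaining) if idx < N else (1, min(K, remaining))
        for part in range(lo, hi + 1):
            # keep enough room for the parts still to come
            rest = remaining - part
            parts_left = M - idx
            if rest < parts_left:
                continue
            extend(prefix + [part], rest)

    extend([], target)
    return out


# ---------------------------------------------------------------------------
# moments and asymptotics


def composition_moments(M: int, K: int, L: int) -> AnchorMoments:
    """Exact mean and variance of the anchor count N.

    Under the uniform distribution on compositions of L+1 into M+1 parts:
    mu = (M+1) C(L-K, M) / C(L, M) and
    sigma^2 = M(M+1) C(L-2K, M) / C(L, M) + mu - mu^2.
    """
    T = math.comb(L, M)
    if T == 0:
        raise ValueError(f"no compositions for M={M}, L={L}")
    if K == 0:
        return AnchorMoments(mu=Fraction(M + 1), sigma2=Fraction(0))
    mu = Fraction((M + 1) * _comb0(L - K, M), T)
    e_nn1 = Fraction(M * (M + 1) * _comb0(L - 2 * K, M), T)
    return AnchorMoments(mu=mu, sigma2=e_nn1 + mu - mu * mu)


def normal_approx(M: int, N: int, K: int, L: int) -> tuple[float, float]:
    """Normal approximation to (pmf, survival) of the anchor count at N.

    pmf ~ C(L,M) phi((N - mu)/sigma) / sigma and
    survival ~ C(L,M) (1 - Phi((N - 1/2 - mu)/sigma)), where the -1/2 is a
    continuity correction.  Both are returned as counts (on the same scale as
    the exact table); divide by C(L, M) for probabilities.
    """
    m = composition_moments(M, K, L)
    mu, s2 = float(m.mu), float(m.sigma2)
    total = float(math.comb(L, M))
    if s2 <= 0.0:
        # degenerate point mass at mu
        pmf = total if N == round(mu) else 0.0
        surv = total if N <= mu else 0.0
        return pmf, surv
    sigma = math.sqrt(s2)
    pmf = total * norm.pdf((N - mu) / sigma) / sigma
    surv = total * norm.sf((N - 0.5 - mu) / sigma)
    return pmf, surv


# ---------------------------------------------------------------------------
# exhaustive oracle


def enumerate_oracle(M: int, K: int, L: int, budget: int = 10**6) -> dict[int, int]:
    """Histogram of anchor counts by brute force over all error placements.

    Every one of the C(L, M) placements of M errors in L read positions is
    enumerated; the number of maximal error-free runs of length >= K is
    tallied.  Refuses instances beyond ``budget`` placements.
    """
    n_placements = math.comb(L, M)
    if n_placements > budget:
        raise ValueError(f"{n_placements} placements exceed budget {budget}")
    hist: dict[int, int] = {}
    for errors in itertools.combinations(range(1, L + 1), M):
        prev = 0
        n_anchors = 0
        for x in (*errors, L + 1):
            if x - prev - 1 >= K:  # run of correct bases between errors
                n_anchors += 1
            prev = x
        hist[n_anchors] = hist.get(n_anchors, 0) + 1
    return hist
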