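"""Parametric simulator of single-molecule sequencing reads.

Errors are modeled as an i.i.d. per-position process on a scan across the
template: each step errs with probability ``rho``; the error type is drawn
from a (substitution, insertion, deletion) mix defaulting to
(0.10, 0.62, 0.28), the indel-dominated profile characteristic of
single-molecule instruments.  An insertion emits a random base without
consuming template (so several may stack), a deletion consumes without
emitting, and a substitution emits a random different base.  Error-free run
lengths are therefore geometric with parameter 1 - rho, which is the
model's validation contract.

Each read carries quality tracks consistent with rho and the mix (constant
phred values; random alternative calls) plus its ground-truth template
interval for downstream mapping-accuracy scoring on the phred scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .banded_alignment import AlignmentResult
from .seq_io import QualityArrays, SeqRecord

__all__ = [
    "SimConfig",
    "SimRead",
    "random_genome",
    "simulate_reads",
    "mapability_phred",
    "write_simulated",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Read simulation parameters.

    rho:         per-base error probability in [0, 1).
    mix:         (substitution, insertion, deletion) fractions, summing to 1.
    read_length: template length drawn per read (constant).
    n_reads:     number of reads.
    seed:        RNG seed (all randomness derives from it).
    """

    rho: float
    n_reads: int
    read_length: int = 1000
    mix: tuple[float, float, float] = (0.10, 0.62, 0.28)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if abs(sum(self.mix) - 1.0) > 1e-9:
            raise ValueError("error-type mix must sum to 1")
        if self.n_reads < 1 or self.read_length < 1:
            raise ValueError("n_reads and read_length must be positive")


@dataclass
class SimRead:
    """A simulated read plus its ground-truth template interval and the
    error events that produced it."""

    record: SeqRecord
    ref_id: str
    strand: str
    start: int  # template interval on the forward genome, 0-based half-open
    end: int
    n_sub: int = 0
    n_ins: int = 0
    n_del: int = 0
    runs: Optional[list[int]] = None  # error-free run lengths, in order

    @property
    def n_errors(self) -> int:
        return self.n_sub + self.n_ins + self.n_del


def random_genome(length: int, gc: float = 0.5, seed: int = 0) -> SeqRecord:
    """An i.i.d. random genome at the given GC fraction; deterministic per
    seed."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(np.array(list(_BASES))[rng.choice(4, size=length, p=p)])
    return SeqRecord(id=f"randgenome_{length}_{seed}", seq=seq)


def _phred(p: float) -> int:
    if p <= 0.0:
        return 93
    return int(np.clip(round(-10.0 * math.log10(p)), 0, 93))


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _corrupt(
    template: str, rho: float, mix, rng
) -> tuple[str, int, int, int, list[int]]:
    """Scan the template emitting an error-corrupted read.

    Returns the read, the per-type event counts and the list of error-free
    run lengths (correct bases emitted between consecutive error events).
    """
    out: list[str] = []
    counts = [0, 0, 0]  # sub, ins, del
    runs: list[int] = []
    run = 0
    i = 0
    T = len(template)
    while i < T:
        if rho > 0.0 and rng.random() < rho:
            kind = int(rng.choice(3, p=mix))
            counts[kind] += 1
            runs.append(run)
            run = 0
            if kind == 0:  # substitution: a random different base
                base = template[i]
                out.append(_BASES[(int(_BASES.index(base)) + 1 + rng.integers(3)) % 4]
                           if base in _BASES else _BASES[rng.integers(4)])
                i += 1
            elif kind == 1:  # insertion: extra random base, template untouched
                out.append(_BASES[rng.integers(4)])
            else:  # deletion: consume silently
                i += 1
        else:
            out.append(template[i])
            run += 1
            i += 1
    runs.append(run)
    return "".join(out), counts[0], counts[1], counts[2], runs


def simulate_reads(genome: SeqRecord, cfg: SimConfig) -> list[SimRead]:
    """Sample reads uniformly from both strands and corrupt them.

    The per-read quality tracks encode the marginal per-base probabilities of
    each error type (phred of rho * mix fraction), with uniformly random
    alternative calls.
    """
    G = len(genome.seq)
    T = cfg.read_length
    if G <= T:
        raise ValueError("genome must be longer than the read length")
    rng = np.random.default_rng(cfg.seed)
    mix = np.asarray(cfg.mix)
    q_sub = _phred(cfg.rho * cfg.mix[0])
    q_ins = _phred(cfg.rho * cfg.mix[1])
    q_del = _phred(cfg.rho * cfg.mix[2])
    reads: list[SimRead] = []
    for n in range(cfg.n_reads):
        start = int(rng.integers(0, G - T + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        template = genome.seq[start : start + T]
        if strand == "-":
            template = "".join(_COMP[b] for b in reversed(template))
        read_seq, n_sub, n_ins, n_del, runs = _corrupt(template, cfg.rho, mix, rng)
        if not read_seq:  # pathological all-deletion draw
            read_seq = "N"
        R = len(read_seq)
        qv = QualityArrays(
            ins=np.full(R, q_ins, dtype=np.int16),
            sub=np.full(R, q_sub, dtype=np.int16),
            del_=np.full(R, q_del, dtype=np.int16),
            sub_alt="".join(_BASES[i] for i in rng.integers(0, 4, size=R)),
            del_alt="".join(_BASES[i] for i in rng.integers(0, 4, size=R)),
        )
        reads.append(
            SimRead(
                record=SeqRecord(id=f"read{n:05d}", seq=read_seq, qv=qv),
                ref_id=genome.id,
                strand=strand,
                start=start,
                end=start + T,
                n_sub=n_sub,
                n_ins=n_ins,
                n_del=n_del,
                runs=runs,
            )
        )
    return reads


def mapability_phred(
    results: Sequence[Optional[AlignmentResult]],
    truths: Sequence[SimRead],
    slack: int = 50,
    cap: float = math.inf,
) -> float:
    """Phred-scaled mapping accuracy: -10 log10((missing + mismapped)/total).

    A read counts as correct when it is mapped to the right reference and
    strand with a start within ``slack`` bases of the truth.  With no wrong
    reads the value is infinite and reported as ``cap``.
    """
    if not truths:
        raise ValueError("no reads to evaluate")
    if len(results) != len(truths):
        raise ValueError("results and truths differ in length")
    wrong = 0
    for res, truth in zip(results, truths):
        if res is None or not res.mapped:
            wrong += 1
        elif (
            res.ref_id != truth.ref_id
            or res.strand != truth.strand
            or abs(res.ref_start - truth.start) > slack
        ):
            wrong += 1
    if wrong == 0:
        return cap
    return -10.0 * math.log10(wrong / len(truths))


def write_simulated(reads: Sequence[SimRead], prefix: str) -> tuple[str, str, str]:
    """Write reads as FASTQ plus sidecar QV table and a truth TSV
    (ref, start, end, strand, read id).  Returns the three paths."""
    from .seq_io import write_qv_table

    fastq = f"{prefix}.fastq"
    qv_path = f"{prefix}.qv.tsv"
    truth = f"{prefix}.truth.tsv"
    with open(fastq, "w") as fh:
        for r in reads:
            qual = "".join(chr(min(int(q), 93) + 33) for q in r.record.qv.sub)
            fh.write(f"@{r.record.id}\n{r.record.seq}\n+\n{qual}\n")
    write_qv_table((r.record for r in reads), qv_path)
    with open(truth, "w") as fh:
        for r in reads:
            fh.write(f"{r.ref_id}\t{r.start}\t{r.end}\t{r.strand}\t{r.record.id}\n")
    return fastq, qv_path, truth
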