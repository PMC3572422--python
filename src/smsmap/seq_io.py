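"""Sequence input/output: FASTA/FASTQ reads, sidecar quality tables, SAM.

Reads may carry five per-base tracks beyond the base calls: phred-scaled
insertion (I), substitution (S) and deletion (D) quality values, and two
alternative base calls (the most likely substituted base and the most likely
deleted base).  FASTA records carry no tracks; FASTQ base qualities are
stored as the substitution track (with insertion and deletion tracks set to
the same generic per-base confidence and alternative calls set to ``N``, so
only a matching alternative call could ever discount a penalty).  The full
five-track form travels in a sidecar TSV keyed by read id.

Internally every coordinate is 0-based half-open; conversion to SAM's
1-based closed convention happens only at emission.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pysam
from Bio import SeqIO

__all__ = [
    "SeqRecord",
    "QualityArrays",
    "SeqParseError",
    "read_seqs",
    "read_qv_table",
    "write_qv_table",
    "write_alignments",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SeqParseError(ValueError):
    pass


@dataclass
class QualityArrays:
    """Per-base phred tracks and alternative calls for one read.

    All five arrays have exactly the read's length; phred values lie in
    [0, 93].
    """

    ins: np.ndarray
    sub: np.ndarray
    del_: np.ndarray
    sub_alt: str
    del_alt: str

    def __post_init__(self) -> None:
        self.ins = np.asarray(self.ins, dtype=np.int16)
        self.sub = np.asarray(self.sub, dtype=np.int16)
        self.del_ = np.asarray(self.del_, dtype=np.int16)
        n = len(self.ins)
        if not (len(self.sub) == len(self.del_) == len(self.sub_alt) == len(self.del_alt) == n):
            raise ValueError("quality tracks must all share the read length")
        for arr in (self.ins, self.sub, self.del_):
            if arr.size and (arr.min() < 0 or arr.max() > 93):
                raise ValueError("phred values must lie in [0, 93]")

    def reverse_complement(self) -> "QualityArrays":
        return QualityArrays(
            ins=self.ins[::-1].copy(),
            sub=self.sub[::-1].copy(),
            del_=self.del_[::-1].copy(),
            sub_alt=revcomp(self.sub_alt),
            del_alt=revcomp(self.del_alt),
        )


@dataclass
class SeqRecord:
    """A named nucleotide sequence over {A,C,G,T,N}, optionally with
    quality tracks of matching length."""

    id: str
    seq: str
    qv: Optional[QualityArrays] = None

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.qv is not None and len(self.qv.ins) != len(self.seq):
            raise ValueError(f"record {self.id!r}: quality tracks do not match length")

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SeqRecord":
        return SeqRecord(
            id=self.id,
            seq=revcomp(self.seq),
            qv=self.qv.reverse_complement() if self.qv else None,
        )


def read_seqs(path: str, format: str = "fasta") -> list[SeqRecord]:
    """Parse a FASTA or FASTQ (Sanger phred+33) file into records.

    Sequences are uppercased; N is permitted.  FASTQ base qualities become
    the substitution track (see module docstring).  Malformed input raises
    :class:`SeqParseError` naming the file.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    records: list[SeqRecord] = []
    try:
        for rec in SeqIO.parse(path, format):
            seq = str(rec.seq).upper()
            qv = None
            if format == "fastq":
                quals = np.asarray(
                    rec.letter_annotations["phred_quality"], dtype=np.int16
                )
                quals = np.clip(quals, 0, 93)
                qv = QualityArrays(
                    ins=quals,
                    sub=quals.copy(),
                    del_=quals.copy(),
                    sub_alt="N" * len(seq),
                    del_alt="N" * len(seq),
                )
            records.append(SeqRecord(id=rec.id, seq=seq, qv=qv))
    except ValueError as exc:
        raise SeqParseError(f"{path}: malformed {format} record: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# sidecar quality tables


def read_qv_table(path: str) -> dict[str, QualityArrays]:
    """Parse the sidecar TSV of quality tracks.

    Columns: id, I, S, D, sub-alt, del-alt; the three phred columns hold
    comma-separated integers and the alternative-call columns comma-separated
    single bases.
    """
    tracks: dict[str, QualityArrays] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise SeqParseError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            rid, i_col, s_col, d_col, sa_col, da_col = parts
            try:
                tracks[rid] = QualityArrays(
                    ins=[int(x) for x in i_col.split(",")],
                    sub=[int(x) for x in s_col.split(",")],
                    del_=[int(x) for x in d_col.split(",")],
                    sub_alt="".join(sa_col.split(",")),
                    del_alt="".join(da_col.split(",")),
                )
            except ValueError as exc:
                raise SeqParseError(f"{path}:{lineno}: {exc}") from exc
    return tracks


def write_qv_table(records: Iterable[SeqRecord], path: str) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.qv is None:
                continue
            fh.write(
                "\t".join(
                    (
                        rec.id,
                        ",".join(map(str, rec.qv.ins.tolist())),
                        ",".join(map(str, rec.qv.sub.tolist())),
                        ",".join(map(str, rec.qv.del_.tolist())),
                        ",".join(rec.qv.sub_alt),
                        ",".join(rec.qv.del_alt),
                    )
                )
                + "\n"
            )


def attach_qv(records: list[SeqRecord], tracks: dict[str, QualityArrays]) -> None:
    """Attach sidecar tracks to records in place (ids without tracks keep
    whatever they had; lengths are validated)."""
    for rec in records:
        qv = tracks.get(rec.id)
        if qv is not None:
            if len(qv.ins) != len(rec.seq):
                raise SeqParseError(
                    f"quality tracks for {rec.id!r} have length {len(qv.ins)}, "
                    f"read has {len(rec.seq)}"
                )
            rec.qv = qv


# ---------------------------------------------------------------------------
# SAM emission

_CIGAR_CODE = {"M": 0, "I": 1, "D": 2}


def write_alignments(results, refs: list[SeqRecord], out: str) -> None:
    """Write alignments as plain-text SAM v1.

    ``results`` is a sequence of alignment results (see
    :mod:`smsmap.banded_alignment`).  Mapped records carry 1-based POS, a
    CIGAR over M/I/D and MAPQ = min(Q, 254); unmapped reads carry flag 4;
    reverse-strand hits carry flag 16 with the stored (already
    reverse-complemented) sequence.
    """
    names = [r.id for r in refs]
    lengths = {r.id: len(r.seq) for r in refs}
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": n, "LN": lengths[n]} for n in names],
        }
    )
    with pysam.AlignmentFile(out, "w", header=header) as sam:
        for res in results:
            seg = pysam.AlignedSegment(header)
            seg.query_name = res.read_id
            seg.query_sequence = res.read_seq
            if not res.mapped:
                seg.is_unmapped = True
                seg.mapping_quality = 0
                sam.write(seg)
                continue
            if res.ref_id not in lengths:
                raise ValueError(f"alignment references unknown sequence {res.ref_id!r}")
            seg.reference_id = names.index(res.ref_id)
            seg.reference_start = res.ref_start  # pysam converts to 1-based POS
            seg.cigartuples = [(_CIGAR_CODE[op], ln) for op, ln in res.cigar]
            seg.mapping_quality = min(res.mapq if res.mapq is not None else 0, 254)
            seg.is_reverse = res.strand == "-"
            sam.write(seg)
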