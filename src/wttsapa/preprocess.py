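"""Read filtration for 3'-end libraries: quality filter, leading poly-T
trimming, minimum-length filter.

A read passes the quality filter when at least ``qual_fraction`` of its
bases have Phred quality >= ``qual_threshold`` (Q10 corresponds to 90%
base-call accuracy); the boundary case (exactly the fraction) passes, and
'N' bases count as failing regardless of their stated quality.  Survivors
then lose their maximal leading run of 'T' — the sequenced complement of
the poly(A) tail — and must retain at least ``min_length_after_trim``
bases (16 nt inclusive) to be kept for mapping.  Filters apply in that
order; surviving reads keep their input order.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass
from typing import Iterator, NamedTuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class Read(NamedTuple):
    read_id: str
    sequence: str
    qualities: tuple[int, ...]


@dataclass(frozen=True)
class PreprocessParams:
    qual_threshold: int = 10
    qual_fraction: float = 0.5
    min_length_after_trim: int = 16

    def __post_init__(self) -> None:
        if not (0 < self.qual_fraction <= 1):
            raise ValueError("qual_fraction must be in (0, 1]")
        if self.min_length_after_trim < 1:
            raise ValueError("min_length_after_trim must be >= 1")


@dataclass
class PreprocessReport:
    n_input: int = 0
    n_failed_quality: int = 0
    n_trimmed: int = 0
    n_failed_length: int = 0
    n_kept: int = 0

    def check(self) -> None:
        if self.n_input != self.n_failed_quality + self.n_failed_length + self.n_kept:
            raise AssertionError("preprocess tallies do not conserve reads")


def quality_pass(read: Read, params: PreprocessParams | None = None) -> bool:
    """True iff >= qual_fraction of bases have Phred >= qual_threshold."""
    params = params or PreprocessParams()
    if not read.sequence:
        raise ValueError(f"empty read {read.read_id!r}")
    good = sum(
        1
        for base, q in zip(read.sequence, read.qualities)
        if base != "N" and q >= params.qual_threshold
    )
    return good / len(read.sequence) >= params.qual_fraction


def trim_leading_t(read: Read) -> Read:
    """Remove the maximal prefix run of 'T' from sequence and qualities."""
    i = 0
    seq = read.sequence
    while i < len(seq) and seq[i] == "T":
        i += 1
    return Read(read.read_id, seq[i:], read.qualities[i:])


def length_pass(read: Read, params: PreprocessParams | None = None) -> bool:
    """True iff the (trimmed) read is at least min_length_after_trim long."""
    params = params or PreprocessParams()
    return len(read.sequence) >= params.min_length_after_trim


def _open_text(path: str | os.PathLike, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def iter_fastq(path: str | os.PathLike) -> Iterator[Read]:
    """Yield reads from a (possibly gzipped) Phred+33 FASTQ file."""
    with _open_text(path) as fh:
        try:
            for i, rec in enumerate(SeqIO.parse(fh, "fastq")):
                yield Read(
                    rec.id,
                    str(rec.seq),
                    tuple(rec.letter_annotations["phred_quality"]),
                )
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record near index {i + 1}: {exc}") from exc


def write_fastq(reads, path: str | os.PathLike) -> int:
    n = 0
    with _open_text(path, "wt") as fh:
        for r in reads:
            rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = list(r.qualities)
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n


def preprocess_reads(
    reads, params: PreprocessParams | None = None, report: PreprocessReport | None = None
) -> Iterator[Read]:
    """Apply quality -> trim -> length in order; yields survivors.

    The ``report`` object (if given) is updated in place while streaming;
    call :func:`preprocess_fastq` for the file-level wrapper.
    """
    params = params or PreprocessParams()
    if report is None:
        report = PreprocessReport()
    for read in reads:
        report.n_input += 1
        if not quality_pass(read, params):
            report.n_failed_quality += 1
            continue
        trimmed = trim_leading_t(read)
        if len(trimmed.sequence) < len(read.sequence):
            report.n_trimmed += 1
        if not length_pass(trimmed, params):
            report.n_failed_length += 1
            continue
        report.n_kept += 1
        yield trimmed


def preprocess_fastq(
    path_in: str | os.PathLike,
    path_out: str | os.PathLike,
    params: PreprocessParams | None = None,
) -> PreprocessReport:
    """Filter + trim a FASTQ file; returns the conservation-checked report."""
    params = params or PreprocessParams()
    report = PreprocessReport()
    write_fastq(preprocess_reads(iter_fastq(path_in), params, report), path_out)
    report.check()
    return report
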