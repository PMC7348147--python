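"""FASTQ read filtering by unknown-base and low-quality-base fractions.

A read is rejected iff strictly more than ``n_threshold`` of its bases are N,
or strictly more than ``lowq_threshold`` of its bases have Phred quality
<= ``q_cutoff``. A read failing both rules is tallied once, under the
N-fraction rule. Order is preserved; filtering is per-record.
"""

from __future__ import annotations

import gzip
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from proxisig.errors import ConfigurationError, ParseError, RecordError

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class ReadRecord:
    """One FASTQ read: id, sequence and per-base Phred scores."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise RecordError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        bad = set(self.sequence.upper()) - VALID_BASES
        if bad:
            raise RecordError(f"read {self.id!r}: invalid bases {sorted(bad)}")


@dataclass
class QCReport:
    n_input: int = 0
    n_rejected_n_fraction: int = 0
    n_rejected_quality: int = 0
    n_passed: int = 0

    def check(self) -> None:
        assert (
            self.n_input
            == self.n_passed + self.n_rejected_n_fraction + self.n_rejected_quality
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _validate_thresholds(n_threshold: float, q_cutoff: int, lowq_threshold: float):
    if not 0 < n_threshold <= 1:
        raise ConfigurationError("n_threshold: must be in (0, 1]")
    if not 0 < lowq_threshold <= 1:
        raise ConfigurationError("lowq_threshold: must be in (0, 1]")
    if q_cutoff < 0:
        raise ConfigurationError("q_cutoff: must be >= 0")


def filter_reads(
    reads: Iterable[ReadRecord],
    n_threshold: float = 0.10,
    q_cutoff: int = 20,
    lowq_threshold: float = 0.50,
    report: QCReport | None = None,
) -> Iterator[ReadRecord]:
    """Yield reads passing both fraction rules; tallies go into ``report``.

    Rejection uses strict inequalities on both fractions ("more than").
    """
    _validate_thresholds(n_threshold, q_cutoff, lowq_threshold)
    if report is None:
        report = QCReport()
    for read in reads:
        report.n_input += 1
        length = len(read.sequence)
        if length == 0:
            report.n_passed += 1
            yield read
            continue
        n_frac = read.sequence.upper().count("N") / length
        if n_frac > n_threshold:
            report.n_rejected_n_fraction += 1
            continue
        lowq_frac = sum(1 for q in read.qualities if q <= q_cutoff) / length
        if lowq_frac > lowq_threshold:
            report.n_rejected_quality += 1
            continue
        report.n_passed += 1
        yield read


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path, phred_offset: int = 33) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a plain or gzipped FASTQ file."""
    if phred_offset not in (33, 64):
        raise ConfigurationError("phred_offset: must be 33 or 64")
    record_no = 0
    with _open_text(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                record_no += 1
                if len(seq) != len(qual):
                    raise RecordError(
                        f"record {record_no} ({title.split()[0]}): "
                        f"sequence/quality length mismatch"
                    )
                quals = tuple(ord(c) - phred_offset for c in qual)
                if any(q < 0 for q in quals):
                    raise RecordError(
                        f"record {record_no}: negative quality; wrong phred offset?"
                    )
                yield ReadRecord(
                    id=title.split()[0], sequence=seq, qualities=quals
                )
        except RecordError:
            raise
        except ValueError as exc:  # malformed FASTQ from Biopython
            raise ParseError(
                f"{path}: malformed FASTQ near record {record_no + 1} "
                f"(approx. line {record_no * 4 + 1}): {exc}"
            ) from exc


def write_fastq(
    reads: Iterable[ReadRecord], path: str | Path, phred_offset: int = 33
) -> int:
    """Write reads to FASTQ (gzipped if the path ends in .gz); returns count."""
    n = 0
    with _open_text(path, "wt") as fh:
        for read in reads:
            qual = "".join(chr(q + phred_offset) for q in read.qualities)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n


def filter_fastq_file(
    in_path: str | Path,
    out_path: str | Path,
    n_threshold: float = 0.10,
    q_cutoff: int = 20,
    lowq_threshold: float = 0.50,
    phred_offset: int = 33,
) -> QCReport:
    """Filter a FASTQ file end to end and return the QC report."""
    report = QCReport()
    passed = filter_reads(
        read_fastq(in_path, phred_offset),
        n_threshold=n_threshold,
        q_cutoff=q_cutoff,
        lowq_threshold=lowq_threshold,
        report=report,
    )
    write_fastq(passed, out_path, phred_offset)
    report.check()
    return report
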