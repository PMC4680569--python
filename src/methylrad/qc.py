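"""Read QC: adaptor/end trimming and quality filtering of 1x36 bp tag reads.

The library design sequences ~32 nt enzyme tags with a 3' adaptor filling the
36-cycle read.  QC removes the adaptor, trims 2 nt from each end of the
insert (ligation-position artefacts), and drops reads containing ambiguous
bases or more than five bases under Q10.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = ["RawRead", "QCConfig", "QCReport", "trim_read", "filter_read",
           "run_qc", "read_fastq", "write_fastq"]


@dataclass(frozen=True)
class RawRead:
    id: str
    seq: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class QCConfig:
    """Trimming/filtering parameters.

    end_trim removes this many bases from *each* end of the insert after
    adaptor removal; min_len discards shorter inserts so that <=2-mismatch
    mapping stays specific.  Quality encoding is Phred+33 unless
    ``phred_offset`` says otherwise.
    """

    end_trim: int = 2
    min_len: int = 26
    adaptor_max_mismatch: int = 1
    adaptor_min_overlap: int = 4
    max_low_quality: int = 5
    low_quality_threshold: int = 10
    phred_offset: int = 33


@dataclass
class QCReport:
    n_input: int = 0
    n_adaptor_trimmed: int = 0
    n_dropped_short: int = 0
    n_dropped_n: int = 0
    n_dropped_low_quality: int = 0
    n_retained: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_short + self.n_dropped_n + self.n_dropped_low_quality

    @property
    def retention(self) -> float:
        return self.n_retained / self.n_input if self.n_input else 0.0

    def as_dict(self) -> dict:
        return {
            "input_reads": self.n_input,
            "adaptor_trimmed": self.n_adaptor_trimmed,
            "dropped_short": self.n_dropped_short,
            "dropped_n": self.n_dropped_n,
            "dropped_low_quality": self.n_dropped_low_quality,
            "retained": self.n_retained,
            "retention": self.retention,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)
            fh.write("\n")


def _find_adaptor(seq: str, adaptor: str, max_mm: int, min_overlap: int) -> int | None:
    """Leftmost start of a 3' adaptor occurrence, or None.

    The adaptor may be internal (full prefix present) or run off the read end;
    the matched region must span >= min_overlap bases with <= max_mm
    mismatches.
    """
    n = len(seq)
    for start in range(0, n - min_overlap + 1):
        region = min(len(adaptor), n - start)
        mm = 0
        for i in range(region):
            if seq[start + i] != adaptor[i]:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return start
    return None


def trim_read(read: RawRead, adaptor: str, config: QCConfig = QCConfig()) -> RawRead | None:
    """Remove a 3' adaptor match, then ``end_trim`` bases from each end.

    Returns None (discard) if the trimmed insert is shorter than
    ``config.min_len``.  Trimming never lengthens a read.
    """
    if not adaptor:
        raise ValueError("adaptor must be non-empty")
    end = len(read.seq)
    hit = _find_adaptor(read.seq, adaptor,
                        config.adaptor_max_mismatch, config.adaptor_min_overlap)
    trimmed_adaptor = hit is not None
    if trimmed_adaptor:
        end = hit
    lo, hi = config.end_trim, end - config.end_trim
    if hi - lo < config.min_len:
        return None
    out = RawRead(read.id, read.seq[lo:hi], read.quals[lo:hi])
    # annotate adaptor removal for run_qc bookkeeping without mutating state
    object.__setattr__(out, "_adaptor_trimmed", trimmed_adaptor)
    return out


def filter_read(read: RawRead, config: QCConfig = QCConfig()) -> str:
    """'keep', or a drop reason: 'N' | 'low_quality'."""
    if "N" in read.seq:
        return "N"
    n_low = sum(1 for q in read.quals if q < config.low_quality_threshold)
    if n_low > config.max_low_quality:
        return "low_quality"
    return "keep"


def read_fastq(path_or_handle) -> Iterator[RawRead]:
    """Stream a (optionally gzipped) FASTQ file as RawRead records."""
    if hasattr(path_or_handle, "read"):
        yield from _parse_fastq(path_or_handle)
    else:
        opener = gzip.open if str(path_or_handle).endswith(".gz") else open
        with opener(path_or_handle, "rt") as fh:
            yield from _parse_fastq(fh)


def _parse_fastq(fh: TextIO) -> Iterator[RawRead]:
    idx = 0
    try:
        for rid, seq, qual in FastqGeneralIterator(fh):
            idx += 1
            yield RawRead(rid.split()[0], seq.upper(),
                          tuple(ord(c) - 33 for c in qual))
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ near record {idx + 1}: {exc}") from exc


def write_fastq(reads: Iterable[RawRead], path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n"
                     + "".join(chr(q + 33) for q in r.quals) + "\n")


def run_qc(reads: Iterable[RawRead], adaptor: str,
           config: QCConfig = QCConfig()) -> tuple[list[RawRead], QCReport]:
    """Trim then filter each read; report totals reconcile exactly."""
    report = QCReport()
    kept: list[RawRead] = []
    for read in reads:
        report.n_input += 1
        trimmed = trim_read(read, adaptor, config)
        if trimmed is None:
            report.n_dropped_short += 1
            continue
        if getattr(trimmed, "_adaptor_trimmed", False):
            report.n_adaptor_trimmed += 1
        verdict = filter_read(trimmed, config)
        if verdict == "N":
            report.n_dropped_n += 1
        elif verdict == "low_quality":
            report.n_dropped_low_quality += 1
        else:
            report.n_retained += 1
            kept.append(trimmed)
    return kept, report
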