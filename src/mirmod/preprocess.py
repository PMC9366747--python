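"""3' adapter trimming and read-length filtering.

Semi-global 3'-adapter search: the best occurrence of an adapter prefix
anchored toward the read 3' end is located under a per-overlap mismatch
budget, and everything from that position onwards is removed.  Reads
shorter than ``min_length`` after trimming are discarded — the retention
stage of a standard small RNA-seq workflow.

Sequences are handled in the RNA alphabet internally; T on input is treated
as U.  Quality strings are carried through untouched and never used in
decisions.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, TextIO


def _as_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def find_adapter_start(
    read: str,
    adapter: str,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
) -> int | None:
    """Start index of the best qualifying adapter occurrence, or None.

    For every start ``i``, the overlap is ``min(len(adapter), len(read) - i)``;
    the occurrence qualifies if ``overlap >= min_overlap`` and the number of
    mismatches between ``read[i:i+overlap]`` and ``adapter[:overlap]`` is at
    most ``floor(max_error_rate * overlap)``.  Among qualifying occurrences
    the one with the most matched bases wins; ties go to the leftmost start.
    Read bases beyond a full adapter occurrence are ignored (they are removed
    with it).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not (0.0 <= max_error_rate < 0.5):
        raise ValueError("max_error_rate must be in [0, 0.5)")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")

    read = _as_rna(read)
    adapter = _as_rna(adapter)
    n, m = len(read), len(adapter)
    best: tuple[int, int] | None = None  # (matches, -start) to maximise
    best_start = None
    for i in range(0, n - min_overlap + 1):
        overlap = min(m, n - i)
        if overlap < min_overlap:
            break
        allowed = math.floor(max_error_rate * overlap)
        mism = 0
        for a, b in zip(read[i:i + overlap], adapter[:overlap]):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        if mism > allowed:
            continue
        matches = overlap - mism
        key = (matches, -i)
        if best is None or key > best:
            best = key
            best_start = i
    return best_start


def trim_adapter(
    read_sequence: str,
    adapter: str,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
) -> str:
    """Remove the best-scoring 3' adapter occurrence and everything after it.

    If no occurrence qualifies the read is returned unchanged (converted to
    the RNA alphabet).  An empty read yields an empty result.
    """
    read = _as_rna(read_sequence)
    if not read:
        return ""
    start = find_adapter_start(read, adapter, max_error_rate, min_overlap)
    return read if start is None else read[:start]


@dataclass
class TrimReport:
    """Read-retention bookkeeping for one library."""

    n_input: int = 0
    n_retained: int = 0
    discards: dict[str, int] = field(default_factory=lambda: {
        "too_short": 0, "no_insert": 0,
    })

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_input if self.n_input else 0.0

    def check(self) -> None:
        if self.n_input != self.n_retained + sum(self.discards.values()):
            raise AssertionError("trim report does not reconcile")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"n_input\t{self.n_input}\n")
            fh.write(f"n_retained\t{self.n_retained}\n")
            fh.write(f"retained_fraction\t{self.retained_fraction:.6f}\n")
            for reason, n in sorted(self.discards.items()):
                fh.write(f"discard_{reason}\t{n}\n")


def _open_maybe_gzip(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def parse_fastq(handle: TextIO) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality); fails with the record index."""
    idx = 0
    while True:
        header = handle.readline()
        if not header:
            return
        seq = handle.readline()
        plus = handle.readline()
        qual = handle.readline()
        header, seq = header.rstrip("\n"), seq.rstrip("\n")
        plus, qual = plus.rstrip("\n"), qual.rstrip("\n")
        if (not header.startswith("@") or not plus.startswith("+")
                or len(qual) != len(seq)):
            raise ValueError(f"malformed FASTQ record at index {idx}")
        yield header[1:].split()[0], seq, qual
        idx += 1


def preprocess_fastq(
    fastq_in: str | Path,
    fastq_out: str | Path,
    adapter: str,
    min_length: int = 20,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
) -> TrimReport:
    """Trim the 3' adapter from every read and keep inserts >= ``min_length``.

    Output reads are written in the RNA alphabet with their (truncated)
    original quality strings.  Returns a reconciled :class:`TrimReport`.
    """
    report = TrimReport()
    with _open_maybe_gzip(fastq_in) as fin, open(fastq_out, "w") as fout:
        for read_id, seq, qual in parse_fastq(fin):
            report.n_input += 1
            trimmed = trim_adapter(seq, adapter, max_error_rate, min_overlap)
            if len(trimmed) == 0:
                report.discards["no_insert"] += 1
            elif len(trimmed) < min_length:
                report.discards["too_short"] += 1
            else:
                report.n_retained += 1
                fout.write(f"@{read_id}\n{trimmed}\n+\n{qual[:len(trimmed)]}\n")
    report.check()
    return report
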