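"""Primer trimming and length/quality filtering of COI amplicon reads.

Nanopore amplicon reads carry the PCR primers at their ends and a per-base
error rate high enough (5–15%) that primer location must tolerate mismatches
and indels.  The QC chain here mirrors a standard amplicon workflow:

1. locate the forward primer near the 5' end and the reverse-complemented
   reverse primer near the 3' end (edit distance, ≤10% of primer length by
   default) and cut out the insert between them — reads missing either
   primer on both strands are rejected;
2. drop inserts outside the expected length window (550–750 nt inclusive);
3. drop reads whose mean quality falls below the platform threshold
   (Q10 for MinION, Q7 for Flongle).

Per-read quality is defined as −10·log10(mean per-base error probability),
the convention Nanopore summary tooling uses — not the arithmetic mean of
Phred values, which overstates quality on error-heavy reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import edlib
import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "LCO1490",
    "HCO2198",
    "Read",
    "QCParams",
    "QCReport",
    "mean_error_prob",
    "phred_to_error_pct",
    "read_mean_q",
    "revcomp",
    "trim_primers",
    "filter_reads",
    "read_fastq",
    "write_fastq",
]

# Folmer-region COI primers amplifying the ~650 nt barcode fragment.
LCO1490 = "GGTCAACAAATCATAAAGATATTGG"
HCO2198 = "TAAACTTCAGGGTGACCAAAAAATCA"

_COMP = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                      "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Read:
    """One amplicon read: sequence plus Phred+33 qualities and platform tag."""

    read_id: str
    seq: str
    qual: str
    platform: str = "minion"

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )
        for ch in self.qual:
            q = ord(ch) - 33
            if not 0 <= q <= 93:
                raise ValueError(
                    f"read {self.read_id!r}: quality char {ch!r} outside Phred 0-93"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class QCParams:
    """Length, quality and primer-trimming thresholds.

    ``min_q`` maps platform → minimum per-read mean quality; the defaults are
    the MinION/Flongle thresholds the length/quality filter applies.
    """

    min_len: int = 550
    max_len: int = 750
    min_q: dict = field(default_factory=lambda: {"minion": 10.0, "flongle": 7.0})
    primer_fwd: str = LCO1490
    primer_rev: str = HCO2198
    primer_max_err: float = 0.1
    # Primers are searched only within a window of this multiple of the
    # primer length at each read end.
    primer_window_factor: float = 1.5

    def __post_init__(self):
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("require 0 < min_len <= max_len")
        if any(q < 0 for q in self.min_q.values()):
            raise ValueError("min_q must be >= 0")


@dataclass
class QCReport:
    """Per-rule read accounting for one QC pass."""

    n_in: int = 0
    n_kept: int = 0
    removed_too_short: int = 0
    removed_too_long: int = 0
    removed_low_quality: int = 0

    def as_rows(self) -> list[tuple[str, int]]:
        return [
            ("input", self.n_in),
            ("kept", self.n_kept),
            ("too_short", self.removed_too_short),
            ("too_long", self.removed_too_long),
            ("low_quality", self.removed_low_quality),
        ]


# -- quality arithmetic ------------------------------------------------------


def mean_error_prob(qual: str) -> float:
    """Arithmetic mean over bases of 10^(−q/10); in (0, 1]."""
    if not qual:
        raise ValueError("empty quality string")
    q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.float64) - 33.0
    return float(np.mean(10.0 ** (-q / 10.0)))


def phred_to_error_pct(q: float) -> float:
    """Phred score → per-base error percentage, rounded to one decimal.

    Q11.6 → 6.9, Q10.2 → 9.5, Q10 → 10.0.
    """
    if q < 0:
        raise ValueError(f"negative Phred score {q}")
    return round(100.0 * 10.0 ** (-q / 10.0), 1)


def read_mean_q(read: Read) -> float:
    """Per-read quality: −10·log10(mean error probability)."""
    return -10.0 * math.log10(mean_error_prob(read.qual))


# -- primer trimming ---------------------------------------------------------

#: Sentinel for a read rejected at primer trimming.
REJECT = None


def _find_primer(window: str, primer: str, max_edits: int) -> tuple[int, int] | None:
    """Best infix match of primer in window; (start, end) 0-based half-open."""
    res = edlib.align(primer, window, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] < 0:
        return None
    start, end = res["locations"][0]
    return start, end + 1


def _trim_one_strand(read: Read, p: QCParams) -> Read | None:
    w = max(1, int(round(p.primer_window_factor * len(p.primer_fwd))))
    rc_rev = revcomp(p.primer_rev)
    w_rev = max(1, int(round(p.primer_window_factor * len(p.primer_rev))))
    max_err_fwd = int(p.primer_max_err * len(p.primer_fwd))
    max_err_rev = int(p.primer_max_err * len(p.primer_rev))

    head = read.seq[:w]
    fwd = _find_primer(head, p.primer_fwd, max_err_fwd)
    if fwd is None:
        return None
    tail_off = max(0, len(read.seq) - w_rev)
    tail = read.seq[tail_off:]
    rev = _find_primer(tail, rc_rev, max_err_rev)
    if rev is None:
        return None
    insert_start = fwd[1]
    insert_end = tail_off + rev[0]
    if insert_end <= insert_start:
        return None
    return replace(
        read,
        seq=read.seq[insert_start:insert_end],
        qual=read.qual[insert_start:insert_end],
    )


def trim_primers(read: Read, p: QCParams) -> Read | None:
    """Cut the insert between the two primers, or REJECT (None).

    Both primers must be found (within ``primer_max_err`` edit-distance
    fraction, each anchored to its read end); reads with only one locatable
    primer are rejected, since the amplicon design implies both.  Both read
    orientations are tried; a read sequenced on the reverse strand is
    returned reverse-complemented into amplicon orientation.
    """
    out = _trim_one_strand(read, p)
    if out is not None:
        return out
    flipped = replace(read, seq=revcomp(read.seq), qual=read.qual[::-1])
    return _trim_one_strand(flipped, p)


# -- length / quality filtering ---------------------------------------------


def filter_reads(
    reads: Iterable[Read], p: QCParams
) -> tuple[list[Read], QCReport]:
    """Keep reads with min_len ≤ len ≤ max_len and mean Q ≥ platform threshold.

    Length bounds are inclusive: only strictly-shorter-than-550 and
    strictly-longer-than-750 reads are removed.
    """
    report = QCReport()
    kept: list[Read] = []
    for r in reads:
        report.n_in += 1
        if len(r) < p.min_len:
            report.removed_too_short += 1
            continue
        if len(r) > p.max_len:
            report.removed_too_long += 1
            continue
        try:
            min_q = p.min_q[r.platform]
        except KeyError:
            raise ValueError(f"read {r.read_id!r}: unknown platform {r.platform!r}")
        if read_mean_q(r) < min_q:
            report.removed_low_quality += 1
            continue
        kept.append(r)
    report.n_kept = len(kept)
    return kept, report


# -- FASTQ I/O ---------------------------------------------------------------


def read_fastq(path: str | Path, platform: str = "minion") -> Iterator[Read]:
    """Yield reads from a 4-line-record Phred+33 FASTQ file."""
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield Read(title.split()[0], seq, qual, platform)


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")
            n += 1
    return n


def write_qc_report(report: QCReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rule\treads\n")
        for rule, n in report.as_rows():
            fh.write(f"{rule}\t{n}\n")
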