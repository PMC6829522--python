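"""Read quality trimming.

Implements the four-rule trimming recipe commonly applied to colony
metagenome reads before assembly: adapter clipping, cutting read ends while
the base quality is below a floor (default Q3), truncating at the first
4-base sliding window whose mean quality drops below 20, and dropping reads
shorter than 50 bp. The window scan advances one base at a time and truncates
at the start of the first failing window; trailing windows shorter than the
window size are evaluated on their actual length.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator


class TrimError(ValueError):
    pass


@dataclass(frozen=True)
class TrimPolicy:
    end_quality_floor: int = 3
    window_size: int = 4
    window_mean_floor: float = 20.0
    min_length: int = 50
    adapters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise TrimError("window_size must be >= 1")
        if min(self.end_quality_floor, self.window_mean_floor, self.min_length) < 0:
            raise TrimError("thresholds must be non-negative")


def _clip_adapters(seq: str, quals: np.ndarray, adapters: tuple[str, ...]):
    for adapter in adapters:
        if not adapter:
            continue
        hit = seq.find(adapter)
        if hit >= 0:
            return seq[:hit], quals[:hit]
        # read-through: a proper adapter prefix at the very end of the read
        for k in range(min(len(adapter), len(seq)) - 1, 2, -1):
            if seq.endswith(adapter[:k]):
                return seq[: len(seq) - k], quals[: len(seq) - k]
    return seq, quals


def trim_read(
    sequence: str, qualities: Iterable[int], policy: TrimPolicy = TrimPolicy()
) -> tuple[str, np.ndarray] | None:
    """Trim one read; returns (sequence, qualities) or None when dropped.

    Rules are applied in order: adapter clipping (exact match, optional),
    low-quality end cutting, sliding-window truncation, minimum-length drop.
    The output is always a contiguous substring of the input with its
    qualities still aligned.
    """
    quals = np.asarray(list(qualities), dtype=int)
    if len(sequence) != len(quals):
        raise TrimError("sequence and quality lengths differ")
    seq = sequence
    if policy.adapters:
        seq, quals = _clip_adapters(seq, quals, policy.adapters)

    lo, hi = 0, len(seq)
    while lo < hi and quals[lo] < policy.end_quality_floor:
        lo += 1
    while hi > lo and quals[hi - 1] < policy.end_quality_floor:
        hi -= 1
    seq, quals = seq[lo:hi], quals[lo:hi]

    w = policy.window_size
    n = len(seq)
    if n:
        prefix = np.concatenate(([0], np.cumsum(quals)))
        starts = np.arange(n)
        ends = np.minimum(starts + w, n)
        means = (prefix[ends] - prefix[starts]) / (ends - starts)
        failing = np.nonzero(means < policy.window_mean_floor)[0]
        if failing.size:
            cut = int(failing[0])
            seq, quals = seq[:cut], quals[:cut]

    if len(seq) < policy.min_length:
        return None
    return seq, quals


# ---------------------------------------------------------------------------
# FASTQ streams


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, np.ndarray]]:
    """Yield (title, sequence, phred qualities) from a FASTQ file (gzip-transparent)."""
    with _open_text(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield title, seq, np.frombuffer(qual.encode("ascii"), dtype=np.uint8) - 33


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, object]]) -> int:
    """Write (title, sequence, qualities-or-quality-string) records; returns count."""
    n = 0
    with _open_text(path, "wt") as handle:
        for title, seq, qual in records:
            if not isinstance(qual, str):
                qual = "".join(chr(int(q) + 33) for q in np.asarray(qual))
            handle.write(f"@{title}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def _pair_key(title: str) -> str:
    name = title.split()[0] if title else title
    if name.endswith("/1") or name.endswith("/2"):
        return name[:-2]
    return name


@dataclass
class TrimSummary:
    both_kept: int = 0
    r1_only: int = 0
    r2_only: int = 0
    both_dropped: int = 0

    @property
    def total_pairs(self) -> int:
        return self.both_kept + self.r1_only + self.r2_only + self.both_dropped


def trim_pairs(
    in1: str | Path,
    in2: str | Path,
    out_prefix: str | Path,
    policy: TrimPolicy = TrimPolicy(),
) -> TrimSummary:
    """Trim mate-synchronized FASTQ files.

    Pairs where both mates survive go to ``<prefix>_R1.fastq`` /
    ``<prefix>_R2.fastq``; single survivors go to ``<prefix>_orphans.fastq``.
    Desynchronized inputs (unequal record counts or mismatching pair names)
    raise an error.
    """
    out_prefix = Path(out_prefix)
    summary = TrimSummary()
    it1, it2 = read_fastq(in1), read_fastq(in2)
    with _open_text(f"{out_prefix}_R1.fastq", "wt") as o1, _open_text(
        f"{out_prefix}_R2.fastq", "wt"
    ) as o2, _open_text(f"{out_prefix}_orphans.fastq", "wt") as oo:
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                break
            if rec1 is None or rec2 is None:
                raise TrimError("mate files are desynchronized: unequal record counts")
            if _pair_key(rec1[0]) != _pair_key(rec2[0]):
                raise TrimError(
                    f"mate files are desynchronized at {rec1[0]!r} vs {rec2[0]!r}"
                )
            t1 = trim_read(rec1[1], rec1[2], policy)
            t2 = trim_read(rec2[1], rec2[2], policy)
            if t1 is not None and t2 is not None:
                _write_rec(o1, rec1[0], t1)
                _write_rec(o2, rec2[0], t2)
                summary.both_kept += 1
            elif t1 is not None:
                _write_rec(oo, rec1[0], t1)
                summary.r1_only += 1
            elif t2 is not None:
                _write_rec(oo, rec2[0], t2)
                summary.r2_only += 1
            else:
                summary.both_dropped += 1
    return summary


def _write_rec(handle: TextIO, title: str, trimmed: tuple[str, np.ndarray]) -> None:
    seq, quals = trimmed
    qual = "".join(chr(int(q) + 33) for q in quals)
    handle.write(f"@{title}\n{seq}\n+\n{qual}\n")
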