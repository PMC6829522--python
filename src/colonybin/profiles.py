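"""Per-scaffold features: GC content, canonical tetranucleotide frequencies,
per-sample mean coverage, and assembly statistics.

Assembled scaffolds are strandless, so 4-mers are pooled with their reverse
complements into 136 canonical keys (the lexicographically smaller of each
pair; the 16 palindromes map to themselves). Mean depth is computed from
aligned-base totals — sum of aligned bases over scaffold length — which equals
the per-base pileup mean in one pass.
"""

from __future__ import annotations

from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import BASES, encode, revcomp


class ProfileError(ValueError):
    pass


# canonical tetranucleotide keys: 136 = (256 - 16)/2 + 16
CANONICAL_TETRAMERS: tuple[str, ...] = tuple(
    sorted(
        {
            min(kmer, revcomp(kmer))
            for kmer in ("".join(p) for p in product(BASES, repeat=4))
        }
    )
)
_CANON_INDEX = {k: i for i, k in enumerate(CANONICAL_TETRAMERS)}
# 256-entry lookup: 2-bit-coded 4-mer -> canonical slot
_CODE_TO_CANON = np.empty(256, dtype=np.int64)
for _p in product(range(4), repeat=4):
    _kmer = "".join(BASES[c] for c in _p)
    _code = _p[0] * 64 + _p[1] * 16 + _p[2] * 4 + _p[3]
    _CODE_TO_CANON[_code] = _CANON_INDEX[min(_kmer, revcomp(_kmer))]


def compute_gc(sequence: str) -> float:
    """GC fraction over unambiguous bases; ambiguous bases are excluded entirely."""
    if not sequence:
        raise ProfileError("empty sequence")
    codes = encode(sequence)
    unambiguous = codes >= 0
    n = int(unambiguous.sum())
    if n == 0:
        raise ProfileError("sequence has no unambiguous bases")
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / n


def compute_tnf(sequence: str) -> np.ndarray:
    """Canonical tetranucleotide frequency vector (136 entries, sums to 1).

    Slides a 4-base window by one; windows containing ambiguous bases are
    skipped; each 4-mer and its reverse complement share one canonical slot.
    """
    if len(sequence) < 4:
        raise ProfileError("sequence shorter than 4 bases")
    codes = encode(sequence).astype(np.int64)
    window_codes = (
        codes[:-3] * 64 + codes[1:-2] * 16 + codes[2:-1] * 4 + codes[3:]
    )
    valid = (
        (codes[:-3] >= 0) & (codes[1:-2] >= 0) & (codes[2:-1] >= 0) & (codes[3:] >= 0)
    )
    if not valid.any():
        raise ProfileError("no unambiguous 4-mer window in sequence")
    counts = np.bincount(_CODE_TO_CANON[window_codes[valid]], minlength=136)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# alignment tables and coverage

ALIGNMENT_COLUMNS = ("read_id", "scaffold_id", "aligned_bases", "mate")


def read_alignment_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(ALIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ProfileError(f"alignment table missing columns {sorted(missing)}")
    if (df["aligned_bases"] < 1).any():
        raise ProfileError("aligned_bases must be >= 1")
    return df[list(ALIGNMENT_COLUMNS)]


def alignment_table_from_sam(path: str | Path) -> pd.DataFrame:
    """Primary alignments of a SAM/BAM file as an alignment table.

    ``aligned_bases`` is the aligned reference length of each record; mate is
    1/2 from the pairing flags (1 for unpaired reads).
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            mate = 2 if rec.is_paired and rec.is_read2 else 1
            span = rec.reference_length or 0
            if span >= 1:
                rows.append((rec.query_name, rec.reference_name, span, mate))
    return pd.DataFrame(rows, columns=list(ALIGNMENT_COLUMNS))


def compute_coverage(
    alignments: pd.DataFrame, scaffold_lengths: Mapping[str, int]
) -> pd.Series:
    """Mean depth per scaffold: sum of aligned bases / scaffold length.

    Every scaffold in ``scaffold_lengths`` appears in the result; scaffolds
    without alignments get 0. Alignments to unknown scaffolds are an error.
    """
    lengths = pd.Series(scaffold_lengths, dtype=float)
    if len(alignments):
        unknown = set(alignments["scaffold_id"]) - set(lengths.index)
        if unknown:
            raise ProfileError(f"alignments reference unknown scaffolds {sorted(unknown)[:3]}")
        totals = alignments.groupby("scaffold_id")["aligned_bases"].sum()
    else:
        totals = pd.Series(dtype=float)
    depth = totals.reindex(lengths.index, fill_value=0) / lengths
    depth.name = "mean_depth"
    return depth


# ---------------------------------------------------------------------------
# assembly statistics


def compute_n50(lengths: Sequence[int]) -> int:
    """Largest L such that scaffolds of length >= L sum to >= half the total."""
    if len(lengths) == 0:
        raise ProfileError("empty length list")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if (arr <= 0).any():
        raise ProfileError("lengths must be positive")
    half = arr.sum() / 2
    csum = np.cumsum(arr)
    return int(arr[np.searchsorted(csum, half)])


def filter_scaffolds(scaffolds: Iterable, min_len: int = 1000) -> list:
    """Keep scaffolds of length >= min_len (boundary inclusive), order preserved."""
    return [s for s in scaffolds if _length_of(s) >= min_len]


def _length_of(s) -> int:
    if hasattr(s, "length"):
        return s.length
    if hasattr(s, "sequence"):
        return len(s.sequence)
    if isinstance(s, tuple):
        return len(s[1])
    return len(s)


def scaffold_profile_table(
    scaffolds: Iterable,
    coverage_by_sample: Mapping[str, pd.Series] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Profile every scaffold: length, GC, TNF, optional per-sample coverage.

    Returns a DataFrame (scaffold_id, length, gc, one ``cov_<sample>`` column
    per sample) and the aligned TNF matrix (n_scaffolds x 136).
    """
    ids, lengths, gcs, tnfs = [], [], [], []
    for s in scaffolds:
        sid, seq = (s.scaffold_id, s.sequence) if hasattr(s, "scaffold_id") else s
        ids.append(sid)
        lengths.append(len(seq))
        gcs.append(compute_gc(seq))
        tnfs.append(compute_tnf(seq))
    df = pd.DataFrame({"scaffold_id": ids, "length": lengths, "gc": gcs})
    if coverage_by_sample:
        for sample_id, depth in coverage_by_sample.items():
            df[f"cov_{sample_id}"] = depth.reindex(ids, fill_value=0.0).to_numpy()
    return df, np.vstack(tnfs)
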