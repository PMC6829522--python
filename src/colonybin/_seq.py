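"""Low-level nucleotide sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn", "TGCAYRMKVBHDNtgcayrmkvbhdn")

# byte-level base -> 2-bit code; ambiguity codes map to -1
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement; IUPAC ambiguity codes are complemented too."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Sequence -> int8 array of 2-bit base codes (-1 for ambiguous bases)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def gc_prefix_sums(seq: str) -> np.ndarray:
    """Cumulative G+C counts; entry i = #GC in seq[:i]. Supports O(1) window GC."""
    codes = encode(seq)
    is_gc = (codes == 1) | (codes == 2)
    out = np.zeros(len(seq) + 1, dtype=np.int64)
    np.cumsum(is_gc, out=out[1:])
    return out
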