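"""Single-copy marker gene accounting: completeness and duplication of genome bins.

Bacterial genomes carry a set of essential genes expected in exactly one copy
(the default catalog size of 107 follows the widely used single-copy HMM set).
The fraction of catalog markers found in a bin estimates its completeness;
markers found more than once indicate contamination or a chimeric bin.

Two detection routes are supported:

* synthetic mode — markers are short unique nucleotide tags planted in
  simulated genomes and found by exact substring search (both strands);
* import mode — marker hits produced by an external gene-prediction +
  profile-HMM pipeline are read from a tab-separated table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._seq import BASES, revcomp

HIT_COLUMNS = ("scaffold_id", "marker_id", "count")

DEFAULT_CATALOG_SIZE = 107


class MarkerError(ValueError):
    pass


@dataclass(frozen=True)
class MarkerCatalog:
    """An ordered set of single-copy marker genes.

    ``sequences`` maps marker_id to its nucleotide tag in synthetic mode and is
    ``None`` in annotation-import mode (real data), where detection is done
    externally and only the accounting runs here.
    """

    marker_ids: tuple[str, ...]
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise MarkerError("marker_ids must be unique")
        if self.sequences is not None:
            missing = set(self.marker_ids) - set(self.sequences)
            if missing:
                raise MarkerError(f"catalog sequences missing for {sorted(missing)[:3]}...")

    @property
    def size(self) -> int:
        return len(self.marker_ids)

    @classmethod
    def synthetic(
        cls, n_markers: int = DEFAULT_CATALOG_SIZE, tag_length: int = 60, seed: int = 0
    ) -> "MarkerCatalog":
        """Generate ``n_markers`` distinct random tags of ``tag_length`` bases.

        Tags are drawn uniformly over {A,C,G,T}; at 60 bp a collision with
        random background (or another tag, or its reverse complement) is
        vanishingly unlikely, which is what makes exact-match detection a
        faithful stand-in for profile-HMM search on synthetic data.
        """
        rng = np.random.default_rng(seed)
        seen: set[str] = set()
        ids = []
        seqs = {}
        while len(ids) < n_markers:
            tag = "".join(rng.choice(list(BASES), size=tag_length))
            if tag in seen or revcomp(tag) in seen:
                continue
            seen.add(tag)
            mid = f"marker_{len(ids):03d}"
            ids.append(mid)
            seqs[mid] = tag
        return cls(tuple(ids), seqs)


def detect_markers(scaffolds: Iterable[tuple[str, str]], catalog: MarkerCatalog) -> pd.DataFrame:
    """Exact-match marker detection on (scaffold_id, sequence) pairs.

    Each marker tag and its reverse complement are searched on every scaffold;
    occurrences on either strand are summed. Returns a hit table with columns
    ``scaffold_id, marker_id, count`` (count >= 1 rows only).
    """
    if catalog.sequences is None:
        raise MarkerError("catalog has no sequences; use import_marker_hits for external annotation")
    rows = []
    tags = [(mid, catalog.sequences[mid], revcomp(catalog.sequences[mid])) for mid in catalog.marker_ids]
    for sid, seq in scaffolds:
        for mid, fwd, rev in tags:
            n = seq.count(fwd)
            if rev != fwd:
                n += seq.count(rev)
            if n:
                rows.append((sid, mid, n))
    return pd.DataFrame(rows, columns=list(HIT_COLUMNS))


def import_marker_hits(table: pd.DataFrame | str | Path) -> pd.DataFrame:
    """Validate an externally produced marker hit table.

    Accepts a DataFrame or a tab-separated file with header columns
    ``scaffold_id, marker_id, count``. Duplicate (scaffold, marker) rows are
    summed; non-positive counts are rejected.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    if list(table.columns) != list(HIT_COLUMNS):
        raise MarkerError(f"expected columns {HIT_COLUMNS}, got {tuple(table.columns)}")
    counts = pd.to_numeric(table["count"], errors="raise")
    if (counts < 1).any():
        raise MarkerError("marker hit counts must be >= 1")
    out = (
        table.assign(count=counts.astype(int))
        .groupby(["scaffold_id", "marker_id"], as_index=False, sort=False)["count"]
        .sum()
    )
    return out[list(HIT_COLUMNS)]


class CompletenessReport(NamedTuple):
    found: int
    total: int
    completeness: float
    duplicated: int


def bin_completeness(hits: pd.DataFrame, catalog: MarkerCatalog) -> CompletenessReport:
    """Completeness/duplication accounting for one bin's marker hits.

    ``found`` counts distinct catalog markers with at least one hit;
    ``duplicated`` counts distinct markers whose total count in the bin is >= 2
    (the signature of a chimeric or contaminated bin).
    """
    total = catalog.size
    if len(hits) == 0:
        return CompletenessReport(0, total, 0.0, 0)
    in_catalog = hits[hits["marker_id"].isin(catalog.marker_ids)]
    per_marker = in_catalog.groupby("marker_id")["count"].sum()
    found = int((per_marker >= 1).sum())
    duplicated = int((per_marker >= 2).sum())
    return CompletenessReport(found, total, found / total, duplicated)


def duplicated_marker_count(hits: pd.DataFrame, scaffold_ids: Sequence[str]) -> int:
    """Number of distinct markers with total count >= 2 across the given scaffolds."""
    sub = hits[hits["scaffold_id"].isin(set(scaffold_ids))]
    if len(sub) == 0:
        return 0
    per_marker = sub.groupby("marker_id")["count"].sum()
    return int((per_marker >= 2).sum())


def quality_flag(
    completeness: float,
    duplicated: int,
    near_complete_floor: float = 0.90,
    high_floor: float = 0.95,
    duplication_cap: int = 5,
) -> str:
    """Categorize a bin: 'high' (>95% complete), 'near_complete' (>90%), else 'partial'.

    Both quality tiers additionally require the duplicated-marker count to stay
    at or below ``duplication_cap``; a heavily duplicated bin is 'partial'
    regardless of completeness. Thresholds are strict inequalities.
    """
    if duplicated > duplication_cap:
        return "partial"
    if completeness > high_floor:
        return "high"
    if completeness > near_complete_floor:
        return "near_complete"
    return "partial"
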