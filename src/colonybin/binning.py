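"""Differential-coverage binning of scaffolds with composition-based refinement.

Scaffolds from the same population share a depth-of-coverage vector across
colony samples in which populations differ in abundance. Plotting the three
per-sample coverages against each other places each population on its own
cloud; this module replaces the interactive selection of those clouds with
deterministic density clustering (DBSCAN semantics) in log10 coverage space.

Bins that still carry many duplicated single-copy markers — the signature of
two populations with coincidentally similar coverage — are refined by
projecting their scaffolds onto the first two principal components of their
tetranucleotide frequencies plus a standardized-GC axis and splitting by
2-means; a split is kept only when it reduces the duplicated-marker count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN, KMeans
from sklearn.decomposition import PCA

from .markers import MarkerCatalog, bin_completeness, duplicated_marker_count, quality_flag
from .mda import StandardizationTable

NOISE = -1


class BinningError(ValueError):
    pass


@dataclass
class CoverageMatrix:
    """Per-scaffold mean depth in each sample chosen for binning."""

    scaffold_ids: tuple[str, ...]
    depths: np.ndarray  # scaffold x sample
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if self.depths.shape != (len(self.scaffold_ids), len(self.sample_ids)):
            raise BinningError("depth matrix shape must be (n_scaffolds, n_samples)")
        if (self.depths < 0).any():
            raise BinningError("depths must be non-negative")

    @classmethod
    def from_coverage(
        cls, coverage_by_sample: Mapping[str, pd.Series], scaffold_ids: Sequence[str]
    ) -> "CoverageMatrix":
        cols = [
            coverage_by_sample[s].reindex(scaffold_ids, fill_value=0.0).to_numpy()
            for s in coverage_by_sample
        ]
        return cls(tuple(scaffold_ids), np.column_stack(cols), tuple(coverage_by_sample))


def coverage_space(
    matrix: CoverageMatrix, pseudocount: float = 0.01, allow_any_samples: bool = False
) -> np.ndarray:
    """log10(depth + pseudocount), the 3D space scaffolds are clustered in.

    The pseudocount keeps zero-coverage scaffolds finite (populations absent
    from a colony are common); three samples are required unless the N-sample
    generalization is explicitly enabled.
    """
    if len(matrix.sample_ids) != 3 and not allow_any_samples:
        raise BinningError(
            f"coverage space expects exactly 3 samples, got {len(matrix.sample_ids)} "
            "(pass allow_any_samples=True to generalize)"
        )
    if pseudocount <= 0:
        raise BinningError("pseudocount must be positive")
    return np.log10(matrix.depths + pseudocount)


def cluster_scaffolds(
    points: np.ndarray,
    min_cluster_size: int = 10,
    neighborhood_radius: float = 0.3,
    length_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Density-based clustering of log-coverage points; noise labeled -1.

    A point whose neighborhood (Euclidean radius, point included) holds at
    least ``min_cluster_size`` points — or that much total length when
    ``length_weights`` is given — is a core point; clusters are the connected
    components of core points plus their reachable neighbors. Labels are
    renumbered by first appearance so identical inputs give identical labels.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) == 0:
        raise BinningError("no points to cluster")
    if neighborhood_radius <= 0:
        raise BinningError("neighborhood radius must be positive")
    model = DBSCAN(eps=neighborhood_radius, min_samples=min_cluster_size)
    raw = model.fit(points, sample_weight=length_weights).labels_
    # renumber cluster labels in order of first appearance
    mapping: dict[int, int] = {}
    labels = np.full(len(raw), NOISE, dtype=int)
    for i, lab in enumerate(raw):
        if lab == -1:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        labels[i] = mapping[lab]
    return labels


# ---------------------------------------------------------------------------
# composition-based refinement


def refine_bin(
    scaffold_ids: Sequence[str],
    gc: np.ndarray,
    tnf: np.ndarray,
    marker_hits: pd.DataFrame,
    max_duplicated: int = 5,
    lengths: np.ndarray | None = None,
) -> list[list[str]]:
    """Split a mixed bin by tetranucleotide composition and GC, recursively.

    A bin whose duplicated-marker count is at or below ``max_duplicated`` is
    returned unchanged. Otherwise its scaffolds are projected onto the first
    two principal components of their TNF matrix with standardized GC as a
    third axis and split by 2-means seeded from the two most GC-distant
    members (deterministic). When scaffold ``lengths`` are given the 2-means
    is length-weighted: TNF sampling noise shrinks with scaffold length, so
    long scaffolds anchor the centroids while short ones are merely assigned.
    The split is accepted only when it lowers the total duplicated-marker
    count, and accepted sub-bins are refined again.
    """
    ids = list(scaffold_ids)
    dup = duplicated_marker_count(marker_hits, ids)
    if dup <= max_duplicated or len(ids) < 2:
        return [ids]
    gc = np.asarray(gc, dtype=float)
    tnf = np.asarray(tnf, dtype=float)
    weights = None if lengths is None else np.asarray(lengths, dtype=float)

    n_pc = min(2, len(ids) - 1, tnf.shape[1])
    pcs = PCA(n_components=n_pc, svd_solver="full").fit_transform(tnf)
    # all axes standardized to unit variance so no axis dominates 2-means
    feats = np.column_stack([pcs, gc])
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    feats = (feats - feats.mean(axis=0)) / sd

    i_lo, i_hi = int(np.argmin(gc)), int(np.argmax(gc))
    init = feats[[i_lo, i_hi]]
    if i_lo == i_hi or np.allclose(init[0], init[1]):
        order = np.lexsort(feats.T[::-1])
        init = feats[[order[0], order[-1]]]
        if np.allclose(init[0], init[1]):  # degenerate: all members identical
            return [ids]
    assign = KMeans(n_clusters=2, init=init, n_init=1, max_iter=300).fit(
        feats, sample_weight=weights
    ).labels_
    left = [ids[i] for i in np.nonzero(assign == 0)[0]]
    right = [ids[i] for i in np.nonzero(assign == 1)[0]]
    if not left or not right:
        return [ids]
    dup_after = duplicated_marker_count(marker_hits, left) + duplicated_marker_count(
        marker_hits, right
    )
    if dup_after >= dup:
        return [ids]
    out: list[list[str]] = []
    for side in (left, right):
        mask = np.isin(ids, side)
        out.extend(
            refine_bin(side, gc[mask], tnf[mask], marker_hits, max_duplicated,
                       None if weights is None else weights[mask])
        )
    return out


def refine_labels(
    labels: np.ndarray,
    scaffold_ids: Sequence[str],
    gc: np.ndarray,
    tnf: np.ndarray,
    marker_hits: pd.DataFrame,
    max_duplicated: int = 5,
    lengths: np.ndarray | None = None,
) -> np.ndarray:
    """Apply refine_bin to every cluster; returns renumbered labels (noise kept)."""
    labels = np.asarray(labels)
    ids = np.asarray(scaffold_ids)
    new = np.full(len(labels), NOISE, dtype=int)
    next_label = 0
    for lab in [l for l in dict.fromkeys(labels) if l != NOISE]:
        mask = labels == lab
        pieces = refine_bin(ids[mask], np.asarray(gc)[mask], np.asarray(tnf)[mask],
                            marker_hits, max_duplicated,
                            None if lengths is None else np.asarray(lengths)[mask])
        for piece in pieces:
            new[np.isin(ids, piece)] = next_label
            next_label += 1
    return new


# ---------------------------------------------------------------------------
# bin assembly and reporting


@dataclass
class GenomeBin:
    """A putative population genome: member scaffolds plus quality statistics."""

    bin_id: str
    scaffold_ids: tuple[str, ...]
    n_contigs: int
    total_length: int
    gc: float
    found_markers: int
    catalog_size: int
    completeness: float
    n_duplicated_markers: int
    quality: str
    abundance: dict[str, float] = field(default_factory=dict)  # per sample + "overall", percent


def assemble_bins(
    labels: np.ndarray,
    profile_df: pd.DataFrame,
    marker_hits: pd.DataFrame,
    catalog: MarkerCatalog,
    reads_per_scaffold: pd.DataFrame | None = None,
    factors: StandardizationTable | None = None,
    max_duplicated: int = 5,
) -> tuple[list[GenomeBin], list[str]]:
    """Summary statistics per bin; returns (bins, noise scaffold ids).

    ``profile_df`` must carry scaffold_id, length and gc; ``reads_per_scaffold``
    (scaffold x sample mapped-read counts) enables standardized relative
    abundance per sample plus the pooled overall value, corrected by the
    per-GC-bin ``factors`` when given.
    """
    labels = np.asarray(labels)
    if len(labels) != len(profile_df):
        raise BinningError("labels must cover all scaffolds")
    ids = profile_df["scaffold_id"].to_numpy()
    lengths = profile_df["length"].to_numpy(dtype=float)
    gcs = profile_df["gc"].to_numpy(dtype=float)

    corrected = None
    if reads_per_scaffold is not None:
        fac = np.ones(len(profile_df))
        if factors is not None:
            fac = np.array([factors.factor_for(g) for g in gcs])
        counts = reads_per_scaffold.reindex(ids, fill_value=0.0)
        corrected = counts.mul(fac, axis=0)

    bins: list[GenomeBin] = []
    for k, lab in enumerate(l for l in dict.fromkeys(labels) if l != NOISE):
        mask = labels == lab
        member_ids = tuple(ids[mask])
        total_len = int(lengths[mask].sum())
        gc = float(np.average(gcs[mask], weights=lengths[mask]))
        hits = marker_hits[marker_hits["scaffold_id"].isin(member_ids)]
        rep = bin_completeness(hits, catalog)
        abundance: dict[str, float] = {}
        if corrected is not None:
            for sample in corrected.columns:
                denom = corrected[sample].sum()
                abundance[sample] = (
                    100.0 * corrected.loc[list(member_ids), sample].sum() / denom
                    if denom > 0 else 0.0
                )
            grand = corrected.to_numpy().sum()
            abundance["overall"] = (
                100.0 * corrected.loc[list(member_ids)].to_numpy().sum() / grand
                if grand > 0 else 0.0
            )
        bins.append(
            GenomeBin(
                bin_id=f"bin_{k + 1}",
                scaffold_ids=member_ids,
                n_contigs=int(mask.sum()),
                total_length=total_len,
                gc=gc,
                found_markers=rep.found,
                catalog_size=rep.total,
                completeness=rep.completeness,
                n_duplicated_markers=rep.duplicated,
                quality=quality_flag(rep.completeness, rep.duplicated,
                                     duplication_cap=max_duplicated),
                abundance=abundance,
            )
        )
    noise_ids = [str(s) for s in ids[labels == NOISE]]
    return bins, noise_ids


def bin_summary_table(bins: Sequence[GenomeBin]) -> pd.DataFrame:
    """One row per bin with the standard accounting columns."""
    rows = []
    for b in bins:
        row = {
            "bin_id": b.bin_id,
            "n_contigs": b.n_contigs,
            "total_length_bp": b.total_length,
            "gc_pct": round(100 * b.gc, 2),
            "essential_genes": f"{b.found_markers}/{b.catalog_size}",
            "completeness_pct": round(100 * b.completeness, 2),
            "n_duplicated_essential_genes": b.n_duplicated_markers,
            "quality": b.quality,
        }
        for sample, value in b.abundance.items():
            row[f"abundance_{sample}_pct"] = round(value, 4)
        rows.append(row)
    return pd.DataFrame(rows)


def extract_bin_reads(alignments: pd.DataFrame, bin_scaffold_ids: Sequence[str]) -> set[str]:
    """Read-pair ids with at least one mate primarily aligned to a bin scaffold.

    Both mates of a selected pair are meant to be emitted downstream (the
    re-assembly hook); this returns the selected pair id set.
    """
    if "mate" not in alignments.columns:
        raise BinningError("alignment table must carry mate flags")
    members = set(bin_scaffold_ids)
    hit = alignments["scaffold_id"].isin(members)
    return set(alignments.loc[hit, "read_id"])


def write_bin_fastas(
    bins: Sequence[GenomeBin], sequences: Mapping[str, str], outdir: str | Path
) -> list[Path]:
    """Write one FASTA per bin (60-column wrapped); returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for b in bins:
        path = outdir / f"{b.bin_id}.fasta"
        with open(path, "w") as fh:
            for sid in b.scaffold_ids:
                fh.write(f">{sid}\n")
                seq = sequences[sid]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        paths.append(path)
    return paths
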