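"""Hierarchical clustering of per-sample genus-level abundance profiles.

Colonies of the same morphospecies host similar microbial communities, so
their genus-level abundance profiles cluster together — replicate colonies
come out as sister leaves of the dendrogram. This module consumes an
abundance table (taxonomic classification itself is upstream and external),
keeps the genera that actually differ across samples, and clusters samples
by average linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist

METRICS = ("euclidean", "braycurtis")


class ClusteringError(ValueError):
    pass


def normalize_profiles(table: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize a sample x genus table to relative abundances."""
    if (table.to_numpy() < 0).any():
        raise ClusteringError("abundances must be non-negative")
    sums = table.sum(axis=1)
    if (sums == 0).any():
        raise ClusteringError(f"all-zero sample rows: {list(table.index[sums == 0])}")
    return table.div(sums, axis=0)


def select_differential_genera(table: pd.DataFrame, min_range: float = 0.001) -> pd.DataFrame:
    """Keep genera whose cross-sample abundance range (max - min) >= min_range."""
    if len(table) < 2:
        raise ClusteringError("need at least 2 samples")
    ranges = table.max(axis=0) - table.min(axis=0)
    return table.loc[:, ranges >= min_range]


@dataclass
class SampleDendrogram:
    """Result of agglomerative clustering: linkage matrix over ordered leaves."""

    sample_ids: tuple[str, ...]
    linkage_matrix: np.ndarray

    def merge_table(self) -> pd.DataFrame:
        z = self.linkage_matrix
        return pd.DataFrame(
            {
                "left": z[:, 0].astype(int),
                "right": z[:, 1].astype(int),
                "height": z[:, 2],
                "size": z[:, 3].astype(int),
            }
        )

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        root = to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.6g}"
            inner = ",".join(walk(c, node.dist) for c in (node.left, node.right))
            return f"({inner}):{length:.6g}"

        inner = ",".join(walk(c, root.dist) for c in (root.left, root.right))
        return f"({inner});"

    def sisters(self, a: str, b: str) -> bool:
        """True when leaves a and b merge with each other before anything else."""
        ia, ib = self.sample_ids.index(a), self.sample_ids.index(b)
        for left, right, _, _ in self.linkage_matrix:
            if {int(left), int(right)} == {ia, ib}:
                return True
        return False


def cluster_samples(
    table: pd.DataFrame, linkage_method: str = "average", metric: str = "euclidean"
) -> SampleDendrogram:
    """Average-linkage agglomerative clustering of sample profiles.

    Samples are ordered lexicographically first so that distance ties break
    the same way regardless of input order. Bray-Curtis requires every row to
    have positive total abundance.
    """
    if len(table) < 2:
        raise ClusteringError("need at least 2 samples")
    if metric not in METRICS:
        raise ClusteringError(f"metric must be one of {METRICS}")
    table = table.loc[sorted(table.index.astype(str))]
    data = table.to_numpy(dtype=float)
    if metric == "braycurtis" and (data.sum(axis=1) == 0).any():
        raise ClusteringError("bray-curtis is undefined for all-zero sample rows")
    dists = pdist(data, metric=metric)
    z = linkage(dists, method=linkage_method)
    return SampleDendrogram(tuple(table.index.astype(str)), z)


def read_abundance_table(path: str | Path) -> pd.DataFrame:
    """Tab-separated abundance table: first column sample ids, rest genera."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return normalize_profiles(df)
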