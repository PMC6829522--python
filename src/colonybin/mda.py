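"""GC-bias standardization of MDA-amplified metagenomes.

Multiple displacement amplification over-amplifies low-GC DNA. Comparing the
GC distribution of the amplified metagenome against an unamplified bulk
sample yields a per-GC-bin standardization factor,

    factor(bin) = bulk_fraction(bin) / amplified_fraction(bin),

which corrects per-scaffold read counts before relative abundances are
computed. Bins occupied only in the amplified sample borrow the nearest
occupied bin's factor and are flagged as smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class BiasError(ValueError):
    pass


@dataclass(frozen=True)
class GcHistogram:
    """Share of total weight per GC bin; bins are half-open [k, k+width) percent."""

    fractions: pd.Series  # indexed by bin lower edge (percent)
    bin_width: float = 1.0

    def occupied_bins(self) -> np.ndarray:
        return self.fractions.index[self.fractions > 0].to_numpy()


def gc_bin(gc: float, bin_width: float = 1.0) -> float:
    """Lower edge (percent) of the GC bin containing ``gc`` (a fraction in [0,1])."""
    pct = min(gc * 100.0, np.nextafter(100.0, 0))  # gc == 1 goes to the top bin
    return float(np.floor(pct / bin_width) * bin_width)


def gc_histogram(items: Iterable[tuple[float, float]], bin_width: float = 1.0) -> GcHistogram:
    """Weight-summed, normalized GC histogram from (gc_fraction, weight) items.

    The weight is the caller's choice of currency — scaffold length, scaffold
    count (weight 1), or mapped reads.
    """
    items = list(items)
    if not items:
        raise BiasError("cannot build a GC histogram from no items")
    gcs = np.array([g for g, _ in items], dtype=float)
    weights = np.array([w for _, w in items], dtype=float)
    if (weights <= 0).any():
        raise BiasError("weights must be positive")
    if ((gcs < 0) | (gcs > 1)).any():
        raise BiasError("gc values must lie in [0, 1]")
    edges = np.array([gc_bin(g, bin_width) for g in gcs])
    series = pd.Series(weights).groupby(edges).sum().sort_index()
    return GcHistogram(series / series.sum(), bin_width)


@dataclass(frozen=True)
class StandardizationTable:
    """Per-GC-bin correction factors with a smoothing flag per bin."""

    factors: pd.Series   # indexed by bin lower edge (percent)
    smoothed: pd.Series  # bool, aligned with factors
    bin_width: float = 1.0

    def factor_for(self, gc: float) -> float:
        """Factor of the bin containing ``gc``; nearest occupied bin if absent."""
        edge = gc_bin(gc, self.bin_width)
        if edge in self.factors.index:
            return float(self.factors[edge])
        nearest = self.factors.index[np.argmin(np.abs(self.factors.index.to_numpy() - edge))]
        return float(self.factors[nearest])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gc_bin": self.factors.index.to_numpy(),
                "factor": self.factors.to_numpy(),
                "smoothed": self.smoothed.to_numpy().astype(int),
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def read(cls, path: str | Path, bin_width: float = 1.0) -> "StandardizationTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            pd.Series(df["factor"].to_numpy(), index=df["gc_bin"].to_numpy()),
            pd.Series(df["smoothed"].astype(bool).to_numpy(), index=df["gc_bin"].to_numpy()),
            bin_width,
        )


def standardization_factors(amplified: GcHistogram, bulk: GcHistogram) -> StandardizationTable:
    """Per-bin factors bulk/amplified over every bin the amplified sample occupies.

    Bins occupied in the amplified sample but absent from the bulk sample get
    the factor of the nearest bulk-and-amplified-occupied bin, flagged as
    smoothed (an extrapolation, inevitable when the amplified assembly reaches
    GC ranges the shallower bulk sample missed).
    """
    if amplified.bin_width != bulk.bin_width:
        raise BiasError("histograms must share a bin width")
    amp_bins = amplified.occupied_bins()
    common = np.array(sorted(set(amp_bins) & set(bulk.occupied_bins())))
    if common.size == 0:
        raise BiasError("no GC bin occupied in both amplified and bulk samples")
    factors: dict[float, float] = {}
    smoothed: dict[float, bool] = {}
    for b in common:
        factors[b] = float(bulk.fractions[b] / amplified.fractions[b])
        smoothed[b] = False
    for b in amp_bins:
        if b not in factors:
            nearest = common[np.argmin(np.abs(common - b))]
            factors[b] = factors[nearest]
            smoothed[b] = True
    idx = sorted(factors)
    return StandardizationTable(
        pd.Series([factors[b] for b in idx], index=idx),
        pd.Series([smoothed[b] for b in idx], index=idx),
        amplified.bin_width,
    )


def corrected_read_count(
    scaffolds: Iterable[tuple[str, float, float]], factors: StandardizationTable
) -> float:
    """Sum of mapped_reads x factor(gc bin) over (scaffold_id, gc, mapped_reads)."""
    return float(sum(reads * factors.factor_for(gc) for _, gc, reads in scaffolds))


def standardized_abundance(
    bin_scaffolds: Sequence[tuple[str, float, float]],
    total_corrected: float,
    factors: StandardizationTable,
) -> float:
    """Standardized relative abundance (percent) of one bin.

    Each scaffold's mapped-read count is multiplied by its GC bin's factor;
    the bin's corrected total is expressed as a percentage of the corrected
    total over all scaffolds (the caller-supplied denominator), so abundances
    over a full partition of the scaffolds sum to 100%.
    """
    if total_corrected <= 0:
        raise BiasError("total corrected read count must be positive")
    return 100.0 * corrected_read_count(bin_scaffolds, factors) / total_corrected
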