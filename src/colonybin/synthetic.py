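"""Synthetic single-colony metagenomes with planted ground truth.

This module emulates the statistical structure that differential-coverage
binning of colony metagenomes relies on:

* a handful of bacterial genomes spanning a wide GC range, each with its own
  k-mer composition (per-genome G-vs-C and A-vs-T skews on top of the GC
  target, so near-identical-GC genomes remain separable by tetranucleotide
  frequencies);
* several "colony" samples whose per-genome abundance vectors differ strongly
  — the signal that makes coverage vectors cluster by genome;
* a whole-genome-amplification (MDA) step that preferentially accepts low-GC
  fragments, and an unbiased "bulk" sample to standardize against;
* fragmentation of genomes into scaffold-like pieces >= 1 kbp with known
  origin, standing in for a metagenome assembly;
* planted single-copy marker tags for exact completeness accounting.

Everything is seeded and deterministic; truth tables record the genome of
origin of every read pair and scaffold.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from ._seq import BASES, decode, encode, gc_prefix_sums
from .markers import MarkerCatalog


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SyntheticGenome:
    """A simulated genome: sequence, GC target, and planted marker intervals.

    ``marker_positions`` holds (marker_id, start, end) in 0-based half-open
    coordinates; marker tags replace background bases, so the genome length is
    exactly the requested length.
    """

    genome_id: str
    sequence: str
    target_gc: float
    marker_positions: tuple[tuple[str, int, int], ...] = ()

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s)


@dataclass
class AbundanceDesign:
    """Genome x sample abundance weights; columns normalize to 1.

    Differential-coverage binning is only identifiable when at least one
    genome changes strongly across samples; a warning is emitted when no
    genome has a max/min cross-sample ratio >= 5.
    """

    matrix: np.ndarray
    genome_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.genome_ids), len(self.sample_ids)):
            raise SimulationError("design matrix shape must be (n_genomes, n_samples)")
        if (self.matrix < 0).any():
            raise SimulationError("abundance weights must be non-negative")
        colsums = self.matrix.sum(axis=0)
        if (colsums == 0).any():
            bad = [s for s, c in zip(self.sample_ids, colsums) if c == 0]
            raise SimulationError(f"degenerate design: all-zero column(s) {bad}")
        self.matrix = self.matrix / colsums
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = self.matrix.max(axis=1) / self.matrix.min(axis=1)
        if not (ratios >= 5).any():
            warnings.warn(
                "no genome has a cross-sample abundance ratio >= 5; "
                "differential-coverage binning may be unidentifiable",
                stacklevel=2,
            )

    def column(self, sample_id: str) -> np.ndarray:
        return self.matrix[:, self.sample_ids.index(sample_id)]


@dataclass(frozen=True)
class MdaBiasModel:
    """Single-parameter GC bias of multiple displacement amplification.

    A fragment of GC fraction g is accepted with probability proportional to
    exp(-beta * (g - reference_gc)); beta = 0 is unbiased, and for beta > 0
    the weight is strictly decreasing in GC, emulating MDA's preference for
    low-GC templates.
    """

    beta: float = 0.0
    reference_gc: float = 0.5

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise SimulationError("bias strength beta must be non-negative")

    def weight(self, gc: np.ndarray | float) -> np.ndarray | float:
        return np.exp(-self.beta * (np.asarray(gc, dtype=float) - self.reference_gc))

    def acceptance_probability(self, gc: np.ndarray | float) -> np.ndarray | float:
        # weight normalized by its maximum over gc in [0, 1] (at gc = 0)
        return np.exp(-self.beta * np.asarray(gc, dtype=float))


@dataclass
class TruthTable:
    """Planted origin of every simulated read pair and scaffold."""

    reads: dict[str, str] = field(default_factory=dict)
    scaffolds: dict[str, str] = field(default_factory=dict)

    def add_reads(self, mapping: dict[str, str]) -> None:
        dup = self.reads.keys() & mapping.keys()
        if dup:
            raise SimulationError(f"read ids emitted twice: {sorted(dup)[:3]}...")
        self.reads.update(mapping)

    def write(self, reads_path: str | Path | None = None, scaffolds_path: str | Path | None = None) -> None:
        if reads_path is not None:
            pd.DataFrame(self.reads.items(), columns=["read_id", "genome_id"]).to_csv(
                reads_path, sep="\t", index=False
            )
        if scaffolds_path is not None:
            pd.DataFrame(self.scaffolds.items(), columns=["scaffold_id", "genome_id"]).to_csv(
                scaffolds_path, sep="\t", index=False
            )

    @classmethod
    def read(cls, reads_path: str | Path | None = None, scaffolds_path: str | Path | None = None) -> "TruthTable":
        tt = cls()
        if reads_path is not None:
            df = pd.read_csv(reads_path, sep="\t")
            tt.reads = dict(zip(df["read_id"], df["genome_id"]))
        if scaffolds_path is not None:
            df = pd.read_csv(scaffolds_path, sep="\t")
            tt.scaffolds = dict(zip(df["scaffold_id"], df["genome_id"]))
        return tt


@dataclass(frozen=True)
class Scaffold:
    """A scaffold-like genome piece; start/end locate it on its source genome."""

    scaffold_id: str
    sequence: str
    genome_id: str | None = None
    start: int | None = None
    end: int | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SimulatedSample:
    """Paired reads of one sample plus the fragment coordinates behind them."""

    sample_id: str
    r1: list[tuple[str, str, str]]  # (title, sequence, quality)
    r2: list[tuple[str, str, str]]
    fragments: pd.DataFrame  # pair_id, genome_id, start, end


# ---------------------------------------------------------------------------
# genome generation

# the 64 codons as 2-bit base-code triplets, in (A,C,G,T)-digit order
_CODON_CODES = np.array(
    [(i // 16, (i // 4) % 4, i % 4) for i in range(64)], dtype=np.int8
)
_CODON_GC = ((_CODON_CODES == 1) | (_CODON_CODES == 2)).sum(axis=1)


def _codon_distribution(
    rng: np.random.Generator,
    bg_gc: float,
    gc_skew: float,
    at_skew: float,
    sigma: float,
) -> np.ndarray:
    """Genome-specific codon distribution with mean codon GC = 3 * bg_gc.

    Starts from the product distribution of the (skewed) base probabilities,
    perturbs it by i.i.d. log-normal factors exp(sigma * Z) — the genome's
    private codon-usage signature — and exponentially tilts it in codon GC
    count to restore the GC target exactly in expectation.
    """
    base_p = np.array(
        [
            (1 - bg_gc) * at_skew,        # A
            bg_gc * (1 - gc_skew),        # C
            bg_gc * gc_skew,              # G
            (1 - bg_gc) * (1 - at_skew),  # T
        ]
    )
    base_p = base_p / base_p.sum()
    q = base_p[_CODON_CODES[:, 0]] * base_p[_CODON_CODES[:, 1]] * base_p[_CODON_CODES[:, 2]]
    q = q * np.exp(sigma * rng.normal(size=64))
    q = q / q.sum()
    target = 3.0 * bg_gc
    if 0.0 < bg_gc < 1.0 and sigma > 0:
        from scipy.optimize import brentq

        def mean_gc(log_t: float) -> float:
            w = q * np.exp(log_t * _CODON_GC)
            return float((w * _CODON_GC).sum() / w.sum()) - target

        log_t = brentq(mean_gc, -60.0, 60.0, xtol=1e-12)
        q = q * np.exp(log_t * _CODON_GC)
        q = q / q.sum()
    return q


def generate_genome(
    genome_id: str,
    length: int,
    target_gc: float,
    n_markers: int,
    catalog: MarkerCatalog | None,
    seed: int,
    gc_skew: float | None = None,
    at_skew: float | None = None,
    codon_sigma: float = 0.4,
    max_placement_tries: int = 1000,
) -> SyntheticGenome:
    """Generate a genome of i.i.d. codons at the target GC with planted markers.

    Background sequence is drawn as i.i.d. triplets from a genome-specific
    codon distribution (seeded log-normal perturbation of strength
    ``codon_sigma`` around the base-product distribution, GC-tilted back to
    the target). Codon usage is what gives real genomes of similar GC their
    distinct tetranucleotide signatures; with ``codon_sigma=0`` the model
    degrades to plain i.i.d. bases, whose canonical (strand-pooled) TNF is
    determined by GC and skews alone. ``gc_skew`` is the G share of G+C and
    ``at_skew`` the A share of A+T; when not given they are drawn from
    U(0.35, 0.65). The whole-genome GC (markers included) realizes the target:
    the background target is adjusted for the ~50%-GC marker tags.
    ``n_markers`` distinct catalog tags are placed at uniform non-overlapping
    positions, each exactly once, replacing the background bases there.
    """
    if length < 10_000:
        raise SimulationError("genome length must be >= 10 kbp")
    if not (0 <= target_gc <= 1):
        raise SimulationError("target_gc must lie in [0, 1]")
    if n_markers > 0 and (catalog is None or catalog.sequences is None):
        raise SimulationError("a sequence-bearing catalog is required to plant markers")
    if catalog is not None and n_markers > catalog.size:
        raise SimulationError("n_markers exceeds catalog size")

    rng = np.random.default_rng(seed)
    if gc_skew is None:
        gc_skew = float(rng.uniform(0.35, 0.65))
    if at_skew is None:
        at_skew = float(rng.uniform(0.35, 0.65))

    # choose and place markers first so background GC can compensate for them
    placements: list[tuple[str, int, int]] = []
    marker_bases = 0
    marker_gc = 0
    if n_markers > 0:
        chosen = rng.choice(catalog.marker_ids, size=n_markers, replace=False)
        occupied: list[tuple[int, int]] = []
        for mid in chosen:
            tag = catalog.sequences[str(mid)]
            mlen = len(tag)
            for _ in range(max_placement_tries):
                start = int(rng.integers(0, length - mlen + 1))
                end = start + mlen
                if all(end <= s or start >= e for s, e in occupied):
                    occupied.append((start, end))
                    placements.append((str(mid), start, end))
                    marker_bases += mlen
                    marker_gc += tag.count("G") + tag.count("C")
                    break
            else:
                raise SimulationError(
                    f"could not place marker {mid} in genome {genome_id} "
                    f"after {max_placement_tries} tries"
                )
        placements.sort(key=lambda p: p[1])

    # background GC adjusted so that the full genome (markers included) hits target
    if length > marker_bases:
        bg_gc = (target_gc * length - marker_gc) / (length - marker_bases)
        bg_gc = min(max(bg_gc, 0.0), 1.0)
    else:
        bg_gc = target_gc
    q = _codon_distribution(rng, bg_gc, gc_skew, at_skew, codon_sigma)
    n_codons = length // 3 + 1
    codons = rng.choice(64, size=n_codons, p=q)
    codes = _CODON_CODES[codons].reshape(-1)[:length].copy()
    for mid, start, end in placements:
        codes[start:end] = encode(catalog.sequences[mid])
    return SyntheticGenome(genome_id, decode(codes), target_gc, tuple(placements))


# ---------------------------------------------------------------------------
# read simulation


def default_quality_profile(read_len: int) -> np.ndarray:
    """Per-position Phred scores: Q38 at the 5' end easing to Q32 at the 3' end."""
    return np.round(np.linspace(38, 32, read_len)).astype(int)


def _quality_string(profile: np.ndarray) -> str:
    return "".join(chr(int(q) + 33) for q in profile)


def _simulate_sample(
    genomes: Sequence[SyntheticGenome],
    weights: np.ndarray,
    n_pairs: int,
    read_len: int,
    insert_mean: float,
    insert_sd: float,
    error_rate: float,
    bias: MdaBiasModel,
    rng: np.random.Generator,
    sample_id: str,
    quality: str,
) -> SimulatedSample:
    w = np.asarray(weights, dtype=float)
    if w.sum() == 0:
        raise SimulationError(f"degenerate design: all-zero weights for sample {sample_id}")
    w = w / w.sum()
    lengths = np.array([g.length for g in genomes])
    enc = [encode(g.sequence) for g in genomes]
    offsets = np.concatenate([[0], np.cumsum(lengths + 1)])[:-1]
    big_cum = np.concatenate([gc_prefix_sums(g.sequence) for g in genomes])

    acc_g: list[np.ndarray] = []
    acc_s: list[np.ndarray] = []
    acc_l: list[np.ndarray] = []
    got = 0
    est_accept = 1.0
    while got < n_pairs:
        batch = int(max(4096, 1.3 * (n_pairs - got) / max(est_accept, 0.02)))
        gi = rng.choice(len(genomes), size=batch, p=w)
        ins = np.round(rng.normal(insert_mean, insert_sd, size=batch)).astype(np.int64)
        ins = np.clip(ins, read_len, lengths[gi])
        start = np.floor(rng.random(batch) * (lengths[gi] - ins + 1)).astype(np.int64)
        base = offsets[gi] + start
        gc = (big_cum[base + ins] - big_cum[base]) / ins
        keep = rng.random(batch) < bias.acceptance_probability(gc)
        est_accept = max(float(keep.mean()), 0.02)
        acc_g.append(gi[keep])
        acc_s.append(start[keep])
        acc_l.append(ins[keep])
        got += int(keep.sum())
    gi = np.concatenate(acc_g)[:n_pairs]
    start = np.concatenate(acc_s)[:n_pairs]
    ins = np.concatenate(acc_l)[:n_pairs]

    r1: list[tuple[str, str, str]] = []
    r2: list[tuple[str, str, str]] = []
    pair_ids = [f"{sample_id}.p{i}" for i in range(n_pairs)]
    for i in range(n_pairs):
        g, s, L = int(gi[i]), int(start[i]), int(ins[i])
        fwd = enc[g][s : s + read_len].copy()
        rev = (3 - enc[g][s + L - read_len : s + L][::-1]).astype(np.int8)
        if error_rate > 0:
            for frag in (fwd, rev):
                nerr = rng.binomial(read_len, error_rate)
                if nerr:
                    pos = rng.choice(read_len, size=nerr, replace=False)
                    frag[pos] = (frag[pos] + rng.integers(1, 4, size=nerr)) % 4
        pid = pair_ids[i]
        r1.append((f"{pid}/1", decode(fwd), quality))
        r2.append((f"{pid}/2", decode(rev), quality))
    fragments = pd.DataFrame(
        {
            "pair_id": pair_ids,
            "genome_id": [genomes[g].genome_id for g in gi],
            "start": start,
            "end": start + ins,
        }
    )
    return SimulatedSample(sample_id, r1, r2, fragments)


def simulate_colony_reads(
    genomes: Sequence[SyntheticGenome],
    design: AbundanceDesign,
    n_pairs: int,
    read_len: int = 150,
    insert_mean: float = 300,
    insert_sd: float = 30,
    error_rate: float = 0.005,
    bias: MdaBiasModel = MdaBiasModel(),
    seed: int = 0,
    quality_profile: np.ndarray | None = None,
) -> tuple[dict[str, SimulatedSample], TruthTable]:
    """Simulate MDA-amplified paired-end reads for every sample of a design.

    Fragments are drawn genome-proportional to the design weights, positioned
    uniformly, and accepted with probability proportional to
    exp(-beta * (gc - reference_gc)). Reads are the fragment's two ends (mate 2
    reverse-complemented) with i.i.d. substitution errors. The truth table
    records each pair's source genome.
    """
    if n_pairs < 1:
        raise SimulationError("n_pairs must be >= 1")
    if read_len >= insert_mean:
        raise SimulationError("read_len must be smaller than insert_mean")
    if quality_profile is None:
        quality_profile = default_quality_profile(read_len)
    quality = _quality_string(np.asarray(quality_profile)[:read_len])
    rng = np.random.default_rng(seed)
    truth = TruthTable()
    samples: dict[str, SimulatedSample] = {}
    for j, sid in enumerate(design.sample_ids):
        sample = _simulate_sample(
            genomes, design.matrix[:, j], n_pairs, read_len, insert_mean, insert_sd,
            error_rate, bias, rng, sid, quality,
        )
        samples[sid] = sample
        truth.add_reads(dict(zip(sample.fragments["pair_id"], sample.fragments["genome_id"])))
    return samples, truth


def simulate_bulk_reads(
    genomes: Sequence[SyntheticGenome],
    weights: Sequence[float],
    n_pairs: int,
    sample_id: str = "bulk",
    **kwargs,
) -> tuple[SimulatedSample, TruthTable]:
    """Simulate the unamplified bulk sample: identical to a colony sample with beta = 0."""
    kwargs.pop("bias", None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # a single column cannot be differential
        design = AbundanceDesign(np.asarray(weights, dtype=float)[:, None],
                                 tuple(g.genome_id for g in genomes), (sample_id,))
        samples, truth = simulate_colony_reads(
            genomes, design, n_pairs, bias=MdaBiasModel(beta=0.0), **kwargs
        )
    return samples[sample_id], truth


# ---------------------------------------------------------------------------
# fragmentation into scaffolds


def fragment_to_scaffolds(
    genomes: Sequence[SyntheticGenome],
    min_len: int = 1000,
    mean_len: float = 5000,
    seed: int = 0,
    protect_markers: bool = True,
) -> tuple[list[Scaffold], TruthTable, float]:
    """Cut genomes at geometric-spaced breakpoints into scaffold-like pieces.

    Pieces shorter than ``min_len`` are discarded (their total share is
    returned as the discarded fraction). Geometric spacing yields the wide,
    assembly-like scaffold length distribution. With ``protect_markers`` a
    breakpoint falling inside a planted marker is pushed to the marker's end,
    so completeness truth stays exact; disable it to stress-test sensitivity
    to split markers.
    """
    if min_len < 1000:
        raise SimulationError("min_len must be >= 1000 bases")
    if mean_len < min_len:
        raise SimulationError("mean_len must be >= min_len")
    rng = np.random.default_rng(seed)
    scaffolds: list[Scaffold] = []
    truth = TruthTable()
    discarded = 0
    total = 0
    counter = 0
    for genome in genomes:
        L = genome.length
        total += L
        starts = [s for _, s, _ in genome.marker_positions]
        ends = [e for _, _, e in genome.marker_positions]
        pos = 0
        while pos < L:
            piece = int(rng.geometric(1.0 / mean_len))
            end = min(pos + piece, L)
            if protect_markers and end < L:
                k = bisect_right(starts, end - 1) - 1
                if k >= 0 and starts[k] < end < ends[k]:
                    end = min(ends[k], L)
            if end - pos >= min_len:
                sid = f"scf_{counter:05d}"
                counter += 1
                scaffolds.append(
                    Scaffold(sid, genome.sequence[pos:end], genome.genome_id, pos, end)
                )
                truth.scaffolds[sid] = genome.genome_id
            else:
                discarded += end - pos
            pos = end
    return scaffolds, truth, discarded / total if total else 0.0


def synthetic_alignments(
    sample: SimulatedSample, scaffolds: Sequence[Scaffold], read_len: int = 150
) -> pd.DataFrame:
    """Truth-based read-to-scaffold alignment table for a simulated sample.

    Stands in for an external aligner: each mate's genomic interval is
    assigned to the scaffold it overlaps most (ties to the leftmost), with
    ``aligned_bases`` equal to the overlap; mates falling entirely in
    discarded inter-scaffold gaps are unmapped and produce no record.
    """
    per_genome: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for gid in {s.genome_id for s in scaffolds}:
        gs = sorted((s for s in scaffolds if s.genome_id == gid), key=lambda s: s.start)
        per_genome[gid] = (
            np.array([s.start for s in gs]),
            np.array([s.end for s in gs]),
            [s.scaffold_id for s in gs],
        )
    rows: list[tuple[str, str, int, int]] = []
    frags = sample.fragments
    for gid, sub in frags.groupby("genome_id", sort=False):
        if gid not in per_genome:
            continue
        starts, ends, ids = per_genome[gid]
        for mate, (a_vec, b_vec) in enumerate(
            (
                (sub["start"].to_numpy(), sub["start"].to_numpy() + read_len),
                (sub["end"].to_numpy() - read_len, sub["end"].to_numpy()),
            ),
            start=1,
        ):
            i0 = np.searchsorted(ends, a_vec, side="right")
            best_ov = np.zeros(len(sub), dtype=np.int64)
            best_ix = np.full(len(sub), -1, dtype=np.int64)
            for k in range(3):  # a mate (<= read_len bases) spans at most a few pieces
                ix = i0 + k
                valid = ix < len(starts)
                ov = np.zeros(len(sub), dtype=np.int64)
                ov[valid] = np.maximum(
                    0,
                    np.minimum(ends[ix[valid]], b_vec[valid])
                    - np.maximum(starts[ix[valid]], a_vec[valid]),
                )
                better = ov > best_ov
                best_ov[better] = ov[better]
                best_ix[better] = ix[better]
            pair_ids = sub["pair_id"].to_numpy()
            for i in np.nonzero(best_ov > 0)[0]:
                rows.append((pair_ids[i], ids[best_ix[i]], int(best_ov[i]), mate))
    return pd.DataFrame(rows, columns=["read_id", "scaffold_id", "aligned_bases", "mate"])


# ---------------------------------------------------------------------------
# genus-level abundance profiles (replicate-clustering bench)


def simulate_genus_profiles(
    n_species: int = 3,
    n_replicates: int = 2,
    n_genera: int = 30,
    noise_sd: float = 0.10,
    seed: int = 0,
    species_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Genus-level relative-abundance table for replicated colony samples.

    Each species gets a Dirichlet base profile over genera; replicates are the
    base profile under i.i.d. log-normal noise, renormalized. Within-species
    distances are therefore much smaller than between-species distances, the
    structure behind replicate samples clustering as sisters.
    """
    rng = np.random.default_rng(seed)
    if species_names is None:
        species_names = [f"sp{i + 1}" for i in range(n_species)]
    rows = {}
    for s in range(n_species):
        base = rng.dirichlet(np.full(n_genera, 0.5))
        for r in range(n_replicates):
            prof = base * np.exp(rng.normal(0.0, noise_sd, size=n_genera))
            rows[f"{species_names[s]}-{r + 1}"] = prof / prof.sum()
    genera = [f"genus_{i:03d}" for i in range(n_genera)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=genera)
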