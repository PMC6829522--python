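"""End-to-end pipeline: simulate -> trim -> profile -> factors -> bin -> assess
-> extract -> report.

In synthetic mode the pipeline generates a colony community with planted
ground truth, bypassing the external assembler and aligner through truth
tables, and finishes with a per-genome recovery evaluation. In real-data mode
it consumes assembled scaffolds (FASTA) plus per-sample alignment tables and
runs the same downstream stages. Every stage's parameters and outputs are
logged to a JSON manifest; a rerun with the same config reproduces the
tables byte for byte.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import binning, mda, profiles, qc, synthetic
from .markers import MarkerCatalog, detect_markers, import_marker_hits

FLOAT_FORMAT = "%.6g"
STAGES = ("simulate", "trim", "profile", "factors", "bin", "assess", "extract", "report")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All stage parameters, seeds and paths of one pipeline run."""

    mode: str = "synthetic"
    seed: int = 0
    # synthetic community
    genomes: list[dict] = field(default_factory=list)  # genome_id, length, gc, n_markers, skews
    sample_ids: list[str] = field(default_factory=list)
    design: list[list[float]] = field(default_factory=list)  # genome x sample
    bulk_weights: list[float] | None = None
    n_pairs: int = 50_000
    read_len: int = 150
    insert_mean: float = 300
    insert_sd: float = 30
    error_rate: float = 0.005
    beta: float = 2.0
    reference_gc: float = 0.5
    catalog_size: int = 107
    tag_length: int = 60
    scaffold_min_len: int = 1000
    scaffold_mean_len: float = 5000
    # trimming
    trim: dict = field(default_factory=dict)
    # binning
    pseudocount: float = 0.01
    neighborhood_radius: float = 0.3
    min_cluster_size: int = 10
    max_duplicated: int = 5
    # real-data inputs
    scaffolds_fasta: str | None = None
    alignment_tables: dict[str, str] = field(default_factory=dict)
    binning_samples: list[str] = field(default_factory=list)
    marker_hits_table: str | None = None
    bulk_sample_id: str | None = None
    # outputs
    write_fastq_subsets: bool = False

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict:
        return asdict(self)


def default_config(seed: int = 0, n_pairs: int = 50_000) -> PipelineConfig:
    """The default synthetic colony community.

    Five 200-kbp genomes span the GC range observed across colony-associated
    populations (42% to 68.5%); two of them sit at nearly the same high GC
    (0.676 vs 0.685) and share an abundance vector, so coverage alone cannot
    separate them and the composition refinement must. Three colony samples
    carry strongly differential abundances; amplification bias beta = 2.
    """
    genomes = [
        {"genome_id": "g1_lowgc", "length": 200_000, "gc": 0.42, "n_markers": 105,
         "gc_skew": 0.50, "at_skew": 0.50},
        {"genome_id": "g2_midgc", "length": 200_000, "gc": 0.50, "n_markers": 105,
         "gc_skew": 0.45, "at_skew": 0.55},
        {"genome_id": "g3_midgc", "length": 200_000, "gc": 0.54, "n_markers": 105,
         "gc_skew": 0.55, "at_skew": 0.45},
        {"genome_id": "g4_highgc", "length": 200_000, "gc": 0.676, "n_markers": 105,
         "gc_skew": 0.35, "at_skew": 0.65},
        {"genome_id": "g5_highgc", "length": 200_000, "gc": 0.685, "n_markers": 105,
         "gc_skew": 0.65, "at_skew": 0.35},
    ]
    design = [
        [0.60, 0.05, 0.05],
        [0.05, 0.60, 0.05],
        [0.05, 0.05, 0.55],
        [0.15, 0.15, 0.175],
        [0.15, 0.15, 0.175],
    ]
    return PipelineConfig(
        mode="synthetic",
        seed=seed,
        genomes=genomes,
        sample_ids=["aeruginosa", "wesenbergii", "panniformis"],
        design=design,
        n_pairs=n_pairs,
    )


def _subseed(seed: int, offset: int) -> int:
    return (int(seed) + offset) % (2**31 - 1)


# ---------------------------------------------------------------------------
# stages (synthetic mode)


def _stage_simulate(cfg: PipelineConfig, state: dict, outdir: Path) -> dict:
    catalog = MarkerCatalog.synthetic(cfg.catalog_size, cfg.tag_length, _subseed(cfg.seed, 11))
    genomes = [
        synthetic.generate_genome(
            spec["genome_id"], spec["length"], spec["gc"], spec.get("n_markers", 0),
            catalog, _subseed(cfg.seed, 101 + i),
            gc_skew=spec.get("gc_skew"), at_skew=spec.get("at_skew"),
        )
        for i, spec in enumerate(cfg.genomes)
    ]
    design = synthetic.AbundanceDesign(
        np.asarray(cfg.design, dtype=float),
        tuple(g.genome_id for g in genomes),
        tuple(cfg.sample_ids),
    )
    scaffolds, scaffold_truth, discarded = synthetic.fragment_to_scaffolds(
        genomes, cfg.scaffold_min_len, cfg.scaffold_mean_len, _subseed(cfg.seed, 7)
    )
    bias = synthetic.MdaBiasModel(beta=cfg.beta, reference_gc=cfg.reference_gc)
    samples, read_truth = synthetic.simulate_colony_reads(
        genomes, design, cfg.n_pairs, cfg.read_len, cfg.insert_mean, cfg.insert_sd,
        cfg.error_rate, bias, _subseed(cfg.seed, 23),
    )
    bulk_w = cfg.bulk_weights or design.matrix.mean(axis=1).tolist()
    bulk, bulk_truth = synthetic.simulate_bulk_reads(
        genomes, bulk_w, cfg.n_pairs, seed=_subseed(cfg.seed, 37),
        read_len=cfg.read_len, insert_mean=cfg.insert_mean, insert_sd=cfg.insert_sd,
        error_rate=cfg.error_rate,
    )
    all_samples = dict(samples)
    all_samples["bulk"] = bulk

    for sid, sample in all_samples.items():
        qc.write_fastq(outdir / f"raw_{sid}_R1.fastq", sample.r1)
        qc.write_fastq(outdir / f"raw_{sid}_R2.fastq", sample.r2)
    with open(outdir / "scaffolds.fasta", "w") as fh:
        for s in scaffolds:
            fh.write(f">{s.scaffold_id}\n")
            for i in range(0, len(s.sequence), 60):
                fh.write(s.sequence[i : i + 60] + "\n")
    read_truth.scaffolds = scaffold_truth.scaffolds
    read_truth.add_reads(dict(zip(bulk.fragments["pair_id"], bulk.fragments["genome_id"])))
    read_truth.write(outdir / "truth_reads.tsv", outdir / "truth_scaffolds.tsv")

    alignments = {
        sid: synthetic.synthetic_alignments(sample, scaffolds, cfg.read_len)
        for sid, sample in all_samples.items()
    }
    for sid, table in alignments.items():
        table.to_csv(outdir / f"aln_{sid}.tsv", sep="\t", index=False)

    state.update(
        catalog=catalog, genomes=genomes, scaffolds=scaffolds, truth=read_truth,
        alignments=alignments, colony_samples=list(cfg.sample_ids),
    )
    return {
        "n_genomes": len(genomes),
        "n_scaffolds": len(scaffolds),
        "discarded_fraction": round(discarded, 4),
        "n_pairs_per_sample": cfg.n_pairs,
        "samples": list(all_samples),
    }


def _stage_trim(cfg: PipelineConfig, state: dict, outdir: Path) -> dict:
    policy = qc.TrimPolicy(**cfg.trim)
    counts = {}
    for sid in state["colony_samples"] + ["bulk"]:
        summary = qc.trim_pairs(
            outdir / f"raw_{sid}_R1.fastq", outdir / f"raw_{sid}_R2.fastq",
            outdir / f"trimmed_{sid}", policy,
        )
        counts[sid] = {
            "both_kept": summary.both_kept, "r1_only": summary.r1_only,
            "r2_only": summary.r2_only, "both_dropped": summary.both_dropped,
        }
    return {"policy": asdict(policy), "pairs": counts}


def _stage_profile(cfg: PipelineConfig, state: dict, outdir: Path) -> dict:
    lengths = {s.scaffold_id: s.length for s in state["scaffolds"]}
    coverage = {
        sid: profiles.compute_coverage(tbl, lengths)
        for sid, tbl in state["alignments"].items()
    }
    profile_df, tnf = profiles.scaffold_profile_table(state["scaffolds"], coverage)
    profile_df.to_csv(outdir / "profiles.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
    state.update(profile_df=profile_df, tnf=tnf, coverage=coverage, lengths=lengths)
    n50 = profiles.compute_n50(list(lengths.values()))
    return {
        "n_scaffolds": len(profile_df),
        "total_length_bp": int(profile_df["length"].sum()),
        "n50_bp": n50,
        "samples": list(coverage),
    }


def _reads_per_scaffold(state: dict, sample_ids: list[str]) -> pd.DataFrame:
    cols = {}
    for sid in sample_ids:
        tbl = state["alignments"][sid]
        cols[sid] = tbl.groupby("scaffold_id")["read_id"].count()
    ids = [s.scaffold_id for s in state["scaffolds"]] if "scaffolds" in state else list(
        state["lengths"]
    )
    return pd.DataFrame(cols).reindex(ids, fill_value=0).astype(float)


def _stage_factors(cfg: PipelineConfig, state: dict, outdir: Path) -> dict:
    bulk_id = cfg.bulk_sample_id or "bulk"
    if bulk_id not in state["alignments"]:
        state["factors"] = None
        return {"skipped": f"no bulk sample {bulk_id!r}; abundances left uncorrected"}
    profile_df = state["profile_df"]
    gc_by_sid = dict(zip(profile_df["scaffold_id"], profile_df["gc"]))
    counts = _reads_per_scaffold(state, state["colony_samples"] + [bulk_id])
    amplified_reads = counts[state["colony_samples"]].sum(axis=1)
    bulk_reads = counts[bulk_id]
    amp_hist = mda.gc_histogram(
        [(gc_by_sid[sid], w) for sid, w in amplified_reads.items() if w > 0]
    )
    bulk_hist = mda.gc_histogram(
        [(gc_by_sid[sid], w) for sid, w in bulk_reads.items() if w > 0]
    )
    factors = mda.standardization_factors(amp_hist, bulk_hist)
    factors.write(outdir / "factors.tsv")
    state["factors"] = factors
    return {
        "n_bins": len(factors.factors),
        "n_smoothed": int(factors.smoothed.sum()),
        "weighting": "mapped reads",
    }


def _stage_bin(cfg: PipelineConfig, state: dict, outdir: Path) -> dict:
    profile_df = state["profile_df"]
    binning_samples = cfg.binning_samples or state["colony_samples"]
    matrix = binning.CoverageMatrix.from_coverage(
        {sid: state["coverage"][sid] for sid in binning_samples},
        list(profile_df["scaffold_id"]),
    )
    points = binning.coverage_space(matrix, cfg.pseudocount)
    labels = binning.cluster_scaffolds(
        points, cfg.min_cluster_size, cfg.neighborhood_radius
    )
    n_initial = len(set(labels) - {binning.NOISE})
    hits = state.get("marker_hits")
    if hits is None:
        hits = detect_markers(
            [(s.scaffold_id, s.sequence) for s in state["scaffolds"]], state["catalog"]
        )
        state["marker_hits"] = hits
    labels = binning.refine_labels(
        labels, profile_df["scaffold_id"], profile_df["gc"].to_numpy(),
        state["tnf"], hits, cfg.max_duplicated,
        lengths=profile_df["length"].to_numpy(),
    )
    state["labels"] = labels
    pd.DataFrame(
        {"scaffold_id": profile_df["scaffold_id"], "bin": labels}
    ).to_csv(outdir / "labels.tsv", sep="\t", index=False)
    return {
        "binning_samples": list(binning_samples),
        "neighborhood_radius": cfg.neighborhood_radius,
        "min_cluster_size": cfg.min_cluster_size,
        "n_initial_bins": n_initial,
        "n_bins_after_refinement": len(set(labels) - {binning.NOISE}),
        "n_noise_scaffolds": int((labels == binning.NOISE).sum()),
    }


def _stage_assess(cfg: PipelineConfig, state: dict, outdir: Path) -> dict:
    counts = _reads_per_scaffold(state, state["colony_samples"])
    bins, noise_ids = binning.assemble_bins(
        state["labels"], state["profile_df"], state["marker_hits"], state["catalog"],
        reads_per_scaffold=counts, factors=state.get("factors"),
        max_duplicated=cfg.max_duplicated,
    )
    state.update(bins=bins, noise_ids=noise_ids)
    table = binning.bin_summary_table(bins)
    table.to_csv(outdir / "bins.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
    sequences = {s.scaffold_id: s.sequence for s in state["scaffolds"]}
    binning.write_bin_fastas(bins, sequences, outdir / "bin_fastas")
    return {
        "n_bins": len(bins),
        "n_noise_scaffolds": len(noise_ids),
        "quality": {b.bin_id: b.quality for b in bins},
    }


def _stage_extract(cfg: PipelineConfig, state: dict, outdir: Path) -> dict:
    aln = pd.concat(
        [state["alignments"][sid] for sid in state["colony_samples"]], ignore_index=True
    )
    pair_dir = outdir / "bin_reads"
    pair_dir.mkdir(parents=True, exist_ok=True)
    n_pairs = {}
    for b in state["bins"]:
        pair_ids = sorted(binning.extract_bin_reads(aln, b.scaffold_ids))
        (pair_dir / f"{b.bin_id}.pairs.txt").write_text("\n".join(pair_ids) + "\n")
        n_pairs[b.bin_id] = len(pair_ids)
        if cfg.write_fastq_subsets:
            _write_pair_subset(outdir, state["colony_samples"], set(pair_ids),
                               pair_dir, b.bin_id)
    return {"pairs_per_bin": n_pairs, "fastq_subsets": cfg.write_fastq_subsets}


def _write_pair_subset(outdir: Path, sample_ids: list[str], wanted: set[str],
                       pair_dir: Path, bin_id: str) -> None:
    for mate in (1, 2):
        records = []
        for sid in sample_ids:
            for title, seq, quals in qc.read_fastq(outdir / f"raw_{sid}_R{mate}.fastq"):
                if qc._pair_key(title) in wanted:
                    records.append((title, seq, quals))
        qc.write_fastq(pair_dir / f"{bin_id}_R{mate}.fastq", records)


def _stage_report(cfg: PipelineConfig, state: dict, outdir: Path) -> dict:
    summary = binning.bin_summary_table(state["bins"])
    summary.to_csv(outdir / "report.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
    info: dict[str, Any] = {"n_bins": len(state["bins"])}
    truth = state.get("truth")
    if truth is not None and truth.scaffolds:
        evaluation = evaluate_bins(
            state["bins"], truth.scaffolds,
            dict(zip(state["profile_df"]["scaffold_id"], state["profile_df"]["length"])),
        )
        evaluation.to_csv(outdir / "evaluation.tsv", sep="\t", index=False,
                          float_format=FLOAT_FORMAT)
        info["min_recall"] = round(float(evaluation["recall"].min()), 4)
        info["min_precision"] = round(float(evaluation["precision"].min()), 4)
    return info


def evaluate_bins(
    bins: list[binning.GenomeBin],
    scaffold_truth: Mapping[str, str],
    lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Length-weighted recovery of each planted genome.

    recall: fraction of a genome's total scaffold length landing in its best
    bin; precision: fraction of that bin's length coming from its majority
    genome. Scaffolds left as noise count against recall.
    """
    genome_total: dict[str, float] = {}
    for sid, gid in scaffold_truth.items():
        genome_total[gid] = genome_total.get(gid, 0.0) + lengths[sid]
    # per-bin, per-genome length
    bin_comp: dict[str, dict[str, float]] = {}
    for b in bins:
        comp: dict[str, float] = {}
        for sid in b.scaffold_ids:
            gid = scaffold_truth.get(sid)
            if gid is not None:
                comp[gid] = comp.get(gid, 0.0) + lengths[sid]
        bin_comp[b.bin_id] = comp
    rows = []
    for gid in sorted(genome_total):
        best_bin, best_len = None, 0.0
        for bid, comp in bin_comp.items():
            if comp.get(gid, 0.0) > best_len:
                best_bin, best_len = bid, comp[gid]
        precision = 0.0
        if best_bin is not None:
            comp = bin_comp[best_bin]
            precision = max(comp.values()) / sum(comp.values())
        rows.append(
            {
                "genome_id": gid,
                "assigned_bin": best_bin or "none",
                "genome_length_bp": int(genome_total[gid]),
                "recall": best_len / genome_total[gid],
                "precision": precision,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# real-data entry points


def _load_real_inputs(cfg: PipelineConfig, state: dict) -> None:
    from Bio import SeqIO

    if not cfg.scaffolds_fasta:
        raise PipelineError("real-data mode requires 'scaffolds_fasta'")
    path = Path(cfg.scaffolds_fasta)
    if not path.exists():
        raise PipelineError(f"scaffold FASTA not found: {path}")
    scaffolds = [
        synthetic.Scaffold(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    scaffolds = profiles.filter_scaffolds(scaffolds, cfg.scaffold_min_len)
    alignments = {}
    for sid, p in cfg.alignment_tables.items():
        p = Path(p)
        if not p.exists():
            raise PipelineError(f"alignment table not found: {p}")
        if p.suffix in {".sam", ".bam"}:
            alignments[sid] = profiles.alignment_table_from_sam(p)
        else:
            alignments[sid] = profiles.read_alignment_table(p)
    hits = None
    if cfg.marker_hits_table:
        hits = import_marker_hits(cfg.marker_hits_table)
    state.update(
        scaffolds=scaffolds, alignments=alignments, truth=None,
        colony_samples=cfg.binning_samples or list(alignments),
        marker_hits=hits,
        catalog=MarkerCatalog(tuple(f"marker_{i:03d}" for i in range(cfg.catalog_size))),
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run all stages; returns (and writes) the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    manifest: dict = {"config": config.to_dict(), "stages": []}
    stage_fns = {
        "simulate": _stage_simulate, "trim": _stage_trim, "profile": _stage_profile,
        "factors": _stage_factors, "bin": _stage_bin, "assess": _stage_assess,
        "extract": _stage_extract, "report": _stage_report,
    }
    for name in STAGES:
        if config.mode == "real" and name in ("simulate", "trim"):
            if name == "simulate":
                _load_real_inputs(config, state)
            manifest["stages"].append({"name": name, "skipped": "real-data mode"})
            continue
        t0 = time.monotonic()
        try:
            info = stage_fns[name](config, state, outdir)
        except Exception as exc:  # noqa: BLE001 - stage name must reach the user
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        manifest["stages"].append(
            {"name": name, "seconds": round(time.monotonic() - t0, 2), **info}
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
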