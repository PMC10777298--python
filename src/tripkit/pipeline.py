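"""End-to-end orchestration: simulate → extract → map → quantify → annotate → motif.

A single :class:`RunConfig` drives every stage with one seed; all
thresholds default to the reliability filter values (norm >= 5,
reads_r >= 10, freq1_r > 0.60).  Every stage writes its TSV next to
the report, the effective configuration is echoed to YAML for
provenance, and the final report is a pure function of the stage
outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import barcodes as bc
from . import expression as expr
from . import mapping as mp
from . import motif as mo
from . import simulate as sim
from ._util import ConfigurationError, load_fasta


@dataclass
class SimulateParams:
    n_insertions: int = 300
    mix: tuple[float, float, float, float] = (7, 7, 7, 1)
    silent_fraction: float = 0.55
    depth_normalization: float = 50.0
    depth_expression: float = 50.0
    depth_mapping: float = 20.0
    error_rate: float = 0.002
    read_length: int = 75
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 200_000, "chr2": 200_000}
    )
    gc: float = 0.41


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    outdir: str = "tripkit_run"
    seed: int = 0
    simulate: bool = True
    simulate_params: SimulateParams = field(default_factory=SimulateParams)
    # external inputs (used when simulate is False)
    genome_fasta: str | None = None
    gff: str | None = None
    chromatin_bed: str | None = None
    fastq_normalization: list[str] = field(default_factory=list)
    fastq_expression: list[str] = field(default_factory=list)
    fastq_mapping: list[str] = field(default_factory=list)
    mapping_paired: bool = True
    read_length: int = 75
    # stage parameters
    k: int = 20
    max_mismatch: int = 2
    anchor_mismatch: int = 1
    index_max_mismatch: int = 1
    collapse_max_distance: int = 2
    collapse_ratio: float = 0.1
    norm_min: int = 5
    reads_r_min: int = 10
    freq1_min: float = 0.60
    silence_threshold: float = 0.0
    top_fraction: float = 0.10
    motif_window: int = 10
    motif_cohort: str = "all"  # "all" or "filtered"

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        sp = data.pop("simulate_params", {})
        cfg = cls(**data)
        if isinstance(sp, dict):
            cfg.simulate_params = SimulateParams(**sp)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["simulate_params"]["mix"] = list(self.simulate_params.mix)
        return d


@dataclass
class Diagnostic:
    code: str
    message: str


def validate_inputs(config: RunConfig) -> list[Diagnostic]:
    """Machine-readable input diagnostics; an empty list means valid."""
    out: list[Diagnostic] = []
    table = bc.PromoterIndexTable()
    try:
        table.validate(config.index_max_mismatch)
    except ConfigurationError as e:
        out.append(Diagnostic("index_table_separation", str(e)))
    if not 0 < config.top_fraction <= 1:
        out.append(Diagnostic("bad_threshold", "top_fraction must be in (0, 1]"))
    if not 0 <= config.freq1_min <= 1:
        out.append(Diagnostic("bad_threshold", "freq1_min must be in [0, 1]"))
    if config.norm_min < 0 or config.reads_r_min < 0:
        out.append(Diagnostic("bad_threshold", "count thresholds must be >= 0"))
    if config.k < 12:
        out.append(Diagnostic("bad_threshold", "k must be >= 12"))
    if not config.simulate:
        for label, path in (
            ("genome_fasta", config.genome_fasta),
            ("gff", config.gff),
        ):
            if not path or not Path(path).exists():
                out.append(Diagnostic("missing_input", f"{label} not found: {path}"))
        for label, paths in (
            ("fastq_normalization", config.fastq_normalization),
            ("fastq_expression", config.fastq_expression),
            ("fastq_mapping", config.fastq_mapping),
        ):
            for p in paths:
                if not Path(p).exists():
                    out.append(Diagnostic("missing_input", f"{label} file not found: {p}"))
        if config.genome_fasta and Path(config.genome_fasta).exists():
            try:
                load_fasta(config.genome_fasta)
            except Exception as e:  # pragma: no cover - defensive
                out.append(Diagnostic("unparsable_fasta", str(e)))
    if config.chromatin_bed and Path(config.chromatin_bed).exists():
        try:
            ann.ChromatinIndex(ann.load_chromatin_bed(config.chromatin_bed))
        except ann.MalformedAnnotationError as e:
            out.append(Diagnostic("overlapping_segments", str(e)))
    if config.simulate:
        sp = config.simulate_params
        if not 0 <= sp.silent_fraction <= 1:
            out.append(Diagnostic("bad_threshold", "silent_fraction must be in [0, 1]"))
        if not 0 <= sp.error_rate < 0.05:
            out.append(Diagnostic("bad_threshold", "error_rate must be in [0, 0.05)"))
    return out


@dataclass
class RunResult:
    """All stage outputs of one run."""

    outdir: Path
    truth: pd.DataFrame | None
    transgenes: pd.DataFrame
    filtered: pd.DataFrame
    promoter_summary: pd.DataFrame
    annotated: pd.DataFrame
    enrichment: pd.DataFrame
    motif: mo.MotifMatrix
    report_text: str
    tallies: dict[str, Any]


class StageError(RuntimeError):
    def __init__(self, stage: str, reason: str):
        super().__init__(f"stage {stage!r} failed: {reason}")
        self.stage = stage


def _median_or_nan(series: pd.Series) -> float:
    return float(series.median()) if len(series) else float("nan")


def build_report(
    transgenes: pd.DataFrame,
    filtered: pd.DataFrame,
    promoter_summary: pd.DataFrame,
    annotated: pd.DataFrame,
    enrichment: pd.DataFrame,
    top_fraction: float,
) -> str:
    """Plain-text run report, recomputable from the stage tables alone."""
    lines = ["# tripkit run report", ""]
    lines.append("## Transgenes per promoter (all mapped)")
    counts = transgenes["promoter"].value_counts()
    total = int(counts.sum())
    for prom in sorted(counts.index):
        lines.append(f"  {prom:12s} {counts[prom]:5d}  ({100 * counts[prom] / total:.1f} %)")
    lines.append(f"  {'total':12s} {total:5d}")
    lines.append("")
    lines.append("## Promoter activity (filtered cohort)")
    for row in promoter_summary.itertuples():
        lines.append(
            f"  {row.promoter:12s} n={row.n:<4d} silent={row.n_silent:<4d} "
            f"expressed={row.n_expressed:<4d} median={row.median_expression:.3g} a.u. "
            f"fold_vs_baseline={row.fold_vs_baseline:.3g}"
        )
    lines.append("")
    top = expr.top_decile(annotated, top_fraction)
    lines.append(
        f"## Distances to nearest TSS/TTS (median, bp): all vs top {top_fraction:.0%}"
    )
    lines.append(
        f"  dist_tss  {_median_or_nan(annotated['dist_tss']):.0f} vs {_median_or_nan(top['dist_tss']):.0f}"
    )
    lines.append(
        f"  dist_tts  {_median_or_nan(annotated['dist_tts']):.0f} vs {_median_or_nan(top['dist_tts']):.0f}"
    )
    lines.append("")
    lines.append("## Element and chromatin proportions: all vs top cohort")
    for row in enrichment.itertuples():
        ratio = f"{row.ratio:.2f}" if np.isfinite(row.ratio) else "NA"
        lines.append(
            f"  [{row.category_type}] {row.category:40s} "
            f"{100 * row.prop_all:5.1f} % -> {100 * row.prop_top:5.1f} %  ratio {ratio}"
        )
    lines.append("")
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage in order and write all outputs under ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    diagnostics = validate_inputs(config)
    if diagnostics:
        raise StageError(
            "validate", "; ".join(f"{d.code}: {d.message}" for d in diagnostics)
        )

    tallies: dict[str, Any] = {}
    truth_df = None

    # --- stage: simulate or load inputs -----------------------------------
    if config.simulate:
        sp = config.simulate_params
        genome = sim.make_genome(
            sim.GenomeConfig(chromosomes=sp.chromosomes, gc=sp.gc), seed=config.seed
        )
        truth = sim.plant_insertions(
            genome,
            sp.n_insertions,
            mix=sp.mix,
            silent_fraction=sp.silent_fraction,
            seed=config.seed,
        )
        simout = sim.simulate_libraries(
            truth,
            genome,
            outdir,
            depths=sim.LibraryDepths(
                sp.depth_normalization, sp.depth_expression, sp.depth_mapping
            ),
            error_rate=sp.error_rate,
            seed=config.seed,
            layouts=sim.default_layouts(sp.read_length, config.mapping_paired),
        )
        genome.write_fasta(outdir / "genome.fa")
        genome.write_gff3(outdir / "genes.gff3")
        genome.write_bed(outdir / "chromatin.bed")
        sequences = genome.sequences
        genes = genome.gene_models
        segments = genome.chromatin_segments
        fq_norm = list(simout.fastq["normalization"])
        fq_expr = list(simout.fastq["expression"])
        fq_map = list(simout.fastq["mapping"])
        tallies["simulated_reads"] = simout.read_counts
        truth_df = pd.read_csv(simout.truth_path, sep="\t")
        read_length = sp.read_length
    else:
        if not config.genome_fasta or not config.gff:
            raise StageError("inputs", "genome_fasta and gff are required")
        sequences = load_fasta(config.genome_fasta)
        genes = ann.load_gene_models(config.gff)
        segments = (
            ann.load_chromatin_bed(config.chromatin_bed)
            if config.chromatin_bed
            else []
        )
        fq_norm = config.fastq_normalization
        fq_expr = config.fastq_expression
        fq_map = config.fastq_mapping
        read_length = config.read_length

    table = bc.PromoterIndexTable()
    layouts = sim.default_layouts(read_length, config.mapping_paired)

    # --- stage: extract + collapse ----------------------------------------
    try:
        raw_norm = bc.extract_library(
            fq_norm, layouts["normalization"], table,
            anchor_mismatch=config.anchor_mismatch,
            index_max_mismatch=config.index_max_mismatch,
        )
        raw_expr = bc.extract_library(
            fq_expr, layouts["expression"], table,
            anchor_mismatch=config.anchor_mismatch,
            index_max_mismatch=config.index_max_mismatch,
        )
        coll_norm, map_norm = bc.collapse_mutants(
            raw_norm, config.collapse_max_distance, config.collapse_ratio
        )
        coll_expr, map_expr = bc.collapse_mutants(
            raw_expr, config.collapse_max_distance, config.collapse_ratio
        )
    except Exception as e:
        raise StageError("extract", str(e)) from e
    raw_norm.write_tsv(outdir / "counts_normalization.tsv", coll_norm)
    raw_expr.write_tsv(outdir / "counts_expression.tsv", coll_expr)
    map_norm.write_tsv(outdir / "collapse_audit_normalization.tsv")
    map_expr.write_tsv(outdir / "collapse_audit_expression.tsv")
    tallies["extract"] = {
        lib: {
            "processed": int(t.processed[lib]),
            "assigned": int(t.total_assigned(lib)),
            "unassigned": int(t.unassigned[lib]),
            "malformed": int(t.malformed[lib]),
        }
        for lib, t in (("normalization", raw_norm), ("expression", raw_expr))
    }

    # --- stage: map --------------------------------------------------------
    try:
        kindex = mp.build_kmer_index(sequences, config.k)
        calls, residuals, map_tallies = mp.map_library(
            fq_map, kindex, layouts["mapping"], table,
            max_mismatch=config.max_mismatch,
            anchor_mismatch=config.anchor_mismatch,
            index_max_mismatch=config.index_max_mismatch,
        )
    except Exception as e:
        raise StageError("map", str(e)) from e
    calls_df = mp.write_insertions_tsv(calls, outdir / "insertions.tsv")
    mp.write_residuals_tsv(residuals, outdir / "mapping_residuals.tsv")
    tallies["map"] = dict(map_tallies)

    # --- stage: quantify ----------------------------------------------------
    try:
        records = expr.table_from_counts(coll_norm, coll_expr, config.norm_min)
        records = expr.classify_silent(records, config.silence_threshold)
        filtered = expr.apply_trip_filters(
            records, calls_df, config.norm_min, config.reads_r_min, config.freq1_min
        )
        summary = expr.promoter_summary(
            filtered, expr.PromoterSummaryOptions(top_fraction=config.top_fraction)
        )
    except Exception as e:
        raise StageError("quantify", str(e)) from e
    records.to_csv(outdir / "transgenes.tsv", sep="\t", index=False, float_format="%.6g")
    filtered.to_csv(
        outdir / "transgenes_filtered.tsv", sep="\t", index=False, float_format="%.6g"
    )
    summary.to_csv(
        outdir / "promoter_summary.tsv", sep="\t", index=False, float_format="%.6g"
    )
    tallies["quantify"] = filtered.attrs.get("drop_reasons", {})

    # --- stage: annotate ----------------------------------------------------
    try:
        annotated = ann.annotate_transgenes(filtered, genes, chromatin=segments or None)
        enrichment = ann.enrichment_report(annotated, top_fraction=config.top_fraction)
    except Exception as e:
        raise StageError("annotate", str(e)) from e
    annotated.to_csv(
        outdir / "transgenes_annotated.tsv", sep="\t", index=False, float_format="%.6g"
    )
    enrichment.to_csv(
        outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g"
    )

    # --- stage: motif -------------------------------------------------------
    try:
        cohort = annotated if config.motif_cohort == "filtered" else calls_df
        windows, skipped = mo.extract_windows(cohort, sequences, config.motif_window)
        matrix = mo.motif_matrix(windows, mo.genome_background(sequences))
    except Exception as e:
        raise StageError("motif", str(e)) from e
    matrix.write_tsv(outdir / "motif.tsv")
    tallies["motif"] = {"windows": len(windows), "skipped": skipped}

    report = build_report(
        calls_df, filtered, summary, annotated, enrichment, config.top_fraction
    )
    (outdir / "report.txt").write_text(report)
    with open(outdir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(tallies, fh, sort_keys=True)

    return RunResult(
        outdir=outdir,
        truth=truth_df,
        transgenes=records,
        filtered=filtered,
        promoter_summary=summary,
        annotated=annotated,
        enrichment=enrichment,
        motif=matrix,
        report_text=report,
        tallies=tallies,
    )
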