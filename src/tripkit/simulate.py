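"""Synthetic TRIP experiment generator.

Builds a toy genome (FASTA + GFF3 + BED chromatin segmentation), plants
barcoded piggyBac reporter insertions at TTAA tetranucleotides, and
emits the three amplicon libraries of a TRIP experiment as FASTQ:

* normalization — gDNA amplicons; read counts track clone abundance,
* expression    — cDNA amplicons; read counts track abundance × activity,
* mapping       — inverse-PCR amplicons joining each barcode to its
  genomic flank, bounded by the first downstream DpnII (GATC) site.

Everything is deterministic for a fixed seed.  The generator is the
package's stand-in for the undeposited CHO sequencing data: four
promoter classes mixed 7:7:7:1, a majority-silent activity
distribution, log-normal clone-abundance drift from a month of
unselected growth, and i.i.d. per-base substitution errors.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._util import (
    BASES,
    ConfigurationError,
    decode_seqs,
    encode_seqs,
    open_text,
    revcomp,
    write_fasta,
)
from .models import (
    ChromatinSegment,
    GeneModel,
    INDEX_BY_CLASS,
    PROMOTER_CLASSES,
    ReadLayout,
    Transcript,
)

# ---------------------------------------------------------------------------
# chromatin-state vocabulary (stand-in for an 11-state CHO-K1 segmentation)

DEFAULT_STATES: tuple[str, ...] = (
    "Active TSS",
    "Flanking active TSS",
    "Strong transcription (H3K36me3)",
    "Weak transcription",
    "Enhancer (H3K27ac high)",
    "Weak enhancer",
    "Bivalent TSS",
    "ZNF genes & repeats",
    "Quiescent/low",
    "Repressed heterochromatin (H3K9me3)",
    "Polycomb repressed regions (H3K27me3)",
)

# genome-coverage weights: the three inactive states dominate, mirroring
# mammalian segmentations where they cover most of the genome
DEFAULT_STATE_WEIGHTS: tuple[float, ...] = (
    0.01, 0.02, 0.03, 0.03, 0.01, 0.02, 0.005, 0.005, 0.60, 0.15, 0.13,
)

#: multiplicative effect of the local chromatin state on reporter activity
DEFAULT_STATE_FACTORS: dict[str, float] = {
    "Active TSS": 2.0,
    "Flanking active TSS": 2.0,
    "Strong transcription (H3K36me3)": 5.0,
    "Weak transcription": 1.5,
    "Enhancer (H3K27ac high)": 3.0,
    "Weak enhancer": 1.5,
    "Bivalent TSS": 0.8,
    "ZNF genes & repeats": 1.0,
    "Quiescent/low": 0.5,
    "Repressed heterochromatin (H3K9me3)": 0.3,
    "Polycomb repressed regions (H3K27me3)": 0.3,
}

#: median activity of each promoter class relative to short_EF1a
DEFAULT_PROMOTER_FACTORS: dict[str, float] = {
    "long_EF1a": 10.0,
    "short_EF1a": 1.0,
    "mPGK": 0.5,
    "PGK": 0.3,
}


@dataclass
class GenomeConfig:
    """Parameters of the toy genome.

    GC defaults to 0.41 (rodent-like); genes are placed sequentially
    with exponential spacing; chromatin segments tile each chromosome
    exactly once with state labels drawn by coverage weight.
    """

    chromosomes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 200_000, "chr2": 200_000}
    )
    gc: float = 0.41
    mean_gene_spacing: int = 8_000
    mean_segment_length: int = 5_000
    state_labels: Sequence[str] = DEFAULT_STATES
    state_weights: Sequence[float] | None = DEFAULT_STATE_WEIGHTS

    def __post_init__(self):
        if not self.chromosomes:
            raise ConfigurationError("at least one chromosome is required")
        for name, length in self.chromosomes.items():
            if length < 10_000:
                raise ConfigurationError(
                    f"chromosome {name!r} is too short ({length} bp) to host a gene; "
                    "minimum is 10 kb"
                )
        if not 0.0 < self.gc < 1.0:
            raise ConfigurationError("gc must be in (0, 1)")


@dataclass
class SyntheticGenome:
    """A toy genome: sequences, gene models and a chromatin segmentation."""

    sequences: dict[str, str]
    gene_models: list[GeneModel]
    chromatin_segments: list[ChromatinSegment]

    def state_at(self, chrom: str, position: int) -> str:
        """Chromatin state label covering a 1-based position."""
        for seg in self.chromatin_segments:
            if seg.chrom == chrom and seg.start <= position <= seg.end:
                return seg.state
        return "unassigned"

    def ttaa_sites(self, chrom: str) -> list[int]:
        """1-based start positions of every TTAA occurrence on a chromosome."""
        seq = self.sequences[chrom]
        out, i = [], seq.find("TTAA")
        while i != -1:
            out.append(i + 1)
            i = seq.find("TTAA", i + 1)
        return out

    def write_fasta(self, path) -> None:
        write_fasta(path, self.sequences)

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, seq in self.sequences.items():
                fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
            for gene in self.gene_models:
                c, s = gene.chrom, gene.strand
                fh.write(
                    f"{c}\ttripkit\tgene\t{gene.start}\t{gene.end}\t.\t{s}\t.\t"
                    f"ID={gene.gene_id}\n"
                )
                for tx in gene.transcripts:
                    fh.write(
                        f"{c}\ttripkit\tmRNA\t{tx.start}\t{tx.end}\t.\t{s}\t.\t"
                        f"ID={tx.transcript_id};Parent={gene.gene_id}\n"
                    )
                    for a, b in tx.exons:
                        fh.write(
                            f"{c}\ttripkit\texon\t{a}\t{b}\t.\t{s}\t.\t"
                            f"Parent={tx.transcript_id}\n"
                        )
                    for a, b in tx.cds:
                        fh.write(
                            f"{c}\ttripkit\tCDS\t{a}\t{b}\t.\t{s}\t0\t"
                            f"Parent={tx.transcript_id}\n"
                        )

    def write_bed(self, path) -> None:
        """Chromatin segmentation as BED4 (0-based half-open)."""
        with open(path, "w") as fh:
            for seg in self.chromatin_segments:
                fh.write(f"{seg.chrom}\t{seg.start - 1}\t{seg.end}\t{seg.state}\n")


@dataclass(frozen=True)
class GroundTruthInsertion:
    """A simulated transgene insertion at a TTAA target site.

    ``position`` is the 1-based coordinate of the first base of the
    TTAA on the plus strand, regardless of transgene orientation.
    ``true_activity`` is 0 for silent insertions.
    """

    barcode: str
    promoter_class: str
    promoter_index: str
    chrom: str
    position: int
    strand: str
    true_activity: float
    clone_abundance: float


# ---------------------------------------------------------------------------
# genome synthesis


def _make_gene(rng, chrom, gid, pos, limit):
    """Try to place one gene starting near `pos`; returns (gene, next_pos) or None."""
    n_ex = int(rng.integers(1, 7))
    exon_lens = rng.integers(300, 900, n_ex)
    intron_lens = rng.integers(500, 3000, max(n_ex - 1, 0))
    length = int(exon_lens.sum() + intron_lens.sum())
    if pos + length + 2000 > limit:
        return None
    exons = []
    cur = pos
    for i in range(n_ex):
        exons.append((cur, cur + int(exon_lens[i]) - 1))
        cur = exons[-1][1] + 1
        if i < n_ex - 1:
            cur += int(intron_lens[i])
    strand = "+" if rng.random() < 0.5 else "-"
    # carve UTRs out of the terminal exons to define a CDS
    u5 = int(rng.integers(60, 200))
    u3 = int(rng.integers(60, 200))
    lo_trim, hi_trim = (u5, u3) if strand == "+" else (u3, u5)
    cds_lo = exons[0][0] + lo_trim
    cds_hi = exons[-1][1] - hi_trim
    cds = [
        (max(a, cds_lo), min(b, cds_hi))
        for a, b in exons
        if min(b, cds_hi) >= max(a, cds_lo)
    ]
    tx = Transcript(f"{gid}.t1", tuple(exons), tuple(cds))
    gene = GeneModel(gid, chrom, strand, (tx,))
    return gene, exons[-1][1]


def make_genome(config: GenomeConfig | None = None, seed: int = 0) -> SyntheticGenome:
    """Generate a deterministic toy genome with genes and chromatin states.

    Raises :class:`ConfigurationError` if a chromosome cannot host a
    gene or if the realized sequence carries fewer than one TTAA per kb
    on average (insertion sites must exist downstream).
    """
    config = config or GenomeConfig()
    rng = np.random.default_rng([int(seed), 101])
    p = np.array(
        [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    )
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    segments: list[ChromatinSegment] = []

    weights = config.state_weights
    if weights is None:
        weights = [1.0] * len(config.state_labels)
    w = np.asarray(weights, dtype=float)
    if len(w) != len(config.state_labels) or (w < 0).any() or w.sum() == 0:
        raise ConfigurationError("state_weights must be non-negative, one per label")
    w = w / w.sum()

    for chrom, length in config.chromosomes.items():
        codes = rng.choice(4, size=length, p=p)
        seq = bytes(BASES[codes]).decode()
        sequences[chrom] = seq
        if seq.count("TTAA") < length / 1000:
            raise ConfigurationError(
                f"chromosome {chrom!r} has fewer than 1 TTAA per kb; "
                "lower the GC fraction"
            )
        # genes
        pos = 2000
        i = 0
        while True:
            made = _make_gene(rng, chrom, f"{chrom}.g{i + 1}", pos, length)
            if made is None:
                break
            gene, end = made
            genes.append(gene)
            i += 1
            pos = end + 1000 + int(rng.exponential(config.mean_gene_spacing))
        # chromatin tiling: exact cover, non-overlapping
        start = 1
        while start <= length:
            seg_len = max(200, int(rng.exponential(config.mean_segment_length)))
            end = min(start + seg_len - 1, length)
            state = config.state_labels[int(rng.choice(len(w), p=w))]
            segments.append(ChromatinSegment(chrom, start, end, state))
            start = end + 1

    return SyntheticGenome(sequences, genes, segments)


# ---------------------------------------------------------------------------
# insertion planting


def _draw_barcodes(rng, n: int, length: int, min_distance: int) -> list[str]:
    """Random barcodes with pairwise Hamming distance >= min_distance.

    Vectorised rejection sampling: draw the whole set, recompute the
    pairwise distance matrix, redraw offenders until the set separates.
    """
    codes = rng.integers(0, 4, size=(n, length), dtype=np.uint8)
    for _ in range(200):
        diff = (codes[:, None, :] != codes[None, :, :]).sum(axis=2)
        np.fill_diagonal(diff, length)
        bad = np.unique(np.argwhere(diff < min_distance)[:, 0])
        if bad.size == 0:
            return decode_seqs(codes)
        codes[bad] = rng.integers(0, 4, size=(bad.size, length), dtype=np.uint8)
    raise ConfigurationError(
        f"could not draw {n} barcodes of length {length} at pairwise distance "
        f">= {min_distance}"
    )


def plant_insertions(
    genome: SyntheticGenome,
    n: int,
    mix: Sequence[float] = (7, 7, 7, 1),
    silent_fraction: float = 0.55,
    seed: int = 0,
    *,
    promoter_factors: Mapping[str, float] = DEFAULT_PROMOTER_FACTORS,
    state_factors: Mapping[str, float] | None = None,
    activity_sigma: float = 1.0,
    abundance_sigma: float = 1.0,
    barcode_length: int = 18,
    min_barcode_distance: int = 5,
) -> list[GroundTruthInsertion]:
    """Plant ``n`` barcoded insertions at distinct TTAA sites.

    Promoter classes are drawn with probabilities proportional to
    ``mix`` in the order (long_EF1a, short_EF1a, mPGK, PGK) — the
    7:7:7:1 library mixing ratio by default.  Exactly
    ``round(silent_fraction * n)`` insertions are silent
    (``true_activity = 0``); active insertions draw a log-normal
    activity scaled by per-promoter and per-chromatin-state factors.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = np.asarray(mix, dtype=float)
    if mix.shape != (4,) or (mix < 0).any() or mix.sum() == 0:
        raise ValueError("mix must be 4 non-negative weights, not all zero")
    rng = np.random.default_rng([int(seed), 202])

    sites = [
        (chrom, pos) for chrom in genome.sequences for pos in genome.ttaa_sites(chrom)
    ]
    if len(sites) < n:
        raise ConfigurationError(
            f"genome has only {len(sites)} TTAA sites but {n} insertions requested"
        )
    chosen = rng.choice(len(sites), size=n, replace=False)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    classes = [PROMOTER_CLASSES[i] for i in rng.choice(4, size=n, p=mix / mix.sum())]
    barcodes = _draw_barcodes(rng, n, barcode_length, min_barcode_distance)

    n_silent = int(round(silent_fraction * n))
    silent = np.zeros(n, dtype=bool)
    if n_silent:
        silent[rng.choice(n, size=min(n_silent, n), replace=False)] = True

    sf = DEFAULT_STATE_FACTORS if state_factors is None else state_factors
    abundance = rng.lognormal(0.0, abundance_sigma, size=n)
    noise = rng.lognormal(0.0, activity_sigma, size=n)

    out = []
    for i in range(n):
        chrom, pos = sites[int(chosen[i])]
        assert genome.sequences[chrom][pos - 1 : pos + 3] == "TTAA"
        cls = classes[i]
        if silent[i]:
            activity = 0.0
        else:
            state = genome.state_at(chrom, pos)
            activity = (
                promoter_factors.get(cls, 1.0) * sf.get(state, 1.0) * float(noise[i])
            )
        out.append(
            GroundTruthInsertion(
                barcode=barcodes[i],
                promoter_class=cls,
                promoter_index=INDEX_BY_CLASS[cls],
                chrom=chrom,
                position=int(pos),
                strand=str(strands[i]),
                true_activity=activity,
                clone_abundance=float(abundance[i]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# library simulation


def insertion_flank(genome: SyntheticGenome, ins: GroundTruthInsertion) -> str:
    """Genomic flank of an insertion: TTAA through the first downstream GATC.

    Downstream is read in transgene orientation; '-' strand flanks are
    returned reverse-complemented so every flank starts with TTAA.  If
    no GATC exists before the chromosome end the flank runs to the end.
    The 4-base GATC site is retained (DpnII digestion leaves the site
    on the self-ligated circle).
    """
    seq = genome.sequences[ins.chrom]
    p0 = ins.position - 1  # 0-based TTAA start
    if ins.strand == "+":
        i = seq.find("GATC", p0 + 4)
        return seq[p0:] if i == -1 else seq[p0 : i + 4]
    i = seq.rfind("GATC", 0, p0)
    return revcomp(seq[: p0 + 4]) if i == -1 else revcomp(seq[i : p0 + 4])


@dataclass(frozen=True)
class LibraryDepths:
    """Mean reads per insertion for each library."""

    normalization: float = 50.0
    expression: float = 50.0
    mapping: float = 20.0


def default_layouts(read_length: int = 75, paired_mapping: bool = True):
    return {
        "normalization": ReadLayout("normalization", read_length=read_length, paired=False),
        "expression": ReadLayout("expression", read_length=read_length, paired=False),
        "mapping": ReadLayout("mapping", read_length=read_length, paired=paired_mapping),
    }


@dataclass
class SimulationOutput:
    """Paths and read-accounting for one simulated experiment."""

    fastq: dict[str, tuple[Path, ...]]
    truth_path: Path
    read_counts: dict[str, int]
    short_flank_barcodes: tuple[str, ...]


def _apply_errors(codes: np.ndarray, error_rate: float, rng) -> np.ndarray:
    if error_rate <= 0 or codes.size == 0:
        return codes
    mask = rng.random(codes.shape) < error_rate
    shift = rng.integers(1, 4, size=codes.shape, dtype=np.uint8)
    return np.where(mask, (codes + shift) % 4, codes)


def _emit_library(path_stem, name, cores, counts, read_length, error_rate, rng, outdir):
    """Expand per-insertion read cores to reads, pad, mutate, write FASTQ."""
    n_reads = int(np.sum(counts))
    L = read_length
    reads = rng.integers(0, 4, size=(n_reads, L), dtype=np.uint8)  # random pad
    row = 0
    for core, c in zip(cores, counts):
        if c == 0:
            continue
        m = min(len(core), L)
        reads[row : row + c, :m] = core[:m]
        row += c
    reads = _apply_errors(reads, error_rate, rng)
    path = Path(outdir) / f"{path_stem}.fastq"
    qual = "I" * L
    with open(path, "w") as fh:
        for i, seq in enumerate(decode_seqs(reads)):
            fh.write(f"@{name}_{i + 1:07d}\n{seq}\n+\n{qual}\n")
    return path, n_reads


def simulate_libraries(
    truth: Sequence[GroundTruthInsertion],
    genome: SyntheticGenome,
    outdir,
    *,
    layouts: Mapping[str, ReadLayout] | None = None,
    depths: LibraryDepths = LibraryDepths(),
    error_rate: float = 0.0,
    seed: int = 0,
    short_flank_threshold: int = 20,
) -> SimulationOutput:
    """Write the three FASTQ libraries plus the ground-truth TSV.

    Normalization counts are Poisson with rate ∝ clone abundance;
    expression counts Poisson with rate ∝ abundance × activity; mapping
    reads carry the barcode (R1) and the DpnII-bounded genomic flank
    (R2).  Substitution errors are applied i.i.d. per base.  Insertions
    whose flank is shorter than ``short_flank_threshold`` are still
    emitted but flagged ``short_flank`` in the truth TSV.
    """
    if not (0 <= error_rate < 0.05):
        raise ValueError("error_rate must be in [0, 0.05)")
    for d in (depths.normalization, depths.expression, depths.mapping):
        if d <= 0:
            raise ValueError("depths must be positive")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layouts = layouts or default_layouts()
    n = len(truth)
    rng_counts = np.random.default_rng([int(seed), 301])
    rng_norm = np.random.default_rng([int(seed), 302])
    rng_expr = np.random.default_rng([int(seed), 303])
    rng_map = np.random.default_rng([int(seed), 304])

    w = np.array([t.clone_abundance for t in truth])
    a = np.array([t.true_activity for t in truth])
    lam_norm = depths.normalization * w / w.mean()
    wa = w * a
    lam_expr = depths.expression * wa / wa.mean() if wa.sum() > 0 else np.zeros(n)
    counts_norm = rng_counts.poisson(lam_norm)
    counts_expr = rng_counts.poisson(lam_expr)
    counts_map = rng_counts.poisson(np.full(n, depths.mapping))

    def cassette(layout, t):
        return encode_seqs(
            [layout.constant_prefix + t.promoter_index + t.barcode]
        )[0]

    fastq: dict[str, tuple[Path, ...]] = {}
    read_counts: dict[str, int] = {}

    for kind, counts, rng in (
        ("normalization", counts_norm, rng_norm),
        ("expression", counts_expr, rng_expr),
    ):
        layout = layouts[kind]
        cores = [cassette(layout, t) for t in truth]
        path, total = _emit_library(
            kind, kind[:4], cores, counts, layout.read_length, error_rate, rng, outdir
        )
        fastq[kind] = (path,)
        read_counts[kind] = total

    # mapping library
    layout = layouts["mapping"]
    flanks = [insertion_flank(genome, t) for t in truth]
    short = tuple(
        t.barcode for t, f in zip(truth, flanks) if len(f) < short_flank_threshold
    )
    r2_cores = [encode_seqs([layout.flank_anchor + f])[0] for f in flanks]
    if layout.paired:
        r1_cores = [cassette(layout, t) for t in truth]
        p1, total = _emit_library(
            "mapping_R1", "map", r1_cores, counts_map, layout.read_length,
            error_rate, np.random.default_rng([int(seed), 305]), outdir,
        )
        p2, _ = _emit_library(
            "mapping_R2", "map", r2_cores, counts_map, layout.read_length,
            error_rate, rng_map, outdir,
        )
        fastq["mapping"] = (p1, p2)
    else:
        cores = [
            np.concatenate([cassette(layout, t), core])
            for t, core in zip(truth, r2_cores)
        ]
        p1, total = _emit_library(
            "mapping", "map", cores, counts_map, layout.read_length,
            error_rate, rng_map, outdir,
        )
        fastq["mapping"] = (p1,)
    read_counts["mapping"] = total

    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w", newline="") as fh:
        wtr = csv.writer(fh, delimiter="\t", lineterminator="\n")
        wtr.writerow(
            [
                "barcode", "promoter_class", "promoter_index", "chrom", "position",
                "strand", "true_activity", "clone_abundance", "short_flank",
            ]
        )
        for t in truth:
            wtr.writerow(
                [
                    t.barcode, t.promoter_class, t.promoter_index, t.chrom,
                    t.position, t.strand, f"{t.true_activity:.6g}",
                    f"{t.clone_abundance:.6g}", int(t.barcode in short),
                ]
            )

    return SimulationOutput(fastq, truth_path, read_counts, short)


def read_truth(path) -> list[GroundTruthInsertion]:
    """Load a truth TSV written by :func:`simulate_libraries`."""
    out = []
    with open_text(path) as fh:
        rdr = csv.DictReader(fh, delimiter="\t")
        for row in rdr:
            out.append(
                GroundTruthInsertion(
                    barcode=row["barcode"],
                    promoter_class=row["promoter_class"],
                    promoter_index=row["promoter_index"],
                    chrom=row["chrom"],
                    position=int(row["position"]),
                    strand=row["strand"],
                    true_activity=float(row["true_activity"]),
                    clone_abundance=float(row["clone_abundance"]),
                )
            )
    return out
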