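"""Map barcodes to genomic insertion loci from the inverse-PCR library.

Each mapping read (pair) carries the barcode on one side and, on the
other, the genomic flank of the insertion: the duplicated TTAA target
site followed by genomic sequence up to the first downstream DpnII
(GATC) site.  Flanks are aligned by exact k-mer seeding on the first k
bases and full-length extension allowing a few substitutions; every
barcode then receives at most one insertion call with two reliability
statistics:

* ``reads_r``  — total mapping reads carrying the barcode (aligned,
  unalignable and ambiguous alike),
* ``freq1_r`` — fraction of those reads supporting the top locus.

The filter ``reads_r >= 10 and freq1_r > 0.60`` marks reliable calls.
The reported coordinate is always the 1-based position of the first T
of the duplicated TTAA on the plus strand, for either orientation.
"""

from __future__ import annotations

import csv
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import zip_longest
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from ._util import revcomp, read_fastq
from .barcodes import (
    PromoterIndexTable,
    collapse_counts,
    demultiplex_index,
    extract_index_barcode,
)
from .models import ReadLayout

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class FlankAlignment:
    """One candidate genomic placement of a flank."""

    chrom: str
    position: int  # 1-based first base of the TTAA target site (+ strand)
    strand: str
    mismatches: int
    flank_length: int
    barcode: str | None = None


@dataclass(frozen=True)
class InsertionCall:
    """Final per-barcode locus call with reliability statistics."""

    promoter: str
    barcode: str
    chrom: str
    position: int
    strand: str
    reads_r: int
    freq1_r: float

    @property
    def passes_mapping_filter(self) -> bool:
        return self.reads_r >= 10 and self.freq1_r > 0.60


def _encode_kmer(seq: str) -> int | None:
    code = 0
    for ch in seq:
        v = _ENC.get(ch)
        if v is None:
            return None
        code = (code << 2) | v
    return code


@dataclass
class KmerIndex:
    """Exact k-mer → genomic position lookup over the forward strand.

    Minus-strand placements are found by querying the reverse
    complement of the flank's seed, so both strands are effectively
    indexed.
    """

    k: int
    sequences: Mapping[str, str]
    hits: dict[int, list[tuple[str, int]]] = field(default_factory=dict)

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """0-based start positions of exact occurrences of ``kmer``."""
        code = _encode_kmer(kmer)
        if code is None:
            return []
        return self.hits.get(code, [])


def build_kmer_index(sequences: Mapping[str, str], k: int = 20) -> KmerIndex:
    """Index every forward-strand k-mer of the genome (k >= 12)."""
    if k < 12:
        raise ValueError("k must be >= 12")
    hits: dict[int, list[tuple[str, int]]] = {}
    mask = (1 << (2 * k)) - 1
    for chrom, seq in sequences.items():
        code, valid = 0, 0
        for i, ch in enumerate(seq):
            v = _ENC.get(ch)
            if v is None:
                valid = 0
                code = 0
                continue
            code = ((code << 2) | v) & mask
            valid += 1
            if valid >= k:
                hits.setdefault(code, []).append((chrom, i - k + 1))
    return KmerIndex(k, sequences, hits)


def _mismatches(a: str, b: str, limit: int) -> int:
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if m > limit:
                return m
    return m


def align_flank(
    flank: str, index: KmerIndex, max_mismatch: int = 2
) -> list[FlankAlignment]:
    """Seed-and-extend alignment of one flank; returns all minimal-mismatch loci.

    The seed is the first k bases of the flank (exact match required);
    extension compares the full flank with at most ``max_mismatch``
    substitutions.  Coordinates are converted to the TTAA-start
    convention for both strands.
    """
    k, L = index.k, len(flank)
    if L < k:
        return []
    candidates: list[FlankAlignment] = []
    # plus strand: flank matches the forward genome starting at the hit
    for chrom, p0 in index.lookup(flank[:k]):
        seq = index.sequences[chrom]
        if p0 + L > len(seq):
            continue
        m = _mismatches(flank, seq[p0 : p0 + L], max_mismatch)
        if m <= max_mismatch:
            candidates.append(FlankAlignment(chrom, p0 + 1, "+", m, L))
    # minus strand: revcomp(flank) matches the forward genome; the seed
    # (first k of the flank) is the revcomp of the segment's last k bases
    rc = revcomp(flank)
    for chrom, q0 in index.lookup(revcomp(flank[:k])):
        s = q0 + k - L
        if s < 0:
            continue
        seq = index.sequences[chrom]
        m = _mismatches(rc, seq[s : s + L], max_mismatch)
        if m <= max_mismatch:
            candidates.append(FlankAlignment(chrom, s + L - 3, "-", m, L))
    if not candidates:
        return []
    best = min(c.mismatches for c in candidates)
    out = [c for c in candidates if c.mismatches == best]
    out.sort(key=lambda c: (c.chrom, c.position, c.strand))
    return out


# ---------------------------------------------------------------------------
# read parsing


@dataclass(frozen=True)
class MappingRead:
    """Parsed mapping read: barcode side plus genomic flank."""

    index: str | None = None
    barcode: str | None = None
    flank: str | None = None
    reason: str | None = None  # anchor_not_found | too_short | flank_too_short | ...

    @property
    def ok(self) -> bool:
        return self.reason is None


def _truncate_at_gatc(flank: str) -> str:
    i = flank.find("GATC", 4)  # the site itself is retained
    return flank if i == -1 else flank[: i + 4]


def parse_mapping_read(
    read: str | tuple[str, str],
    layout: ReadLayout,
    *,
    min_flank: int = 20,
    anchor_mismatch: int = 1,
) -> MappingRead:
    """Extract (index, barcode, flank) from a mapping read or read pair.

    The flank is the sequence following the transposon-end anchor,
    truncated at the first GATC if present (site retained); flanks
    shorter than ``min_flank`` — the aligner's seed length — are
    rejected as ``flank_too_short``.
    """
    if layout.paired:
        r1, r2 = read
    else:
        r1 = r2 = read
    ext = extract_index_barcode(r1, layout, anchor_mismatch)
    if not ext.ok:
        return MappingRead(reason=ext.reason)
    anchor = layout.flank_anchor.upper()
    if layout.paired:
        start = 0
        hay = r2.upper()
    else:
        start = layout.cassette_length
        hay = r2.upper()
    window = hay[start : start + len(anchor)]
    if (
        len(window) < len(anchor)
        or sum(a != b for a, b in zip(window, anchor)) > anchor_mismatch
    ):
        return MappingRead(ext.index, ext.barcode, reason="anchor_not_found")
    flank = _truncate_at_gatc(hay[start + len(anchor) :])
    if len(flank) < min_flank:
        return MappingRead(ext.index, ext.barcode, reason="flank_too_short")
    return MappingRead(ext.index, ext.barcode, flank)


# ---------------------------------------------------------------------------
# calling


def call_insertions(
    grouped: Mapping[tuple[str, str], Sequence[Sequence[FlankAlignment]]]
) -> tuple[list[InsertionCall], list[tuple[str, str, int, str]]]:
    """Call one locus per barcode from per-read alignment candidate lists.

    ``grouped`` maps (promoter, barcode) to one candidate list per
    read: empty = unalignable, length > 1 = ambiguous.  Both count
    toward ``reads_r`` but vote for no locus, so chimeric or repetitive
    products depress ``freq1_r``.  Ties at the top locus break
    lexicographically by (chrom, position, strand).  Barcodes with no
    votes at all yield no call and are returned as residuals.
    """
    calls: list[InsertionCall] = []
    residuals: list[tuple[str, str, int, str]] = []
    for (promoter, barcode), per_read in sorted(grouped.items()):
        reads_r = len(per_read)
        votes: Counter = Counter()
        for cands in per_read:
            if len(cands) == 1:
                c = cands[0]
                votes[(c.chrom, c.position, c.strand)] += 1
        if not votes:
            residuals.append((promoter, barcode, reads_r, "no_unambiguous_alignment"))
            continue
        top = min(votes, key=lambda loc: (-votes[loc], loc))
        calls.append(
            InsertionCall(
                promoter=promoter,
                barcode=barcode,
                chrom=top[0],
                position=top[1],
                strand=top[2],
                reads_r=reads_r,
                freq1_r=votes[top] / reads_r,
            )
        )
    return calls, residuals


def _iter_read_pairs(paths: Sequence, paired: bool) -> Iterator[str | tuple[str, str]]:
    if paired:
        it1 = read_fastq(paths[0])
        it2 = read_fastq(paths[1])
        for (t1, s1, _), (t2, s2, _) in zip_longest(it1, it2, fillvalue=(None, "", "")):
            if t1 is None or t2 is None:
                raise ValueError("paired FASTQ files have unequal read counts")
            yield (s1, s2)
    else:
        for _t, s, _q in read_fastq(paths[0]):
            yield s


def map_library(
    fastq_paths: Sequence,
    index: KmerIndex,
    layout: ReadLayout,
    table: PromoterIndexTable | None = None,
    *,
    max_mismatch: int = 2,
    anchor_mismatch: int = 1,
    index_max_mismatch: int = 1,
    collapse: bool = True,
) -> tuple[list[InsertionCall], list[tuple[str, str, int, str]], Counter]:
    """Full mapping stage: parse reads, align flanks, call loci.

    Mutant barcodes are first collapsed into genuine ones (per
    promoter) so error reads rejoin their parent read group.  Returns
    (calls, residuals, rejection tallies).  Identical flank strings are
    aligned once and cached.
    """
    table = table or PromoterIndexTable()
    tallies: Counter = Counter()
    flanks_by_key: dict[tuple[str, str], list[str | None]] = defaultdict(list)
    for read in _iter_read_pairs(fastq_paths, layout.paired):
        parsed = parse_mapping_read(
            read, layout, min_flank=index.k, anchor_mismatch=anchor_mismatch
        )
        tallies["reads"] += 1
        if parsed.barcode is None:
            tallies[parsed.reason] += 1
            continue
        promoter = demultiplex_index(parsed.index, table, index_max_mismatch)
        if promoter == "unassigned":
            tallies["unassigned_index"] += 1
            continue
        if not parsed.ok:
            tallies[parsed.reason] += 1
            flanks_by_key[(promoter, parsed.barcode)].append(None)
        else:
            flanks_by_key[(promoter, parsed.barcode)].append(parsed.flank)

    if collapse:
        merged: dict[tuple[str, str], list[str | None]] = defaultdict(list)
        by_prom: dict[str, dict[str, int]] = defaultdict(dict)
        for (prom, bc), fl in flanks_by_key.items():
            by_prom[prom][bc] = len(fl)
        for prom, counts in by_prom.items():
            _, mapping, _ = collapse_counts(counts)
            for bc, genuine in mapping.items():
                merged[(prom, genuine)].extend(flanks_by_key[(prom, bc)])
        flanks_by_key = merged

    cache: dict[str, list[FlankAlignment]] = {}
    grouped: dict[tuple[str, str], list[list[FlankAlignment]]] = {}
    for key, flanks in flanks_by_key.items():
        per_read = []
        for fl in flanks:
            if fl is None:
                per_read.append([])
                continue
            if fl not in cache:
                cache[fl] = align_flank(fl, index, max_mismatch)
            per_read.append(cache[fl])
        grouped[key] = per_read
    calls, residuals = call_insertions(grouped)
    return calls, residuals, tallies


def calls_from_sam(
    sam_path, barcode_tag: str = "BC", promoter_tag: str = "PM"
) -> tuple[list[InsertionCall], list[tuple[str, str, int, str]]]:
    """Alternative input path: pre-aligned flanks from SAM/BAM.

    Each record must carry the barcode in ``barcode_tag`` (and
    optionally the promoter in ``promoter_tag``).  The alignment start
    is converted to the TTAA-start convention: forward reads report
    their reference start, reverse reads the start of the last four
    reference bases.  Unmapped records still count toward ``reads_r``.
    """
    import pysam

    grouped: dict[tuple[str, str], list[list[FlankAlignment]]] = defaultdict(list)
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            if not rec.has_tag(barcode_tag):
                continue
            bc = rec.get_tag(barcode_tag)
            prom = rec.get_tag(promoter_tag) if rec.has_tag(promoter_tag) else "NA"
            key = (str(prom), str(bc))
            if rec.is_unmapped:
                grouped[key].append([])
                continue
            if rec.is_reverse:
                pos = rec.reference_end - 3  # 1-based first T of the terminal TTAA
                strand = "-"
            else:
                pos = rec.reference_start + 1
                strand = "+"
            grouped[key].append(
                [FlankAlignment(rec.reference_name, pos, strand, 0, rec.query_length)]
            )
    return call_insertions(grouped)


def calls_to_frame(calls: Iterable[InsertionCall]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            (
                c.promoter, c.barcode, c.chrom, c.position, c.strand,
                c.reads_r, c.freq1_r, c.passes_mapping_filter,
            )
            for c in calls
        ],
        columns=[
            "promoter", "barcode", "chrom", "position", "strand",
            "reads_r", "freq1_r", "passes_mapping_filter",
        ],
    )
    return df.sort_values(["promoter", "barcode"], ignore_index=True)


def write_insertions_tsv(calls: Iterable[InsertionCall], path) -> pd.DataFrame:
    df = calls_to_frame(calls)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df


def write_residuals_tsv(residuals, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["promoter", "barcode", "reads_r", "reason"])
        for row in residuals:
            w.writerow(row)
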