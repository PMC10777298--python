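"""Shared domain types: gene models, chromatin segments, read layouts.

Coordinates are 1-based inclusive throughout the in-memory API; GFF3 is
written 1-based and BED 0-based half-open per the format standards.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Transcript:
    """One transcript: exon and CDS intervals in genomic coordinates.

    Intervals are (start, end) 1-based inclusive, sorted by start
    regardless of strand.
    """

    transcript_id: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more transcripts.

    ``tss``/``tts`` are strand-aware: the TSS is the *distal* transcript
    start (furthest upstream over all transcripts) and the TTS the
    furthest-downstream transcript end.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    transcripts: tuple[Transcript, ...]

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class ChromatinSegment:
    """One chromatin-state segment, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    state: str


@dataclass(frozen=True)
class ReadLayout:
    """Structure of a simulated/parsed amplicon read.

    The constant prefix anchors the index+barcode cassette at the read
    start; mapping reads additionally carry a transposon-end anchor in
    front of the genomic flank (on the mate read when paired).
    """

    library_kind: str  # normalization | expression | mapping
    constant_prefix: str = "TGATCGGAAGAGCACACG"
    index_length: int = 5
    barcode_length: int = 18
    read_length: int = 75
    paired: bool = True
    flank_anchor: str = "CCCTAGAAAGATA"  # transposon-end anchor (mapping only)

    def __post_init__(self):
        if len(self.constant_prefix) < 8:
            raise ValueError("constant_prefix must be at least 8 nt")

    @property
    def cassette_length(self) -> int:
        return len(self.constant_prefix) + self.index_length + self.barcode_length


#: Fixed promoter-index table: 5-bp index → promoter name.  The four
#: indexes are pairwise Hamming distance >= 4, so single-mismatch
#: demultiplexing is unambiguous.
DEFAULT_PROMOTER_INDEXES: dict[str, str] = {
    "TACAA": "short_EF1a",
    "CCGAG": "long_EF1a",
    "CTAGT": "mPGK",
    "AGCTC": "PGK",
}

#: Promoter classes in the order the library mixing ratio (7:7:7:1) is given.
PROMOTER_CLASSES: tuple[str, ...] = ("long_EF1a", "short_EF1a", "mPGK", "PGK")

INDEX_BY_CLASS: dict[str, str] = {v: k for k, v in DEFAULT_PROMOTER_INDEXES.items()}
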