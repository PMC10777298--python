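"""Barcode extraction, index demultiplexing, counting and error collapsing.

A read carries ``constant_prefix + 5-nt promoter index + 18-nt barcode``.
The promoter index encodes which promoter drives the construct; the
barcode identifies the individual integration.  PCR/sequencing
substitution errors create low-count mutant barcodes one or two
mismatches away from a genuine one; those are merged back by a greedy
directional network collapse (count-descending order, Hamming distance
<= 2, count ratio < 0.1) — the standard deterministic scheme for
UMI/barcode error correction.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from ._util import ConfigurationError, hamming, read_fastq
from .models import DEFAULT_PROMOTER_INDEXES, ReadLayout

_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class PromoterIndexTable:
    """5-bp index sequence → promoter name (case-insensitive).

    Demultiplexing at ``max_mismatch`` is only unambiguous when indexes
    are pairwise Hamming distance >= 2*max_mismatch + 1; ``validate``
    enforces that.
    """

    entries: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PROMOTER_INDEXES)
    )

    def __post_init__(self):
        upper = {k.upper(): v for k, v in self.entries.items()}
        object.__setattr__(self, "entries", upper)
        lengths = {len(k) for k in upper}
        if len(lengths) > 1:
            raise ConfigurationError("promoter indexes must all have the same length")

    @property
    def index_length(self) -> int:
        return len(next(iter(self.entries)))

    def validate(self, max_mismatch: int) -> None:
        keys = list(self.entries)
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                if hamming(a, b) < 2 * max_mismatch + 1:
                    raise ConfigurationError(
                        f"indexes {a} and {b} are too close (distance "
                        f"{hamming(a, b)}) for max_mismatch={max_mismatch}"
                    )

    def promoters(self) -> tuple[str, ...]:
        return tuple(self.entries.values())


@dataclass(frozen=True)
class Extraction:
    """Result of pulling (index, barcode) out of one read."""

    index: str | None = None
    barcode: str | None = None
    reason: str | None = None  # anchor_not_found | too_short | ambiguous_base_in_barcode

    @property
    def ok(self) -> bool:
        return self.reason is None


def extract_index_barcode(
    read: str, layout: ReadLayout, anchor_mismatch: int = 1
) -> Extraction:
    """Locate the constant prefix and return the following index and barcode.

    The prefix is matched at its expected offset (the read start)
    allowing at most ``anchor_mismatch`` substitutions.  Rejections are
    data, not exceptions.
    """
    prefix = layout.constant_prefix.upper()
    lp = len(prefix)
    need = lp + layout.index_length + layout.barcode_length
    if len(read) < need:
        return Extraction(reason="too_short")
    window = read[:lp].upper()
    mism = sum(a != b for a, b in zip(window, prefix))
    if mism > anchor_mismatch:
        return Extraction(reason="anchor_not_found")
    index = read[lp : lp + layout.index_length].upper()
    barcode = read[lp + layout.index_length : need].upper()
    if not _DNA.issuperset(barcode):
        return Extraction(reason="ambiguous_base_in_barcode")
    return Extraction(index=index, barcode=barcode)


def demultiplex_index(
    index: str, table: PromoterIndexTable, max_mismatch: int = 1
) -> str:
    """Return the unique promoter within ``max_mismatch``, else "unassigned"."""
    table.validate(max_mismatch)
    index = index.upper()
    if len(index) != table.index_length:
        return "unassigned"
    best, best_d, tie = None, max_mismatch + 1, False
    for seq, name in table.entries.items():
        d = sum(a != b for a, b in zip(index, seq))
        if d < best_d:
            best, best_d, tie = name, d, False
        elif d == best_d:
            tie = True
    if best is None or tie:
        return "unassigned"
    return best


@dataclass
class BarcodeCountTable:
    """Raw barcode counts per (library_kind, promoter) plus rejection tallies."""

    counts: dict[tuple[str, str], Counter] = field(default_factory=dict)
    unassigned: Counter = field(default_factory=Counter)  # per library_kind
    malformed: Counter = field(default_factory=Counter)
    processed: Counter = field(default_factory=Counter)

    def add(self, library_kind: str, promoter: str | None, barcode: str | None) -> None:
        self.processed[library_kind] += 1
        if barcode is None:
            self.malformed[library_kind] += 1
        elif promoter is None or promoter == "unassigned":
            self.unassigned[library_kind] += 1
        else:
            self.counts.setdefault((library_kind, promoter), Counter())[barcode] += 1

    def total_assigned(self, library_kind: str) -> int:
        return sum(
            sum(c.values()) for (lib, _), c in self.counts.items() if lib == library_kind
        )

    def conserved(self) -> bool:
        """assigned + unassigned + malformed == processed, per library."""
        return all(
            self.total_assigned(lib) + self.unassigned[lib] + self.malformed[lib]
            == self.processed[lib]
            for lib in self.processed
        )

    def write_tsv(self, path, collapsed: "BarcodeCountTable | None" = None) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["library", "promoter", "barcode", "raw_count", "collapsed_count"])
            for (lib, prom), counter in sorted(self.counts.items()):
                coll = collapsed.counts.get((lib, prom), {}) if collapsed else {}
                for bc in sorted(counter, key=lambda b: (-counter[b], b)):
                    w.writerow([lib, prom, bc, counter[bc], coll.get(bc, 0) if collapsed else ""])


def count_barcodes(
    stream: Iterable[tuple[str, str | None, str | None]]
) -> BarcodeCountTable:
    """Exact multiset counting of (library_kind, promoter, barcode) records.

    ``barcode=None`` marks a malformed read; ``promoter`` of None or
    "unassigned" marks an index that failed demultiplexing.
    """
    table = BarcodeCountTable()
    for lib, prom, bc in stream:
        table.add(lib, prom, bc)
    return table


def iter_extracted(
    fastq_paths: Sequence, layout: ReadLayout, table: PromoterIndexTable,
    *, anchor_mismatch: int = 1, index_max_mismatch: int = 1,
) -> Iterator[tuple[str, str | None, str | None]]:
    """Stream (library_kind, promoter, barcode) records from FASTQ files."""
    for path in fastq_paths:
        for _title, seq, _qual in read_fastq(path):
            ext = extract_index_barcode(seq, layout, anchor_mismatch)
            if not ext.ok:
                yield layout.library_kind, None, None
            else:
                prom = demultiplex_index(ext.index, table, index_max_mismatch)
                yield layout.library_kind, prom, ext.barcode


def extract_library(
    fastq_paths: Sequence, layout: ReadLayout,
    table: PromoterIndexTable | None = None, **kw,
) -> BarcodeCountTable:
    """Read FASTQ files, extract and demultiplex, return raw counts."""
    table = table or PromoterIndexTable()
    return count_barcodes(iter_extracted(fastq_paths, layout, table, **kw))


# ---------------------------------------------------------------------------
# mutant collapsing


@dataclass(frozen=True)
class MergeRecord:
    mutant: str
    genuine: str
    distance: int
    ratio: float


@dataclass
class GenuineBarcodeMap:
    """Idempotent mutant → genuine barcode map, per (library, promoter)."""

    mapping: dict[tuple[str, str], dict[str, str]] = field(default_factory=dict)
    merges: dict[tuple[str, str], list[MergeRecord]] = field(default_factory=dict)

    def resolve(self, library: str, promoter: str, barcode: str) -> str:
        return self.mapping.get((library, promoter), {}).get(barcode, barcode)

    def write_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["library", "promoter", "mutant", "genuine", "distance", "ratio"])
            for (lib, prom), recs in sorted(self.merges.items()):
                for r in recs:
                    w.writerow([lib, prom, r.mutant, r.genuine, r.distance, f"{r.ratio:.4g}"])


def collapse_counts(
    counts: Mapping[str, int], max_distance: int = 2, ratio_threshold: float = 0.1
) -> tuple[dict[str, int], dict[str, str], list[MergeRecord]]:
    """Greedy directional collapse of one barcode-count stratum.

    Barcodes are visited in (count descending, lexicographic) order; a
    barcode merges into the first already-accepted genuine barcode at
    Hamming distance <= ``max_distance`` whose *original* count
    satisfies ``count < ratio_threshold * genuine_count``.  Returns
    (collapsed counts, mutant→genuine map incl. identities, merge log).
    """
    order = sorted(counts, key=lambda b: (-counts[b], b))
    genuine: list[str] = []
    mapping: dict[str, str] = {}
    merges: list[MergeRecord] = []
    for bc in order:
        target = None
        for g in genuine:
            if len(g) != len(bc):
                continue
            if counts[bc] >= ratio_threshold * counts[g]:
                continue
            d = hamming(bc, g)
            if d <= max_distance:
                target = g
                break
        if target is None:
            genuine.append(bc)
            mapping[bc] = bc
        else:
            mapping[bc] = target
            merges.append(
                MergeRecord(bc, target, hamming(bc, target), counts[bc] / counts[target])
            )
    collapsed: dict[str, int] = {g: 0 for g in genuine}
    for bc, c in counts.items():
        collapsed[mapping[bc]] += c
    return collapsed, mapping, merges


def collapse_mutants(
    table: BarcodeCountTable, max_distance: int = 2, ratio_threshold: float = 0.1
) -> tuple[BarcodeCountTable, GenuineBarcodeMap]:
    """Collapse mutant barcodes per (library, promoter) stratum.

    Total read counts are conserved within each stratum.
    """
    out = BarcodeCountTable(
        unassigned=Counter(table.unassigned),
        malformed=Counter(table.malformed),
        processed=Counter(table.processed),
    )
    gmap = GenuineBarcodeMap()
    for key, counter in table.counts.items():
        collapsed, mapping, merges = collapse_counts(
            counter, max_distance, ratio_threshold
        )
        out.counts[key] = Counter(collapsed)
        gmap.mapping[key] = mapping
        gmap.merges[key] = merges
    return out, gmap
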