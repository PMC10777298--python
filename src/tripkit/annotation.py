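"""Gene-element and chromatin-type annotation of transgene loci.

Element definitions follow the conventions of the assay's reporting:

* gene body — from 1000 bp upstream of the *distal* transcription
  start site to the transcription termination site,
* promoter  — the window -1000…+100 bp around the TSS in
  transcription orientation (1101 bases),
* 5'UTR / 3'UTR — exonic sequence up-/downstream of the CDS,
* exon / intron — transcript exons and the gaps between them.

A locus overlapping several labels is classified by the fixed priority
promoter > utr5 > utr3 > exon > intron; no overlap means intergenic.
Distances to the nearest TSS and TTS are unsigned and taken over all
genes, not only the host gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from ._util import TripkitError
from .models import ChromatinSegment, GeneModel, Transcript

ELEMENT_PRIORITY: tuple[str, ...] = ("promoter", "utr5", "utr3", "exon", "intron")


class MalformedAnnotationError(TripkitError):
    pass


# ---------------------------------------------------------------------------
# GFF3 / BED input


def load_gene_models(gff_path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features from a GFF3 file via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for gene in db.features_of_type("gene"):
        transcripts = []
        for tx in db.children(gene, featuretype=("mRNA", "transcript")):
            exons = tuple(
                sorted((e.start, e.end) for e in db.children(tx, featuretype="exon"))
            )
            cds = tuple(
                sorted((c.start, c.end) for c in db.children(tx, featuretype="CDS"))
            )
            if exons:
                transcripts.append(Transcript(tx.id, exons, cds))
        if transcripts:
            genes.append(GeneModel(gene.id, gene.seqid, gene.strand, tuple(transcripts)))
    return genes


def load_chromatin_bed(bed_path) -> list[ChromatinSegment]:
    """Read a BED4 segmentation into 1-based inclusive segments."""
    df = pd.read_csv(
        bed_path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "state"], dtype={"chrom": str, "state": str},
    )
    return [
        ChromatinSegment(r.chrom, int(r.start) + 1, int(r.end), r.state)
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# element index


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for a, b in sorted(ivs):
        if out and a <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def gene_element_intervals(
    gene: GeneModel, promoter_upstream: int = 1000, promoter_downstream: int = 100
) -> dict[str, list[tuple[int, int]]]:
    """Per-gene element intervals (1-based inclusive), unioned over transcripts."""
    utr5, utr3, exons, introns = [], [], [], []
    for tx in gene.transcripts:
        for a, b in tx.cds:
            if not any(ea <= a and b <= eb for ea, eb in tx.exons):
                raise MalformedAnnotationError(
                    f"gene {gene.gene_id}: CDS ({a}, {b}) not contained in any exon"
                )
        exons.extend(tx.exons)
        for (_, e1), (s2, _) in zip(tx.exons, tx.exons[1:]):
            if s2 > e1 + 1:
                introns.append((e1 + 1, s2 - 1))
        if tx.cds:
            cds_lo = tx.cds[0][0]
            cds_hi = tx.cds[-1][1]
            lo_side = [  # exonic sequence before the CDS in genomic coords
                (a, min(b, cds_lo - 1)) for a, b in tx.exons if a < cds_lo
            ]
            hi_side = [(max(a, cds_hi + 1), b) for a, b in tx.exons if b > cds_hi]
            lo_side = [(a, b) for a, b in lo_side if a <= b]
            hi_side = [(a, b) for a, b in hi_side if a <= b]
            if gene.strand == "+":
                utr5.extend(lo_side)
                utr3.extend(hi_side)
            else:
                utr5.extend(hi_side)
                utr3.extend(lo_side)
    tss = gene.tss
    if gene.strand == "+":
        promoter = [(tss - promoter_upstream, tss + promoter_downstream)]
    else:
        promoter = [(tss - promoter_downstream, tss + promoter_upstream)]
    return {
        "promoter": promoter,
        "utr5": _merge_intervals(utr5),
        "utr3": _merge_intervals(utr3),
        "exon": _merge_intervals(exons),
        "intron": _merge_intervals(introns),
    }


@dataclass
class ElementIndex:
    """Interval index of labeled gene elements; overlapping labels allowed."""

    trees: dict[str, IntervalTree] = field(default_factory=dict)
    genes: dict[str, GeneModel] = field(default_factory=dict)

    def query(self, chrom: str, position: int) -> list[tuple[str, str]]:
        """(element, gene_id) labels overlapping a 1-based position."""
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data[0], iv.data[1]) for iv in tree.at(position))


def build_element_index(
    genes: Sequence[GeneModel],
    promoter_upstream: int = 1000,
    promoter_downstream: int = 100,
) -> ElementIndex:
    index = ElementIndex()
    for gene in genes:
        index.genes[gene.gene_id] = gene
        elements = gene_element_intervals(gene, promoter_upstream, promoter_downstream)
        tree = index.trees.setdefault(gene.chrom, IntervalTree())
        for element, ivs in elements.items():
            for a, b in ivs:
                if b >= a:
                    tree.addi(max(a, 1), b + 1, (element, gene.gene_id))
    return index


def classify_element(
    chrom: str, position: int, index: ElementIndex
) -> tuple[str, str | None]:
    """Classify one locus: (element, gene_id) by the fixed element priority.

    Ties between genes for the winning element type are broken by TSS
    proximity; no overlapping label means ("intergenic", None).
    """
    labels = index.query(chrom, position)
    if not labels:
        return "intergenic", None
    by_element: dict[str, list[str]] = {}
    for element, gid in labels:
        by_element.setdefault(element, []).append(gid)
    for element in ELEMENT_PRIORITY:
        if element in by_element:
            gids = by_element[element]
            gid = min(
                gids, key=lambda g: (abs(index.genes[g].tss - position), g)
            )
            return element, gid
    return "intergenic", None  # pragma: no cover - priority covers all labels


def nearest_distances(
    chrom: str, position: int, genes: Sequence[GeneModel]
) -> tuple[int | None, int | None]:
    """Unsigned bp to the nearest TSS and nearest TTS over all genes.

    Computed independently of each other; (None, None) when the
    chromosome carries no gene.
    """
    tss = [abs(g.tss - position) for g in genes if g.chrom == chrom]
    tts = [abs(g.tts - position) for g in genes if g.chrom == chrom]
    if not tss:
        return None, None
    return min(tss), min(tts)


# ---------------------------------------------------------------------------
# chromatin overlap


class ChromatinIndex:
    """Point lookup into a non-overlapping chromatin segmentation."""

    def __init__(self, segments: Sequence[ChromatinSegment]):
        self.trees: dict[str, IntervalTree] = {}
        for seg in segments:
            self.trees.setdefault(seg.chrom, IntervalTree()).addi(
                seg.start, seg.end + 1, seg.state
            )
        for chrom, tree in self.trees.items():
            ivs = sorted(tree)
            for a, b in zip(ivs, ivs[1:]):
                if a.end > b.begin:
                    raise MalformedAnnotationError(
                        f"overlapping chromatin segments on {chrom} at {b.begin}"
                    )

    def state_at(self, chrom: str, position: int) -> str:
        tree = self.trees.get(chrom)
        if tree is None:
            return "unassigned"
        hits = tree.at(position)
        if not hits:
            return "unassigned"
        return next(iter(hits)).data


def chromatin_overlap(
    chrom: str, position: int, segments: Sequence[ChromatinSegment] | ChromatinIndex
) -> str:
    """State label of the unique segment containing a 1-based position."""
    index = (
        segments if isinstance(segments, ChromatinIndex) else ChromatinIndex(segments)
    )
    return index.state_at(chrom, position)


# ---------------------------------------------------------------------------
# cohort annotation and enrichment


def annotate_transgenes(
    df: pd.DataFrame,
    genes: Sequence[GeneModel],
    element_index: ElementIndex | None = None,
    chromatin: Sequence[ChromatinSegment] | ChromatinIndex | None = None,
    **window_kw,
) -> pd.DataFrame:
    """Add element, gene_id, dist_tss, dist_tts and chromatin_type columns."""
    element_index = element_index or build_element_index(genes, **window_kw)
    chrom_index = None
    if chromatin is not None:
        chrom_index = (
            chromatin
            if isinstance(chromatin, ChromatinIndex)
            else ChromatinIndex(chromatin)
        )
    out = df.copy()
    elements, gids, d_tss, d_tts, states = [], [], [], [], []
    for row in df.itertuples():
        element, gid = classify_element(row.chrom, row.position, element_index)
        dts, dtt = nearest_distances(row.chrom, row.position, genes)
        elements.append(element)
        gids.append(gid)
        d_tss.append(dts)
        d_tts.append(dtt)
        states.append(
            chrom_index.state_at(row.chrom, row.position) if chrom_index else "unassigned"
        )
    out["element"] = elements
    out["gene_id"] = gids
    out["dist_tss"] = d_tss
    out["dist_tts"] = d_tts
    out["chromatin_type"] = states
    return out


def enrichment_report(
    annotated: pd.DataFrame,
    activity_col: str = "normalized_expression",
    top_fraction: float = 0.10,
) -> pd.DataFrame:
    """Category proportions among all vs the most active transgenes.

    For every gene-element and chromatin-type category: the proportion
    over the whole cohort, the proportion over the top
    ceil(top_fraction*n) most active records, and their ratio (the
    fold-enrichment of the category among highly active transgenes).
    Categories absent from the baseline report a NaN ratio.
    """
    from .expression import top_decile

    if annotated.empty:
        raise ValueError("cannot build an enrichment report from an empty cohort")
    ranked = annotated.rename(columns={activity_col: "normalized_expression"}) \
        if activity_col != "normalized_expression" else annotated
    top = top_decile(ranked, top_fraction)
    if top.empty:
        raise ValueError("top set is empty; provide a larger cohort")
    rows = []
    for kind, col in (("element", "element"), ("chromatin", "chromatin_type")):
        if col not in annotated.columns:
            continue
        all_prop = annotated[col].value_counts(normalize=True)
        top_prop = top[col].value_counts(normalize=True)
        for cat in sorted(set(all_prop.index) | set(top_prop.index)):
            p_all = float(all_prop.get(cat, 0.0))
            p_top = float(top_prop.get(cat, 0.0))
            rows.append(
                {
                    "category_type": kind,
                    "category": cat,
                    "prop_all": p_all,
                    "prop_top": p_top,
                    "ratio": p_top / p_all if p_all > 0 else float("nan"),
                }
            )
    return pd.DataFrame(rows)
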