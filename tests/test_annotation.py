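"""Gene-element classification, distances, chromatin overlap, enrichment."""

import numpy as np
import pandas as pd
import pytest

from oracles import brute_element_label
from tripkit.annotation import (
    ChromatinIndex,
    MalformedAnnotationError,
    annotate_transgenes,
    build_element_index,
    chromatin_overlap,
    classify_element,
    enrichment_report,
    gene_element_intervals,
    load_chromatin_bed,
    load_gene_models,
    nearest_distances,
)
from tripkit.models import ChromatinSegment, GeneModel, Transcript


def _gene(gid, chrom, strand, exons, cds):
    return GeneModel(gid, chrom, strand, (Transcript(f"{gid}.t1", exons, cds),))


@pytest.fixture(scope="module")
def small_genes():
    plus = _gene(
        "gP", "c", "+",
        exons=((5000, 5600), (6500, 7000), (8000, 8800)),
        cds=((5200, 5600), (6500, 7000), (8000, 8500)),
    )
    minus = _gene(
        "gM", "c", "-",
        exons=((20_000, 20_700), (22_000, 22_900)),
        cds=((20_300, 20_700), (22_000, 22_600)),
    )
    return [plus, minus]


class TestElementIntervals:
    def test_plus_strand_promoter_window(self, small_genes):
        ivs = gene_element_intervals(small_genes[0])
        assert ivs["promoter"] == [(4000, 5100)]
        assert ivs["promoter"][0][1] - ivs["promoter"][0][0] + 1 == 1101

    def test_minus_strand_promoter_window(self, small_genes):
        ivs = gene_element_intervals(small_genes[1])
        # TSS is the distal (largest) coordinate on '-'
        assert ivs["promoter"] == [(22_800, 23_900)]

    def test_utrs_are_strand_aware(self, small_genes):
        plus = gene_element_intervals(small_genes[0])
        assert plus["utr5"] == [(5000, 5199)]
        assert plus["utr3"] == [(8501, 8800)]
        minus = gene_element_intervals(small_genes[1])
        assert minus["utr5"] == [(22_601, 22_900)]
        assert minus["utr3"] == [(20_000, 20_299)]

    def test_single_exon_cds_equals_exon_has_no_utr_or_intron(self):
        g = _gene("g1", "c", "+", exons=((100, 400),), cds=((100, 400),))
        ivs = gene_element_intervals(g)
        assert ivs["utr5"] == [] and ivs["utr3"] == [] and ivs["intron"] == []

    def test_cds_outside_exons_is_malformed(self):
        g = _gene("gBad", "c", "+", exons=((100, 400),), cds=((100, 500),))
        with pytest.raises(MalformedAnnotationError, match="gBad"):
            gene_element_intervals(g)


class TestClassifyElement:
    def test_promoter_outranks_intron_of_other_gene(self):
        host = _gene("host", "c", "+", exons=((1000, 1100), (9000, 9100)), cds=())
        nested = _gene("nested", "c", "+", exons=((6000, 6400),), cds=((6000, 6400),))
        index = build_element_index([host, nested])
        # 5000..5100 overlaps host's intron and nested's promoter window
        assert classify_element("c", 5050, index) == ("promoter", "nested")

    def test_far_position_is_intergenic(self, small_genes):
        index = build_element_index(small_genes)
        assert classify_element("c", 15_000, index) == ("intergenic", None)

    def test_tss_plus_50_is_promoter(self, small_genes):
        index = build_element_index(small_genes)
        assert classify_element("c", 5050, index)[0] == "promoter"

    def test_agrees_with_per_base_oracle_on_random_positions(self, toy_genome):
        genes = toy_genome.gene_models
        index = build_element_index(genes)
        rng = np.random.default_rng(13)
        for _ in range(1000):
            chrom = "chrA" if rng.random() < 0.5 else "chrB"
            pos = int(rng.integers(1, len(toy_genome.sequences[chrom]) + 1))
            assert classify_element(chrom, pos, index) == brute_element_label(
                genes, chrom, pos
            )

    def test_mirror_genome_classifies_mirrored_positions_identically(self, toy_genome):
        """Flipping the genome (and annotations) must not change element calls."""
        genes = toy_genome.gene_models
        index = build_element_index(genes)
        flip = {"+": "-", "-": "+"}
        mirrored = []
        N = {c: len(s) for c, s in toy_genome.sequences.items()}

        def m(x, chrom):
            return N[chrom] - x + 1

        for g in genes:
            txs = []
            for tx in g.transcripts:
                exons = tuple(sorted((m(b, g.chrom), m(a, g.chrom)) for a, b in tx.exons))
                cds = tuple(sorted((m(b, g.chrom), m(a, g.chrom)) for a, b in tx.cds))
                txs.append(Transcript(tx.transcript_id, exons, cds))
            mirrored.append(GeneModel(g.gene_id, g.chrom, flip[g.strand], tuple(txs)))
        midx = build_element_index(mirrored)
        rng = np.random.default_rng(14)
        for _ in range(300):
            chrom = "chrA" if rng.random() < 0.5 else "chrB"
            pos = int(rng.integers(1, N[chrom] + 1))
            assert (
                classify_element(chrom, pos, index)
                == classify_element(chrom, m(pos, chrom), midx)
            )

    def test_element_proportions_partition_any_cohort(self, toy_genome):
        index = build_element_index(toy_genome.gene_models)
        rng = np.random.default_rng(15)
        labels = [
            classify_element(
                "chrA", int(rng.integers(1, len(toy_genome.sequences["chrA"]))), index
            )[0]
            for _ in range(400)
        ]
        props = pd.Series(labels).value_counts(normalize=True)
        assert props.sum() == pytest.approx(1.0)
        assert set(props.index) <= {
            "promoter", "utr5", "utr3", "exon", "intron", "intergenic"
        }


class TestNearestDistances:
    def test_position_at_tss_has_zero_distance(self, small_genes):
        d_tss, _ = nearest_distances("c", 5000, small_genes)
        assert d_tss == 0

    def test_nearest_over_all_genes(self, small_genes):
        # gP TSS at 5000, gM TSS at 22900
        d_tss, d_tts = nearest_distances("c", 8000, small_genes)
        assert d_tss == 3000
        assert d_tts == 800  # gP TTS at 8800

    def test_chromosome_without_genes_reports_absent(self, small_genes):
        assert nearest_distances("empty", 100, small_genes) == (None, None)

    def test_medians_match_brute_force_scan(self, toy_genome, truth60):
        genes = toy_genome.gene_models
        got = [
            nearest_distances(t.chrom, t.position, genes) for t in truth60
        ]
        brute = []
        for t in truth60:
            same = [g for g in genes if g.chrom == t.chrom]
            brute.append(
                (
                    min(abs(g.tss - t.position) for g in same),
                    min(abs(g.tts - t.position) for g in same),
                )
            )
        assert got == brute


class TestChromatinOverlap:
    SEGS = [
        ChromatinSegment("c", 1, 1000, "Quiescent/low"),
        ChromatinSegment("c", 1001, 5000, "Strong transcription (H3K36me3)"),
    ]

    def test_label_of_containing_segment(self):
        assert (
            chromatin_overlap("c", 2500, self.SEGS)
            == "Strong transcription (H3K36me3)"
        )

    def test_bed_boundary_convention(self, tmp_path):
        bed = tmp_path / "s.bed"
        bed.write_text("c\t0\t1000\tstateA\nc\t1000\t2000\tstateB\n")
        segs = load_chromatin_bed(bed)
        index = ChromatinIndex(segs)
        assert index.state_at("c", 1000) == "stateA"  # last base of first segment
        assert index.state_at("c", 1001) == "stateB"  # first base of the next

    def test_absent_chromosome_and_gap_are_unassigned(self):
        assert chromatin_overlap("other", 10, self.SEGS) == "unassigned"
        assert chromatin_overlap("c", 9999, self.SEGS) == "unassigned"

    def test_overlapping_segments_rejected(self):
        bad = self.SEGS + [ChromatinSegment("c", 900, 1200, "X")]
        with pytest.raises(MalformedAnnotationError):
            ChromatinIndex(bad)

    def test_assignment_is_a_function(self, toy_genome):
        index = ChromatinIndex(toy_genome.chromatin_segments)
        rng = np.random.default_rng(16)
        for _ in range(200):
            pos = int(rng.integers(1, len(toy_genome.sequences["chrB"]) + 1))
            state = index.state_at("chrB", pos)
            assert isinstance(state, str) and state != "unassigned"


class TestEnrichment:
    def test_fold_ratio_arithmetic(self):
        df = pd.DataFrame(
            {
                "barcode": [f"B{i}" for i in range(20)],
                "element": ["utr5"] * 2 + ["intron"] * 18,
                "chromatin_type": ["open"] * 20,
                "normalized_expression": [9.0, 8.0] + [1.0] * 18,
            }
        )
        out = enrichment_report(df, top_fraction=0.10)
        utr5 = out[(out["category_type"] == "element") & (out["category"] == "utr5")]
        # 10 % overall, 100 % of the top 2 records -> ratio 10
        assert utr5["prop_all"].iloc[0] == pytest.approx(0.1)
        assert utr5["ratio"].iloc[0] == pytest.approx(10.0)

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValueError):
            enrichment_report(pd.DataFrame(columns=["element", "normalized_expression"]))

    def test_active_state_enriched_when_it_boosts_activity(self, toy_genome):
        """A chromatin state with a strong activity factor shows ratio > 1."""
        from tripkit.simulate import plant_insertions

        truth = plant_insertions(toy_genome, 250, silent_fraction=0.3, seed=33)
        df = pd.DataFrame(
            {
                "barcode": [t.barcode for t in truth],
                "chrom": [t.chrom for t in truth],
                "position": [t.position for t in truth],
                "normalized_expression": [t.true_activity for t in truth],
            }
        )
        annotated = annotate_transgenes(
            df, toy_genome.gene_models, chromatin=toy_genome.chromatin_segments
        )
        out = enrichment_report(annotated, top_fraction=0.10)
        strong = out[
            (out["category_type"] == "chromatin")
            & (out["category"] == "Strong transcription (H3K36me3)")
        ]
        if len(strong) and strong["prop_all"].iloc[0] > 0:
            assert strong["ratio"].iloc[0] > 1.0


class TestGff3RoundTrip:
    def test_gene_models_survive_gff3_round_trip(self, toy_genome, tmp_path):
        path = tmp_path / "genes.gff3"
        toy_genome.write_gff3(path)
        loaded = load_gene_models(path)
        orig = {g.gene_id: g for g in toy_genome.gene_models}
        assert set(g.gene_id for g in loaded) == set(orig)
        for g in loaded:
            o = orig[g.gene_id]
            assert (g.chrom, g.strand, g.tss, g.tts) == (o.chrom, o.strand, o.tss, o.tts)
            assert g.transcripts[0].exons == o.transcripts[0].exons
            assert g.transcripts[0].cds == o.transcripts[0].cds
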