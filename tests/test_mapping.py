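"""Flank alignment and insertion-locus calling."""

import numpy as np
import pytest

from oracles import brute_kmer_hits
from tripkit._util import revcomp
from tripkit.mapping import (
    FlankAlignment,
    align_flank,
    build_kmer_index,
    call_insertions,
    calls_from_sam,
    map_library,
    parse_mapping_read,
)
from tripkit.simulate import default_layouts, insertion_flank

LAYOUT = default_layouts()["mapping"]


@pytest.fixture(scope="module")
def kindex(toy_genome):
    return build_kmer_index(toy_genome.sequences, k=20)


class TestKmerIndex:
    def test_kmer_from_fasta_found_at_source(self, toy_genome, kindex):
        seq = toy_genome.sequences["chrA"]
        assert ("chrA", 1234) in kindex.lookup(seq[1234:1254])

    def test_absent_kmer_gives_empty_hits(self, kindex):
        assert kindex.lookup("N" * 20) == []
        # a k-mer carefully absent: extremely unlikely to occur by chance
        assert kindex.lookup("ACGT" * 5) == sorted(
            brute_kmer_hits(kindex.sequences, "ACGT" * 5)
        )

    def test_hits_match_brute_force_scan(self, toy_genome, kindex):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            chrom = "chrA" if rng.random() < 0.5 else "chrB"
            seq = toy_genome.sequences[chrom]
            i = int(rng.integers(0, len(seq) - 20))
            kmer = seq[i : i + 20]
            assert sorted(kindex.lookup(kmer)) == brute_kmer_hits(
                toy_genome.sequences, kmer
            )

    def test_k_below_minimum_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            build_kmer_index(toy_genome.sequences, k=8)


class TestParseMappingRead:
    def test_simulated_pair_round_trips(self, toy_genome, truth60):
        t = truth60[0]
        flank = insertion_flank(toy_genome, t)
        r1 = LAYOUT.constant_prefix + t.promoter_index.upper() + t.barcode + "ACGT"
        r2 = (LAYOUT.flank_anchor + flank)[: LAYOUT.read_length]
        parsed = parse_mapping_read((r1, r2), LAYOUT, min_flank=12)
        assert parsed.barcode == t.barcode
        assert flank.startswith(parsed.flank)

    def test_flank_truncated_at_gatc_with_site_retained(self):
        flank = "TTAA" + "C" * 21 + "GATC" + "A" * 30
        r1 = LAYOUT.constant_prefix + "TACAA" + "A" * 18
        r2 = LAYOUT.flank_anchor + flank
        parsed = parse_mapping_read((r1, r2), LAYOUT, min_flank=20)
        assert parsed.flank == "TTAA" + "C" * 21 + "GATC"
        assert len(parsed.flank) == 25 + 4  # offset 25 + retained site

    def test_short_flank_rejected(self):
        r1 = LAYOUT.constant_prefix + "TACAA" + "A" * 18
        r2 = LAYOUT.flank_anchor + "TTAACCGATC"
        parsed = parse_mapping_read((r1, r2), LAYOUT, min_flank=20)
        assert parsed.reason == "flank_too_short"

    def test_missing_flank_anchor_rejected(self):
        r1 = LAYOUT.constant_prefix + "TACAA" + "A" * 18
        parsed = parse_mapping_read((r1, "G" * 60), LAYOUT, min_flank=20)
        assert parsed.reason == "anchor_not_found"


class TestAlignFlank:
    def test_error_free_flank_maps_to_truth_locus(self, toy_genome, truth60, kindex):
        for t in truth60[:25]:
            flank = insertion_flank(toy_genome, t)
            if len(flank) < 20:
                continue
            cands = align_flank(flank, kindex)
            assert len(cands) == 1
            c = cands[0]
            assert (c.chrom, c.position, c.strand) == (t.chrom, t.position, t.strand)
            assert c.mismatches == 0

    def test_substituted_flank_still_maps(self, toy_genome, truth60, kindex):
        t = next(
            t for t in truth60 if len(insertion_flank(toy_genome, t)) >= 30
        )
        flank = insertion_flank(toy_genome, t)
        mutated = flank[:25] + ("A" if flank[25] != "A" else "C") + flank[26:]
        cands = align_flank(mutated, kindex, max_mismatch=2)
        assert any(
            (c.chrom, c.position, c.strand) == (t.chrom, t.position, t.strand)
            for c in cands
        )

    def test_duplicated_flank_reports_both_loci(self):
        rng = np.random.default_rng(3)
        chunk = "".join(rng.choice(list("ACGT"), size=60))
        flank = "TTAA" + chunk[:40]
        genome = {
            "dup": chunk.join(["".join(rng.choice(list("ACGT"), size=500))] * 2)
        }
        # plant the flank (not just the chunk) twice
        seq = "".join(rng.choice(list("ACGT"), size=300))
        genome = {"dup": seq + flank + seq + flank + seq}
        idx = build_kmer_index(genome, k=20)
        cands = align_flank(flank, idx)
        positions = {(c.position, c.strand) for c in cands}
        assert positions == {(301, "+"), (301 + 44 + 300, "+")}

    def test_minus_strand_coordinate_convention(self, toy_genome, kindex):
        # take a genomic TTAA and read its flank in minus orientation
        pos = toy_genome.ttaa_sites("chrB")[5]
        seq = toy_genome.sequences["chrB"]
        flank = revcomp(seq[max(0, pos - 40) : pos + 3])
        cands = align_flank(flank, kindex)
        assert any(
            (c.chrom, c.position, c.strand) == ("chrB", pos, "-") for c in cands
        )

    def test_strand_mirror_symmetry(self, toy_genome, truth60, kindex):
        """Reverse-complementing the genome maps position p to N - p - 2."""
        mirrored = {c: revcomp(s) for c, s in toy_genome.sequences.items()}
        midx = build_kmer_index(mirrored, k=20)
        flip = {"+": "-", "-": "+"}
        checked = 0
        for t in truth60[:15]:
            flank = insertion_flank(toy_genome, t)
            if len(flank) < 20:
                continue
            orig = align_flank(flank, kindex)
            mirror = align_flank(flank, midx)
            assert len(orig) == len(mirror) == 1
            N = len(toy_genome.sequences[t.chrom])
            assert mirror[0].position == N - orig[0].position - 2
            assert mirror[0].strand == flip[orig[0].strand]
            checked += 1
        assert checked >= 10


class TestCallInsertions:
    A = FlankAlignment("chr1", 100, "+", 0, 40)
    B = FlankAlignment("chr2", 900, "-", 0, 40)

    def test_majority_locus_wins_with_correct_stats(self):
        grouped = {("p", "BC1"): [[self.A]] * 12 + [[self.B]] * 3}
        calls, residuals = call_insertions(grouped)
        (c,) = calls
        assert (c.chrom, c.position, c.reads_r, c.freq1_r) == ("chr1", 100, 15, 0.8)
        assert c.passes_mapping_filter

    def test_nine_reads_fail_depth_threshold(self):
        grouped = {("p", "BC1"): [[self.A]] * 9}
        (c,), _ = call_insertions(grouped)
        assert c.freq1_r == 1.0 and not c.passes_mapping_filter

    def test_freq1_exactly_at_boundary_fails_strict_inequality(self):
        grouped = {("p", "BC1"): [[self.A]] * 6 + [[self.B]] * 4}
        (c,), _ = call_insertions(grouped)
        assert c.reads_r == 10 and c.freq1_r == 0.6
        assert not c.passes_mapping_filter

    def test_ambiguous_and_unalignable_reads_depress_freq1(self):
        grouped = {("p", "BC1"): [[self.A]] * 8 + [[], [self.A, self.B]]}
        (c,), _ = call_insertions(grouped)
        assert c.reads_r == 10 and c.freq1_r == 0.8

    def test_freq1_monotone_in_top_locus_support(self):
        base = [[self.A]] * 7 + [[self.B]] * 3
        (c0,), _ = call_insertions({("p", "B"): base})
        (c1,), _ = call_insertions({("p", "B"): base + [[self.A]]})
        assert c1.freq1_r >= c0.freq1_r

    def test_voteless_barcode_reported_as_residual(self):
        grouped = {("p", "BC1"): [[], []]}
        calls, residuals = call_insertions(grouped)
        assert not calls
        assert residuals == [("p", "BC1", 2, "no_unambiguous_alignment")]


class TestMapLibrary:
    def test_noise_free_library_recovers_all_mappable_loci(
        self, toy_genome, truth60, clean_sim
    ):
        """Error-free reads with enough depth give exact calls, freq1 = 1."""
        idx = build_kmer_index(toy_genome.sequences, k=12)
        calls, residuals, tallies = map_library(
            clean_sim.fastq["mapping"], idx, LAYOUT
        )
        short = set(clean_sim.short_flank_barcodes)
        by_bc = {c.barcode: c for c in calls}
        for t in truth60:
            if t.barcode in short:
                continue
            c = by_bc[t.barcode]
            assert (c.chrom, c.position, c.strand) == (t.chrom, t.position, t.strand)
            if c.reads_r >= 15:
                assert c.freq1_r == 1.0

    def test_called_positions_sit_on_reference_ttaa(self, toy_genome, clean_sim):
        idx = build_kmer_index(toy_genome.sequences, k=12)
        calls, _, _ = map_library(clean_sim.fastq["mapping"], idx, LAYOUT)
        for c in calls:
            assert (
                toy_genome.sequences[c.chrom][c.position - 1 : c.position + 3]
                == "TTAA"
            )


class TestSamInput:
    def test_calls_from_tagged_sam(self, tmp_path):
        import pysam

        header = {"HD": {"VN": "1.6"}, "SQ": [{"LN": 1000, "SN": "chr1"}]}
        path = tmp_path / "flanks.sam"
        with pysam.AlignmentFile(str(path), "w", header=header) as fh:
            for i, (start, reverse) in enumerate([(99, False)] * 11 + [(200, True)] * 12):
                a = pysam.AlignedSegment()
                a.query_name = f"r{i}"
                a.query_sequence = "A" * 40
                a.reference_id = 0
                a.reference_start = start
                a.cigarstring = "40M"
                a.flag = 16 if reverse else 0
                a.set_tag("BC", "BARCODE1" if not reverse else "BARCODE2")
                a.set_tag("PM", "mPGK")
                fh.write(a)
        calls, _ = calls_from_sam(path)
        by_bc = {c.barcode: c for c in calls}
        assert by_bc["BARCODE1"].position == 100  # 0-based 99 -> 1-based 100
        assert by_bc["BARCODE1"].strand == "+"
        # reverse read spanning [200, 240): TTAA-start = reference_end - 3
        assert by_bc["BARCODE2"].position == 237
        assert by_bc["BARCODE2"].strand == "-"
        assert by_bc["BARCODE2"].passes_mapping_filter
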