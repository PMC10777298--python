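"""Independent brute-force oracles used to cross-check the implementation.

Each oracle re-derives an expected result by the most direct route
possible (full matrices, per-base scans, exact rational arithmetic) and
deliberately shares no code with the package internals it checks.
"""

from fractions import Fraction
from math import comb, log10

import numpy as np


def brute_collapse(counts: dict, max_distance: int = 2, ratio: float = 0.1) -> dict:
    """All-pairs matrix route to the directional collapse mutant->genuine map."""
    barcodes = sorted(counts, key=lambda b: (-counts[b], b))
    n = len(barcodes)
    dist = np.full((n, n), 10**9)
    for i in range(n):
        for j in range(n):
            if len(barcodes[i]) == len(barcodes[j]):
                dist[i, j] = sum(
                    a != b for a, b in zip(barcodes[i], barcodes[j])
                )
    kept: list[int] = []
    assign = {}
    for i, bc in enumerate(barcodes):
        target = None
        for j in kept:  # kept is in descending-count order already
            if (
                dist[i, j] <= max_distance
                and counts[bc] < ratio * counts[barcodes[j]]
            ):
                target = barcodes[j]
                break
        if target is None:
            kept.append(i)
            assign[bc] = bc
        else:
            assign[bc] = target
    return assign


def brute_element_label(genes, chrom, pos, up=1000, down=100):
    """Per-base element classification written directly from the definitions."""
    hits = []  # (element, gene)
    for g in genes:
        if g.chrom != chrom:
            continue
        if g.strand == "+":
            win = (g.tss - up, g.tss + down)
        else:
            win = (g.tss - down, g.tss + up)
        if win[0] <= pos <= win[1]:
            hits.append(("promoter", g))
        for tx in g.transcripts:
            in_exon = any(a <= pos <= b for a, b in tx.exons)
            if in_exon:
                hits.append(("exon", g))
                if tx.cds:
                    lo, hi = tx.cds[0][0], tx.cds[-1][1]
                    if pos < lo:
                        hits.append(("utr5" if g.strand == "+" else "utr3", g))
                    elif pos > hi:
                        hits.append(("utr3" if g.strand == "+" else "utr5", g))
            elif tx.start <= pos <= tx.end:
                hits.append(("intron", g))
    for element in ("promoter", "utr5", "utr3", "exon", "intron"):
        cands = [g for e, g in hits if e == element]
        if cands:
            g = min(cands, key=lambda g: (abs(g.tss - pos), g.gene_id))
            return element, g.gene_id
    return "intergenic", None


def exact_binomial_log_odds(k: int, n: int, p: float) -> float:
    """Signed log10 binomial tail by exact rational summation (n small)."""
    pf = Fraction(p)
    qf = 1 - pf
    if n == 0:
        return 0.0
    if k >= n * p:
        tail = sum(comb(n, i) * pf**i * qf ** (n - i) for i in range(k, n + 1))
        return -log10(float(tail))
    tail = sum(comb(n, i) * pf**i * qf ** (n - i) for i in range(0, k + 1))
    return log10(float(tail))


def brute_flank(sequences: dict, chrom: str, position: int, strand: str) -> str:
    """Direct substring scan for the DpnII-bounded flank of an insertion."""
    seq = sequences[chrom]
    p0 = position - 1

    def rc(s):
        return s[::-1].translate(str.maketrans("ACGT", "TGCA"))

    if strand == "+":
        i = p0 + 4
        while i + 4 <= len(seq) and seq[i : i + 4] != "GATC":
            i += 1
        return seq[p0:] if i + 4 > len(seq) else seq[p0 : i + 4]
    i = p0 - 4
    while i >= 0 and seq[i : i + 4] != "GATC":
        i -= 1
    return rc(seq[: p0 + 4]) if i < 0 else rc(seq[i : p0 + 4])


def brute_kmer_hits(sequences: dict, kmer: str) -> list[tuple[str, int]]:
    """All 0-based forward-strand occurrences of a k-mer by repeated str.find."""
    out = []
    for chrom, seq in sequences.items():
        i = seq.find(kmer)
        while i != -1:
            out.append((chrom, i))
            i = seq.find(kmer, i + 1)
    return sorted(out)
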