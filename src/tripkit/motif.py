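"""Position-specific nucleotide statistics around insertion sites.

piggyBac integrates at TTAA tetranucleotides and duplicates the target
site, so windows centred on insertion loci show an invariant TTAA at
positions +1…+4 and AT-rich flanks.  Windows are orientation-normalized
(minus-strand sites are reverse-complemented), position 0 does not
exist (-1 abuts +1), and per-position enrichment against genome-wide
background frequencies is scored with a pLogo-style binomial tail
statistic:

    log_odds(pos, base) = -log10 P(X >= k)   if k/n >= background
                        = +log10 P(X <= k)   otherwise

with X ~ Binomial(n, background).  Positive values mark
over-representation, negative depletion, computed in log space for
numerical stability.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from ._util import revcomp

NUCLEOTIDES = ("A", "C", "G", "T")
_LN10 = np.log(10.0)


def window_positions(W: int) -> list[int]:
    """Position labels -W…-1, +1…+4 (target site), +5…+(W+4)."""
    return list(range(-W, 0)) + list(range(1, W + 5))


def extract_windows(
    insertions: pd.DataFrame | Sequence, sequences: Mapping[str, str], W: int = 10
) -> tuple[list[str], int]:
    """Oriented (2W+4)-nt windows around insertion sites.

    ``insertions`` provides chrom, position (1-based TTAA start) and
    strand; minus-strand windows are reverse-complemented so every
    window reads in transgene orientation.  Sites whose window would
    run off the chromosome are skipped; the skip count is returned.
    """
    if isinstance(insertions, pd.DataFrame):
        records = list(insertions[["chrom", "position", "strand"]].itertuples(index=False))
    else:
        records = list(insertions)
    windows, skipped = [], 0
    for chrom, position, strand in records:
        seq = sequences[chrom]
        p0 = int(position) - 1
        lo, hi = p0 - W, p0 + 4 + W
        if lo < 0 or hi > len(seq):
            skipped += 1
            continue
        win = seq[lo:hi]
        windows.append(win if strand == "+" else revcomp(win))
    return windows, skipped


def genome_background(sequences: Mapping[str, str]) -> dict[str, float]:
    """Genome-wide mononucleotide frequencies."""
    counts = Counter()
    for seq in sequences.values():
        counts.update(seq)
    total = sum(counts[b] for b in NUCLEOTIDES)
    return {b: counts[b] / total for b in NUCLEOTIDES}


@dataclass
class MotifMatrix:
    """Counts, frequencies and binomial log-odds per window position."""

    positions: list[int]
    counts: np.ndarray  # (P, 4) ints, columns A C G T
    frequencies: np.ndarray
    background: dict[str, float]
    log_odds: np.ndarray
    n_sites: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, pos in enumerate(self.positions):
            row = {"position": pos}
            for j, b in enumerate(NUCLEOTIDES):
                row[f"count_{b}"] = int(self.counts[i, j])
                row[f"freq_{b}"] = self.frequencies[i, j]
                row[f"log_odds_{b}"] = self.log_odds[i, j]
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def binomial_log_odds(k: int, n: int, p: float) -> float:
    """Signed log10 binomial tail probability (pLogo-style height).

    Enrichment (k >= n*p) uses the upper tail P(X >= k) and is
    reported as a positive value; depletion uses the lower tail
    P(X <= k) and is negative.
    """
    if n == 0:
        return 0.0
    if k >= n * p:
        return float(-binom.logsf(k - 1, n, p) / _LN10)
    return float(binom.logcdf(k, n, p) / _LN10)


def motif_matrix(
    windows: Sequence[str], background: Mapping[str, float], W: int | None = None
) -> MotifMatrix:
    """Build the position × nucleotide matrix from oriented windows."""
    if not windows:
        raise ValueError("at least one window is required")
    bg = {b: float(background[b]) for b in NUCLEOTIDES}
    if not all(v > 0 for v in bg.values()) or abs(sum(bg.values()) - 1) > 1e-6:
        raise ValueError("background frequencies must be positive and sum to 1")
    length = len(windows[0])
    if any(len(w) != length for w in windows):
        raise ValueError("windows must all have the same length")
    if W is None:
        W = (length - 4) // 2
    positions = window_positions(W)
    n = len(windows)
    counts = np.zeros((length, 4), dtype=int)
    base_idx = {b: j for j, b in enumerate(NUCLEOTIDES)}
    for win in windows:
        for i, ch in enumerate(win):
            j = base_idx.get(ch)
            if j is not None:
                counts[i, j] += 1
    col_sums = counts.sum(axis=1, keepdims=True)
    freqs = counts / np.where(col_sums == 0, 1, col_sums)
    log_odds = np.zeros_like(freqs)
    for i in range(length):
        n_i = int(counts[i].sum())
        for j, b in enumerate(NUCLEOTIDES):
            log_odds[i, j] = binomial_log_odds(int(counts[i, j]), n_i, bg[b])
    return MotifMatrix(positions, counts, freqs, bg, log_odds, n)


def at_content_profile(matrix: MotifMatrix) -> np.ndarray:
    """Per-position A+T frequency across the window."""
    a = matrix.frequencies[:, NUCLEOTIDES.index("A")]
    t = matrix.frequencies[:, NUCLEOTIDES.index("T")]
    return a + t


def plot_motif(matrix: MotifMatrix, path) -> None:
    """Simple stacked-bar rendering of the per-position log-odds."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, len(matrix.positions) / 2), 3))
    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    x = np.arange(len(matrix.positions))
    pos_bottom = np.zeros(len(x))
    neg_bottom = np.zeros(len(x))
    for j, b in enumerate(NUCLEOTIDES):
        vals = matrix.log_odds[:, j]
        up = np.clip(vals, 0, None)
        dn = np.clip(vals, None, 0)
        ax.bar(x, up, bottom=pos_bottom, color=colors[b], label=b, width=0.8)
        ax.bar(x, dn, bottom=neg_bottom, color=colors[b], width=0.8)
        pos_bottom += up
        neg_bottom += dn
    ax.set_xticks(x)
    ax.set_xticklabels([str(p) for p in matrix.positions], fontsize=7)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("position relative to target site")
    ax.set_ylabel("signed -log10 binomial tail")
    ax.legend(ncol=4, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
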