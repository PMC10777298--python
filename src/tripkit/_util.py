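"""Small sequence and I/O helpers shared across the package."""

from __future__ import annotations

import gzip
from typing import Iterable, Iterator, TextIO

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte-level base codes used by the vectorised read builders
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


class TripkitError(Exception):
    """Base class for errors raised by tripkit."""


class ConfigurationError(TripkitError):
    """A configuration value is inconsistent or unusable."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-aware, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings.

    Raises ValueError on unequal lengths — callers that treat
    unequal-length sequences as unmergeable must guard first.
    """
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def encode_seqs(seqs: Iterable[str]) -> np.ndarray:
    """Encode equal-length DNA strings into a (n, L) uint8 array of base codes 0..3."""
    seqs = list(seqs)
    if not seqs:
        return np.zeros((0, 0), dtype=np.uint8)
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return _BASE_INDEX[arr].reshape(len(seqs), len(seqs[0]))


def decode_seqs(codes: np.ndarray) -> list[str]:
    """Inverse of :func:`encode_seqs`."""
    chars = BASES[codes]
    return [bytes(row).decode() for row in chars]


def open_text(path, mode: str = "rt") -> TextIO:
    """Open plain or gzip text transparently based on the ``.gz`` suffix."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode.rstrip("t") or "r")


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) from a FASTQ file (plain or gzip)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open_text(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(path, records: Iterable[tuple[str, str, str]]) -> int:
    """Write (title, sequence, quality) records as FASTQ; returns record count."""
    n = 0
    with open_text(path, "wt") as fh:
        for title, seq, qual in records:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def load_fasta(path) -> dict[str, str]:
    """Load a FASTA file into a chromosome → uppercase-sequence dict."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(path, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
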