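"""Amplicon layout shared by the synthetic generator and the read filter.

The sequencing construct is a 129-nt single-end amplicon:

    [30-nt lineage barcode][65-nt constant region 1][10-nt sample index][24-nt constant region 2]

Each sorted (timepoint, state) sample is amplified with a reverse primer
carrying a distinct 10-nt sample index, so demultiplexing happens on the
index segment rather than on separate files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

# Constant regions of the reference amplicon (positions 31-95 and 106-129,
# 1-based) flanking the barcode and the sample index.
CONSTANT1 = "AGCAGAGCTACGCACTCTATGCTAGTGCTAGAGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
CONSTANT2 = "ATCTCGTATGCCGTCTTCTGCTTG"

BARCODE_LENGTH = 30
INDEX_LENGTH = 10
READ_LENGTH = BARCODE_LENGTH + len(CONSTANT1) + INDEX_LENGTH + len(CONSTANT2)  # 129

# Segment slices within a read.
BARCODE_SLICE = slice(0, BARCODE_LENGTH)
CONSTANT1_SLICE = slice(BARCODE_LENGTH, BARCODE_LENGTH + len(CONSTANT1))
INDEX_SLICE = slice(CONSTANT1_SLICE.stop, CONSTANT1_SLICE.stop + INDEX_LENGTH)
CONSTANT2_SLICE = slice(INDEX_SLICE.stop, INDEX_SLICE.stop + len(CONSTANT2))

MAX_PHRED = 40

ALPHABET = "ACGT"


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def _encode(seqs: list[str]) -> np.ndarray:
    """Equal-length nucleotide strings -> (n, L) uint8 matrix."""
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)


def min_pairwise_hamming(seqs: list[str]) -> int:
    """Minimum pairwise Hamming distance over a set of equal-length strings."""
    if len(seqs) < 2:
        return len(seqs[0]) if seqs else 0
    mat = _encode(seqs)
    best = mat.shape[1]
    # chunked O(n^2) comparison; fine up to ~10^4 sequences of length 30
    chunk = 256
    for start in range(0, len(seqs), chunk):
        block = mat[start : start + chunk]
        d = (block[:, None, :] != mat[None, :, :]).sum(axis=2)
        i = np.arange(start, start + block.shape[0])
        d[np.arange(block.shape[0]), i] = mat.shape[1]  # mask self-distance
        best = min(best, int(d.min()))
    return best


def random_distinct_sequences(
    n: int, length: int, min_dist: int, rng: np.random.Generator
) -> list[str]:
    """Draw n uniform ACGT sequences with pairwise Hamming distance >= min_dist.

    Rejection sampling against the accepted set; for length 30 and min_dist 7
    collisions are vanishingly rare, so this terminates almost immediately.
    """
    accepted: list[str] = []
    accepted_mat = np.empty((0, length), dtype=np.uint8)
    codes = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    attempts = 0
    while len(accepted) < n:
        attempts += 1
        if attempts > 50 * n + 1000:
            raise RuntimeError("cannot satisfy the pairwise-distance floor")
        cand = codes[rng.integers(0, 4, size=length)]
        if accepted_mat.size:
            if int((accepted_mat != cand).sum(axis=1).min()) < min_dist:
                continue
        accepted_mat = np.vstack([accepted_mat, cand])
        accepted.append(cand.tobytes().decode())
    return accepted


def constant_quality_model(score: int = MAX_PHRED) -> Callable:
    """Quality model emitting a fixed Phred score at every position."""
    if not 0 <= score <= MAX_PHRED:
        raise ValueError("Phred score outside [0, 40]")

    def model(n_reads: int, length: int, rng: np.random.Generator) -> np.ndarray:
        return np.full((n_reads, length), score, dtype=np.int16)

    return model


def noisy_quality_model(mean: float = 36.0, sd: float = 3.0) -> Callable:
    """Gaussian per-base Phred scores, rounded and clipped to [0, 40]."""

    def model(n_reads: int, length: int, rng: np.random.Generator) -> np.ndarray:
        q = rng.normal(mean, sd, size=(n_reads, length))
        return np.clip(np.rint(q), 0, MAX_PHRED).astype(np.int16)

    return model


@dataclass
class AmpliconSpec:
    """Parameters of the amplicon readout.

    per_base_error_rate is the independent substitution probability applied
    to every base of a synthetic read; reads_per_cell scales sequencing depth
    relative to sorted cell numbers.
    """

    barcode_length: int = BARCODE_LENGTH
    constant1: str = CONSTANT1
    index_length: int = INDEX_LENGTH
    constant2: str = CONSTANT2
    per_base_error_rate: float = 0.0
    quality_model: Callable = field(default_factory=constant_quality_model)
    reads_per_cell: float = 1.0

    def __post_init__(self) -> None:
        if len(self.constant1) != 65:
            raise ValueError("constant region 1 must be 65 nt")
        if len(self.constant2) != 24:
            raise ValueError("constant region 2 must be 24 nt")
        if not 0.0 <= self.per_base_error_rate < 1.0:
            raise ValueError("per_base_error_rate outside [0, 1)")
        if self.reads_per_cell <= 0:
            raise ValueError("reads_per_cell must be positive")

    @property
    def read_length(self) -> int:
        return (
            self.barcode_length
            + len(self.constant1)
            + self.index_length
            + len(self.constant2)
        )
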