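"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASES = np.frombuffer(b"ACGT", dtype="S1")

DNA_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming() needs equal lengths, got {len(a)} and {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def mismatches_within(a: str, b: str, limit: int) -> bool:
    """True if the Hamming distance between equal-length a, b is <= limit."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return False
    return len(a) == len(b)


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA string of length n."""
    return rng.choice(_BASES, size=n).tobytes().decode()


def random_dna_matrix(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    """(rows, cols) array of single-character DNA bytes."""
    return rng.choice(_BASES, size=(rows, cols))


def is_dna(seq: str) -> bool:
    return bool(seq) and set(seq.upper()) <= set("ACGTN")
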