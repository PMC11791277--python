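"""Core nucleotide-sequence container and codon arithmetic.

All coordinates in this package are 1-based and inclusive, following the
convention used for coding sequences (CDS): codon ``k`` spans nucleotides
``3k-2 .. 3k``, so RAS codon 12 occupies nt 34-36 and codon 61 occupies
nt 181-183.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_TABLE = str.maketrans("ACGT", "TGCA")

#: Watson-Crick partner of each base.
WATSON_CRICK = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: index-space complement: A<->T, C<->G under the ACGT encoding.
COMPLEMENT_INDEX = np.array([3, 2, 1, 0], dtype=np.int8)


def complement(bases: str) -> str:
    """Base-wise complement (no reversal)."""
    return bases.translate(_COMPLEMENT_TABLE)


def reverse_complement(bases: str) -> str:
    return complement(bases)[::-1]


def encode(bases: str) -> np.ndarray:
    """Encode an ACGT string as an int8 array (A=0, C=1, G=2, T=3)."""
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    if (out < 0).any():
        bad = bases[int(np.argmax(out < 0))]
        raise ValueError(f"non-ACGT symbol {bad!r} in sequence")
    return out


_BASES_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def decode(indices: np.ndarray) -> str:
    return _BASES_BYTES[np.asarray(indices, dtype=np.int64)].tobytes().decode("ascii")


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence restricted to the ACGT alphabet.

    Positions are 1-based and inclusive throughout; ambiguity codes are
    rejected so that hydrogen-bond and composition arithmetic stay exact.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("sequence must be non-empty")
        encode(self.bases)  # validates the alphabet

    def __len__(self) -> int:
        return len(self.bases)

    def base(self, position: int) -> str:
        """Base at a 1-based position."""
        if not 1 <= position <= len(self.bases):
            raise IndexError(f"position {position} outside 1..{len(self.bases)}")
        return self.bases[position - 1]

    def region(self, start: int, end: int) -> str:
        """Subsequence spanning 1-based inclusive ``start..end``."""
        if not 1 <= start <= end <= len(self.bases):
            raise IndexError(f"region {start}..{end} outside 1..{len(self.bases)}")
        return self.bases[start - 1 : end]

    def codon(self, codon_index: int) -> str:
        """Codon ``k`` spanning nt ``3k-2 .. 3k``."""
        return self.region(3 * codon_index - 2, 3 * codon_index)

    def to_array(self) -> np.ndarray:
        return encode(self.bases)

    def reverse_complement(self, new_id: str | None = None) -> "NucleotideSequence":
        return NucleotideSequence(new_id or f"{self.id}_rc", reverse_complement(self.bases))


def codon_of(position: int) -> int:
    """Codon index containing a 1-based CDS position."""
    if position < 1:
        raise ValueError("CDS positions are 1-based")
    return (position + 2) // 3


def codon_span(codon_index: int) -> tuple[int, int]:
    """1-based inclusive nucleotide span of a codon."""
    return 3 * codon_index - 2, 3 * codon_index
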