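"""Mutation matrices, site frequencies, and base-composition summaries.

These are the read-level analyses applied to amplicon sequencing of a
mutagenized coding sequence: the 4x4 substitution-count matrix (reported
without pyrimidine-strand collapsing, so C→T and G→A stay separate),
per-site substitution frequencies with hotspot-codon roll-ups, and A+T
enrichment arithmetic for whole-genome base-composition shifts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sequence import BASES, NucleotideSequence
from .synthetic_data import ReadSet

__all__ = [
    "MutationMatrix",
    "CompositionSummary",
    "HOTSPOT_CODON_POSITIONS",
    "tally_matrix",
    "overall_frequency",
    "site_frequency",
    "hotspot_codon_report",
    "base_composition",
    "at_enrichment",
]

#: Nucleotide positions (1-based CDS) of the three RAS hotspot codons.
HOTSPOT_CODON_POSITIONS = {12: (34, 35, 36), 13: (37, 38, 39), 61: (181, 182, 183)}

#: Diploid human genome size used for absolute A+T-gain projections.
DEFAULT_GENOME_BP = 6.2e9


@dataclass
class MutationMatrix:
    """4x4 substitution counts ``counts[ref][obs]`` plus per-base coverage.

    Coverage of a reference base is the total number of sequenced bases
    compared against it, i.e. the row sum, so frequencies are normalized by
    coverage rather than by the mismatch total.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 4):
            raise ValueError("counts must be 4x4 (rows=ref base, cols=observed)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def coverage(self) -> np.ndarray:
        """Sequenced-base totals per reference base (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def total_coverage(self) -> int:
        return int(self.counts.sum())

    @property
    def total_mismatches(self) -> int:
        return int(self.counts.sum() - np.trace(self.counts))

    def frequency(self) -> np.ndarray:
        """Per-cell frequencies ``counts/coverage``; NaN where uncovered."""
        cov = self.coverage.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov[:, None] > 0, self.counts / cov[:, None], np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(BASES), columns=list(BASES))

    def frequency_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.frequency(), index=list(BASES), columns=list(BASES))


@dataclass(frozen=True)
class CompositionSummary:
    """Base percentages of total bases; always sums to 100."""

    a: float
    c: float
    g: float
    t: float

    def __post_init__(self) -> None:
        for name, v in zip("acgt", (self.a, self.c, self.g, self.t)):
            if v < 0:
                raise ValueError(f"{name.upper()}% must be non-negative")
        total = self.a + self.c + self.g + self.t
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"composition must sum to 100%, got {total}")

    @property
    def at_percent(self) -> float:
        return self.a + self.t

    @property
    def gc_percent(self) -> float:
        return self.c + self.g

    def as_dict(self) -> dict[str, float]:
        return {"A": self.a, "C": self.c, "G": self.g, "T": self.t}


def _iter_anchored(
    reads: ReadSet | Iterable[NucleotideSequence | tuple[str, int]],
) -> Iterable[tuple[str, int]]:
    """Yield (bases, 1-based offset) pairs from any accepted read container."""
    if isinstance(reads, ReadSet):
        for bases, _qual, offset in reads.reads:
            yield bases, offset
        return
    for item in reads:
        if isinstance(item, NucleotideSequence):
            yield item.bases, 1
        else:
            bases, offset = item
            yield bases, offset


def tally_matrix(reads, ref: NucleotideSequence) -> MutationMatrix:
    """Tally every compared base into a 4x4 (ref, observed) count matrix.

    ``reads`` may be a :class:`ReadSet`, a list of full-length product
    sequences (anchored at position 1), or ``(bases, offset)`` pairs. Reads
    must map ungapped within the reference.
    """
    ref_idx = ref.to_array()
    counts = np.zeros((4, 4), dtype=np.int64)
    for bases, offset in _iter_anchored(reads):
        end = offset + len(bases) - 1
        if offset < 1 or end > len(ref):
            raise ValueError(
                f"read spanning {offset}..{end} extends outside reference 1..{len(ref)}"
            )
        read_idx = NucleotideSequence("r", bases).to_array()
        np.add.at(counts, (ref_idx[offset - 1 : end], read_idx), 1)
    return MutationMatrix(counts)


def overall_frequency(matrix: MutationMatrix) -> float:
    """Total mismatches over total compared bases."""
    if matrix.total_coverage == 0:
        raise ValueError("zero total coverage; frequency undefined")
    return matrix.total_mismatches / matrix.total_coverage


def site_frequency(
    reads,
    ref: NucleotideSequence,
    positions: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-position coverage, alternative counts, and substitution frequency.

    Returns a frame indexed by 1-based position with columns ``ref``,
    ``coverage``, ``A``/``C``/``G``/``T`` observed counts, and
    ``frequency`` (non-reference fraction; NaN where coverage is zero —
    uncovered sites are flagged, never reported as 0).
    """
    L = len(ref)
    ref_idx = ref.to_array()
    obs = np.zeros((L, 4), dtype=np.int64)
    for bases, offset in _iter_anchored(reads):
        end = offset + len(bases) - 1
        if offset < 1 or end > L:
            raise ValueError(
                f"read spanning {offset}..{end} extends outside reference 1..{L}"
            )
        read_idx = NucleotideSequence("r", bases).to_array()
        np.add.at(obs, (np.arange(offset - 1, end), read_idx), 1)

    coverage = obs.sum(axis=1)
    ref_counts = obs[np.arange(L), ref_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(coverage > 0, (coverage - ref_counts) / coverage, np.nan)
    table = pd.DataFrame(
        {
            "ref": list(ref.bases),
            "coverage": coverage,
            **{b: obs[:, i] for i, b in enumerate(BASES)},
            "frequency": freq,
        },
        index=pd.RangeIndex(1, L + 1, name="position"),
    )
    if positions is not None:
        positions = list(positions)
        bad = [p for p in positions if not 1 <= p <= L]
        if bad:
            raise ValueError(f"positions outside reference 1..{L}: {bad}")
        table = table.loc[positions]
    return table


def hotspot_codon_report(table: pd.DataFrame) -> pd.DataFrame:
    """Mean per-site frequency for hotspot codons 12, 13 and (if covered) 61.

    Requires the codon-12/13 positions (nt 34-39); codon 61 (nt 181-183) is
    included when those positions are present, as for a full-length CDS but
    not for the short exon-2 amplicon.
    """
    required = HOTSPOT_CODON_POSITIONS[12] + HOTSPOT_CODON_POSITIONS[13]
    missing = [p for p in required if p not in table.index]
    if missing:
        raise ValueError(f"site-frequency table missing required positions {missing}")
    rows = []
    for codon, span in HOTSPOT_CODON_POSITIONS.items():
        if codon == 61 and not all(p in table.index for p in span):
            continue
        freqs = table.loc[list(span), "frequency"].to_numpy(dtype=float)
        rows.append(
            {
                "codon": codon,
                "positions": f"{span[0]}-{span[-1]}",
                "mean_frequency": float(np.mean(freqs)),
            }
        )
    return pd.DataFrame(rows).set_index("codon")


def base_composition(source) -> CompositionSummary:
    """Percentages of A/C/G/T from a sequence or per-base counts."""
    if isinstance(source, NucleotideSequence):
        seq = source.bases
        counts = {b: seq.count(b) for b in BASES}
    elif isinstance(source, str):
        counts = {b: source.count(b) for b in BASES}
        if sum(counts.values()) != len(source):
            raise ValueError("sequence contains non-ACGT symbols")
    elif isinstance(source, dict):
        counts = {b: float(source.get(b, 0)) for b in BASES}
    else:
        arr = np.asarray(source, dtype=float)
        if arr.shape != (4,):
            raise ValueError("counts must be a length-4 vector in ACGT order")
        counts = dict(zip(BASES, arr))
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("empty input: no bases to summarize")
    return CompositionSummary(*(100.0 * counts[b] / total for b in BASES))


def at_enrichment(
    before: CompositionSummary,
    after: CompositionSummary,
    genome_bp: float = DEFAULT_GENOME_BP,
) -> dict[str, float]:
    """A+T fold change and the absolute nucleotide gain it implies.

    ``fold`` is the ratio of A+T percentages; ``absolute_gain`` projects the
    excess onto a genome of ``genome_bp`` base pairs:
    ``(fold - 1) * (AT%_before / 100) * genome_bp``.
    """
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    if before.at_percent == 0:
        raise ValueError("baseline A+T percentage is zero; fold undefined")
    fold = after.at_percent / before.at_percent
    gain = (fold - 1.0) * (before.at_percent / 100.0) * genome_bp
    return {"fold": fold, "absolute_gain": gain}
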