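"""Codon-level annotation of coding variants and stability classification.

Annotates single-nucleotide coding variants against a CDS using the
standard genetic code, flags the RAS hotspot codons (12, 13, 61), applies
the codon-12 transforming-residue rule (any replacement of Gly12 except
Pro confers the transformed phenotype), and classifies predicted ΔΔG
stability changes with strict ±3 kcal/mol thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from Bio.Seq import Seq

from .sequence import NucleotideSequence, codon_of, codon_span

__all__ = [
    "CodingVariant",
    "Consequence",
    "StabilityRecord",
    "HRAS_MUTANT_DDG",
    "annotate",
    "apply_variant",
    "is_transforming",
    "classify_stability",
    "count_by_class",
]

HOTSPOT_CODONS = frozenset({12, 13, 61})
#: The CG→TA transition class: C→T on one strand is G→A on the other.
_TRANSITIONS_CG_TA = frozenset({("C", "T"), ("G", "A")})

#: FoldX-style ΔΔG predictions (kcal/mol) for the seven single HRAS point
#: mutants recovered from biased-dNTP mutagenesis, relative to wild type.
HRAS_MUTANT_DDG: dict[str, float] = {
    "Cys186Tyr": -0.49,
    "Val187Met": -0.36,
    "Gly12Cys": -0.076,
    "Ala11Val": 0.88,
    "Thr74Ile": -0.45,
    "Glu143Lys": 3.2,
    "Gly10Asp": 21.0,
}


@dataclass(frozen=True)
class CodingVariant:
    """A single-nucleotide substitution at a 1-based CDS position."""

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        for base in (self.ref, self.alt):
            if base not in "ACGT":
                raise ValueError(f"invalid base {base!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.position < 1:
            raise ValueError("CDS positions are 1-based")

    def __str__(self) -> str:
        return f"{self.ref}{self.position}{self.alt}"


@dataclass(frozen=True)
class Consequence:
    """Codon-level annotation of a coding variant."""

    variant: CodingVariant
    codon_index: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    synonymous: bool
    hotspot: bool
    transition: bool

    @property
    def label(self) -> str:
        return f"{self.ref_aa}{self.codon_index}{self.alt_aa}"


@dataclass(frozen=True)
class StabilityRecord:
    """A labeled ΔΔG prediction with its stability class."""

    label: str
    ddg: float
    stability_class: str

    def __post_init__(self) -> None:
        expected = classify_stability(self.ddg)
        if self.stability_class != expected:
            raise ValueError(
                f"class {self.stability_class!r} inconsistent with ddg={self.ddg} "
                f"(expected {expected!r})"
            )


def annotate(variant: CodingVariant, cds: NucleotideSequence) -> Consequence:
    """Annotate a variant against a CDS (length must be a codon multiple)."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    if variant.position > len(cds):
        raise ValueError(f"position {variant.position} outside CDS 1..{len(cds)}")
    observed = cds.base(variant.position)
    if observed != variant.ref:
        raise ValueError(
            f"variant ref {variant.ref} does not match CDS base {observed} at "
            f"position {variant.position}"
        )
    codon_index = codon_of(variant.position)
    start, _ = codon_span(codon_index)
    ref_codon = cds.codon(codon_index)
    within = variant.position - start
    alt_codon = ref_codon[:within] + variant.alt + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return Consequence(
        variant=variant,
        codon_index=codon_index,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        synonymous=ref_aa == alt_aa,
        hotspot=codon_index in HOTSPOT_CODONS,
        transition=(variant.ref, variant.alt) in _TRANSITIONS_CG_TA,
    )


def apply_variant(cds: NucleotideSequence, variant: CodingVariant) -> NucleotideSequence:
    """Return the CDS with the variant applied (ref checked first)."""
    if cds.base(variant.position) != variant.ref:
        raise ValueError(
            f"variant ref {variant.ref} does not match CDS at {variant.position}"
        )
    bases = cds.bases[: variant.position - 1] + variant.alt + cds.bases[variant.position :]
    return NucleotideSequence(f"{cds.id}_{variant}", bases)


def is_transforming(consequence: Consequence) -> bool:
    """Codon-12 transforming rule: any non-Gly, non-Pro replacement of Gly12.

    Codons 13 and 61 are surfaced through the hotspot flag only; the
    phenotype rule is stated for the glycine at position 12.
    """
    return (
        consequence.codon_index == 12
        and not consequence.synonymous
        and consequence.alt_aa not in ("G", "P")
    )


def classify_stability(ddg: float) -> str:
    """Classify a ΔΔG (kcal/mol): stabilizing < -3, destabilizing > 3,
    neutral otherwise (strict inequalities; ±3 exactly is neutral)."""
    if not math.isfinite(ddg):
        raise ValueError(f"ddg must be finite, got {ddg}")
    if ddg < -3.0:
        return "stabilizing"
    if ddg > 3.0:
        return "destabilizing"
    return "neutral"


def count_by_class(records: Iterable) -> dict[str, int]:
    """Count stability classes; every class is present, possibly zero.

    ``records`` may be :class:`StabilityRecord` objects, ``(label, ddg)``
    pairs, or bare ΔΔG values.
    """
    counts = {"stabilizing": 0, "neutral": 0, "destabilizing": 0}
    n = 0
    for item in records:
        if isinstance(item, StabilityRecord):
            cls = item.stability_class
        elif isinstance(item, (tuple, list)):
            cls = classify_stability(float(item[1]))
        else:
            cls = classify_stability(float(item))
        counts[cls] += 1
        n += 1
    if n == 0:
        raise ValueError("no stability records supplied")
    return counts
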