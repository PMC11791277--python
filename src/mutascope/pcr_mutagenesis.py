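"""Error-prone PCR under an unbalanced dNTP pool.

The model: at each templated position the polymerase incorporates the
Watson-Crick partner with weight equal to that dNTP's concentration, and a
wrong base ``w`` with weight ``delta(template, w) * [dNTP_w]``, where the
discrimination factor ``delta`` is a small dimensionless constant. With an
excess of dTTP over dCTP the dominant mispair is dG:dT; because successive
copy events alternate strands, the same mispair surfaces as G→A and C→T in
equal measure on the reported strand — the CG→TA transition class.

A final molecule is modeled as a single lineage: over ``cycles`` thermal
cycles it is copied with probability ``dup_prob`` per cycle, each copy
applying the misincorporation model and flipping the strand. This preserves
per-product mutation-load statistics without tracking the exponentially
growing molecule population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .sequence import (
    BASES,
    BASE_INDEX,
    COMPLEMENT_INDEX,
    WATSON_CRICK,
    NucleotideSequence,
    decode,
)

__all__ = [
    "DNTPPool",
    "MisincorporationModel",
    "PCRRun",
    "incorporation_probs",
    "replication_step",
    "simulate_pcr",
    "mutation_frequency",
]


@dataclass(frozen=True)
class DNTPPool:
    """The four deoxynucleotide concentrations, in μM."""

    datp: float = 50.0
    dctp: float = 50.0
    dgtp: float = 50.0
    dttp: float = 50.0

    def __post_init__(self) -> None:
        for name, conc in self.as_dict().items():
            if conc <= 0:
                raise ValueError(f"[{name}] must be strictly positive, got {conc}")

    def as_dict(self) -> dict[str, float]:
        return {"dATP": self.datp, "dCTP": self.dctp, "dGTP": self.dgtp, "dTTP": self.dttp}

    def concentration(self, base: str) -> float:
        return {"A": self.datp, "C": self.dctp, "G": self.dgtp, "T": self.dttp}[base]

    @property
    def ratio_t_over_c(self) -> float:
        """The mutagenic driver [dTTP]/[dCTP]."""
        return self.dttp / self.dctp


#: Default discrimination factor for the transition-producing mispairs.
DEFAULT_TRANSITION_DELTA = 1e-4


@dataclass(frozen=True)
class MisincorporationModel:
    """Discrimination factors ``delta[(template, wrong_base)]``.

    ``delta`` is dimensionless and multiplies the wrong dNTP's
    concentration; pairs not listed fall back to ``default_delta``. The
    Watson-Crick partner never appears as a key (correct incorporation has
    implicit factor 1).
    """

    delta: dict[tuple[str, str], float] = field(default_factory=dict)
    default_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.default_delta < 0:
            raise ValueError("default_delta must be >= 0")
        for (tmpl, wrong), value in self.delta.items():
            if tmpl not in BASES or wrong not in BASES:
                raise ValueError(f"invalid base pair ({tmpl}, {wrong})")
            if wrong == WATSON_CRICK[tmpl]:
                raise ValueError(
                    f"({tmpl}, {wrong}) is the Watson-Crick pairing; "
                    "delta applies to wrong incorporations only"
                )
            if value < 0:
                raise ValueError(f"delta({tmpl}, {wrong}) must be >= 0")

    def delta_for(self, template: str, wrong: str) -> float:
        return self.delta.get((template, wrong), self.default_delta)

    @classmethod
    def transition_bias(cls, delta: float = DEFAULT_TRANSITION_DELTA) -> "MisincorporationModel":
        """The two mispairs behind CG→TA transitions: G:dTTP and C:dATP."""
        return cls(delta={("G", "T"): delta, ("C", "A"): delta}, default_delta=0.0)

    @classmethod
    def perfect(cls) -> "MisincorporationModel":
        return cls(delta={}, default_delta=0.0)


@dataclass(frozen=True)
class PCRRun:
    """Cycling parameters for a lineage-sampled PCR."""

    cycles: int = 50
    dup_prob: float = 0.9
    n_products: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if not 0.0 < self.dup_prob <= 1.0:
            raise ValueError("dup_prob must lie in (0, 1]")
        if self.n_products < 1:
            raise ValueError("n_products must be >= 1")


def incorporation_probs(
    template_base: str, pool: DNTPPool, model: MisincorporationModel
) -> np.ndarray:
    """Incorporation probability vector over A, C, G, T.

    The correct (Watson-Crick) base carries weight equal to its dNTP
    concentration; each wrong base carries ``delta * [dNTP]``. The vector is
    the normalized weights, hence monotone increasing in the correct dNTP's
    concentration.
    """
    if template_base not in BASES:
        raise ValueError(f"invalid template base {template_base!r}")
    correct = WATSON_CRICK[template_base]
    weights = np.zeros(4)
    for base in BASES:
        conc = pool.concentration(base)
        if base == correct:
            weights[BASE_INDEX[base]] = conc
        else:
            weights[BASE_INDEX[base]] = model.delta_for(template_base, base) * conc
    return weights / weights.sum()


def _incorporation_matrix(pool: DNTPPool, model: MisincorporationModel) -> np.ndarray:
    """P[template, incorporated] for all four template bases."""
    return np.vstack([incorporation_probs(b, pool, model) for b in BASES])


class ReplicationResult(NamedTuple):
    copy: NucleotideSequence
    misincorporated_positions: list[int]  # 1-based template positions


def replication_step(
    template: NucleotideSequence,
    pool: DNTPPool,
    model: MisincorporationModel,
    rng: np.random.Generator,
) -> ReplicationResult:
    """Synthesize one complementary copy of ``template``.

    Each incorporated base is drawn independently from
    :func:`incorporation_probs`; the copy is returned 5'→3' (i.e. the
    reverse of the incorporation order), so a perfect polymerase returns
    the exact reverse complement.
    """
    tmpl_idx = template.to_array()
    probs = _incorporation_matrix(pool, model)
    cum = np.cumsum(probs, axis=1)
    u = rng.random(len(tmpl_idx))
    incorporated = (u[:, None] > cum[tmpl_idx]).sum(axis=1).astype(np.int8)
    correct = COMPLEMENT_INDEX[tmpl_idx]
    mis = np.nonzero(incorporated != correct)[0]
    copy = NucleotideSequence(f"{template.id}_copy", decode(incorporated[::-1]))
    return ReplicationResult(copy, [int(p) + 1 for p in mis])


def simulate_pcr(
    template: NucleotideSequence,
    pool: DNTPPool,
    model: MisincorporationModel,
    run: PCRRun,
) -> list[NucleotideSequence]:
    """Sample final PCR products as independent lineage walks.

    Each product starts as one strand of the double-stranded template
    (chosen uniformly); at each of ``run.cycles`` cycles it is copied with
    probability ``run.dup_prob``. A copy applies the misincorporation model
    and flips the tracked strand, so mispairs on either strand surface as
    both C→T and G→A after reporting. All products are returned in the
    template's orientation.
    """
    rng = np.random.default_rng(run.seed)
    probs = _incorporation_matrix(pool, model)
    # transition matrices in template-aligned space:
    # sense parent: aligned child base = complement(incorporated)
    m_sense = probs[:, COMPLEMENT_INDEX]
    # antisense parent: template base = complement(aligned), child aligned = incorporated
    m_anti = probs[COMPLEMENT_INDEX, :]
    cum_sense = np.cumsum(m_sense, axis=1)
    cum_anti = np.cumsum(m_anti, axis=1)

    n, L = run.n_products, len(template)
    aligned = np.tile(template.to_array(), (n, 1))
    # the starting material is double-stranded: a sampled product descends
    # from either original strand with equal probability, which balances
    # sense/antisense template exposures along the lineage
    antisense = rng.random(n) < 0.5
    for _ in range(run.cycles):
        copied = rng.random(n) < run.dup_prob
        for is_anti, cum in ((False, cum_sense), (True, cum_anti)):
            sel = copied & (antisense == is_anti)
            if not sel.any():
                continue
            block = aligned[sel]
            u = rng.random(block.shape)
            aligned[sel] = (u[:, :, None] > cum[block]).sum(axis=2).astype(np.int8)
        antisense[copied] = ~antisense[copied]

    return [
        NucleotideSequence(f"{template.id}_product_{i}", decode(aligned[i]))
        for i in range(n)
    ]


def mutation_frequency(
    products: list[NucleotideSequence], reference: NucleotideSequence
) -> float:
    """Per-base mismatch fraction of ``products`` against ``reference``."""
    if not products:
        raise ValueError("no products supplied")
    ref_idx = reference.to_array()
    mismatches = 0
    compared = 0
    for product in products:
        if len(product) != len(reference):
            raise ValueError(
                f"product {product.id} length {len(product)} != reference "
                f"length {len(reference)}"
            )
        mismatches += int((product.to_array() != ref_idx).sum())
        compared += len(reference)
    return mismatches / compared
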