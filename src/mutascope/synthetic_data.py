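"""Synthetic inputs with known ground truth.

Generators for every input the downstream analyses consume: a RAS-like
coding sequence with the canonical hotspot codons, amplicon read sets
carrying a configurable substitution spectrum, base-composition pairs with
a prescribed A+T fold change, and patient cohorts with paired tumor/healthy
melting temperatures. Every generator is a pure function of its arguments,
including the seed, so downstream estimates can be checked against the
embedded truth.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequence import BASES, NucleotideSequence, codon_span, decode, encode

__all__ = [
    "HOTSPOT_CODONS",
    "ReferenceSpec",
    "ReadSet",
    "CohortTable",
    "make_reference",
    "simulate_reads",
    "simulate_composition_pair",
    "simulate_cohort",
]

#: Codons pinned by the hotspot template, keyed by codon index. Codon 12
#: (GGC, nt 34-36) and codon 13 (GGT, nt 37-39) are the Gly hotspots; codon
#: 61 (CAG, nt 181-183) is the Gln hotspot; codons 11 (GCC) and 23 (CTG)
#: host the recurrent passenger variants C32>T and G69>A.
HOTSPOT_CODONS: dict[int, str] = {
    11: "GCC",
    12: "GGC",
    13: "GGT",
    23: "CTG",
    61: "CAG",
}

_GC_TOLERANCE = 0.02
_PLACEHOLDER_QUALITY = "F"  # Phred+33 for Q37


@dataclass(frozen=True)
class ReferenceSpec:
    """Recipe for a random reference sequence.

    With ``hotspot_template`` set the sequence is at least 183 nt long and
    carries the pinned codons of :data:`HOTSPOT_CODONS`; the remaining
    positions are drawn to bring the overall GC fraction within ±0.02 of
    ``gc_target``.
    """

    length: int
    gc_target: float = 0.5
    hotspot_template: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be positive")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ValueError("gc_target must lie in [0, 1]")
        if self.hotspot_template and self.length < 183:
            raise ValueError(
                "hotspot_template requires length >= 183 so that codon 61 "
                "(nt 181-183) fits inside the sequence"
            )


@dataclass
class ReadSet:
    """Ungapped amplicon reads plus the truth used to generate them.

    ``reads`` holds ``(bases, quality, offset)`` triples where ``offset`` is
    the 1-based reference position of the first read base. ``truth`` is the
    per-reference-position substitution probability vector.
    """

    reads: list[tuple[str, str, int]]
    truth: np.ndarray
    reference_id: str = ""

    def __post_init__(self) -> None:
        self.truth = np.asarray(self.truth, dtype=float)
        if ((self.truth < 0) | (self.truth > 1)).any():
            raise ValueError("truth probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.reads)

    def to_fastq(self, handle) -> None:
        """Write reads as Sanger/Phred+33 FASTQ, offsets in the description."""
        records = []
        for i, (bases, qual, offset) in enumerate(self.reads):
            rec = SeqRecord(
                Seq(bases),
                id=f"read_{i}",
                description=f"offset={offset}",
            )
            rec.letter_annotations["phred_quality"] = [ord(q) - 33 for q in qual]
            records.append(rec)
        SeqIO.write(records, handle, "fastq")

    def fastq_bytes(self) -> bytes:
        buf = io.StringIO()
        self.to_fastq(buf)
        return buf.getvalue().encode("ascii")

    @classmethod
    def from_fastq(cls, handle, truth: np.ndarray | None = None) -> "ReadSet":
        reads = []
        for rec in SeqIO.parse(handle, "fastq"):
            offset = 1
            for token in rec.description.split():
                if token.startswith("offset="):
                    offset = int(token.split("=", 1)[1])
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            reads.append((str(rec.seq), qual, offset))
        if truth is None:
            truth = np.zeros(0)
        return cls(reads=reads, truth=truth)


@dataclass
class CohortTable:
    """Per-patient tumor/healthy records with gene status and melting Tm.

    The backing frame has one row per (patient, tissue) with columns
    ``patient_id``, ``tissue`` (tumor|healthy), ``tm`` and one WT/mutant
    status column per gene.
    """

    frame: pd.DataFrame
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"patient_id", "tissue", "tm"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if not self.genes:
            self.genes = [
                c for c in self.frame.columns if c not in ("patient_id", "tissue", "tm")
            ]
        if not np.isfinite(self.frame["tm"].to_numpy(dtype=float)).all():
            raise ValueError("all Tm values must be finite")
        counts = self.frame.groupby("patient_id")["tissue"].value_counts().unstack(fill_value=0)
        for tissue in ("tumor", "healthy"):
            if tissue not in counts.columns or not (counts[tissue] == 1).all():
                bad = (
                    counts.index[counts.get(tissue, pd.Series(0, index=counts.index)) != 1]
                    .tolist()
                )
                raise ValueError(f"patients without exactly one {tissue} row: {bad}")

    @property
    def n_patients(self) -> int:
        return self.frame["patient_id"].nunique()

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.4f")

    @classmethod
    def from_tsv(cls, path) -> "CohortTable":
        return cls(frame=pd.read_csv(path, sep="\t"))


def make_reference(spec: ReferenceSpec) -> NucleotideSequence:
    """Draw a random reference sequence satisfying ``spec``.

    The number of G/C bases among the free (non-pinned) positions is chosen
    so that the realized whole-sequence GC fraction is as close as possible
    to ``gc_target``; with the hotspot template the pinned codons are placed
    first and excluded from that adjustment.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.length
    fixed: dict[int, str] = {}
    if spec.hotspot_template:
        for codon_index, codon in HOTSPOT_CODONS.items():
            start, _ = codon_span(codon_index)
            for k, base in enumerate(codon):
                fixed[start + k] = base  # 1-based
    free_positions = np.array([p for p in range(1, n + 1) if p not in fixed], dtype=int)
    fixed_gc = sum(1 for b in fixed.values() if b in "GC")
    target_gc_total = spec.gc_target * n
    gc_free = int(round(target_gc_total - fixed_gc))
    gc_free = min(max(gc_free, 0), len(free_positions))

    realized = (fixed_gc + gc_free) / n
    if abs(realized - spec.gc_target) > _GC_TOLERANCE:
        raise ValueError(
            f"gc_target {spec.gc_target:.3f} unattainable: pinned codons force "
            f"GC fraction {realized:.3f}"
        )

    bases = np.empty(n, dtype="U1")
    shuffled = rng.permutation(free_positions)
    gc_positions, at_positions = shuffled[:gc_free], shuffled[gc_free:]
    # split each pair evenly (accounting for pinned codons) so the two
    # strands carry symmetric substitution opportunities: a C->T load can
    # then be compared to G->A without a composition correction
    fixed_g = sum(1 for b in fixed.values() if b == "G")
    fixed_a = sum(1 for b in fixed.values() if b == "A")
    n_g = min(max(int(round((fixed_gc + gc_free) / 2)) - fixed_g, 0), gc_free)
    n_a = min(max(int(round((n - fixed_gc - gc_free) / 2)) - fixed_a, 0),
              len(at_positions))
    bases[gc_positions[:n_g] - 1] = "G"
    bases[gc_positions[n_g:] - 1] = "C"
    bases[at_positions[:n_a] - 1] = "A"
    bases[at_positions[n_a:] - 1] = "T"
    for pos, base in fixed.items():
        bases[pos - 1] = base
    label = "hotspot_ref" if spec.hotspot_template else "ref"
    return NucleotideSequence(f"{label}_L{n}_seed{spec.seed}", "".join(bases))


def _uniform_spectrum() -> np.ndarray:
    """Default conditional spectrum: uniform over the three alternatives."""
    spec = np.full((4, 4), 1.0 / 3.0)
    np.fill_diagonal(spec, 0.0)
    return spec


def _validate_spectrum(spectrum: np.ndarray) -> np.ndarray:
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != (4, 4):
        raise ValueError("spectrum must be a 4x4 matrix (rows: ref base ACGT)")
    if (spectrum < 0).any():
        raise ValueError("spectrum entries must be non-negative")
    if not np.allclose(np.diag(spectrum), 0.0):
        raise ValueError("spectrum diagonal (ref -> ref) must be zero")
    rowsums = spectrum.sum(axis=1)
    if not np.allclose(rowsums, 1.0, atol=1e-9):
        raise ValueError(
            f"spectrum rows must sum to 1 over the alternatives, got {rowsums}"
        )
    return spectrum


def simulate_reads(
    ref: NucleotideSequence,
    rate: float | np.ndarray,
    n_reads: int,
    read_len: int,
    seed: int,
    spectrum: np.ndarray | None = None,
) -> ReadSet:
    """Simulate ungapped amplicon reads with a known substitution truth.

    ``rate`` is a global per-base substitution probability or a per-site
    vector over the reference; substituted bases are drawn from the 4x4
    conditional ``spectrum`` (row = reference base, distribution over the
    three alternatives). Qualities are a constant Q37 placeholder.
    """
    if read_len < 1 or read_len > len(ref):
        raise ValueError("read_len must be in 1..len(ref)")
    if n_reads < 1:
        raise ValueError("n_reads must be positive")
    spectrum = _uniform_spectrum() if spectrum is None else _validate_spectrum(spectrum)
    L = len(ref)
    site_rate = np.broadcast_to(np.asarray(rate, dtype=float), (L,)).copy()
    if ((site_rate < 0) | (site_rate > 1)).any():
        raise ValueError("substitution probabilities must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    ref_idx = ref.to_array()
    offsets = rng.integers(1, L - read_len + 2, size=n_reads)  # 1-based start
    cols = offsets[:, None] - 1 + np.arange(read_len)[None, :]
    read_idx = ref_idx[cols].astype(np.int8)
    per_base_rate = site_rate[cols]
    mutate = rng.random(size=read_idx.shape) < per_base_rate
    if mutate.any():
        cum = np.cumsum(spectrum, axis=1)
        u = rng.random(size=int(mutate.sum()))
        rows = cum[read_idx[mutate]]
        read_idx[mutate] = (u[:, None] > rows).sum(axis=1).astype(np.int8)

    qual = _PLACEHOLDER_QUALITY * read_len
    reads = [
        (decode(read_idx[i]), qual, int(offsets[i])) for i in range(n_reads)
    ]
    return ReadSet(reads=reads, truth=site_rate, reference_id=ref.id)


def simulate_composition_pair(baseline, fold_at: float):
    """Baseline/treated base-composition pair with a prescribed A+T fold.

    The treated A+T percentage equals baseline A+T x ``fold_at``; the G+C
    complement absorbs the difference so the vector still sums to 100.
    Within each pair (A:T and G:C) the baseline proportions are preserved.
    Returns a ``(before, after)`` pair of
    :class:`~mutascope.mutation_spectrum.CompositionSummary`.
    """
    from .mutation_spectrum import CompositionSummary

    if fold_at <= 0:
        raise ValueError("fold_at must be positive")
    if not isinstance(baseline, CompositionSummary):
        baseline = CompositionSummary(*np.asarray(baseline, dtype=float))
    at_before = baseline.at_percent
    at_after = at_before * fold_at
    if at_after > 100.0 + 1e-9:
        raise ValueError(
            f"fold_at={fold_at} would push A+T to {at_after:.2f}% (> 100%)"
        )
    at_after = min(at_after, 100.0)
    gc_after = 100.0 - at_after
    if at_before == 0 and fold_at != 1.0:
        raise ValueError("baseline A+T is zero; fold change undefined")
    a_share = baseline.a / at_before if at_before > 0 else 0.5
    g_share = baseline.g / baseline.gc_percent if baseline.gc_percent > 0 else 0.5
    after = CompositionSummary(
        a=at_after * a_share,
        c=gc_after * (1 - g_share),
        g=gc_after * g_share,
        t=at_after * (1 - a_share),
    )
    return baseline, after


def simulate_cohort(
    n_patients: int,
    prevalence: dict[str, float],
    tm_wt: float = 78.7,
    delta_tm_mut: float = 1.3,
    noise_sd: float = 0.1,
    seed: int = 0,
    tm_gene: str | None = None,
) -> CohortTable:
    """Simulate a paired tumor/healthy cohort with per-gene mutation status.

    Exactly ``round(n_patients * prevalence[gene])`` patients carry a mutant
    tumor status for each gene. Tumor Tm of patients mutated in ``tm_gene``
    (the gene read out by the melting assay; defaults to ``"KRAS"`` when
    present, else the first gene) is drawn at ``tm_wt - delta_tm_mut`` plus
    Gaussian noise; all healthy tissues and WT tumors sit at ``tm_wt`` plus
    noise.
    """
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not prevalence:
        raise ValueError("at least one gene prevalence is required")
    for gene, p in prevalence.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"prevalence for {gene} outside [0, 1]: {p}")
    genes = list(prevalence)
    if tm_gene is None:
        tm_gene = "KRAS" if "KRAS" in genes else genes[0]
    if tm_gene not in genes:
        raise ValueError(f"tm_gene {tm_gene!r} not among genes {genes}")

    rng = np.random.default_rng(seed)
    status = {}
    for gene in genes:
        n_mut = int(np.floor(n_patients * prevalence[gene] + 0.5))
        carriers = rng.permutation(n_patients)[:n_mut]
        col = np.full(n_patients, "WT", dtype=object)
        col[carriers] = "mutant"
        status[gene] = col

    rows = []
    for i in range(n_patients):
        pid = f"P{i + 1:04d}"
        shift = delta_tm_mut if status[tm_gene][i] == "mutant" else 0.0
        tumor_tm = tm_wt - shift + rng.normal(0.0, noise_sd)
        healthy_tm = tm_wt + rng.normal(0.0, noise_sd)
        for tissue, tm in (("tumor", tumor_tm), ("healthy", healthy_tm)):
            row = {"patient_id": pid, "tissue": tissue, "tm": tm}
            for gene in genes:
                # healthy tissue is WT by construction
                row[gene] = status[gene][i] if tissue == "tumor" else "WT"
            rows.append(row)
    frame = pd.DataFrame(rows, columns=["patient_id", "tissue", "tm", *genes])
    return CohortTable(frame=frame, genes=genes)
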