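"""Cohort-level screening statistics.

Mutation-prevalence summaries, a paired tumor-versus-healthy Tm comparison
by one-sided sign-flip permutation, and ΔΔCt fold-change arithmetic for
relative qPCR quantification (e.g. cytosolic mtDNA release normalized to a
nuclear reference gene).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_data import CohortTable

__all__ = [
    "PrevalenceReport",
    "QpcrMeasurement",
    "TmShiftResult",
    "prevalence",
    "tm_shift_test",
    "ddct_fold",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class PrevalenceReport:
    """Mutant fraction for one gene; exact fraction plus display rounding."""

    gene: str
    n_mutant: int
    n_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_mutant <= self.n_total:
            raise ValueError("need 0 <= n_mutant <= n_total")
        if self.n_total == 0:
            raise ValueError("empty cohort")

    @property
    def percent(self) -> float:
        return 100.0 * self.n_mutant / self.n_total

    @property
    def percent_display(self) -> int:
        """Half-up integer rounding, the convention used for reporting."""
        return _round_half_up(self.percent)


@dataclass(frozen=True)
class QpcrMeasurement:
    """Paired cycle thresholds: target gene vs reference gene."""

    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ct_target) and np.isfinite(self.ct_reference)):
            raise ValueError("Ct values must be finite")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass(frozen=True)
class TmShiftResult:
    mean_delta_tm: float
    p_value: float
    n_pairs: int
    n_perm: int


def prevalence(table: CohortTable, gene: str) -> PrevalenceReport:
    """Per-patient mutant prevalence of ``gene``, counted on tumor rows."""
    if gene not in table.genes:
        raise ValueError(f"gene {gene!r} not in cohort table (has {table.genes})")
    tumor = table.frame[table.frame["tissue"] == "tumor"]
    n_mut = int((tumor[gene] == "mutant").sum())
    return PrevalenceReport(gene=gene, n_mutant=n_mut, n_total=len(tumor))


def paired_deltas(
    table: CohortTable, gene: str | None = None, status: str = "mutant"
) -> np.ndarray:
    """Per-patient tumor-minus-healthy Tm differences.

    When ``gene`` is given, restricted to patients whose tumor carries the
    requested ``status`` for that gene.
    """
    frame = table.frame
    tumor = frame[frame["tissue"] == "tumor"].set_index("patient_id")
    healthy = frame[frame["tissue"] == "healthy"].set_index("patient_id")
    unpaired = sorted(set(tumor.index) ^ set(healthy.index))
    if unpaired:
        raise ValueError(f"patients lacking a tissue pair: {unpaired}")
    if gene is not None:
        if gene not in table.genes:
            raise ValueError(f"gene {gene!r} not in cohort table")
        tumor = tumor[tumor[gene] == status]
    ids = tumor.index
    return (tumor["tm"] - healthy.loc[ids, "tm"]).to_numpy(dtype=float)


def tm_shift_test(
    table: CohortTable,
    gene: str | None = None,
    status: str = "mutant",
    n_perm: int = 9999,
    seed: int = 0,
) -> TmShiftResult:
    """One-sided paired sign-flip permutation test of a tumor Tm decrease.

    The statistic is the mean paired difference (tumor - healthy). Under
    the null of no shift each difference is sign-symmetric, so the
    permutation distribution flips signs uniformly; the p-value is the
    add-one-corrected probability of a permuted statistic at or below the
    observed one (one-sided: a Tm decrease is the alternative).
    """
    if n_perm < 999:
        raise ValueError("n_perm must be >= 999 for a usable permutation resolution")
    deltas = paired_deltas(table, gene=gene, status=status)
    if deltas.size == 0:
        raise ValueError("no patients match the requested filter")
    observed = float(deltas.mean())
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, deltas.size)) * 2 - 1
    perm_stats = signs @ deltas / deltas.size
    p = (1 + int((perm_stats <= observed).sum())) / (n_perm + 1)
    return TmShiftResult(
        mean_delta_tm=observed, p_value=p, n_pairs=int(deltas.size), n_perm=n_perm
    )


def ddct_fold(sample: QpcrMeasurement, calibrator: QpcrMeasurement) -> float:
    """Relative quantification ``2**(-ΔΔCt)`` of sample vs calibrator."""
    ddct = sample.delta_ct - calibrator.delta_ct
    return float(2.0 ** (-ddct))
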