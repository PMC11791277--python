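"""Thermodynamic selection and detection of AT-enriched alleles.

A CG→TA transition converts a three-hydrogen-bond G:C pair into a
two-bond A:T pair, lowering the duplex melting temperature. This module
makes that observable computable: hydrogen-bond counting, a GC-content
melting-temperature estimate (Marmur-Schildkraut form with salt and length
terms), synthetic SYBR-Green-style melting profiles with derivative-peak Tm
calling, Tm-shift classification of samples against a wild-type reference,
and denaturation-gradient (3D-PCR-style) selection in which AT-richer
amplicons are recovered at lower denaturation temperatures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequence import NucleotideSequence

__all__ = [
    "ThermoParams",
    "MeltingProfile",
    "SelectionResult",
    "hydrogen_bond_count",
    "gc_percent",
    "tm_estimate",
    "melt_curve",
    "classify_sample",
    "td_selection",
]

#: Tm gain per percentage point of GC, °C (Marmur-Schildkraut slope).
GC_SLOPE = 0.41
#: Shortest sequence for which the GC-content formula is considered valid.
MIN_TM_LENGTH = 14


@dataclass(frozen=True)
class ThermoParams:
    """Parameters of the melting model.

    ``na_molar`` is the monovalent cation concentration (mol/L);
    ``sigmoid_width`` the two-state transition width (°C);
    ``delta_tm_threshold`` the minimum Tm drop below wild type (°C) to call
    a sample mutant — the default 0.4 °C sits just below the smallest
    single-transition WT-mutant gap resolved by the assay (0.5 °C).
    """

    na_molar: float = 0.05
    sigmoid_width: float = 0.3
    delta_tm_threshold: float = 0.4

    def __post_init__(self) -> None:
        if self.na_molar <= 0:
            raise ValueError("na_molar must be positive")
        if self.sigmoid_width <= 0:
            raise ValueError("sigmoid_width must be positive")
        if self.delta_tm_threshold < 0:
            raise ValueError("delta_tm_threshold must be >= 0")


@dataclass
class MeltingProfile:
    """Fluorescence melt curve on a temperature grid with its called Tm."""

    temps: np.ndarray
    fluorescence: np.ndarray
    derivative: np.ndarray  # -dF/dT
    tm_called: float

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.derivative = np.asarray(self.derivative, dtype=float)
        if not (np.diff(self.temps) > 0).all():
            raise ValueError("temperature grid must be strictly increasing")
        if not self.temps[0] <= self.tm_called <= self.temps[-1]:
            raise ValueError("tm_called must lie within the temperature grid")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temperature_c": self.temps,
                "fluorescence": self.fluorescence,
                "neg_dF_dT": self.derivative,
            }
        )


@dataclass
class SelectionResult:
    """Per-temperature recovery sets of a denaturation-gradient run."""

    recovered: dict[float, set[str]]
    td: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"temperature_c": t, "sequence_id": sid, "recovered": sid in ids}
            for t, ids in sorted(self.recovered.items())
            for sid in sorted(self.td)
        ]
        return pd.DataFrame(rows)


def hydrogen_bond_count(seq: NucleotideSequence | str) -> int:
    """Hydrogen bonds of the perfect duplex: 3 per G:C pair, 2 per A:T pair.

    Additive over concatenation; one CG→TA transition lowers the count by
    exactly 1.
    """
    bases = seq.bases if isinstance(seq, NucleotideSequence) else seq
    NucleotideSequence("hb", bases)  # validates non-empty ACGT
    gc = sum(bases.count(b) for b in "GC")
    return 3 * gc + 2 * (len(bases) - gc)


def gc_percent(seq: NucleotideSequence | str) -> float:
    """GC base composition as a percentage of length."""
    bases = seq.bases if isinstance(seq, NucleotideSequence) else seq
    NucleotideSequence("gc", bases)
    return 100.0 * sum(bases.count(b) for b in "GC") / len(bases)


def tm_estimate(seq: NucleotideSequence | str, params: ThermoParams = ThermoParams()) -> float:
    """GC-content melting-temperature estimate, °C.

    ``Tm = 81.5 + 16.6 log10([Na+]) + 0.41 GC% - 675/L``. Strictly
    increasing in GC% at fixed length and salt, so one CG→TA transition in
    a window of length L lowers Tm by exactly ``0.41 * 100/L``. For windows
    shorter than 14 nt the formula is not valid; a nearest-neighbor model
    would be needed instead.
    """
    bases = seq.bases if isinstance(seq, NucleotideSequence) else seq
    if len(bases) < MIN_TM_LENGTH:
        raise ValueError(
            f"sequence length {len(bases)} < {MIN_TM_LENGTH}: the GC-content "
            "formula is unreliable; use a nearest-neighbor model for short probes"
        )
    return (
        81.5
        + 16.6 * math.log10(params.na_molar)
        + GC_SLOPE * gc_percent(bases)
        - 675.0 / len(bases)
    )


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def melt_curve(
    species: list[tuple[float, float]],
    params: ThermoParams = ThermoParams(),
    temps: np.ndarray | None = None,
    grid_step: float = 0.1,
) -> MeltingProfile:
    """Synthesize a melt curve for a mixture of duplex species.

    ``species`` is a list of ``(weight, Tm)`` pairs with non-negative
    weights summing to 1. Fluorescence is the weighted sum of two-state
    sigmoids ``logistic((Tm - T)/width)``; the negative derivative is taken
    by central differences on the grid and the Tm is called at its discrete
    argmax (no interpolation).
    """
    if not species:
        raise ValueError("species list must be non-empty")
    weights = np.array([w for w, _ in species], dtype=float)
    tms = np.array([tm for _, tm in species], dtype=float)
    if (weights < 0).any():
        raise ValueError("species weights must be non-negative")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"species weights must sum to 1, got {weights.sum()}")
    if temps is None:
        temps = np.arange(tms.min() - 5.0, tms.max() + 5.0 + grid_step / 2, grid_step)
    temps = np.asarray(temps, dtype=float)
    if temps[0] > tms.min() or temps[-1] < tms.max():
        raise ValueError("temperature grid must span all species Tm values")

    fluor = np.zeros_like(temps)
    for w, tm in zip(weights, tms):
        fluor += w * _logistic((tm - temps) / params.sigmoid_width)
    neg_deriv = -np.gradient(fluor, temps)
    tm_called = float(temps[int(np.argmax(neg_deriv))])
    return MeltingProfile(temps, fluor, neg_deriv, tm_called)


def classify_sample(
    sample: MeltingProfile, wt_tm: float, params: ThermoParams = ThermoParams()
) -> str:
    """Call a sample ``"mutant"`` iff its Tm sits at least
    ``delta_tm_threshold`` below the wild-type Tm, else ``"WT"``."""
    return "mutant" if wt_tm - sample.tm_called >= params.delta_tm_threshold else "WT"


def td_selection(
    seqs: list[NucleotideSequence],
    gradient: list[float],
    params: ThermoParams = ThermoParams(),
) -> SelectionResult:
    """Denaturation-gradient selection of AT-rich amplicons.

    Each sequence's denaturation temperature Td is its
    :func:`tm_estimate`; it is recovered at a gradient temperature T iff
    ``Td <= T`` (full denaturation, hard threshold), so recovery sets are
    nested non-decreasing in temperature and AT-enriched (mutated)
    sequences appear at lower temperatures than GC-rich ones.
    """
    if not gradient:
        raise ValueError("gradient must be non-empty")
    td = {s.id: tm_estimate(s, params) for s in seqs}
    recovered = {
        float(t): {sid for sid, d in td.items() if d <= t} for t in gradient
    }
    return SelectionResult(recovered=recovered, td=td)
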