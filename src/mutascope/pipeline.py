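"""Pipeline orchestration: one validated config, seeded stages, a manifest.

Stages run in dependency order (simulate → mutpcr → spectrum → melt →
select3d → consequence → cohort). Every stochastic stage derives its own
seed from the global seed by a fixed counter scheme (``seed + 1000 * stage
index``), so any stage can be reproduced in isolation. Re-running an
identical config reproduces byte-identical artifacts; the manifest lists
every produced file with its SHA-256 digest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import cohort_screen, io, mutation_spectrum, pcr_mutagenesis, thermo_select
from .sequence import NucleotideSequence
from .synthetic_data import (
    ReferenceSpec,
    make_reference,
    simulate_cohort,
    simulate_composition_pair,
    simulate_reads,
)
from .variant_consequence import (
    HRAS_MUTANT_DDG,
    CodingVariant,
    annotate,
    classify_stability,
    is_transforming,
)

logger = logging.getLogger("mutascope.pipeline")

STAGE_ORDER = [
    "simulate",
    "mutpcr",
    "spectrum",
    "melt",
    "select3d",
    "consequence",
    "cohort",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    length: int = 183
    gc_target: float = 0.55
    hotspot_template: bool = True
    n_reads: int = 2000
    read_len: int = 150
    rate: float = 0.0072
    n_patients: int = 135
    prevalence: dict[str, float] = Field(
        default_factory=lambda: {"KRAS": 39 / 135, "BRAF": 19 / 135, "PI3K": 16 / 135}
    )
    tm_wt: float = 78.7
    delta_tm_mut: float = 1.3
    noise_sd: float = 0.1
    composition_baseline: list[float] = Field(
        default_factory=lambda: [29.5, 20.5, 20.5, 29.5]
    )
    composition_fold_at: float = 1.03


class MutPcrConfig(_Strict):
    dctp: float = 10.0
    dttp: float = 1000.0
    datp: float = 50.0
    dgtp: float = 50.0
    delta: float = pcr_mutagenesis.DEFAULT_TRANSITION_DELTA
    cycles: int = 30
    dup_prob: float = 0.9
    n_products: int = 200


class SpectrumConfig(_Strict):
    source: str = "products"  # "products" or "reads"


class MeltConfig(_Strict):
    species: list[list[float]] = Field(default_factory=lambda: [[1.0, 77.4]])
    wt_tm: float = 78.7
    sigmoid_width: float = 0.3
    delta_tm_threshold: float = 0.4


class Select3dConfig(_Strict):
    gradient: list[float] = Field(
        default_factory=lambda: [78.0 + k for k in range(11)]
    )
    max_sequences: int = 50


class ConsequenceConfig(_Strict):
    variants: list[list] = Field(
        default_factory=lambda: [[32, "C", "T"], [34, "G", "T"], [69, "G", "A"]]
    )
    ddg: dict[str, float] = Field(default_factory=lambda: dict(HRAS_MUTANT_DDG))


class CohortStageConfig(_Strict):
    n_perm: int = 9999
    genes: list[str] | None = None


class RunConfig(_Strict):
    """Validated pipeline configuration; unknown keys are rejected."""

    stages: list[str] = Field(default_factory=lambda: list(STAGE_ORDER))
    seed: int = 0
    out_dir: str = "mutascope_out"
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    mutpcr: MutPcrConfig = Field(default_factory=MutPcrConfig)
    spectrum: SpectrumConfig = Field(default_factory=SpectrumConfig)
    melt: MeltConfig = Field(default_factory=MeltConfig)
    select3d: Select3dConfig = Field(default_factory=Select3dConfig)
    consequence: ConsequenceConfig = Field(default_factory=ConsequenceConfig)
    cohort: CohortStageConfig = Field(default_factory=CohortStageConfig)

    def model_post_init(self, _ctx) -> None:
        unknown = [s for s in self.stages if s not in STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: global seed plus 1000 x stage index, mod 2^31."""
    return (global_seed + 1000 * STAGE_ORDER.index(stage)) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} needs {path.name}, produced by the "
            f"{produced_by!r} stage; run it first or add it to `stages`"
        )
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages and return the artifact manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced: list[Path] = []
    stages = [s for s in STAGE_ORDER if s in config.stages]

    for stage in stages:
        logger.info("stage=%s seed=%d", stage, stage_seed(config.seed, stage))
        produced += _STAGE_RUNNERS[stage](config, out)

    manifest = {
        "stages": stages,
        "seed": config.seed,
        "files": {p.name: _sha256(p) for p in sorted(set(produced))},
        "config": json.loads(config.model_dump_json()),
    }
    _dump_json(manifest, out / "manifest.json")
    return manifest


def _run_simulate(config: RunConfig, out: Path) -> list[Path]:
    cfg = config.simulate
    seed = stage_seed(config.seed, "simulate")
    ref = make_reference(
        ReferenceSpec(
            length=cfg.length,
            gc_target=cfg.gc_target,
            hotspot_template=cfg.hotspot_template,
            seed=seed,
        )
    )
    io.write_fasta(ref, out / "reference.fasta")
    reads = simulate_reads(
        ref, cfg.rate, n_reads=cfg.n_reads, read_len=cfg.read_len, seed=seed + 1
    )
    io.write_fastq(reads, out / "reads.fastq")
    cohort = simulate_cohort(
        cfg.n_patients,
        cfg.prevalence,
        tm_wt=cfg.tm_wt,
        delta_tm_mut=cfg.delta_tm_mut,
        noise_sd=cfg.noise_sd,
        seed=seed + 2,
    )
    cohort.to_tsv(out / "cohort.tsv")
    before, after = simulate_composition_pair(
        cfg.composition_baseline, cfg.composition_fold_at
    )
    with open(out / "composition.tsv", "w") as fh:
        fh.write("condition\tA\tC\tG\tT\tAT\n")
        for name, comp in (("baseline", before), ("treated", after)):
            fh.write(
                f"{name}\t{comp.a:.6f}\t{comp.c:.6f}\t{comp.g:.6f}\t"
                f"{comp.t:.6f}\t{comp.at_percent:.6f}\n"
            )
    _dump_json(
        {"stage": "simulate", "seed": seed, **json.loads(cfg.model_dump_json())},
        out / "simulate_params.json",
    )
    return [
        out / "reference.fasta",
        out / "reads.fastq",
        out / "cohort.tsv",
        out / "composition.tsv",
        out / "simulate_params.json",
    ]


def _run_mutpcr(config: RunConfig, out: Path) -> list[Path]:
    cfg = config.mutpcr
    ref = io.read_single_fasta(_require(out / "reference.fasta", "mutpcr", "simulate"))
    pool = pcr_mutagenesis.DNTPPool(
        datp=cfg.datp, dctp=cfg.dctp, dgtp=cfg.dgtp, dttp=cfg.dttp
    )
    model = pcr_mutagenesis.MisincorporationModel.transition_bias(cfg.delta)
    run = pcr_mutagenesis.PCRRun(
        cycles=cfg.cycles,
        dup_prob=cfg.dup_prob,
        n_products=cfg.n_products,
        seed=stage_seed(config.seed, "mutpcr"),
    )
    products = pcr_mutagenesis.simulate_pcr(ref, pool, model, run)
    io.write_fasta(products, out / "products.fasta")
    freq = pcr_mutagenesis.mutation_frequency(products, ref)
    with open(out / "mutpcr_summary.tsv", "w") as fh:
        fh.write("dATP_uM\tdCTP_uM\tdGTP_uM\tdTTP_uM\tratio_T_over_C\tmutation_frequency\n")
        fh.write(
            f"{pool.datp:g}\t{pool.dctp:g}\t{pool.dgtp:g}\t{pool.dttp:g}\t"
            f"{pool.ratio_t_over_c:g}\t{freq:.6f}\n"
        )
    return [out / "products.fasta", out / "mutpcr_summary.tsv"]


def _run_spectrum(config: RunConfig, out: Path) -> list[Path]:
    cfg = config.spectrum
    ref = io.read_single_fasta(_require(out / "reference.fasta", "spectrum", "simulate"))
    if cfg.source == "products":
        source = io.read_fasta(_require(out / "products.fasta", "spectrum", "mutpcr"))
    elif cfg.source == "reads":
        source = io.read_fastq(_require(out / "reads.fastq", "spectrum", "simulate"))
    else:
        raise ValueError(f"spectrum.source must be 'products' or 'reads', got {cfg.source!r}")
    matrix = mutation_spectrum.tally_matrix(source, ref)
    matrix.to_frame().to_csv(out / "mutation_matrix.tsv", sep="\t")
    table = mutation_spectrum.site_frequency(source, ref)
    table.to_csv(out / "site_frequency.tsv", sep="\t", float_format="%.6g")
    hotspots = mutation_spectrum.hotspot_codon_report(table)
    _dump_json(
        {
            "overall_frequency": mutation_spectrum.overall_frequency(matrix),
            "codons": {
                str(codon): {
                    "positions": row["positions"],
                    "mean_frequency": row["mean_frequency"],
                }
                for codon, row in hotspots.iterrows()
            },
        },
        out / "hotspots.json",
    )
    return [out / "mutation_matrix.tsv", out / "site_frequency.tsv", out / "hotspots.json"]


def _run_melt(config: RunConfig, out: Path) -> list[Path]:
    cfg = config.melt
    params = thermo_select.ThermoParams(
        sigmoid_width=cfg.sigmoid_width, delta_tm_threshold=cfg.delta_tm_threshold
    )
    species = [(w, tm) for w, tm in cfg.species]
    lo = min(tm for _, tm in species + [(1.0, cfg.wt_tm)]) - 5.0
    hi = max(tm for _, tm in species + [(1.0, cfg.wt_tm)]) + 5.0
    profile = thermo_select.melt_curve(
        species, params, temps=np.arange(lo, hi + 0.05, 0.1)
    )
    profile.to_frame().to_csv(out / "melt_profile.csv", index=False, float_format="%.6g")
    call = thermo_select.classify_sample(profile, cfg.wt_tm, params)
    with open(out / "melt_calls.tsv", "w") as fh:
        fh.write("tm_called\twt_tm\tdelta_tm\tcall\n")
        fh.write(
            f"{profile.tm_called:.2f}\t{cfg.wt_tm:.2f}\t"
            f"{cfg.wt_tm - profile.tm_called:.2f}\t{call}\n"
        )
    return [out / "melt_profile.csv", out / "melt_calls.tsv"]


def _run_select3d(config: RunConfig, out: Path) -> list[Path]:
    cfg = config.select3d
    seqs = io.read_fasta(_require(out / "products.fasta", "select3d", "mutpcr"))
    seqs = seqs[: cfg.max_sequences]
    result = thermo_select.td_selection(seqs, cfg.gradient)
    result.to_frame().to_csv(out / "td_selection.tsv", sep="\t", index=False)
    return [out / "td_selection.tsv"]


def _run_consequence(config: RunConfig, out: Path) -> list[Path]:
    cfg = config.consequence
    ref = io.read_single_fasta(
        _require(out / "reference.fasta", "consequence", "simulate")
    )
    with open(out / "consequences.tsv", "w") as fh:
        fh.write(
            "position\tref\talt\tcodon\tref_codon\talt_codon\tref_aa\talt_aa\t"
            "synonymous\thotspot\ttransition\ttransforming\n"
        )
        for pos, ref_base, alt_base in cfg.variants:
            cons = annotate(CodingVariant(int(pos), ref_base, alt_base), ref)
            fh.write(
                f"{pos}\t{ref_base}\t{alt_base}\t{cons.codon_index}\t"
                f"{cons.ref_codon}\t{cons.alt_codon}\t{cons.ref_aa}\t{cons.alt_aa}\t"
                f"{cons.synonymous}\t{cons.hotspot}\t{cons.transition}\t"
                f"{is_transforming(cons)}\n"
            )
    with open(out / "stability.tsv", "w") as fh:
        fh.write("mutation\tddg_kcal_mol\tclass\n")
        for label, ddg in cfg.ddg.items():
            fh.write(f"{label}\t{ddg:g}\t{classify_stability(ddg)}\n")
    return [out / "consequences.tsv", out / "stability.tsv"]


def _run_cohort(config: RunConfig, out: Path) -> list[Path]:
    from .synthetic_data import CohortTable

    cfg = config.cohort
    table = CohortTable.from_tsv(_require(out / "cohort.tsv", "cohort", "simulate"))
    genes = cfg.genes or table.genes
    _dump_json(
        {
            gene: {
                "n_mutant": (rep := cohort_screen.prevalence(table, gene)).n_mutant,
                "n_total": rep.n_total,
                "percent": rep.percent,
                "percent_display": rep.percent_display,
            }
            for gene in genes
        },
        out / "prevalence.json",
    )
    seed = stage_seed(config.seed, "cohort")
    with open(out / "tm_test.tsv", "w") as fh:
        fh.write("gene\tstatus\tn_pairs\tmean_delta_tm\tp_value\tn_perm\n")
        for gene in genes:
            res = cohort_screen.tm_shift_test(
                table, gene=gene, n_perm=cfg.n_perm, seed=seed
            )
            fh.write(
                f"{gene}\tmutant\t{res.n_pairs}\t{res.mean_delta_tm:.4f}\t"
                f"{res.p_value:.6f}\t{res.n_perm}\n"
            )
    return [out / "prevalence.json", out / "tm_test.tsv"]


_STAGE_RUNNERS = {
    "simulate": _run_simulate,
    "mutpcr": _run_mutpcr,
    "spectrum": _run_spectrum,
    "melt": _run_melt,
    "select3d": _run_select3d,
    "consequence": _run_consequence,
    "cohort": _run_cohort,
}
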