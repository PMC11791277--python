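# Methods

## The misincorporation model

Error-prone PCR is modeled at the level of single incorporations. For a
template base `b` with Watson–Crick partner `b*`, the polymerase
incorporates `b*` with weight equal to its dNTP concentration, and a wrong
base `w` with weight `δ(b, w) · [dNTP_w]`, where `δ` is a dimensionless
discrimination factor. Probabilities are the normalized weights, so the
error rate at a G template under a dTTP excess is

```
p(G:dT) = δ·[dTTP] / ([dCTP] + δ·[dTTP] + …)
```

which is monotone in the [dTTP]/[dCTP] ratio — the mechanism by which the
pool bias sets the mutation load. The default model activates only the two
transition-producing mispairs, G:dTTP and C:dATP, with `δ = 1e-4`. No
kinetic constants are available for this quantity; δ is the model's one
free parameter and was fixed once at a value giving per-base loads of
order 0.1–10% across a 1–100-fold ratio sweep, the regime of interest.
All other mispairs default to δ = 0, so the simulated spectrum is exactly
CG→TA unless configured otherwise.

A final PCR product is sampled as an independent **lineage walk**: over
`cycles` thermal cycles (default 50; analyses here use 30) the molecule is
copied with probability `dup_prob` (default 0.9) per cycle. Each copy
applies the incorporation model base by base and flips the tracked strand;
products are reported in the template's orientation. Lineages start on a
uniformly chosen strand of the double-stranded starting material. This
matters: a lineage with k copy events exposes the two strands
`ceil(k/2)`/`floor(k/2)` times if it always starts on the sense strand,
which biases G→A over C→T by a few percent; the random start equalizes the
exposures, and C→T vs G→A balance is then a binomial question. Lineage
sampling preserves per-product mutation-load statistics without tracking
the exponentially growing population; it does not model amplification
yield, stalling after mismatches, proofreading, or indels.

## Synthetic data and what it does (not) emulate

All inputs are generated, seeded, and carry their ground truth:

- **References** (`make_reference`): random sequences with a target GC
  fraction (realized within ±0.02) and, optionally, the RAS hotspot
  template — codons 11/12/13/23/61 pinned to GCC/GGC/GGT/CTG/CAG at CDS
  nt 31–33, 34–36, 37–39, 67–69, 181–183 (1-based, codon k = nt 3k−2..3k),
  so the canonical variants C32>T (Ala11Val), G34>T (Gly12Cys) and G69>A
  (synonymous Leu23) are replayable. Within the G+C and A+T pools the two
  bases are assigned in exactly equal numbers, so the two strands present
  symmetric substitution opportunities and C→T can be compared with G→A
  without a composition correction. A real gene is not base-balanced; the
  generator trades that realism for an exact symmetry null.
- **Reads** (`simulate_reads`): ungapped substrings with i.i.d.
  substitutions at a global or per-site rate and a 4×4 conditional
  spectrum; constant Q37 qualities. No indels, adapters, duplicates, or
  quality structure — passing recovery tests therefore says nothing about
  alignment or trimming artifacts in real data.
- **Composition pairs** (`simulate_composition_pair`): the treated A+T
  percentage is baseline × fold; the G+C complement absorbs the difference
  (within each pair the baseline proportions are kept), so the pair
  round-trips exactly through `at_enrichment`.
- **Cohorts** (`simulate_cohort`): exactly `round(n·prevalence)` mutant
  patients per gene; tumor Tm of patients mutated in the assayed gene sits
  `delta_tm_mut` (default 1.3 °C, the scale of the observed wild-type vs
  Val12 gap) below the wild-type Tm (default 78.7 °C) with Gaussian noise
  (default 0.1 °C). Healthy tissue is always wild type — no field effects,
  no tumor purity, no heteroduplex intermediates.

## Spectrum analysis

Mutation matrices are 12-type (4×4 off-diagonal) without pyrimidine
collapsing, normalized by per-reference-base coverage. Zero-coverage
positions are reported as missing (NaN), never as 0. Hotspot roll-ups
average the three per-site frequencies of codons 12, 13 and — when the
table covers nt 181–183 — 61. `at_enrichment` projects a fold change onto
a genome of 6.2 Gbp (diploid human) by default:
`gain = (fold − 1) · AT%/100 · genome_bp`.

## Melting model

Tm uses the GC-content (Marmur–Schildkraut) form with salt and length
terms, `81.5 + 16.6·log10[Na+] + 0.41·GC% − 675/L`, defaulting to 50 mM
Na+. The model's virtue here is its exact coupling: one CG→TA transition
in a window of length L shifts Tm by −0.41·(100/L) °C, so all assertions
about shifts and orderings are closed-form. Absolute Tm values are not
calibrated to any instrument (dye and buffer effects are ignored), and
sequences under 14 nt are rejected rather than extrapolated; a
nearest-neighbor model is the natural extension point if absolute accuracy
is ever needed. Note that applying the formula to gene-wide GC contents of
59.1% vs 37.6% predicts an 8.8 °C offset while melting assays on short
amplicons report ~5 °C; only the sign and ordering are meaningful, since
the amplicon-local GC content is what the assay actually sees.

Melt curves are mixtures of two-state sigmoids `w·logistic((Tm−T)/width)`
(width default 0.3 °C) on a 0.1 °C grid; −dF/dT is taken by central
differences and the Tm is called at the discrete argmax (no
interpolation), so the call is exact to one grid step. Samples are called
mutant when the called Tm sits at least `delta_tm_threshold` (default
0.4 °C, just under the smallest single-transition gap the assay resolves,
0.5 °C) below the wild-type Tm. Denaturation-gradient selection is a hard
threshold — a sequence is recovered at temperature T iff its estimated
Td ≤ T — reproducing the all-or-nothing character of gradient lanes;
recovery sets are therefore nested in T by construction.

## Variant consequence and stability

Annotation uses the standard genetic code (single-nucleotide variants
only; multi-nucleotide changes are annotated independently). The
transforming rule is deliberately narrow: true only for non-synonymous
codon-12 changes to residues other than Pro, because that is the rule
established for the position-12 glycine; codons 13 and 61 carry the
hotspot flag but are not called transforming. ΔΔG classification is a
strict step function — stabilizing below −3 kcal/mol, destabilizing above
+3, neutral otherwise, with ±3 exactly classified neutral. The module
ships the seven FoldX-style ΔΔG predictions for the HRAS mutants recovered
from biased-dNTP mutagenesis (`HRAS_MUTANT_DDG`) as a reference dataset;
it does not compute ΔΔG from structure.

## Cohort statistics

The tumor-vs-healthy comparison is a one-sided paired sign-flip
permutation test on mean(tumor Tm − healthy Tm), chosen over a two-way
ANOVA because it is exact, assumption-light and seeded-reproducible; only
direction and significance are claimed. The p-value uses the add-one
convention `(1 + #{perm ≤ obs}) / (n_perm + 1)` (default 9999
permutations) so it can never be zero. Null calibration was checked by KS
uniformity over 200 null cohorts; power at the synthetic 1.3 °C effect
with 0.1 °C noise and 50 pairs is effectively 1. Prevalence percentages
round half-up to integers for display while the exact fraction is always
retained. ΔΔCt folds are `2^−(ΔCt_sample − ΔCt_calibrator)` with
ΔCt = Ct_target − Ct_reference.

## Pipeline determinism and problem sizes

Stage seeds derive from the global seed as `seed + 1000·stage_index`, so
any stage is reproducible in isolation; identical configs produce
byte-identical artifacts (SHA-256 in the manifest; logs are excluded from
hashing). TSVs are tab-delimited UTF-8 with mandatory headers; JSON uses
sorted keys.

Default analysis sizes — 2000 products × 30 cycles for the ratio sweep,
5×10⁴ reads × 150 nt for rate recovery, 135-patient cohorts with 9999
permutations, 200 null cohorts for calibration — were chosen so the
binomial/permutation resolution comfortably supports the assertions made
(3σ bands, p < 0.001) while the whole suite runs in well under a minute of
simulation time per analysis.

## Known limitations

- Per-base mutation frequency is the only load statistic; per-clone
  mutated fractions (and hence "mutations per sequence" style summaries)
  can be derived from products but are not modeled as a separate quantity.
- No amplification-efficiency model: the observed drop in PCR yield at
  extreme bias has no counterpart here.
- The melting model is relative, not absolute; empirical Td values cannot
  be reproduced, only orderings.
- Cohort simulation draws gene statuses independently across genes; real
  colorectal cohorts show mutual exclusivity between KRAS and BRAF.
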