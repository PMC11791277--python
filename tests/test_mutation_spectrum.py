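"""Mutation matrices, site frequencies, hotspot roll-ups, composition."""

import numpy as np
import pytest

from mutascope.mutation_spectrum import (
    CompositionSummary,
    at_enrichment,
    base_composition,
    hotspot_codon_report,
    overall_frequency,
    site_frequency,
    tally_matrix,
)
from mutascope.pcr_mutagenesis import (
    DNTPPool,
    MisincorporationModel,
    PCRRun,
    simulate_pcr,
)
from mutascope.sequence import BASE_INDEX, NucleotideSequence
from mutascope.synthetic_data import ReadSet, simulate_reads


def brute_force_matrix(reads, ref):
    """Independent oracle: per-read, per-base double loop."""
    counts = np.zeros((4, 4), dtype=int)
    for bases, _qual, offset in reads.reads:
        for k, obs in enumerate(bases):
            counts[BASE_INDEX[ref.bases[offset - 1 + k]], BASE_INDEX[obs]] += 1
    return counts


class TestTallyMatrix:
    def test_identical_reads_have_zero_off_diagonal(self, hotspot_ref):
        reads = simulate_reads(hotspot_ref, 0.0, n_reads=20, read_len=60, seed=0)
        m = tally_matrix(reads, hotspot_ref)
        off = m.counts.sum() - np.trace(m.counts)
        assert off == 0

    def test_hand_tally_on_two_reads(self):
        ref = NucleotideSequence("r", "ACGT")
        reads = ReadSet(reads=[("ACGT", "FFFF", 1), ("ATGT", "FFFF", 1)], truth=np.zeros(4))
        m = tally_matrix(reads, ref)
        c, t = BASE_INDEX["C"], BASE_INDEX["T"]
        assert m.counts[c, t] == 1
        assert m.coverage[c] == 2
        assert m.frequency()[c, t] == 0.5

    def test_count_conservation(self, hotspot_ref):
        reads = simulate_reads(hotspot_ref, 0.05, n_reads=500, read_len=100, seed=1)
        m = tally_matrix(reads, hotspot_ref)
        assert m.total_coverage == 500 * 100

    def test_matches_brute_force_oracle(self, hotspot_ref):
        reads = simulate_reads(hotspot_ref, 0.03, n_reads=1000, read_len=120, seed=2)
        m = tally_matrix(reads, hotspot_ref)
        assert (m.counts == brute_force_matrix(reads, hotspot_ref)).all()

    def test_read_past_reference_end_rejected(self, hotspot_ref):
        reads = ReadSet(reads=[("A" * 50, "F" * 50, 180)], truth=np.zeros(183))
        with pytest.raises(ValueError, match="180..229"):
            tally_matrix(reads, hotspot_ref)

    def test_biased_pcr_products_dominated_by_cg_to_ta(self, hotspot_ref):
        products = simulate_pcr(
            hotspot_ref,
            DNTPPool(dctp=10, dttp=1000),
            MisincorporationModel.transition_bias(),
            PCRRun(cycles=30, n_products=500, seed=3),
        )
        freq = tally_matrix(products, hotspot_ref).frequency()
        c, g, t, a = (BASE_INDEX[b] for b in "CGTA")
        ct, ga = freq[c, t], freq[g, a]
        others = [
            freq[i, j]
            for i in range(4)
            for j in range(4)
            if i != j and (i, j) not in ((c, t), (g, a))
        ]
        assert min(ct, ga) > max(others)


class TestOverallFrequency:
    def test_zero_off_diagonal(self, hotspot_ref):
        reads = simulate_reads(hotspot_ref, 0.0, n_reads=10, read_len=50, seed=0)
        assert overall_frequency(tally_matrix(reads, hotspot_ref)) == 0.0

    def test_arithmetic_72_over_10000(self):
        from mutascope.mutation_spectrum import MutationMatrix

        counts = np.diag([2500 - 18] * 4) + 18 * (np.ones((4, 4), dtype=int) - np.eye(4, dtype=int)) // 3
        m = MutationMatrix(counts)
        assert m.total_coverage == 10_000
        assert overall_frequency(m) == pytest.approx(m.total_mismatches / 10_000)

    def test_recovers_generator_rate(self, hotspot_ref):
        q = 0.0072
        reads = simulate_reads(hotspot_ref, q, n_reads=20_000, read_len=150, seed=4)
        n = 20_000 * 150
        se = np.sqrt(q * (1 - q) / n)
        assert abs(overall_frequency(tally_matrix(reads, hotspot_ref)) - q) <= 3 * se

    def test_zero_coverage_rejected(self):
        from mutascope.mutation_spectrum import MutationMatrix

        with pytest.raises(ValueError, match="coverage"):
            overall_frequency(MutationMatrix(np.zeros((4, 4), dtype=int)))


class TestSiteFrequency:
    def test_zero_rate_gives_zero_everywhere_covered(self, hotspot_ref):
        reads = simulate_reads(hotspot_ref, 0.0, n_reads=200, read_len=150, seed=5)
        table = site_frequency(reads, hotspot_ref)
        covered = table[table["coverage"] > 0]
        assert (covered["frequency"] == 0.0).all()

    def test_single_site_injection_recovered(self, hotspot_ref):
        rates = np.zeros(183)
        rates[33] = 0.02  # 1-based position 34
        reads = simulate_reads(hotspot_ref, rates, n_reads=5000, read_len=150, seed=6)
        table = site_frequency(reads, hotspot_ref)
        cov34 = table.loc[34, "coverage"]
        se = np.sqrt(0.02 * 0.98 / cov34)
        assert abs(table.loc[34, "frequency"] - 0.02) <= 3 * se
        se0 = np.sqrt(0.02 * 0.98 / table.loc[35, "coverage"])
        assert table.loc[35, "frequency"] <= 3 * se0

    def test_zero_coverage_positions_flagged_not_zero(self, hotspot_ref):
        reads = ReadSet(reads=[(hotspot_ref.region(1, 50), "F" * 50, 1)], truth=np.zeros(183))
        table = site_frequency(reads, hotspot_ref)
        assert np.isnan(table.loc[100, "frequency"])
        assert table.loc[100, "coverage"] == 0

    def test_subset_restriction_preserves_values(self, hotspot_ref):
        reads = simulate_reads(hotspot_ref, 0.02, n_reads=500, read_len=150, seed=7)
        full = site_frequency(reads, hotspot_ref)
        sub = site_frequency(reads, hotspot_ref, positions=[34, 35, 36])
        assert (sub["frequency"] == full.loc[[34, 35, 36], "frequency"]).all()

    def test_positions_outside_reference_rejected(self, hotspot_ref):
        reads = simulate_reads(hotspot_ref, 0.0, n_reads=5, read_len=50, seed=0)
        with pytest.raises(ValueError, match="outside"):
            site_frequency(reads, hotspot_ref, positions=[184])

    def test_subset_consistency_with_overall_frequency(self, hotspot_ref):
        """Coverage-weighted mean of site frequencies equals the aggregate
        mismatch fraction on the same positions."""
        reads = simulate_reads(hotspot_ref, 0.03, n_reads=400, read_len=150, seed=8)
        table = site_frequency(reads, hotspot_ref)
        covered = table[table["coverage"] > 0]
        weighted = (covered["frequency"] * covered["coverage"]).sum() / covered["coverage"].sum()
        m = tally_matrix(reads, hotspot_ref)
        assert weighted == pytest.approx(overall_frequency(m))

    def test_gc_hotspot_sites_more_mutable_than_at_sites(self, hotspot_ref):
        """Under [dTTP]>[dCTP] the G/C positions of codons 12/13/61 carry
        higher frequencies than the A/T positions nt 39 and 182."""
        products = simulate_pcr(
            hotspot_ref,
            DNTPPool(dctp=10, dttp=1000),
            MisincorporationModel.transition_bias(),
            PCRRun(cycles=30, n_products=2000, seed=9),
        )
        table = site_frequency(products, hotspot_ref)
        gc_sites = [34, 35, 36, 37, 38, 181, 183]
        at_sites = [39, 182]
        assert min(table.loc[gc_sites, "frequency"]) > max(table.loc[at_sites, "frequency"])


class TestHotspotReport:
    def test_all_zero_table(self, hotspot_ref):
        reads = simulate_reads(hotspot_ref, 0.0, n_reads=300, read_len=183, seed=0)
        report = hotspot_codon_report(site_frequency(reads, hotspot_ref))
        assert (report["mean_frequency"] == 0.0).all()
        assert list(report.index) == [12, 13, 61]

    def test_codon_12_is_mean_of_nt_34_36(self, hotspot_ref):
        table = site_frequency(
            ReadSet(reads=[(hotspot_ref.bases, "F" * 183, 1)], truth=np.zeros(183)),
            hotspot_ref,
        )
        table.loc[34, "frequency"] = 0.01
        table.loc[35, "frequency"] = 0.02
        table.loc[36, "frequency"] = 0.03
        report = hotspot_codon_report(table)
        assert report.loc[12, "mean_frequency"] == pytest.approx(0.02)
        assert report.loc[12, "positions"] == "34-36"

    def test_missing_required_positions_rejected(self, hotspot_ref):
        reads = simulate_reads(hotspot_ref, 0.0, n_reads=5, read_len=50, seed=0)
        table = site_frequency(reads, hotspot_ref, positions=[34, 35])
        with pytest.raises(ValueError, match="missing"):
            hotspot_codon_report(table)

    def test_codon_61_omitted_for_short_amplicon(self, hotspot_ref):
        # a 178-nt exon-2-style window covers codons 12/13 but not 61
        table = site_frequency(
            ReadSet(reads=[(hotspot_ref.region(1, 178), "F" * 178, 1)], truth=np.zeros(183)),
            hotspot_ref,
            positions=list(range(1, 179)),
        )
        report = hotspot_codon_report(table)
        assert list(report.index) == [12, 13]


class TestComposition:
    @pytest.mark.parametrize(
        "seq,expected_at",
        [("ATAT", 100.0), ("ACGT", 50.0), ("GGCC", 0.0)],
    )
    def test_sequence_at_percent(self, seq, expected_at):
        assert base_composition(seq).at_percent == expected_at

    def test_counts_input(self):
        comp = base_composition({"A": 30, "T": 29, "C": 21, "G": 20})
        assert comp.at_percent == pytest.approx(59.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            base_composition({"A": 0})

    def test_at_enrichment_identity(self):
        comp = CompositionSummary(29.5, 20.5, 20.5, 29.5)
        result = at_enrichment(comp, comp)
        assert result["fold"] == 1.0
        assert result["absolute_gain"] == 0.0

    def test_at_enrichment_diploid_genome_gain(self):
        before = CompositionSummary(29.5, 20.5, 20.5, 29.5)  # AT = 59%
        after = CompositionSummary(30.385, 19.615, 19.615, 30.385)  # AT = 59 * 1.03
        result = at_enrichment(before, after, genome_bp=6.2e9)
        assert result["fold"] == pytest.approx(1.03)
        assert result["absolute_gain"] == pytest.approx(0.03 * 0.59 * 6.2e9, rel=1e-6)

    def test_at_enrichment_hand_example(self):
        before = CompositionSummary(25.0, 25.0, 25.0, 25.0)  # AT = 50
        after = CompositionSummary(25.5, 24.5, 24.5, 25.5)  # AT = 51
        result = at_enrichment(before, after, genome_bp=1e6)
        assert result["fold"] == pytest.approx(1.02)
        assert result["absolute_gain"] == pytest.approx(1e4)

    def test_zero_baseline_at_rejected(self):
        gc_only = CompositionSummary(0.0, 50.0, 50.0, 0.0)
        with pytest.raises(ValueError, match="zero"):
            at_enrichment(gc_only, gc_only)
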