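"""Synthetic-data generator: determinism, planted structure, readout model."""

import numpy as np
import pytest

import deamseq as d
from deamseq.core import encode


class TestBuildReference:
    def test_deterministic_for_fixed_seed(self):
        a = d.build_reference(1, [("chr1", 10_000)], gc_fraction=0.5)
        b = d.build_reference(1, [("chr1", 10_000)], gc_fraction=0.5)
        assert a.contigs == b.contigs
        c = d.build_reference(2, [("chr1", 10_000)], gc_fraction=0.5)
        assert c.contigs != a.contigs

    def test_duplicate_contig_names_rejected(self):
        spikes = [("lambda", "ACGT" * 10, "unmodified"),
                  ("lambda", "TTTT" * 10, "all-5mC")]
        with pytest.raises(ValueError, match="duplicate"):
            d.build_reference(1, [("chr1", 100)], spike_ins=spikes)
        with pytest.raises(ValueError, match="duplicate"):
            d.build_reference(1, [("chr1", 100), ("chr1", 200)])

    def test_cpg_enrichment_raises_cpg_count(self):
        lo = d.build_reference(5, [("chr1", 50_000)], cpg_enrichment=1.0)
        hi = d.build_reference(5, [("chr1", 50_000)], cpg_enrichment=4.0)
        assert hi.contigs["chr1"].count("CG") > lo.contigs["chr1"].count("CG")

    def test_gc_fraction_controls_composition(self):
        ref = d.build_reference(7, [("chr1", 50_000)], gc_fraction=0.6,
                                cpg_enrichment=1.0)
        seq = ref.contigs["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.6) < 0.02

    @pytest.mark.parametrize("kwargs", [
        {"gc_fraction": 0.0}, {"gc_fraction": 1.0},
        {"cpg_enrichment": 0.0},
    ])
    def test_parameter_validation(self, kwargs):
        with pytest.raises(ValueError):
            d.build_reference(1, [("chr1", 100)], **kwargs)

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError):
            d.build_reference(1, [("chr1", 0)])

    def test_spike_ins_labeled(self, small_ref):
        assert small_ref.label("lambda_spike") == "unmodified"
        assert small_ref.label("spike_5mC") == "all-5mC"
        assert small_ref.label("chr1") == "genomic"


class TestPlantModifications:
    def test_zero_probabilities_give_empty_map(self, small_ref):
        mods = d.plant_modifications(small_ref, 0.0, 0.0, 0.0, seed=1)
        assert len(mods) == 0

    def test_full_cpg_5hmc_covers_every_cpg_cytosine(self, small_ref):
        mods = d.plant_modifications(small_ref, 0.0, 1.0, 0.0, seed=1)
        seq = small_ref.contigs["chr1"]
        n_cpg = seq.count("CG")
        entries = list(mods.iter_entries())
        assert all(st == "5hmC" for _, _, _, st in entries)
        # every CpG contributes a plus-strand C and a minus-strand C
        assert len(entries) == 2 * n_cpg
        plus = {(p) for c, p, s, _ in entries if s == "+"}
        for p in list(plus)[:50]:
            assert seq[p:p + 2] == "CG"

    def test_planted_count_matches_binomial(self):
        p = 0.1
        ref = d.build_reference(14, [("chr1", 150_000)], cpg_enrichment=1.0)
        mods = d.plant_modifications(ref, 0.0, p, 0.0, seed=2)
        n_cpg_cytosines = 2 * ref.contigs["chr1"].count("CG")
        assert n_cpg_cytosines > 10_000
        expect = n_cpg_cytosines * p
        tol = 4 * np.sqrt(n_cpg_cytosines * p * (1 - p))
        assert abs(len(mods) - expect) < tol

    def test_entries_address_reference_cytosines(self, small_ref):
        mods = d.plant_modifications(small_ref, 0.3, 0.1, 0.01, seed=3)
        mods.validate_against(small_ref)  # raises on violation

    def test_spike_in_contigs_skipped(self, small_ref):
        mods = d.plant_modifications(small_ref, 1.0, 0.0, 0.0, seed=4)
        contigs = {c for c, _, _, _ in mods.iter_entries()}
        assert contigs == {"chr1"}

    def test_probability_validation(self, small_ref):
        with pytest.raises(ValueError):
            d.plant_modifications(small_ref, -0.1, 0.0, 0.0, seed=1)
        with pytest.raises(ValueError):
            d.plant_modifications(small_ref, 0.7, 0.5, 0.0, seed=1)


class TestSimulateReads:
    def test_zero_depth_gives_empty_read_set(self, small_ref, ideal_model):
        reads = d.simulate_reads(small_ref, d.ModificationMap(), ideal_model,
                                 mean_depth=0.0, read_len=100, seed=1)
        assert len(reads) == 0

    def test_deterministic_fastq_for_fixed_seed(self, small_ref):
        mods = d.plant_modifications(small_ref, seed=5)
        a = d.simulate_reads(small_ref, mods, d.EA3A_V10, 2.0, 100, seed=9)
        b = d.simulate_reads(small_ref, mods, d.EA3A_V10, 2.0, 100, seed=9)
        assert a.fastq_text() == b.fastq_text()

    def test_read_length_and_truth_conservation(self, small_ref, ideal_model):
        reads = d.simulate_reads(small_ref, d.ModificationMap(), ideal_model,
                                 mean_depth=1.0, read_len=80, seed=2)
        assert all(len(s) == 80 for s in reads.sequences)
        assert len(reads.truth) == len(reads)
        L = {n: small_ref.length(n) for n in small_ref.contigs}
        for r in reads.truth.itertuples():
            assert 0 <= r.start <= L[r.contig] - 80

    def test_full_conversion_leaves_no_c_at_original_c(self, ideal_model):
        ref = d.ReferenceSet.from_pairs([("c", "AACGTTCCAGGTACCA" * 20)])
        reads = d.simulate_reads(ref, d.ModificationMap(), ideal_model,
                                 mean_depth=5.0, read_len=50, seed=3)
        seq = ref.contigs["c"]
        for r, s in zip(reads.truth.itertuples(), reads.sequences):
            frag = seq[r.start:r.start + 50]
            if r.strand == "+":
                for i, base in enumerate(frag):
                    if base == "C":
                        assert s[i] == "T"
            else:
                mol = d.revcomp(frag)
                for i, base in enumerate(mol):
                    if base == "C":
                        assert s[i] == "T"

    def test_planted_5hmc_always_reads_c_under_ideal_model(self, ideal_model):
        ref = d.ReferenceSet.from_pairs([("c", "ATACGATTAGGCATTA" * 30)])
        mods = d.ModificationMap()
        mods.add("c", 3, "+", "5hmC")  # the C of the first CG
        reads = d.simulate_reads(ref, mods, ideal_model, 20.0, 60, seed=4)
        seen = 0
        for r, s in zip(reads.truth.itertuples(), reads.sequences):
            if r.strand == "+" and r.start <= 3 < r.start + 60:
                assert s[3 - r.start] == "C"
                seen += 1
        assert seen > 0

    def test_read_len_validation(self, small_ref, ideal_model):
        with pytest.raises(ValueError):
            d.simulate_reads(small_ref, d.ModificationMap(), ideal_model,
                             1.0, 0, seed=1)
        with pytest.raises(ValueError):
            d.simulate_reads(small_ref, d.ModificationMap(), ideal_model,
                             1.0, 10_000, seed=1)  # longer than spike-ins


class TestSimulateColonies:
    def test_zero_probability_reproduces_substrate(self, substrate):
        model = d.DeaminationModel.uniform("none", 0.0, 0.0, 0.0)
        reads = d.simulate_colonies(substrate, "unmodified", model, 5, seed=1)
        assert all(s == substrate for s in reads.sequences)

    def test_full_probability_converts_every_cytosine(self, substrate, ideal_model):
        reads = d.simulate_colonies(substrate, "all-5mC", ideal_model, 5, seed=1)
        expect = substrate.replace("C", "T")
        assert all(s == expect for s in reads.sequences)

    def test_empty_substrate_rejected(self, ideal_model):
        with pytest.raises(ValueError):
            d.simulate_colonies("", "unmodified", ideal_model, 5, seed=1)

    def test_5hmc_leak_matches_binomial_quantiles(self, substrate):
        n_colonies = 50
        n_c = substrate.count("C")
        reads = d.simulate_colonies(substrate, "all-5hmC", d.EA3A_V10,
                                    n_colonies, seed=8)
        total_t = sum(
            sum(1 for a, b in zip(substrate, s) if a == "C" and b == "T")
            for s in reads.sequences
        )
        n = n_colonies * n_c
        p = 0.0016
        from scipy.stats import binom
        lo, hi = binom.ppf([0.0005, 0.9995], n, p)
        assert lo <= total_t <= hi


class TestSimulateMixture:
    def test_extreme_fractions_match_model_cells(self, substrate):
        for frac, expect in [(0.0, 0.0008), (1.0, 0.9984)]:
            rs = d.simulate_mixture(frac, 4000, substrate, d.EA3A_V10, seed=5)
            fr = d.amplicon_site_fractions(rs, substrate)
            pooled = fr["n_C"].sum() / (fr["n_C"].sum() + fr["n_T"].sum())
            se = np.sqrt(expect * (1 - expect) / 4000)
            assert abs(pooled - expect) < max(4 * se, 5e-4)

    def test_half_mixture_within_binomial_error(self, substrate):
        rs = d.simulate_mixture(0.5, 10_000, substrate, d.EA3A_V10, seed=6)
        fr = d.amplicon_site_fractions(rs, substrate)
        pooled = fr["n_C"].sum() / (fr["n_C"].sum() + fr["n_T"].sum())
        expect = 0.5 * 0.9984 + 0.5 * 0.0008
        se = np.sqrt(0.25 / 10_000)  # molecules are the independent unit
        assert abs(pooled - expect) < 4 * se

    def test_validation(self, substrate, ideal_model):
        with pytest.raises(ValueError):
            d.simulate_mixture(1.5, 10, substrate, ideal_model)
        with pytest.raises(ValueError):
            d.simulate_mixture(0.5, 0, substrate, ideal_model)


class TestSimulateKinetics:
    def test_saturation_limit(self):
        pts = d.simulate_kinetics(2.0, 0.5, 1.0, 0.4, [5000.0], 0.0, 1)
        assert pts[0].frac_deaminated == pytest.approx(2.0 * 1.0 * 0.4, rel=1e-3)

    def test_half_saturation_rate(self):
        pts = d.simulate_kinetics(2.0, 0.5, 1.0, 0.1, [0.5], 0.0, 1)
        # rate = k_cat/2 at [S] = K_M
        assert pts[0].frac_deaminated == pytest.approx(1.0 * 0.1 * 1.0)

    def test_clamped_to_unit_interval(self):
        pts = d.simulate_kinetics(10.0, 0.1, 10.0, 10.0, [5.0], 0.0, 1)
        assert pts[0].frac_deaminated == 1.0

    def test_substrate_validation(self):
        with pytest.raises(ValueError):
            d.simulate_kinetics(1.0, 1.0, 1.0, 1.0, [1.0, -0.5], 0.0, 1)
        with pytest.raises(ValueError):
            d.simulate_kinetics(-1.0, 1.0, 1.0, 1.0, [1.0], 0.0, 1)

    def test_default_assays_stay_in_unit_interval(self):
        for assay in d.KINETIC_DEFAULTS.values():
            pts = d.simulate_kinetics(
                assay.k_cat, assay.K_M, assay.enzyme_conc, assay.time,
                list(assay.substrate_concs), 0.0, 1)
            for p in pts:
                assert 0.0 < p.frac_deaminated < 1.0
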