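"""Generator contracts: calibration, exact counts, determinism, truth tables."""

import numpy as np
import pandas as pd
import pytest

from paraloci import synthetic_data as sd
from paraloci.locus_model import InputError


class TestFamily:
    def test_identity_calibration_within_one_point(self, family):
        realized = family.realized_identity.values
        assert np.abs(realized - sd.DEFAULT_IDENTITY).max() <= 1.0

    def test_focal_pair_identity_in_published_band(self, family):
        ident = family.realized_identity.loc[family.acceptor, family.donor]
        assert 92.7 <= ident <= 94.7

    def test_focal_pair_exon89_differs_by_three(self, family):
        e89 = family.diff_table[family.diff_table.region.isin(["exon 8", "exon 9"])]
        assert len(e89) == 3
        by_region = e89.region.value_counts()
        assert by_region["exon 8"] == 2 and by_region["exon 9"] == 1

    def test_generation_deterministic(self, family):
        again = sd.simulate_family(sd.FamilyConfig(seed=1))
        for name in family.genes:
            assert again.genes[name].sequence == family.genes[name].sequence
        pd.testing.assert_frame_equal(again.diff_table, family.diff_table)

    def test_identical_target_pair_possible(self):
        """A pair targeted at 100% identity collapses to equal sequences."""
        cfg = sd.FamilyConfig(
            n_loci=3,
            names=("CYP2D84", "CYP2D50-1", "CYP2D50-2"),
            target_identity=np.array([
                [100.0, 100.0, 93.7],
                [100.0, 100.0, 93.7],
                [93.7, 93.7, 100.0],
            ]),
            seed=0,
        )
        fam = sd.simulate_family(cfg)
        assert fam.genes["CYP2D84"].sequence == fam.genes["CYP2D50-1"].sequence

    def test_non_additive_matrix_rejected(self):
        t = sd.DEFAULT_IDENTITY.copy()
        t[0, 1] = t[1, 0] = 60.0  # wildly inconsistent with the rest
        with pytest.raises(sd.GenerationError):
            sd.simulate_family(sd.FamilyConfig(target_identity=t))

    def test_all_family_cds_translate_cleanly(self, family):
        for gene in family.genes.values():
            protein = gene.protein()
            assert protein.endswith("*") and "*" not in protein[:-1]

    def test_splice_dinucleotides_canonical(self, family):
        for gene in family.genes.values():
            exons = gene.exons
            for left, right in zip(exons, exons[1:]):
                intron = gene.sequence[left.end : right.start - 1]
                assert intron[:2] == "GT" and intron[-2:] == "AG"


class TestCohort:
    def test_singleton_variant_single_heterozygote(self, family):
        spec = sd.CohortSpec(
            n_samples=72,
            variants=(sd.VariantPlan("CYP2D50-1", 92, "G", "A", 1),),
            seed=5,
        )
        cohort = sd.simulate_cohort(family, spec)
        carriers = [
            (h1[91], h2[91]) for h1, h2 in cohort.haplotypes
            if "A" in (h1[91], h2[91])
        ]
        assert len(carriers) == 1 and sorted(carriers[0]) == ["A", "G"]

    def test_hybrid_allele_count_42_of_144(self, cohort):
        assert sum(a + b for a, b in cohort.hybrid_flags) == 42

    def test_exact_counts_realized(self, family, cohort):
        ref = family.acceptor_gene.sequence
        count = sum(
            (h1[4239] == "G") + (h2[4239] == "G") for h1, h2 in cohort.haplotypes
        )
        assert count == 61  # 42 hybrid tails + 19 planted alleles
        assert ref[4239] == "T"

    def test_binomial_mode_seeded_determinism(self, family):
        spec = sd.CohortSpec(
            n_samples=12,
            variants=(sd.VariantPlan("CYP2D50-1", 92, "G", "A", 6),),
            sampling_mode="binomial",
            seed=11,
        )
        a = sd.simulate_cohort(family, spec)
        b = sd.simulate_cohort(family, spec)
        assert a.haplotypes == b.haplotypes

    def test_excess_allele_count_rejected(self, family):
        with pytest.raises(InputError):
            sd.CohortSpec(
                n_samples=10,
                variants=(sd.VariantPlan("CYP2D50-1", 92, "G", "A", 21),),
            )

    def test_masked_site_never_converted(self, family, cohort):
        """Hybrid tails copy the donor's observed allele, so the confounded
        position keeps the acceptor base."""
        for (h1, h2), (f1, f2) in zip(cohort.haplotypes, cohort.hybrid_flags):
            for hap, flag in ((h1, f1), (h2, f2)):
                if flag:
                    assert hap[sd.MASKED_ACCEPTOR_POS - 1] == "C"
                    assert hap[3687] == "C"  # first tract site converted


class TestSangerConsensus:
    def test_equal_bases_pass_through(self):
        assert sd.simulate_sanger_consensus("AA", "AA").sequence == "AA"

    def test_heterozygous_iupac_code(self):
        assert sd.simulate_sanger_consensus("C", "T").sequence == "Y"
        assert sd.simulate_sanger_consensus("T", "C").sequence == "Y"

    def test_non_acgt_base_rejected(self):
        with pytest.raises(InputError):
            sd.simulate_sanger_consensus("AX", "AA")

    def test_het_deletion_recorded_as_event(self):
        cons = sd.simulate_sanger_consensus("ACGT", "A--T")
        assert cons.sequence == "ACGT"
        assert len(cons.indels) == 1
        ev = cons.indels[0]
        assert (ev.g_start, ev.g_end, ev.zygosity) == (2, 3, "HET")


class TestTranscripts:
    def test_empty_expressed_set(self, family):
        assert sd.simulate_transcripts(family, expressed=()) == []

    def test_six_expressed_loci(self, family):
        transcripts = sd.simulate_transcripts(family)
        loci = {tid.rsplit(".", 1)[0] for tid, _ in transcripts}
        assert loci == set(sd.EXPRESSED_DEFAULT)
        assert len(loci) == 6

    def test_copy_counts_respected(self, family):
        out = sd.simulate_transcripts(
            family, expressed={"CYP2D50-1"}, copy_counts={"CYP2D50-1": 4})
        assert len(out) == 4

    def test_unknown_locus_rejected(self, family):
        with pytest.raises(InputError):
            sd.simulate_transcripts(family, expressed={"CYP2D99"})


class TestQpcr:
    def test_perfect_efficiency_slope(self):
        plate = sd.simulate_qpcr(sd.QpcrSpec(seed=0))
        std = plate.standards[plate.standards.assay == "actin"]
        slope = np.polyfit(np.log10(std.quantity), std.ct, 1)[0]
        assert slope == pytest.approx(-1 / np.log10(2), abs=1e-9)
        assert abs(slope) == pytest.approx(3.3219, abs=1e-4)

    def test_seeded_determinism(self):
        a = sd.simulate_qpcr(sd.QpcrSpec(seed=9, ct_noise_sd=0.2))
        b = sd.simulate_qpcr(sd.QpcrSpec(seed=9, ct_noise_sd=0.2))
        pd.testing.assert_frame_equal(a.samples, b.samples)

    def test_invalid_specs_rejected(self):
        with pytest.raises(InputError):
            sd.QpcrSpec(ct_noise_sd=-1)
        with pytest.raises(InputError):
            sd.QpcrSpec(efficiency=1.5)
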