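"""Variant calling, annotation, frequencies, novelty."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from paraloci import synthetic_data as sd
from paraloci import variant_analysis as va
from paraloci.locus_model import InputError, Intronic


@pytest.fixture(scope="module")
def known_table():
    from importlib import resources
    with resources.files("paraloci.data").joinpath("known_variants.tsv").open() as fh:
        return va.KnownVariantTable.from_frame(pd.read_csv(fh, sep="\t"))


@pytest.fixture(scope="module")
def cohort_calls(cohort):
    return [
        va.call_variants(cohort.consensus(s), cohort.family.acceptor_gene)
        for s in range(cohort.spec.n_samples)
    ]


class TestCalling:
    def test_reference_consensus_yields_no_calls(self, family):
        gene = family.acceptor_gene
        assert va.call_variants(gene.sequence, gene) == []

    def test_ambiguity_code_decodes_to_het(self, family):
        gene = family.acceptor_gene
        seq = list(gene.sequence)
        assert seq[91] == "G"
        seq[91] = "R"  # A/G
        (call,) = va.call_variants("".join(seq), gene)
        assert (call.g_start, call.ref, call.alt, call.genotype) == (92, "G", "A", "HET")
        assert call.effect == "R31H"

    def test_plain_mismatch_decodes_to_mut(self, family):
        gene = family.acceptor_gene
        seq = list(gene.sequence)
        seq[4239] = "G"
        (call,) = va.call_variants("".join(seq), gene)
        assert call.genotype == "MUT"
        assert call.effect == "S491A"

    def test_invalid_symbol_rejected(self, family):
        gene = family.acceptor_gene
        with pytest.raises(InputError):
            va.call_variants("Z" + gene.sequence[1:], gene)

    def test_length_mismatch_rejected(self, family):
        gene = family.acceptor_gene
        with pytest.raises(InputError):
            va.call_variants(gene.sequence[:-1], gene)

    def test_full_cohort_round_trip_exact(self, cohort):
        """Generator truth table recovered exactly: precision = recall = 1."""
        per_sample = [
            va.call_variants(cohort.consensus(s), cohort.family.acceptor_gene,
                             merge_mnv=False)
            for s in range(cohort.spec.n_samples)
        ]
        called = {
            (s, int(r.g_start), r.ref, r.alt, r.genotype)
            for s, calls in enumerate(per_sample) for r in calls
        }
        truth = {
            (int(row["sample"]), int(row["g_start"]), row["ref"], row["alt"],
             row["genotype"])
            for _, row in cohort.truth.iterrows()
        }
        assert called == truth

    @pytest.mark.parametrize("seed", [11, 12])
    def test_recovery_across_seeds(self, family, seed):
        spec = sd.CohortSpec(
            n_samples=8,
            variants=(
                sd.VariantPlan("CYP2D50-1", 92, "G", "A", 3),
                sd.VariantPlan("CYP2D50-1", 500, "G", "T", 5)
                if family.acceptor_gene.sequence[499] == "G" else
                sd.VariantPlan("CYP2D50-1", 4226, "C", "T", 5),
            ),
            seed=seed,
        )
        cohort = sd.simulate_cohort(family, spec)
        per_sample = [
            va.call_variants(cohort.consensus(s), family.acceptor_gene,
                             merge_mnv=False)
            for s in range(8)
        ]
        called = {
            (s, int(r.g_start), r.ref, r.alt, r.genotype)
            for s, calls in enumerate(per_sample) for r in calls
        }
        truth = {
            (int(row["sample"]), int(row["g_start"]), row["ref"], row["alt"],
             row["genotype"])
            for _, row in cohort.truth.iterrows()
        }
        assert called == truth


class TestRegion:
    @pytest.mark.parametrize("pos,region", [
        (92, "exon 1"),
        (1, "exon 1"),
        (3688, "intron 7"),
        (189, "exon 1"),
        (190, "intron 1"),
    ])
    def test_region_classification(self, family, pos, region):
        assert va.classify_region(family.acceptor_gene, pos) == region


class TestEffect:
    def test_missense_r31h(self, family):
        assert va.annotate_effect(family.acceptor_gene, 92, "G", "A") == "R31H"

    def test_missense_s491a_codon_index(self, family):
        """g.4240 maps to c.1471; codon ceil(1471/3) = 491."""
        effect = va.annotate_effect(family.acceptor_gene, 4240, "T", "G")
        assert effect == "S491A"
        assert int(effect[1:-1]) == -(-1471 // 3) == 491

    def test_in_codon_mnv_translated_as_unit(self, family):
        assert va.annotate_effect(family.acceptor_gene, 2542, "AAG", "GGA") == "K248G"

    def test_eleven_bp_deletion_is_frameshift(self, family):
        gene = family.acceptor_gene
        ref = gene.sequence[3332:3343]
        assert ref == "CCACATGACAT"
        assert va.annotate_effect(gene, 3333, ref, "-") == "378 fs"

    def test_intronic_change(self, family):
        base = family.acceptor_gene.sequence[3687]
        alt = "A" if base != "A" else "C"
        assert va.annotate_effect(family.acceptor_gene, 3688, base, alt) == "intronic"

    def test_agrees_with_brute_force_translation_oracle(self, family):
        """Random exonic substitutions vs whole-CDS mutate-translate-diff."""
        gene = family.acceptor_gene
        smap = gene.splice_map
        cds = gene.cds()
        rng = np.random.default_rng(17)
        tested = 0
        while tested < 60:
            g = int(rng.integers(1, len(gene.sequence) + 1))
            c = smap.g_to_c(g)
            if isinstance(c, Intronic):
                continue
            ref = gene.sequence[g - 1]
            alt = "ACGT"[int(rng.integers(4))]
            if alt == ref:
                continue
            mutated = cds[: c - 1] + alt + cds[c:]
            prot_ref = str(Seq(cds).translate())
            prot_alt = str(Seq(mutated).translate())
            diffs = [
                (i + 1, a, b) for i, (a, b) in enumerate(zip(prot_ref, prot_alt))
                if a != b
            ]
            effect = va.annotate_effect(gene, g, ref, alt)
            if not diffs:
                assert effect == "synonymous"
            else:
                (idx, a, b), = diffs
                assert effect == f"{a}{idx}{b}"
            tested += 1


class TestFrequencies:
    def test_singleton_frequency(self):
        assert va.allele_frequency(1, 0, 72) == 0.69

    def test_zero_carriers(self):
        assert va.allele_frequency(0, 0, 72) == 0.0

    def test_mixed_zygosity(self):
        assert va.allele_frequency(25, 18, 72) == 42.36

    def test_zero_genotyped_rejected(self):
        with pytest.raises(InputError):
            va.allele_frequency(0, 0, 0)

    def test_planted_counts_reproduced(self, cohort, cohort_calls):
        aggregated = va.aggregate_cohort(cohort_calls, cohort.spec.n_samples)
        by_key = {v.key: v for v in aggregated}
        assert by_key[(92, "G", "A")].frequency_pct == 3.47
        assert by_key[(134, "G", "A")].frequency_pct == 0.69
        assert by_key[(4240, "T", "G")].frequency_pct == 42.36
        assert by_key[(4226, "C", "T")].frequency_pct == 7.64


class TestNovelty:
    def test_known_variant_gets_rs(self, cohort, cohort_calls, known_table):
        aggregated = va.annotate_novelty(
            va.aggregate_cohort(cohort_calls, 72), known_table)
        by_key = {v.key: v for v in aggregated}
        assert by_key[(4240, "T", "G")].rs_id == "rs396861920"
        assert by_key[(2605, "C", "A")].rs_id == "rs1148503187"

    def test_six_missense_rows_novel(self, cohort, cohort_calls, known_table):
        aggregated = va.annotate_novelty(
            va.aggregate_cohort(cohort_calls, 72), known_table)
        published = {"R31H", "G45E", "G376A", "T486I", "L487V", "S489F",
                     "Q269K", "Q475K", "S491A", "C496S"}
        novel = {
            v.effect for v in aggregated
            if v.effect in published and v.rs_id == "novel"
        }
        assert novel == {"R31H", "G45E", "G376A", "T486I", "L487V", "S489F"}

    def test_empty_known_table_all_novel(self, cohort_calls):
        aggregated = va.annotate_novelty(
            va.aggregate_cohort(cohort_calls, 72), va.KnownVariantTable())
        assert all(v.rs_id == "novel" for v in aggregated)
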