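"""Diagnostic sites, masking, conversion tracts, diploid hybrid calling."""

import numpy as np
import pandas as pd
import pytest

from paraloci import hybrid_detection as hd
from paraloci import synthetic_data as sd
from paraloci.locus_model import ExonSpan, GeneModel


def _site(pos, base_a="A", base_b="G", informative=True, reason=None):
    return hd.DiagnosticSite(pos, pos + 59, base_a, base_b, informative, reason)


class TestDiagnosticSites:
    def test_identical_genes_no_sites(self):
        gene = GeneModel("g", "ATGAAATAA", (ExonSpan(1, 1, 9),))
        assert hd.find_diagnostic_sites(gene, gene) == []

    def test_engineered_catalogue_recovered(self, family, masked_sites):
        tract = [s for s in masked_sites if s.pos_a >= 3688]
        assert len(tract) == 31
        assert tract[0].pos_a == 3688
        assert tract[-1].pos_a == 4240
        expected = {p: (a, b) for p, a, b in sd.TRACT_SITES}
        for site in tract:
            base_a, base_b = expected[site.pos_a]
            assert (site.base_a, site.base_b) == (base_a, base_b)

    def test_donor_coordinate_offset(self, masked_sites):
        by_pos = {s.pos_a: s for s in masked_sites}
        assert by_pos[3805].pos_b == 3864

    def test_gap_columns_yield_no_site(self):
        a = GeneModel("a", "ATGGGGCCCTAA", (ExonSpan(1, 1, 12),))
        b = GeneModel("b", "ATGGGGAAACCCTAA", (ExonSpan(1, 1, 15),))
        sites = hd.find_diagnostic_sites(a, b)
        assert sites == []  # pure insertion, no substitution column


class TestMasking:
    def test_confounded_site_masked_with_reason(self, masked_sites):
        (masked,) = [s for s in masked_sites if not s.informative]
        assert masked.pos_a == 3805
        assert "donor polymorphism" in masked.reason

    def test_empty_donor_table_no_masking(self, family):
        sites = hd.find_diagnostic_sites(family.acceptor_gene, family.donor_gene)
        out = hd.mask_confounded_sites(
            sites, pd.DataFrame(columns=["g_position", "ref", "alt"]))
        assert all(s.informative for s in out)

    def test_masked_sites_excluded_from_states(self, family, masked_sites):
        states = hd.classify_allele_at_sites(
            family.acceptor_gene.sequence, masked_sites)
        n_informative = sum(1 for s in masked_sites if s.informative)
        assert len(states) == n_informative


class TestStateClassification:
    def test_wild_type_all_acceptor(self, family, masked_sites):
        states = hd.classify_allele_at_sites(
            family.acceptor_gene.sequence, masked_sites)
        assert set(states) == {hd.ACCEPTOR}

    def test_fully_converted_tail(self, family, cohort, masked_sites):
        for s in range(cohort.spec.n_samples):
            f1, f2 = cohort.hybrid_flags[s]
            if f1 or f2:
                hap = cohort.haplotypes[s][0 if f1 else 1]
                states = hd.classify_allele_at_sites(hap, masked_sites)
                tract_states = [
                    st for st, site in
                    zip(states, (x for x in masked_sites if x.informative))
                    if site.pos_a >= 3688
                ]
                assert set(tract_states) == {hd.DONOR}
                return
        pytest.fail("no hybrid haplotype in cohort")

    def test_single_converted_site(self):
        sites = [_site(100), _site(200), _site(300)]
        states = hd.classify_allele_at_sites("A" * 199 + "G" + "A" * 200, sites)
        assert states == (hd.ACCEPTOR, hd.DONOR, hd.ACCEPTOR)


class TestTractDetection:
    def test_engineered_replica_breakpoint_interval(self, family, cohort, masked_sites):
        """The tract starts at the first catalogue site; the interval is
        bounded below by the retained upstream site at g.3625."""
        for s in range(cohort.spec.n_samples):
            f1, f2 = cohort.hybrid_flags[s]
            if f1 or f2:
                hap = cohort.haplotypes[s][0 if f1 else 1]
                states = hd.classify_allele_at_sites(hap, masked_sites)
                call = hd.detect_conversion_tract(states, masked_sites)
                assert call.is_hybrid
                assert call.tract == (3688, 4240)
                assert call.switching_interval == (3625, 3688)
                return
        pytest.fail("no hybrid haplotype in cohort")

    def test_all_acceptor_no_tract(self):
        sites = [_site(p) for p in (10, 20, 30)]
        call = hd.detect_conversion_tract(
            (hd.ACCEPTOR,) * 3, sites)
        assert not call.is_hybrid and call.tract is None

    def test_isolated_donor_state_below_min_run(self):
        sites = [_site(p) for p in (10, 20, 30)]
        call = hd.detect_conversion_tract(
            (hd.ACCEPTOR, hd.ACCEPTOR, hd.DONOR), sites, min_run=2)
        assert not call.is_hybrid and call.label == "none"

    def test_interior_tract_not_labelled_hybrid(self):
        sites = [_site(p) for p in (10, 20, 30, 40)]
        call = hd.detect_conversion_tract(
            (hd.ACCEPTOR, hd.DONOR, hd.DONOR, hd.ACCEPTOR), sites)
        assert call.label == "conversion_segment"
        assert not call.is_hybrid
        assert call.tract == (20, 30)

    @pytest.mark.parametrize("seed", range(100))
    def test_random_tail_conversion_recovery(self, seed):
        """Planted tail tracts over random site maps: tract recovered, and the
        switching interval is the tightest informative flanking pair."""
        rng = np.random.default_rng(seed)
        n_sites = int(rng.integers(5, 40))
        positions = np.sort(rng.choice(np.arange(10, 5000), n_sites, replace=False))
        sites = [_site(int(p)) for p in positions]
        start_idx = int(rng.integers(0, n_sites - 1))
        states = [hd.ACCEPTOR] * start_idx + [hd.DONOR] * (n_sites - start_idx)
        call = hd.detect_conversion_tract(states, sites, upstream_boundary=1)
        assert call.is_hybrid
        assert call.tract == (sites[start_idx].pos_a, sites[-1].pos_a)
        expected_lower = sites[start_idx - 1].pos_a if start_idx else 1
        assert call.switching_interval == (expected_lower, sites[start_idx].pos_a)
        # the true breakpoint lies strictly inside the open interval
        assert expected_lower < sites[start_idx].pos_a

    def test_masking_leaves_interval_unchanged(self, family, cohort, masked_sites):
        """Re-running with the confounded site force-unmasked but absent from
        the allele's converted set would split the tract; with masking the
        interval is stable."""
        for s in range(cohort.spec.n_samples):
            f1, f2 = cohort.hybrid_flags[s]
            if f1 or f2:
                hap = cohort.haplotypes[s][0 if f1 else 1]
                break
        all_sites = hd.find_diagnostic_sites(
            family.acceptor_gene, family.donor_gene)
        unmasked_call = hd.detect_conversion_tract(
            hd.classify_allele_at_sites(hap, all_sites), all_sites)
        masked_call = hd.detect_conversion_tract(
            hd.classify_allele_at_sites(hap, masked_sites), masked_sites)
        assert masked_call.switching_interval == (3625, 3688)
        assert unmasked_call.switching_interval != masked_call.switching_interval

    def test_empty_state_vector_no_call(self):
        call = hd.detect_conversion_tract((), [])
        assert call.tract is None and not call.is_hybrid


class TestDiploidCalling:
    def test_het_at_every_site_one_allele(self, cohort, masked_sites):
        for s in range(cohort.spec.n_samples):
            f1, f2 = cohort.hybrid_flags[s]
            planted = (f1 or f2) and not (f1 and f2)
            if planted:
                count = hd.call_hybrids_diploid(
                    cohort.consensus(s).sequence, masked_sites)
                assert count >= 1
                return

    def test_hom_donor_everywhere_two_alleles(self, family, masked_sites):
        donor_observed = family.donor_observed_sequence()
        hap = list(family.acceptor_gene.sequence)
        for _, row in family.diff_table.iterrows():
            if row.pos_a >= 3688:
                hap[int(row.pos_a) - 1] = donor_observed[int(row.pos_b) - 1]
        consensus = sd.simulate_sanger_consensus("".join(hap), "".join(hap))
        assert hd.call_hybrids_diploid(consensus.sequence, masked_sites) == 2

    def test_wild_type_zero(self, family, masked_sites):
        assert hd.call_hybrids_diploid(
            family.acceptor_gene.sequence, masked_sites) == 0

    def test_cohort_recovers_planted_hybrid_count(self, cohort, masked_sites):
        counts = [
            hd.call_hybrids_diploid(cohort.consensus(s).sequence, masked_sites)
            for s in range(cohort.spec.n_samples)
        ]
        assert sum(counts) == 42


class TestFrequency:
    def test_published_cohort_fraction(self):
        counts = [1] * 42 + [0] * 30
        assert hd.hybrid_frequency(counts, 72) == 29.17

    def test_zero(self):
        assert hd.hybrid_frequency([0] * 72, 72) == 0.0

    def test_all_alleles(self):
        assert hd.hybrid_frequency([2] * 72, 72) == 100.0

    def test_invalid_count_rejected(self):
        with pytest.raises(Exception):
            hd.hybrid_frequency([3], 1)
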