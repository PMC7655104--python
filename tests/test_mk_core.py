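"""Codon pathway counting, MK counting, polarization, NI and contingency tests."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dynasel.mk_core import (
    SENSE_CODONS,
    SiteClassCounts,
    chi_square_test,
    codon_change_paths,
    count_divergence,
    count_polymorphisms,
    fisher_exact_two_tailed,
    major_allele_profile,
    neutrality_index,
    polarize,
    results_to_table,
    run_mk,
)
from dynasel.popgen_io import ConsensusSequence, DomainSpan
from dynasel.synthetic_data import SimulationConfig, simulate_gene_history

from oracles import fisher_two_tailed_enumeration


class TestCodonChangePaths:
    @pytest.mark.parametrize(
        "a, b, n_diff, dn, ds, n_paths",
        [
            ("TTA", "TTG", 1, 0.0, 1.0, 1),  # Leu -> Leu
            ("AAA", "CAA", 1, 1.0, 0.0, 1),  # Lys -> Gln
            # two orderings: via CAT (2 non-syn) and via CCA (1 syn + 1 non-syn)
            ("CCT", "CAA", 2, 1.5, 0.5, 2),
            # ordering via TAG (stop) excluded; only TAT->TCT->TCG admissible
            ("TAT", "TCG", 2, 1.0, 1.0, 1),
            ("ATG", "ATG", 0, 0.0, 0.0, 0),
        ],
    )
    def test_known_pathways(self, a, b, n_diff, dn, ds, n_paths):
        summary = codon_change_paths(a, b)
        assert summary.n_diff == n_diff
        assert summary.dn_frac == pytest.approx(dn)
        assert summary.ds_frac == pytest.approx(ds)
        assert summary.n_paths_used == n_paths

    def test_ambiguous_codon_rejected(self):
        with pytest.raises(ValueError, match="gaps or ambiguous"):
            codon_change_paths("ANA", "AAA")
        with pytest.raises(ValueError, match="gaps or ambiguous"):
            codon_change_paths("A-A", "AAA")

    def test_stop_endpoint_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            codon_change_paths("TAA", "AAA")

    def test_pathway_conservation_all_sense_codon_pairs(self):
        # dn + ds equals the nucleotide Hamming distance for every pair,
        # and the per-site decomposition sums to the totals
        for a in SENSE_CODONS:
            for b in SENSE_CODONS:
                s = codon_change_paths(a, b)
                hamming = sum(x != y for x, y in zip(a, b))
                assert s.n_diff == hamming
                assert s.dn_frac + s.ds_frac == pytest.approx(hamming, abs=1e-12)
                assert s.dn_frac >= 0 and s.ds_frac >= 0
                assert s.dn_frac == pytest.approx(sum(v for _, v, _ in s.per_site))
                assert s.ds_frac == pytest.approx(sum(v for _, _, v in s.per_site))

    def test_symmetry(self):
        # class counts do not depend on direction
        for a, b in [("CCT", "CAA"), ("TAT", "TCG"), ("AAA", "AGG")]:
            fwd, rev = codon_change_paths(a, b), codon_change_paths(b, a)
            assert fwd.dn_frac == pytest.approx(rev.dn_frac)
            assert fwd.ds_frac == pytest.approx(rev.ds_frac)


class TestCountPolymorphisms:
    def test_synonymous_singleton(self, make_aln):
        aln = make_aln(["AAA", "AAA", "AAA", "AAG"], "AAA")
        pn, ps, _ = count_polymorphisms(aln)
        assert (pn, ps) == (0.0, 1.0)

    def test_nonsynonymous_balanced(self, make_aln):
        aln = make_aln(["GAT", "GAT", "GCT", "GCT"], "GAT")
        pn, ps, _ = count_polymorphisms(aln)
        assert (pn, ps) == (1.0, 0.0)

    def test_two_segregating_sites_in_one_codon(self, make_aln):
        # AAA background; AAG is a synonymous change, CAA a non-synonymous one
        aln = make_aln(["AAA", "AAA", "AAG", "CAA"], "AAA")
        pn, ps, ledger = count_polymorphisms(aln)
        assert (pn, ps) == (1.0, 1.0)
        classified = [e for e in ledger if e["kind"] == "polymorphism"]
        assert {e["class"] for e in classified} == {"syn", "nonsyn"}

    def test_haplotype_with_missing_codon_skipped(self, make_aln):
        # the N-bearing haplotype cannot contribute its codon
        aln = make_aln(["AAA", "AAA", "AAN", "AAG"], "AAA")
        pn, ps, _ = count_polymorphisms(aln)
        assert (pn, ps) == (0.0, 1.0)


class TestCountDivergence:
    def test_synonymous_fixed_difference(self):
        consensus = ConsensusSequence("TTA", np.ones(3))
        dn, ds, _ = count_divergence(consensus, "TTG")
        assert (dn, ds) == (0.0, 1.0)

    def test_pathway_averaged_codon(self):
        consensus = ConsensusSequence("CCT", np.ones(3))
        dn, ds, _ = count_divergence(consensus, "CAA")
        assert dn == pytest.approx(1.5)
        assert ds == pytest.approx(0.5)

    def test_shared_polymorphism_contributes_no_divergence(self):
        # site polymorphic in the ingroup (frequency < 1): not a fixed difference
        consensus = ConsensusSequence("AAA", np.array([0.6, 1.0, 1.0]))
        dn, ds, _ = count_divergence(consensus, "GAA")
        assert (dn, ds) == (0.0, 0.0)

    def test_missing_codon_skipped_and_logged(self):
        consensus = ConsensusSequence("AANTTA", np.ones(6))
        dn, ds, ledger = count_divergence(consensus, "ACNTTG")
        assert (dn, ds) == (0.0, 1.0)
        assert any(e["kind"] == "skipped_codon" for e in ledger)


class TestPolarize:
    def _cons(self, seq):
        return ConsensusSequence(seq, np.ones(len(seq)))

    def test_focal_lineage_change(self):
        # focal A, sister G, outgroup G: the change happened on the focal branch
        pol, _ = polarize(self._cons("AAA"), "GAA", "GAA")
        assert pol.focal_dn == pytest.approx(1.0)
        assert pol.sister_dn == pol.ambiguous_dn == 0.0

    def test_sister_lineage_change(self):
        pol, _ = polarize(self._cons("AAA"), "GAA", "AAA")
        assert pol.sister_dn == pytest.approx(1.0)
        assert pol.focal_dn == pol.ambiguous_dn == 0.0

    def test_three_alleles_ambiguous(self):
        pol, _ = polarize(self._cons("AAA"), "GAA", "CAA")
        assert pol.ambiguous_dn == pytest.approx(1.0)
        assert pol.focal_dn == pol.sister_dn == 0.0

    def test_outgroup_missing_at_site_ambiguous(self):
        pol, _ = polarize(self._cons("AAA"), "GAA", "NAA")
        assert pol.ambiguous_dn == pytest.approx(1.0)

    def test_requires_outgroup(self):
        with pytest.raises(ValueError, match="outgroup"):
            polarize(self._cons("AAA"), "GAA", None)

    def test_additivity_with_multihit_codons(self):
        # focal and sister hits in the same codon: fractional pathway counts
        # must still satisfy focal + sister + ambiguous == unpolarized
        config = SimulationConfig(
            seed=5, n_codons=40, n_ingroup_haplotypes=8,
            dn_focal=10, ds_focal=8, dn_sister=10, ds_sister=8,
            dn_outgroup=6, ds_outgroup=6, pn=0, ps=0,
            n_singleton_n=0, n_singleton_s=0, allow_multihit=True,
        )
        for seed in range(8):
            aln, _ = simulate_gene_history(config, seed=seed)
            consensus = major_allele_profile(aln)
            dn, ds, _ = count_divergence(consensus, aln.sister)
            pol, _ = polarize(consensus, aln.sister, aln.outgroup)
            assert pol.focal_dn + pol.sister_dn + pol.ambiguous_dn == pytest.approx(dn)
            assert pol.focal_ds + pol.sister_ds + pol.ambiguous_ds == pytest.approx(ds)


class TestNeutralityIndex:
    @pytest.mark.parametrize(
        "pn, ps, dn, ds, expected",
        [
            (14, 20, 52, 24, 0.323),  # strong excess of fixed non-synonymous changes
            (5, 25, 40, 32, 0.160),
            (14, 20, 17, 8, 0.329),
            (1, 5, 9, 0, 0.000),  # Ds = 0 with Dn > 0
            (10, 10, 10, 10, 1.0),  # neutral expectation
            (0, 6, 6, 11, 0.0),  # Pn = 0
        ],
    )
    def test_values(self, pn, ps, dn, ds, expected):
        ni = neutrality_index(SiteClassCounts(pn=pn, ps=ps, dn=dn, ds=ds))
        assert round(ni, 3) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "pn, ps, dn, ds",
        [(3, 0, 5, 5), (3, 5, 0, 5), (2, 0, 0, 4)],
    )
    def test_undefined_cases(self, pn, ps, dn, ds):
        assert neutrality_index(SiteClassCounts(pn=pn, ps=ps, dn=dn, ds=ds)) is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            neutrality_index(SiteClassCounts(pn=-1, ps=1, dn=1, ds=1))

    def test_monotone_in_dn(self):
        # one extra fixed non-synonymous difference never increases NI
        for pn in (1, 5, 14):
            for ps in (1, 10, 20):
                for dn in (1, 5, 52):
                    for ds in (1, 10, 24):
                        ni = neutrality_index(SiteClassCounts(pn, ps, dn, ds))
                        ni_plus = neutrality_index(SiteClassCounts(pn, ps, dn + 1, ds))
                        if ni is not None and ni_plus is not None:
                            assert ni_plus <= ni + 1e-12


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected, rel",
        [
            ([[8, 4], [14, 59]], 0.0016, 0.05),
            ([[1, 1], [1, 1]], 1.0, 1e-9),
            ([[5, 0], [0, 5]], 2 / 252, 1e-9),  # enumeration over 6 tables
        ],
    )
    def test_known_values(self, table, expected, rel):
        assert fisher_exact_two_tailed(table) == pytest.approx(expected, rel=rel)

    def test_zero_margin_convention(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert fisher_exact_two_tailed([[0, 3], [0, 7]]) == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_tailed([[-1, 2], [3, 4]])

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    def test_matches_enumeration_oracle(self, a, b, c, d):
        table = [[a, b], [c, d]]
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        expected = fisher_two_tailed_enumeration(table)
        assert fisher_exact_two_tailed(table) == pytest.approx(expected, rel=1e-7)


class TestChiSquare:
    def test_mk_table_pvalues(self):
        assert round(chi_square_test([[52, 24], [14, 20]]), 3) == 0.007
        assert round(chi_square_test([[18, 15], [5, 25]]), 3) == 0.002

    def test_homogeneous_table(self):
        assert chi_square_test([[10, 10], [10, 10]]) == pytest.approx(1.0)

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(ValueError, match="expected"):
            chi_square_test([[0, 0], [5, 5]])

    def test_yates_and_g_variants(self):
        table = [[18, 15], [5, 25]]
        plain = chi_square_test(table)
        yates = chi_square_test(table, correction=True)
        g = chi_square_test(table, method="g")
        assert plain < yates  # the continuity correction is conservative
        assert 0 < g < 0.05


class TestRunMK:
    def test_recovers_planted_counts_and_polarization(self):
        config = SimulationConfig(seed=11)  # Nnk-like planted history
        aln, ledger = simulate_gene_history(config)
        result = run_mk(aln)[0]
        pn, ps, dn, ds = ledger.expected_unpolarized()
        assert result.counts.rounded() == SiteClassCounts(pn, ps, dn, ds)
        totals = ledger.totals()
        pol = result.polarized
        assert pol.focal_dn == totals["dn_focal"]
        assert pol.focal_ds == totals["ds_focal"]
        assert pol.sister_dn == totals["dn_sister"]
        assert pol.sister_ds == totals["ds_sister"]

    def test_no_variation_yields_undefined_statistics(self, make_aln):
        aln = make_aln(["ATGAAA", "ATGAAA"], "ATGAAA", outgroup="ATGAAA")
        result = run_mk(aln)[0]
        assert result.counts == SiteClassCounts(0, 0, 0, 0)
        assert result.ni is None
        assert result.p_fisher == 1.0
        assert result.p_chisq is None
        assert "no-variation" in result.flags

    def test_domain_partition_counts_sum_to_full_length(self):
        config = SimulationConfig(seed=23, n_codons=90, n_ingroup_haplotypes=30,
                                  dn_focal=5, ds_focal=4, dn_sister=5, ds_sister=4,
                                  dn_outgroup=3, ds_outgroup=3, pn=6, ps=6,
                                  n_singleton_n=2, n_singleton_s=2)
        aln, _ = simulate_gene_history(config)
        spans = [DomainSpan("a", 1, 30), DomainSpan("b", 31, 60), DomainSpan("c", 61, 90)]
        results = run_mk(aln, spans)
        full = results[0].counts
        for attr in ("pn", "ps", "dn", "ds"):
            total = sum(getattr(r.counts, attr) for r in results[1:])
            assert total == pytest.approx(getattr(full, attr))

    def test_overlapping_domains_rejected(self, make_aln):
        aln = make_aln(["ATGAAA", "ATGAAA"], "ATGAAA")
        with pytest.raises(ValueError, match="overlap"):
            run_mk(aln, [DomainSpan("a", 1, 2), DomainSpan("b", 2, 2)])

    def test_polarize_without_outgroup_rejected(self, make_aln):
        aln = make_aln(["ATGAAA", "ATGAAA"], "ATGAAA")
        with pytest.raises(ValueError, match="outgroup"):
            run_mk(aln, polarize_lineages=True)

    def test_results_table_shape(self):
        aln, _ = simulate_gene_history(SimulationConfig(seed=2))
        frame = results_to_table(run_mk(aln, [DomainSpan("ZAD", 1, 71)]))
        assert list(frame["region"]) == ["full-length", "ZAD"]
        for column in ("Dn", "Ds", "Pn", "Ps", "NI", "Dn_focal", "Ds_focal"):
            assert column in frame.columns
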