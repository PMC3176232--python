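import itertools
import math
import random

import numpy as np
import pytest
from hypothesis import given, strategies as st

from popgenscan import diversity
from popgenscan.alignment import build_site_masks
from popgenscan.diversity import (CODON_TABLE, NeutralityConstants,
                                  UndefinedStatisticError, UnfoldedSFS,
                                  classify_codon_differences, divergence_by_class,
                                  fay_wu_H_normalized, jukes_cantor,
                                  mean_pairwise_differences, nei_gojobori_sites,
                                  pairwise_pi, segregating_sites,
                                  site_class_totals, tajimas_D, unfolded_sfs)

from . import oracles
from .conftest import make_alignment, random_alignment

SENSE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")


class TestNeiGojoboriSites:
    @pytest.mark.parametrize("codon,expected", [
        ("TTT", 1 / 3), ("GGG", 1.0), ("ATG", 0.0),
    ])
    def test_known_codons(self, codon, expected):
        assert nei_gojobori_sites(codon) == pytest.approx(expected, abs=1e-12)

    def test_all_sense_codons_match_enumeration(self):
        for codon in SENSE_CODONS:
            assert nei_gojobori_sites(codon) == pytest.approx(
                oracles.syn_sites(codon), abs=1e-12), codon

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            nei_gojobori_sites("TAA")


class TestClassifyCodonDifferences:
    @pytest.mark.parametrize("a,b,expected", [
        ("TTT", "TTC", (1.0, 0.0)),   # Phe->Phe
        ("TTT", "TTA", (0.0, 1.0)),   # Phe->Leu
        ("AAA", "AAA", (0.0, 0.0)),
    ])
    def test_single_changes(self, a, b, expected):
        assert classify_codon_differences(a, b) == pytest.approx(expected)

    def test_multistep_pairs_match_pathway_enumeration(self, rng):
        pairs = [(rng.choice(SENSE_CODONS), rng.choice(SENSE_CODONS))
                 for _ in range(300)]
        for a, b in pairs:
            expected = oracles.pathway_differences(a, b)
            if expected is None:
                continue            # every pathway passes through a stop
            got = classify_codon_differences(a, b)
            assert got == pytest.approx(expected, abs=1e-12), (a, b)

    @given(st.sampled_from(SENSE_CODONS), st.sampled_from(SENSE_CODONS))
    def test_counts_sum_to_hamming_distance(self, a, b):
        hamming = sum(x != y for x, y in zip(a, b))
        s, r = classify_codon_differences(a, b)
        assert s + r == pytest.approx(hamming, abs=1e-12)


class TestSiteConservation:
    def test_syn_plus_rep_is_three_per_codon(self, small_gene):
        aln, mask, _ = small_gene
        totals = site_class_totals(aln, mask)
        assert totals.syn_sites + totals.rep_sites == pytest.approx(
            3.0 * totals.n_codons, abs=1e-9)


class TestPairwisePi:
    def test_identical_sequences_zero(self):
        aln = make_alignment(["ACGT", "ACGT"], "ACGT")
        mask = build_site_masks(aln)
        assert pairwise_pi(aln, mask, "all") == 0.0

    def test_single_pair_arithmetic(self):
        anc = "A" * 100
        other = "T" * 3 + "A" * 97
        aln = make_alignment([anc, other], anc)
        mask = build_site_masks(aln)
        assert pairwise_pi(aln, mask, "all") == pytest.approx(0.03)

    def test_no_usable_sites_is_an_error(self):
        aln = make_alignment(["N-", "AA"], "AA")
        mask = build_site_masks(aln)
        with pytest.raises(UndefinedStatisticError):
            pairwise_pi(aln, mask, "all")


class TestSegregatingSites:
    def test_ingroup_only_definition(self):
        # column 1 varies only in the outgroup: not segregating
        aln = make_alignment(["AAAT", "AAAT", "AAAA", "AAAA"], "ACAA")
        mask = build_site_masks(aln)
        assert segregating_sites(aln, mask) == 1


class TestUnfoldedSFS:
    def test_singleton_polarization(self):
        aln = make_alignment(["AC", "AC", "AC", "TC"], "AC")
        sfs = unfolded_sfs(aln, build_site_masks(aln))
        assert list(sfs.xi) == [1, 0, 0]

    def test_third_state_outgroup_excluded(self):
        aln = make_alignment(["AC", "AC", "TC", "TC"], "GC")
        sfs = unfolded_sfs(aln, build_site_masks(aln))
        assert sfs.S == 0
        # ... but the site still counts as segregating (D needs no polarization)
        assert segregating_sites(aln, build_site_masks(aln)) == 1

    @given(st.integers(0, 2**32 - 1))
    def test_sfs_total_is_polarized_biallelic_count(self, seed):
        aln = random_alignment(random.Random(seed))
        mask = build_site_masks(aln)
        sfs = unfolded_sfs(aln, mask)
        assert sfs.S == sum(oracles.unfolded_sfs(list(aln.ingroup), aln.outgroup))


class TestTajimasD:
    def test_undefined_for_no_segregation(self):
        with pytest.raises(UndefinedStatisticError):
            tajimas_D(0, 0.0, 10)

    def test_zero_when_pi_equals_watterson(self):
        n, S = 54, 77
        a1 = NeutralityConstants.from_n(n).a1
        assert tajimas_D(S, S / a1, n) == pytest.approx(0.0, abs=1e-12)

    def test_all_singletons_negative_and_matches_oracle(self):
        n, S = 10, 20
        xi = np.zeros(n - 1, dtype=int)
        xi[0] = S
        pi = diversity.sfs_theta_pi(xi, n)
        d = tajimas_D(S, pi, n)
        assert d < 0
        assert d == pytest.approx(oracles.tajimas_D(S, pi, n), abs=1e-12)


class TestFayWuH:
    def test_high_frequency_derived_strongly_negative(self):
        n, S = 10, 5
        xi = np.zeros(n - 1, dtype=int)
        xi[-1] = S
        h = fay_wu_H_normalized(UnfoldedSFS(n=n, xi=xi, sites_polarized=S))
        assert h < -2
        assert h == pytest.approx(oracles.fay_wu_H_norm(list(xi), n), abs=1e-12)

    def test_singletons_positive(self):
        n, S = 10, 5
        xi = np.zeros(n - 1, dtype=int)
        xi[0] = S
        h = fay_wu_H_normalized(UnfoldedSFS(n=n, xi=xi, sites_polarized=S))
        assert h > 0

    def test_undefined_with_no_polarized_sites(self):
        with pytest.raises(UndefinedStatisticError):
            fay_wu_H_normalized(UnfoldedSFS(n=10, xi=np.zeros(9, dtype=int),
                                            sites_polarized=40))


class TestOracleEquivalence:
    """pi, S, D and H against longhand implementations on random alignments."""

    def test_random_alignments_match_brute_force(self):
        rng = random.Random(777)
        checked_D = checked_H = 0
        for _ in range(60):
            aln = random_alignment(rng)
            mask = build_site_masks(aln)
            ingroup = list(aln.ingroup)
            S = segregating_sites(aln, mask)
            assert S == oracles.segregating_sites(ingroup)
            assert pairwise_pi(aln, mask, "all") == pytest.approx(
                oracles.pi_per_site(ingroup), abs=1e-9)
            pi_count = mean_pairwise_differences(aln, mask)
            assert pi_count == pytest.approx(
                oracles.mean_pairwise_differences(ingroup), abs=1e-9)
            if S >= 1 and aln.n >= 4:
                assert tajimas_D(S, pi_count, aln.n) == pytest.approx(
                    oracles.tajimas_D(S, pi_count, aln.n), abs=1e-9)
                checked_D += 1
            xi = oracles.unfolded_sfs(ingroup, aln.outgroup)
            sfs = unfolded_sfs(aln, mask)
            assert list(sfs.xi) == xi
            if sfs.S >= 1:
                assert fay_wu_H_normalized(sfs) == pytest.approx(
                    oracles.fay_wu_H_norm(xi, aln.n), abs=1e-9)
                checked_H += 1
        assert checked_D >= 30 and checked_H >= 30


class TestDivergence:
    def test_identical_outgroup_zero(self):
        aln = make_alignment(["ATGAAA", "ATGAAA"], "ATGAAA", exons=((0, 6),))
        mask = build_site_masks(aln)
        assert divergence_by_class(aln, mask, "syn") == 0.0
        assert divergence_by_class(aln, mask, "rep") == 0.0

    def test_jukes_cantor_closed_form(self):
        assert jukes_cantor(0.05) == pytest.approx(0.05174, abs=5e-6)

    def test_jukes_cantor_domain_error(self):
        with pytest.raises(UndefinedStatisticError):
            jukes_cantor(0.75)

    def test_single_synonymous_difference(self):
        # GGA->GGG is synonymous (Gly); ingroup monomorphic
        aln = make_alignment(["GGAGGAGGAGGA", "GGAGGAGGAGGA"],
                             "GGGGGAGGAGGA", exons=((0, 12),))
        mask = build_site_masks(aln)
        totals = site_class_totals(aln, mask, include_outgroup=True)
        expected_p = 1.0 / totals.syn_sites
        assert divergence_by_class(aln, mask, "syn") == pytest.approx(
            jukes_cantor(expected_p), abs=1e-12)
        assert divergence_by_class(aln, mask, "rep") == 0.0
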