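"""K2P distances and Nei-Gojobori Ka/Ks."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocomp.divergence import (
    DistanceMatrix,
    KaKsCounts,
    PairwiseSiteCounts,
    SaturationError,
    count_site_patterns,
    divergence_matrix,
    jukes_cantor,
    k2p_distance,
    k2p_matrix,
    k2p_pairwise,
    kaks_vs_reference,
    nei_gojobori,
)
from mitocomp.simulate import evolve_k2p, random_sequence, simulate_codon_pair


class TestSitePatterns:
    def test_hand_count(self):
        c = count_site_patterns("AAAAAAAAAA", "GAAAAAAAAC")
        assert (c.sites, c.transitions, c.transversions) == (10, 1, 1)

    def test_identical(self):
        c = count_site_patterns("ACGT", "ACGT")
        assert c.P == c.Q == 0.0

    def test_gap_and_n_exclusion(self):
        c = count_site_patterns("A-CG", "AACG")
        assert c.sites == 3 and c.transitions == 0 and c.transversions == 0
        c = count_site_patterns("ANCG", "AACG")
        assert c.sites == 3

    def test_transition_vs_transversion_classes(self):
        # A<->G and C<->T are transitions; everything else transversions
        c = count_site_patterns("AGCT", "GATC")
        assert c.transitions == 4
        c = count_site_patterns("AC", "CA")
        assert c.transversions == 2

    def test_no_comparable_sites(self):
        with pytest.raises(ValueError, match="comparable"):
            count_site_patterns("--", "AA")

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="lengths"):
            count_site_patterns("AAA", "AA")


class TestK2P:
    def test_zero_distance(self):
        assert k2p_distance(PairwiseSiteCounts(100, 0, 0)) == 0.0

    def test_closed_form(self):
        # P = Q = 0.1: d = -1/2 ln(0.7 * sqrt(0.8))
        d = k2p_distance(PairwiseSiteCounts(10, 1, 1))
        assert d == pytest.approx(-0.5 * math.log(0.7 * math.sqrt(0.8)))
        assert d == pytest.approx(0.2341, abs=5e-5)

    def test_saturation_is_explicit(self):
        with pytest.raises(SaturationError):
            k2p_distance(PairwiseSiteCounts(10, 5, 0))

    @given(st.integers(0, 30), st.integers(0, 20))
    @settings(max_examples=100, deadline=None)
    def test_dominates_p_distance(self, ts, tv):
        counts = PairwiseSiteCounts(100, ts, tv)
        if 1 - 2 * counts.P - counts.Q <= 0 or 1 - 2 * counts.Q <= 0:
            return
        assert k2p_distance(counts) >= counts.p_distance - 1e-12

    def test_transitions_only_reduction(self):
        # with Q=0 the formula reduces to -1/2 ln(1-2P)
        c = PairwiseSiteCounts(100, 12, 0)
        assert k2p_distance(c) == pytest.approx(-0.5 * math.log(1 - 0.24))

    def test_simulation_recovery_within_three_se(self):
        """Estimator recovers a planted distance of 0.10 on a 100 kb pair,
        within three standard errors (K2P large-sample variance)."""
        anc = random_sequence(100_000, seed=11)
        der = evolve_k2p(anc, 0.10, kappa=2.0, seed=11)
        c = count_site_patterns(anc, der)
        d = k2p_distance(c)
        c1 = 1.0 / (1 - 2 * c.P - c.Q)
        c2 = 1.0 / (1 - 2 * c.Q)
        c3 = 0.5 * (c1 + c2)
        var = (c1**2 * c.P + c3**2 * c.Q - (c1 * c.P + c3 * c.Q) ** 2) / c.sites
        assert abs(d - 0.10) <= 3 * math.sqrt(var)


class TestNeiGojobori:
    def test_identical_sequences(self):
        c = nei_gojobori("ATGTTT", "ATGTTT")
        assert c.syn_diffs == c.nonsyn_diffs == 0.0
        assert c.Ka == c.Ks == 0.0

    def test_synonymous_single_difference(self):
        c = nei_gojobori("TTA", "CTA")  # Leu -> Leu under table 5
        assert c.syn_diffs == 1.0 and c.nonsyn_diffs == 0.0

    def test_nonsynonymous_single_difference(self):
        c = nei_gojobori("TTT", "TGT")  # Phe -> Cys
        assert c.syn_diffs == 0.0 and c.nonsyn_diffs == 1.0

    def test_two_position_pathway_average(self):
        # TTT (Phe) vs TTA+GTT? use TTA (Leu) vs CTG (Leu): differs at
        # positions 1 and 3; both orders stay within Leu, all steps synonymous
        c = nei_gojobori("TTA", "CTG")
        assert c.syn_diffs == 2.0 and c.nonsyn_diffs == 0.0

    def test_sites_sum_to_three_per_codon(self):
        a, b = simulate_codon_pair(200, 0.05, 0.01, seed=0)
        c = nei_gojobori(a, b)
        assert c.syn_sites + c.nonsyn_sites == pytest.approx(3 * 200)
        # pathway-averaged differences equal the per-codon nucleotide diffs
        ndiff = sum(1 for x, y in zip(a, b) if x != y)
        assert c.syn_diffs + c.nonsyn_diffs == pytest.approx(ndiff)

    def test_symmetry(self):
        a, b = simulate_codon_pair(300, 0.08, 0.02, seed=5)
        cab, cba = nei_gojobori(a, b), nei_gojobori(b, a)
        assert cab.syn_sites == pytest.approx(cba.syn_sites)
        assert cab.syn_diffs == pytest.approx(cba.syn_diffs)
        assert cab.nonsyn_diffs == pytest.approx(cba.nonsyn_diffs)

    def test_internal_stop_is_an_error(self):
        with pytest.raises(ValueError, match="stop codon"):
            nei_gojobori("ATGTAA", "ATGTAA")

    def test_gap_codon_pairwise_deletion(self):
        c = nei_gojobori("ATG---TTT", "ATGAAATTT")
        assert c.syn_sites + c.nonsyn_sites == pytest.approx(6.0)

    def test_jukes_cantor_closed_form(self):
        assert jukes_cantor(0.05) == pytest.approx(-0.75 * math.log(1 - 0.2 / 3))
        assert jukes_cantor(0.05) == pytest.approx(0.0517, abs=1e-4)
        with pytest.raises(SaturationError):
            jukes_cantor(0.80)

    def test_matches_independent_ng86_implementation(self):
        """Cross-check against biopython's NG86 on simulated codon pairs.

        Small discrepancies are expected from different stop-codon
        handling in site counting; agreement is required to ~5%.
        """
        from Bio.Data.CodonTable import unambiguous_dna_by_id
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        for seed in range(3):
            a, b = simulate_codon_pair(400, 0.08, 0.02, seed=seed)
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86",
                               codon_table=unambiguous_dna_by_id[5])
            mine = nei_gojobori(a, b)
            assert mine.Ka == pytest.approx(dn, rel=0.05, abs=5e-4)
            assert mine.Ks == pytest.approx(ds, rel=0.05)


class TestMatrices:
    def test_identical_taxa_zero_offdiagonal(self):
        dm = k2p_matrix({"a": "ACGTACGTAC", "b": "ACGTACGTAC"})
        assert dm.get("a", "b") == 0.0

    def test_distance_matrix_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], np.array([[1.0, 2.0], [2.0, 0.0]]))

    def test_synthetic_taxa_recover_planted_distances(self):
        anc = random_sequence(50_000, seed=3)
        aln = {"anc": anc}
        for i, d in enumerate((0.05, 0.10, 0.20)):
            aln[f"t{i}"] = evolve_k2p(anc, d, seed=100 + i)
        dm = k2p_matrix(aln)
        for i, d in enumerate((0.05, 0.10, 0.20)):
            assert dm.get("anc", f"t{i}") == pytest.approx(d, abs=0.01)

    def test_saturation_error_names_pair(self):
        sat = {"x": "A" * 400, "y": "G" * 400}
        with pytest.raises(SaturationError, match="x vs y"):
            k2p_matrix(sat)

    def test_kaks_vs_reference_frame(self):
        a, b = simulate_codon_pair(500, 0.08, 0.02, seed=1)
        _, c = simulate_codon_pair(500, 0.08, 0.02, seed=2)
        df = kaks_vs_reference({"ref": a, "x": b, "y": a}, "ref")
        assert set(df.index) == {"x", "y"}
        assert df.loc["x", "Ka/Ks"] < 1.0  # purifying constraint planted
        assert df.loc["y", "Ks"] == 0.0

    def test_divergence_matrix_ka_mode_symmetric(self):
        a, b = simulate_codon_pair(300, 0.06, 0.015, seed=7)
        dm = divergence_matrix({"a": a, "b": b}, method="Ka")
        assert dm.values[0, 1] == dm.values[1, 0] > 0.0
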