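"""NG86 counting, Jukes-Cantor correction, filters, branch estimates, and
transition/transversion spectra, checked against independent oracles."""

import math

import numpy as np
import pytest

from matrisome.io import SequenceRecord, read_newick, validate_codon_alignment
from matrisome.kaks import (
    SaturationError,
    branch_estimates,
    choose_master,
    count_sites,
    filter_alignment_members,
    filter_estimates,
    jc_correct,
    pairwise_ng86,
    silent_rate,
    titv_spectrum,
    KaKsEstimate,
)

from conftest import random_codon_seq
from ng_oracle import SENSE, oracle_path_counts, oracle_sites


class TestCountSites:
    def test_phe_ttt(self):
        s, n = count_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_trp_tgg_has_no_synonymous_site(self):
        s, n = count_sites("TGG")
        assert s == 0.0
        assert n == 3.0

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            count_sites("TAA")

    def test_ambiguous_codon_rejected(self):
        with pytest.raises(ValueError):
            count_sites("ATN")

    def test_sites_sum_to_three_and_match_oracle(self):
        for codon in SENSE:
            s, n = count_sites(codon)
            so, no = oracle_sites(codon)
            assert s + n == pytest.approx(3.0)
            assert s == pytest.approx(so, abs=1e-12)


class TestPairwiseNG86:
    def test_identical_sequences(self):
        a = SequenceRecord("a", "", "ATGGCTAAA")
        e = pairwise_ng86(a, SequenceRecord("b", "", "ATGGCTAAA"))
        assert e.Sd == e.Sn == 0
        assert e.dS == e.dN == 0
        assert "omega_undefined" in e.flags

    def test_single_synonymous_difference(self):
        # TTT -> TTC is Phe -> Phe
        e = pairwise_ng86(SequenceRecord("a", "", "TTTATGGAA"),
                          SequenceRecord("b", "", "TTCATGGAA"))
        assert e.Sd == 1.0
        assert e.Sn == 0.0
        assert e.pn == 0.0

    def test_symmetry(self, rng):
        for _ in range(30):
            a = SequenceRecord("a", "", random_codon_seq(rng, 8))
            b = SequenceRecord("b", "", random_codon_seq(rng, 8))
            e1, e2 = pairwise_ng86(a, b), pairwise_ng86(b, a)
            for field in ("Sd", "Sn", "S", "N", "ps", "pn"):
                assert getattr(e1, field) == pytest.approx(getattr(e2, field))

    def test_counts_match_oracle_on_random_short_pairs(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 6))
            sa, sb = random_codon_seq(rng, n), random_codon_seq(rng, n)
            e = pairwise_ng86(SequenceRecord("a", "", sa),
                              SequenceRecord("b", "", sb))
            Sd = Sn = S2 = N2 = 0.0
            for i in range(n):
                ca, cb = sa[3 * i: 3 * i + 3], sb[3 * i: 3 * i + 3]
                sd, sn = oracle_path_counts(ca, cb)
                Sd += sd
                Sn += sn
                S2 += oracle_sites(ca)[0] + oracle_sites(cb)[0]
                N2 += oracle_sites(ca)[1] + oracle_sites(cb)[1]
            assert e.Sd == pytest.approx(Sd, abs=1e-9)
            assert e.Sn == pytest.approx(Sn, abs=1e-9)
            assert e.S == pytest.approx(S2 / 2, abs=1e-9)
            assert e.N == pytest.approx(N2 / 2, abs=1e-9)

    def test_gapped_codons_skipped(self):
        e = pairwise_ng86(SequenceRecord("a", "", "TT-ATGGAA"),
                          SequenceRecord("b", "", "TTCATGGAA"))
        assert e.codons_compared == 2
        assert e.Sd == e.Sn == 0

    def test_no_comparable_codons(self):
        with pytest.raises(ValueError, match="comparable"):
            pairwise_ng86(SequenceRecord("a", "", "NNN"),
                          SequenceRecord("b", "", "AAA"))


class TestJukesCantor:
    def test_zero(self):
        assert jc_correct(0.0) == 0.0

    def test_closed_form_value(self):
        assert jc_correct(0.3) == pytest.approx(-0.75 * math.log(0.6))
        assert jc_correct(0.3) == pytest.approx(0.38312, abs=1e-5)

    def test_saturation_boundary(self):
        with pytest.raises(SaturationError):
            jc_correct(0.75)

    def test_inverts_expected_proportion_map(self):
        for d in np.arange(0.01, 1.501, 0.01):
            p = 0.75 * (1 - math.exp(-4 * d / 3))
            assert jc_correct(p) == pytest.approx(d, abs=1e-9)


def _est(ds, dn, omega, flags=()):
    return KaKsEstimate("a", "b", 1, 1, 10, 20, 0.1, 0.05, ds, dn, omega,
                        10, frozenset(flags))


class TestFilters:
    def test_reasons_in_documented_order(self):
        table = [
            (_est(0.005, 0.002, 0.4), "dS<0.01"),
            (_est(0.2, 2.5, 12.5), "omega>10"),
            (_est(3.5, 0.5, 0.14), "dS>3"),
            (_est(0.5, 3.2, 6.4), "dN>3"),
            (_est(0.0, 0.0, float("nan"), {"omega_undefined"}), "dS<0.01"),
        ]
        kept, discarded = filter_estimates([e for e, _ in table])
        assert not kept
        assert [r for _, r in discarded] == [r for _, r in table]

    def test_exactly_one_survivor(self):
        ests = [
            _est(0.2, 0.1, 0.5),           # passes
            _est(0.005, 0.002, 0.4),       # dS too small
            _est(0.2, 2.5, 12.5),          # omega too large
            _est(0.5, 3.2, 6.4),           # dN too large
        ]
        kept, discarded = filter_estimates(ests)
        assert len(kept) == 1 and kept[0] is ests[0]
        assert len(discarded) == 3

    def test_boundaries_are_strict(self):
        kept, _ = filter_estimates([_est(0.01, 0.01, 1.0), _est(3.0, 3.0, 1.0),
                                    _est(0.2, 0.1, 10.0)])
        assert len(kept) == 3  # dS=0.01, dS/dN=3, omega=10 all survive

    def test_gap_filter_strictly_greater(self):
        cols = 100 * 3
        gappy = "-" * 93 + "A" * (cols - 93)       # 31%
        edge = "-" * 90 + "A" * (cols - 90)        # exactly 30%
        clean = "A" * cols
        aln = validate_codon_alignment([
            SequenceRecord("gappy", "", gappy),
            SequenceRecord("edge", "", edge),
            SequenceRecord("clean", "", clean),
        ])
        filtered, removed = filter_alignment_members(aln, 0.30)
        assert removed == ["gappy"]
        assert filtered.member_ids() == ["edge", "clean"]

    def test_gap_free_unchanged(self):
        aln = validate_codon_alignment([SequenceRecord("a", "", "ATGGCT"),
                                        SequenceRecord("b", "", "ATGGCC")])
        filtered, removed = filter_alignment_members(aln)
        assert removed == []
        assert filtered.member_ids() == ["a", "b"]

    def test_all_removed_is_error(self):
        aln = validate_codon_alignment([SequenceRecord("a", "", "---GCT")])
        with pytest.raises(ValueError):
            filter_alignment_members(aln)


class TestSilentRate:
    def test_direct_substitution(self):
        assert silent_rate(0.04, 2e6).mu == pytest.approx(1.0e-8)

    def test_zero_ds(self):
        assert silent_rate(0.0, 1e6).mu == 0.0

    def test_doubling_T_halves_mu(self):
        assert silent_rate(0.1, 2e6).mu == pytest.approx(
            silent_rate(0.1, 1e6).mu / 2)

    def test_nonpositive_T_rejected(self):
        with pytest.raises(ValueError):
            silent_rate(0.1, 0.0)


class TestBranchEstimates:
    def test_identical_tips_give_zero(self):
        seq = "ATGGCTAAA"
        aln = validate_codon_alignment(
            [SequenceRecord(x, "", seq) for x in "ABC"])
        for e in branch_estimates(aln, read_newick("((A:1,B:1):1,C:1);")):
            assert e.dS == 0 and e.dN == 0

    def test_single_synonymous_change_lands_on_right_branch(self):
        root = "TTTGAAAAA"
        aln = validate_codon_alignment([
            SequenceRecord("A", "", "TTCGAAAAA"),  # TTT->TTC on A's branch
            SequenceRecord("B", "", root),
            SequenceRecord("C", "", root),
        ])
        ests = {e.id_a: e for e in
                branch_estimates(aln, read_newick("((A:1,B:1):1,C:1);"))}
        assert ests["A"].Sd == 1 and ests["A"].Sn == 0
        assert ests["B"].Sd == 0 and ests["C"].Sd == 0

    def test_fewer_than_three_leaves_rejected(self):
        aln = validate_codon_alignment([SequenceRecord("A", "", "ATG"),
                                        SequenceRecord("B", "", "ATG")])
        with pytest.raises(ValueError, match="3 leaves"):
            branch_estimates(aln, read_newick("(A:1,B:1);"))

    def test_branch_omega_recovers_planted_value(self):
        from matrisome.simulate import CodonSimSpec, simulate_codon_alignment

        tree_text = "((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);"
        Sd = Sn = S = N = 0.0
        for rep in range(20):
            spec = CodonSimSpec(read_newick(tree_text), omega=0.5, kappa=1.0,
                                n_codons=300, seed=500 + rep)
            aln, _ = simulate_codon_alignment(spec)
            for e in branch_estimates(aln, spec.tree):
                Sd, Sn, S, N = Sd + e.Sd, Sn + e.Sn, S + e.S, N + e.N
        omega_hat = (Sn / N) / (Sd / S)
        assert omega_hat == pytest.approx(0.5, rel=0.2)


class TestMasterAndSpectra:
    def test_master_tie_broken_lexicographically(self):
        recs = [SequenceRecord("s2", "", "AAAA"), SequenceRecord("s1", "", "AAAA"),
                SequenceRecord("s3", "", "AATT")]
        assert choose_master(recs) == "s1"

    def test_star_center_wins(self):
        center = "AAAAAAAA"
        recs = [SequenceRecord("hub", "", center)]
        for i, pos in enumerate((0, 2, 4, 6)):
            mutated = center[:pos] + "T" + center[pos + 1:]
            recs.append(SequenceRecord(f"leaf{i}", "", mutated))
        assert choose_master(recs) == "hub"

    def test_two_sequences_tie(self):
        assert choose_master([SequenceRecord("b", "", "AC"),
                              SequenceRecord("a", "", "GT")]) == "a"

    def test_synonymous_transition(self):
        s = titv_spectrum(SequenceRecord("m", "", "GCT"),
                          SequenceRecord("q", "", "GCC"))
        assert (s.transitions, s.transversions) == (1, 0)
        assert (s.silent, s.nonsilent) == (1, 0)

    def test_nonsilent_transversion(self):
        s = titv_spectrum(SequenceRecord("m", "", "GCT"),
                          SequenceRecord("q", "", "GAT"))
        assert (s.transitions, s.transversions) == (0, 1)
        assert (s.silent, s.nonsilent) == (0, 1)

    def test_identical_all_zero(self):
        s = titv_spectrum(SequenceRecord("m", "", "GCTGCT"),
                          SequenceRecord("q", "", "GCTGCT"))
        assert s.transitions == s.transversions == s.indels == 0

    def test_titv_sum_equals_hamming_over_ungapped(self, rng):
        for _ in range(25):
            a = random_codon_seq(rng, 10)
            b = random_codon_seq(rng, 10)
            s = titv_spectrum(SequenceRecord("m", "", a), SequenceRecord("q", "", b))
            hamming = sum(1 for x, y in zip(a, b) if x != y)
            assert s.transitions + s.transversions == hamming
            assert s.silent + s.nonsilent <= s.transitions + s.transversions

    def test_gap_column_counts_as_indel(self):
        s = titv_spectrum(SequenceRecord("m", "", "GC-"),
                          SequenceRecord("q", "", "GCT"))
        assert s.indels == 1 and s.transitions == s.transversions == 0


class TestJukesCantorProperty:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.floats(min_value=0.0, max_value=0.7499))
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_monotone_and_dominates_p(self, p):
        d = jc_correct(p)
        assert d >= p - 1e-12  # correction only inflates the proportion
        if p > 1e-9:
            assert jc_correct(p * 0.5) <= d
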