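import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given
from hypothesis import strategies as st

from tandemscape.codons import random_cds
from tandemscape.molevo import (
    ClockParams,
    align_proteins,
    backtranslate,
    classify_selection,
    divergence_time,
    divergence_time_ma,
    kaks_pair,
    kaks_ratio,
    ng86,
    round_half_up,
    translate,
)

from _oracles import gotoh_score, ng86_brute


class TestDivergenceTime:
    @pytest.mark.parametrize(
        "ks,expected_ma", [(0.6, 20.0), (0.7, 23.3), (2.5, 83.3), (0.0, 0.0)]
    )
    def test_grass_clock_dates(self, ks, expected_ma):
        assert divergence_time_ma(ks, ClockParams(1.5e-8)) == expected_ma

    def test_linear_in_ks(self):
        t1 = divergence_time(0.31)
        assert divergence_time(3 * 0.31) == pytest.approx(3 * t1)

    def test_negative_ks_rejected(self):
        with pytest.raises(ValueError):
            divergence_time(-0.1)

    def test_invalid_clock_rejected(self):
        with pytest.raises(ValueError):
            ClockParams(0.0)


class TestRatioAndSelection:
    @pytest.mark.parametrize(
        "ka,ks,expected",
        [(0.34, 2.32, 0.15), (0.24, 2.99, 0.08), (0.0, 1.0, 0.0), (0.145, 1.0, 0.15)],
    )
    def test_two_decimal_half_up(self, ka, ks, expected):
        assert kaks_ratio(ka, ks) == expected

    def test_zero_ks_is_undefined_not_zero(self):
        assert math.isnan(kaks_ratio(0.2, 0.0))

    @pytest.mark.parametrize(
        "ratio,label",
        [(0.15, "negative"), (1.0, "neutral"), (1.7, "positive"),
         (float("nan"), "undefined"), (1.0 + 1e-12, "neutral")],
    )
    def test_selection_labels(self, ratio, label):
        assert classify_selection(ratio) == label


class TestAlignment:
    def test_identical_sequences_score_is_diagonal_sum(self):
        blosum = substitution_matrices.load("BLOSUM62")
        seq = "MKVLAW"
        a1, a2, score = align_proteins(seq, seq)
        assert a1 == a2 == seq
        assert score == sum(blosum[c, c] for c in seq)

    def test_single_gap_column(self):
        a1, a2, _ = align_proteins("ACD", "AD")
        assert len(a1) == len(a2) == 3
        assert a2.count("-") == 1 and "-" not in a1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_proteins("", "ACD")

    def test_score_matches_affine_dp_oracle(self, rng):
        blosum = substitution_matrices.load("BLOSUM62")
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(20):
            p1 = "".join(rng.choice(list(aas), size=10))
            p2 = "".join(rng.choice(list(aas), size=rng.integers(6, 13)))
            _, _, score = align_proteins(p1, p2)
            assert score == pytest.approx(
                gotoh_score(p1, p2, blosum, -10.0, -0.5)
            )


class TestBacktranslate:
    def test_ungapped_pair_keeps_codon_order(self):
        cds = "ATGGCTTGG"
        ca = backtranslate("MAW", "MAW", cds, cds)
        assert ca.codons1 == ["ATG", "GCT", "TGG"]
        assert ca.included.all()

    def test_protein_gap_becomes_codon_gap(self):
        ca = backtranslate("MAW", "M-W", "ATGGCTTGG", "ATGTGG")
        assert ca.codons2 == ["ATG", "---", "TGG"]
        assert list(ca.included) == [True, False, True]

    def test_translation_mismatch_names_offender(self):
        with pytest.raises(ValueError, match="geneX"):
            backtranslate("MAW", "MAW", "ATGGCTTGG", "ATGGCTTGC", id1="a", id2="geneX")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="3 x protein length"):
            backtranslate("MAW", "MAW", "ATGGCTTGG", "ATGTGG")

    def test_roundtrip_reproduces_protein_alignment(self, rng):
        from tandemscape.codons import GENETIC_CODE

        for _ in range(10):
            c1 = random_cds(rng, 30)
            c2 = random_cds(rng, 28)
            from tandemscape.molevo import translate

            a1, a2, _ = align_proteins(translate(c1), translate(c2))
            ca = backtranslate(a1, a2, c1, c2)
            back1 = "".join(
                "-" if c == "---" else GENETIC_CODE[c] for c in ca.codons1
            )
            back2 = "".join(
                "-" if c == "---" else GENETIC_CODE[c] for c in ca.codons2
            )
            assert (back1, back2) == (a1, a2)


class TestNG86:
    def test_identical_cds_zero_rates(self):
        r = kaks_pair("ATGGCTTGGAAA" * 10, "ATGGCTTGGAAA" * 10)
        assert r.Ka == 0.0 and r.Ks == 0.0
        assert math.isnan(r.ratio) and r.selection == "undefined"

    def test_single_synonymous_change_hand_computed(self):
        # AAA CCG GGG vs AAA CCA GGG: one synonymous difference (Pro codon)
        # S = 1/3 (AAA) + 1 (CCG/CCA) + 1 (GGG) = 7/3; Sd = 1, Nd = 0
        r = kaks_pair("AAACCGGGG", "AAACCAGGG")
        assert r.Sd == pytest.approx(1.0) and r.Nd == pytest.approx(0.0)
        assert r.S == pytest.approx(7 / 3)
        expected_ks = -0.75 * math.log(1 - (4 / 3) * (1 / r.S))
        assert r.Ks == pytest.approx(expected_ks)
        assert r.Ka == 0.0

    def test_symmetry(self, rng):
        for _ in range(10):
            anc = random_cds(rng, 50)
            other = random_cds(rng, 50)
            r1 = kaks_pair(anc, other)
            r2 = kaks_pair(other, anc)
            for attr in ("S", "N", "Sd", "Nd"):
                assert getattr(r1, attr) == getattr(r2, attr)

    def test_agreement_with_pathway_enumeration_oracle(self, rng):
        for _ in range(10):
            c1 = random_cds(rng, 80)
            c2 = random_cds(rng, 80)
            r = ng86(backtranslate(translate(c1), translate(c2), c1, c2))
            S, N, Sd, Nd, ka, ks = ng86_brute(c1, c2)
            assert r.S == pytest.approx(S, abs=1e-9)
            assert r.N == pytest.approx(N, abs=1e-9)
            assert r.Sd == pytest.approx(Sd, abs=1e-9)
            assert r.Nd == pytest.approx(Nd, abs=1e-9)
            if math.isfinite(ks):
                assert r.Ks == pytest.approx(ks, abs=1e-9)

    def test_concatenation_pools_counts_additively(self, rng):
        c1a, c2a = random_cds(rng, 40), random_cds(rng, 40)
        c1b, c2b = random_cds(rng, 30), random_cds(rng, 30)
        # force ungapped equal-length alignments for clean concatenation
        from tandemscape.molevo import translate

        ca = backtranslate(translate(c1a), translate(c2a), c1a, c2a)
        cb = backtranslate(translate(c1b), translate(c2b), c1b, c2b)
        cc = backtranslate(
            translate(c1a + c1b), translate(c2a + c2b), c1a + c1b, c2a + c2b
        )
        ra, rb, rc = ng86(ca), ng86(cb), ng86(cc)
        assert rc.S == pytest.approx(ra.S + rb.S)
        assert rc.Sd == pytest.approx(ra.Sd + rb.Sd)
        assert rc.Nd == pytest.approx(ra.Nd + rb.Nd)

    @given(st.integers(0, 2**31 - 1))
    def test_rates_are_nonnegative(self, seed):
        r = kaks_pair(
            random_cds(np.random.default_rng(seed), 30),
            random_cds(np.random.default_rng(seed + 1), 30),
        )
        assert (math.isnan(r.Ka) or r.Ka >= 0) and (math.isnan(r.Ks) or r.Ks >= 0)
        assert r.S + r.N <= 3 * 30 + 1e-9


def test_round_half_up_behaviour():
    assert round_half_up(0.145, 2) == 0.15
    assert round_half_up(23.333333, 1) == 23.3
    assert round_half_up(2.5, 0) == 3.0
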