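"""Codon-level metrics against enumeration oracles and closed forms."""

import itertools
import math
import random

import numpy as np
import pytest

from clonedecay.codon import (
    SENSE_CODONS,
    STOP_CODONS,
    SaturationError,
    dnds_from_codon_variants,
    jukes_cantor,
    k2p_distance,
    nearest_sexual_distance,
    ng86_pathway_counts,
    ng86_site_counts,
    pairwise_dnds,
    radicality_score,
    translate_codon,
)


def brute_force_pathways(a, b):
    """Independent re-enumeration of NG86 pathway counts."""
    diff = [i for i in range(3) if a[i] != b[i]]
    open_paths, every = [], []
    for order in itertools.permutations(diff):
        cur, nd, sd, blocked = a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            if (translate_codon(cur) if cur not in STOP_CODONS else "*") == (
                translate_codon(nxt) if nxt not in STOP_CODONS else "*"
            ):
                sd += 1
            else:
                nd += 1
            cur = nxt
        every.append((nd, sd))
        if not blocked:
            open_paths.append((nd, sd))
    paths = open_paths or every
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


class TestSiteCounts:
    @pytest.mark.parametrize(
        "codon,expected_s",
        [("TTT", 1 / 3), ("ATG", 0.0), ("GGG", 1.0)],
    )
    def test_known_codons(self, codon, expected_s):
        n, s = ng86_site_counts(codon)
        assert s == pytest.approx(expected_s)
        assert n + s == pytest.approx(3.0)

    def test_all_sense_codons_sum_to_three(self):
        for codon in SENSE_CODONS:
            n, s = ng86_site_counts(codon)
            assert n + s == pytest.approx(3.0)
            assert 0 <= s <= 3

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_site_counts("TAA")


class TestPathwayCounts:
    def test_identity(self):
        assert ng86_pathway_counts("TTT", "TTT") == (0.0, 0.0)

    def test_single_step_nonsynonymous(self):
        assert ng86_pathway_counts("TTT", "TTA") == (1.0, 0.0)

    def test_sampled_pairs_match_brute_force(self):
        rng = random.Random(0)
        pairs = [
            (rng.choice(SENSE_CODONS), rng.choice(SENSE_CODONS))
            for _ in range(500)
        ]
        for a, b in pairs:
            nd, sd = ng86_pathway_counts(a, b)
            end, esd = brute_force_pathways(a, b)
            assert nd == pytest.approx(end), (a, b)
            assert sd == pytest.approx(esd), (a, b)

    def test_hamming_conservation(self):
        rng = random.Random(1)
        for _ in range(300):
            a, b = rng.choice(SENSE_CODONS), rng.choice(SENSE_CODONS)
            nd, sd = ng86_pathway_counts(a, b)
            h = sum(x != y for x, y in zip(a, b))
            assert nd + sd == pytest.approx(h)


class TestDistances:
    def test_jukes_cantor_closed_form(self):
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.1) == pytest.approx(0.107326, abs=1e-6)

    def test_jukes_cantor_saturation(self):
        with pytest.raises(SaturationError):
            jukes_cantor(0.75)

    def test_k2p_closed_form(self):
        d = k2p_distance("A" * 100, "G" + "A" * 99)
        assert d.P == pytest.approx(0.01)
        assert d.Q == 0.0
        assert d.d == pytest.approx(-0.5 * math.log(0.98), abs=1e-12)
        assert d.d == pytest.approx(0.010101, abs=1e-6)

    def test_k2p_zero_iff_identical(self):
        assert k2p_distance("ACGT", "ACGT").d == 0.0

    def test_k2p_exceeds_p_distance(self):
        rng = np.random.default_rng(2)
        bases = np.array(list("ACGT"))
        for _ in range(20):
            a = "".join(rng.choice(bases, size=300))
            b = "".join(
                c if rng.random() > 0.1 else rng.choice(bases) for c in a
            )
            d = k2p_distance(a, b)
            assert d.d >= d.P + d.Q - 1e-12

    def test_k2p_saturation_error(self):
        with pytest.raises(SaturationError):
            k2p_distance("AG" * 50, "GA" * 50)

    def test_jc_k2p_first_order_agreement(self):
        p = 1e-4
        jc = jukes_cantor(p)
        n = 10000
        k2p = k2p_distance("A" * n, "G" + "A" * (n - 1)).d  # P = 1e-4
        assert abs(jc - p) < 1e-6
        assert abs(k2p - p) < 1e-6

    def test_nearest_sexual(self):
        name, d = nearest_sexual_distance(
            "A" * 100, {"x": "A" * 100, "y": "GG" + "A" * 98}
        )
        assert name == "x" and d == 0.0


class TestPairwiseDnds:
    def test_identical_sequences_ratio_one(self):
        est = pairwise_dnds("ATGTTTGGA", "ATGTTTGGA")
        assert est.ratio == pytest.approx(1.0)
        assert est.Nd == est.Sd == 0.0

    def test_symmetry(self):
        a, b = "ATGTTTGGACGA", "ATGTTAGGACGT"
        ea = pairwise_dnds(a, b)
        eb = pairwise_dnds(b, a)
        assert ea.ratio == pytest.approx(eb.ratio)
        assert ea.Nd == pytest.approx(eb.Nd)

    def test_hand_computed_two_codon_pair(self):
        # TTT->TTA is the only difference: nonsynonymous (Phe->Leu)
        est = pairwise_dnds("TTTGGA", "TTAGGA")
        assert est.Sd == 0.0 and est.Nd == 1.0
        assert est.dS == 0.0 and est.dN > 0
        assert est.ratio == pytest.approx((est.dN + 0.01) / 0.01)

    def test_matches_biopython_on_single_step_codons(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        rng = random.Random(3)
        for _ in range(5):
            codons = [rng.choice(SENSE_CODONS) for _ in range(40)]
            other = []
            for c in codons:
                if rng.random() < 0.3:
                    syn_neighbors = [
                        c[:p] + b + c[p + 1 :]
                        for p in range(3)
                        for b in "ACGT"
                        if b != c[p]
                        and (c[:p] + b + c[p + 1 :]) not in STOP_CODONS
                    ]
                    other.append(rng.choice(syn_neighbors))
                else:
                    other.append(c)
            a, b = "".join(codons), "".join(other)
            mine = pairwise_dnds(a, b, c=0.0)
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            assert mine.dN == pytest.approx(dn, abs=1e-9)
            assert mine.dS == pytest.approx(ds, abs=1e-9)

    def test_empty_input_flagged(self):
        est = dnds_from_codon_variants([None, None])
        assert not est.valid and math.isnan(est.ratio)

    def test_masked_codons_skipped_in_both(self):
        full = pairwise_dnds("TTTGGA", "TTAGGA")
        skipped = pairwise_dnds("TTTGGA", "TTAGGA", skip_codons=[0])
        assert skipped.Nd == 0.0
        assert skipped.n_codons == full.n_codons - 1


class TestRadicality:
    def test_symmetry_all_pairs(self):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for m in ("PAM100", "BLOSUM90"):
            for a, b in itertools.combinations(aas, 2):
                assert radicality_score(a, b, m) == radicality_score(b, a, m)

    def test_blosum90_matches_biopython_canonical(self):
        from Bio.Align import substitution_matrices

        ref = substitution_matrices.load("BLOSUM90")
        assert radicality_score("W", "G", "BLOSUM90") == int(ref["W"]["G"])
        assert radicality_score("I", "L", "BLOSUM90") == int(ref["I"]["L"])

    def test_conservative_above_radical(self):
        for m in ("PAM100", "BLOSUM90"):
            assert radicality_score("I", "L", m) > radicality_score("W", "G", m)

    def test_stop_rejected(self):
        with pytest.raises(ValueError):
            radicality_score("*", "G")
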