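"""Site filtering, masking and SNP classification on hand-built tables."""

import numpy as np
import pandas as pd
import pytest

from clonedecay.classify import (
    annotate_synonymity,
    classify_sites,
    default_sister_map,
    classify_dataset,
    filter_sites,
    flag_paralog_contigs,
    map_sites_to_orfs,
    mask_multi_variant_codons,
    polarize_derived,
)
from clonedecay.data import SampleMeta

from conftest import build_table, sexual_panel


def hybrid(sid="H1", genomotype="ET", category="F1", clone="c1"):
    return SampleMeta(sid, genomotype, len(genomotype), category, clone)


class TestFilterSites:
    def test_called_fraction_boundary(self):
        samples = sexual_panel(2) + [hybrid(f"H{i}") for i in range(1, 5)]
        # 10 ingroup + 1 outgroup; sites A (8/10 called), B (7/10), C triallelic,
        # D (outgroup missing, ingroup complete)
        g, m = (0, 1), None
        rows = [
            [g] * 4 + [m, m] + [g] * 5,
            [g] * 3 + [m, m, m] + [g] * 5,
            [g] * 11,
            [g] * 6 + [m] + [g] * 4,
        ]
        sites = [
            ("c1", 0, "A", "G"),
            ("c1", 1, "A", "G"),
            ("c1", 2, "A", "G,C"),
            ("c1", 3, "A", "G"),
        ]
        table = build_table(sites, rows, samples)
        filtered, keep, log = filter_sites(table, min_called_fraction=0.8)
        assert keep.tolist() == [True, False, False, True]
        assert log["removed_undercalled"] == 1
        assert log["removed_not_biallelic"] == 1
        assert filtered.n_sites == 2

    def test_include_outgroup_switch(self):
        samples = sexual_panel(2)  # 6 ingroup + 1 outgroup
        g = (0, 1)
        # 6/6 ingroup called, outgroup missing: kept without outgroup,
        # dropped (6/7 < 0.9) when the outgroup counts
        table = build_table([("c1", 0, "A", "G")], [[g] * 6 + [None]], samples)
        _, keep_a, _ = filter_sites(table, min_called_fraction=0.9)
        _, keep_b, _ = filter_sites(
            table, min_called_fraction=0.9, include_outgroup=True
        )
        assert keep_a.tolist() == [True]
        assert keep_b.tolist() == [False]


class TestParalogFlagging:
    def test_shared_het_incl_outgroup_flags_contig(self):
        samples = sexual_panel(1)  # E,T,N one each + outgroup
        het, hom = (0, 1), (0, 0)
        table = build_table(
            [("bad", 0, "A", "G"), ("good", 0, "A", "G")],
            [
                [het, het, het, het],   # het in all species and outgroup
                [het, het, het, hom],   # outgroup homozygous: fine
            ],
            samples,
        )
        flagged, spurious = flag_paralog_contigs(table)
        assert flagged == {"bad"}
        assert spurious.tolist() == [True, False]

    def test_requires_outgroup(self):
        samples = sexual_panel(1, with_outgroup=False)
        table = build_table([("c", 0, "A", "G")], [[(0, 1)] * 3], samples)
        with pytest.raises(ValueError):
            flag_paralog_contigs(table)


ORFS = pd.DataFrame(
    [{"orf_id": "orf1", "contig": "c1", "start": 12, "end": 27}]
)
# c1: 12 nt flank + ATG GGT AAA TTT TAA + flank
REF = {"c1": "A" * 12 + "ATG" + "GGT" + "AAA" + "TTT" + "TAA" + "A" * 12}


class TestCodonMapping:
    def sites(self):
        return pd.DataFrame(
            [
                ("c1", 2, "A", "G"),    # flank
                ("c1", 15, "G", "A"),   # codon 1 pos 0
                ("c1", 16, "G", "A"),   # codon 1 pos 1 (same codon)
                ("c1", 18, "A", "T"),   # codon 2 pos 0
                ("c1", 24, "T", "G"),   # stop codon
            ],
            columns=["contig", "pos", "ref", "alt"],
        )

    def test_map_sites_to_orfs(self):
        cm = map_sites_to_orfs(self.sites(), ORFS)
        assert cm["orf_id"].tolist() == [None, "orf1", "orf1", "orf1", "orf1"]
        assert cm["codon_index"].tolist()[1:] == [1, 1, 2, 4]
        assert cm["codon_pos"].tolist()[1:] == [0, 1, 0, 0]
        assert cm["in_stop_codon"].tolist() == [False, False, False, False, True]

    def test_mask_multi_variant_codons(self):
        cm = map_sites_to_orfs(self.sites(), ORFS)
        masked = mask_multi_variant_codons(cm)
        assert masked.tolist() == [False, True, True, False, False]


class TestSynonymity:
    def test_hand_annotations(self):
        sites = pd.DataFrame(
            [
                ("c1", 17, "T", "C"),  # GGT -> GGC: Gly/Gly synonymous
                ("c1", 18, "A", "T"),  # AAA -> TAA: stop gain
                ("c1", 21, "T", "C"),  # TTT -> CTT: Phe -> Leu
                ("c1", 24, "T", "G"),  # stop codon: noncoding
                ("c1", 2, "A", "G"),   # flank: noncoding
            ],
            columns=["contig", "pos", "ref", "alt"],
        )
        cm = map_sites_to_orfs(sites, ORFS)
        masked = np.zeros(len(sites), dtype=bool)
        ann = annotate_synonymity(sites, cm, masked, REF, ORFS)
        assert ann["synonymity"].tolist() == [
            "synonymous", "stop_gain", "nonsynonymous", "noncoding", "noncoding",
        ]
        assert ann.loc[2, "aa_ref"] == "F" and ann.loc[2, "aa_alt"] == "L"

    def test_masked_label(self):
        sites = pd.DataFrame(
            [("c1", 15, "G", "A"), ("c1", 16, "G", "A")],
            columns=["contig", "pos", "ref", "alt"],
        )
        cm = map_sites_to_orfs(sites, ORFS)
        masked = mask_multi_variant_codons(cm)
        ann = annotate_synonymity(sites, cm, masked, REF, ORFS)
        assert ann["synonymity"].tolist() == ["masked", "masked"]


class TestClassifySites:
    def panel(self):
        return sexual_panel(2) + [hybrid()]

    def test_categories(self):
        samples = self.panel()
        r, a, het = (0, 0), (1, 1), (0, 1)
        rows = [
            # E polymorphic -> intraspecific
            [het, r, r, r, r, r, r, r],
            # E fixed alt, T/N ref -> interspecific ExT, ExN
            [a, a, r, r, r, r, r, r],
            # sexuals invariant, hybrid carries alt -> private
            [r, r, r, r, r, r, r, het],
            # invariant everywhere -> unclassified
            [r, r, r, r, r, r, r, r],
            # T entirely missing -> unclassified (missing species)
            [r, r, None, None, r, r, r, r],
            # hybrid het must not create an intraspecific call
            [r, r, a, a, a, a, r, het],
        ]
        table = build_table(
            [("c1", i, "A", "G") for i in range(len(rows))], rows, samples
        )
        out = classify_sites(table)
        assert out["category"].tolist() == [
            "intraspecific",
            "interspecific_fixed",
            "private_asexual",
            "unclassified",
            "unclassified",
            "interspecific_fixed",
        ]
        assert out.loc[0, "focal_species"] == "E"
        assert out.loc[1, "pairs"] == "ExT,ExN"
        assert out.loc[2, "derived_idx"] == 1
        assert out.loc[3, "reason"] == "invariant_in_ingroup"
        assert out.loc[4, "reason"] == "missing_sexual_species"
        assert out.loc[5, "pairs"] == "ExT,ExN"

    def test_any_species_poly_wins_priority(self):
        samples = self.panel()
        r, a, het = (0, 0), (1, 1), (0, 1)
        # N polymorphic while E and T differ: intraspecific takes priority
        rows = [[a, a, r, r, het, r, r, r]]
        table = build_table([("c1", 0, "A", "G")], rows, samples)
        out = classify_sites(table)
        assert out.loc[0, "category"] == "intraspecific"
        assert out.loc[0, "focal_species"] == "N"


class TestPolarization:
    def test_sister_and_fallback_rules(self):
        samples = sexual_panel(2) + [hybrid()]
        r, a, het = (0, 0), (1, 1), (0, 1)
        rows = [
            # site 0: T poly, sister N monomorphic ref -> derived = alt
            [r, r, het, r, r, r, r, r],
            # site 1: E poly, T/N consensus alt -> derived = ref
            [het, r, a, a, a, a, r, r],
            # site 2: E poly, T/N disagree, outgroup ref -> derived = alt
            [het, r, a, a, r, r, r, r],
            # site 3: T poly, sister N also poly, outgroup ref -> fallback
            [r, r, het, r, het, r, r, r],
        ]
        table = build_table(
            [("c1", i, "A", "G") for i in range(len(rows))], rows, samples
        )
        classes = classify_sites(table)
        polar = polarize_derived(table, classes)
        assert polar["derived_idx"].tolist() == [1, 0, 1, 1]
        assert polar["polarized"].all()

    def test_unpolarized_when_no_outgroup_consensus(self):
        samples = sexual_panel(2) + [hybrid()]
        r, het = (0, 0), (0, 1)
        # T poly, sister N poly, outgroup het -> cannot polarize
        rows = [[r, r, het, r, het, r, het, r]]
        table = build_table([("c1", 0, "A", "G")], rows, samples)
        classes = classify_sites(table)
        polar = polarize_derived(table, classes)
        assert not polar["polarized"].iloc[0]

    def test_default_sister_map_shape(self):
        m = default_sister_map()
        assert m["T"] == ("N",) and m["N"] == ("T",)
        assert set(m["E"]) == {"T", "N"}


class TestEndToEnd:
    def test_confusion_matrix_diagonal(self, small_sim, small_cls):
        truth_by_site = {r["site"]: r for r in small_sim.truth["sites"]}
        expected_map = {
            "intraspecific": "intraspecific",
            "interspecific_fixed": "interspecific_fixed",
            "private_asexual": "private_asexual",
            "outgroup_only": "unclassified",
        }
        frame = small_cls.frame
        by_orig = dict(zip(frame["orig_site"], frame["category"]))
        for site, rec in truth_by_site.items():
            want = expected_map[rec["cls"]]
            if rec["cls"] == "private_asexual" and not rec["emitted"]:
                want = "unclassified"  # erased by LOH in its only carrier
            assert by_orig[site] == want, (site, rec["cls"], by_orig[site])

    def test_synonymity_recovery(self, small_sim, small_cls):
        truth_by_site = {r["site"]: r for r in small_sim.truth["sites"]}
        f = small_cls.frame
        for _, row in f.iterrows():
            rec = truth_by_site[row["orig_site"]]
            if row["masked"] or row["in_stop_codon"]:
                continue
            assert row["synonymity"] == rec["synonymity"], rec

    def test_private_derived_allele_recovery(self, small_sim, small_cls):
        truth_by_site = {r["site"]: r for r in small_sim.truth["sites"]}
        f = small_cls.frame
        sel = f["category"] == "private_asexual"
        for _, row in f[sel].iterrows():
            rec = truth_by_site[row["orig_site"]]
            assert row["derived_allele"] == rec["derived"]
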