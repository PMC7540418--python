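"""Spectra, heterozygosity, LOH and the quadratic fit on hand-built cases."""

import math

import numpy as np
import pandas as pd
import pytest

from clonedecay.classify import SiteClassification
from clonedecay.data import SampleMeta
from clonedecay.spectra import (
    call_loh,
    clone_sharing_spectrum,
    fit_loh_vs_private,
    heterozygosity,
    homozygous_private_fraction,
    private_snp_proportion,
    site_frequency_spectrum,
    syn_class,
)

from conftest import build_table, sexual_panel


def toy_cls(table, records):
    """SiteClassification with a minimal hand-written annotation frame."""
    defaults = {
        "category": "unclassified",
        "focal_species": "",
        "synonymity": "synonymous",
        "polarized": True,
        "derived_idx": 1,
    }
    rows = [{**defaults, **r} for r in records]
    frame = pd.DataFrame(rows, index=range(len(rows)))
    return SiteClassification(table=table, frame=frame, log={})


class TestSynClass:
    def test_mapping(self):
        got = syn_class(
            pd.Series(["synonymous", "nonsynonymous", "stop_gain", "masked",
                       "noncoding"])
        )
        assert got.tolist() == [
            "synonymous", "nonsynonymous", "nonsynonymous", "other", "other",
        ]


HYBRID = SampleMeta("H1", "ET", 2, "old_clone", "c1")


def loh_fixture():
    samples = sexual_panel(2) + [HYBRID]
    r, a, het = (0, 0), (1, 1), (0, 1)
    rows = [
        # E fixed alt vs T/N ref; hybrid homozygous -> LOH retaining E
        [a, a, r, r, r, r, r, a],
        # same configuration but hybrid still heterozygous
        [a, a, r, r, r, r, r, het],
        # E and T both alt: the ET hybrid's parents agree -> uninformative
        [a, a, a, a, r, r, r, a],
        # private SNPs: homozygous, heterozygous, and not carried
        [r, r, r, r, r, r, r, a],
        [r, r, r, r, r, r, r, het],
        [r, r, r, r, r, r, r, r],
    ]
    table = build_table(
        [("c1", i, "A", "G") for i in range(len(rows))], rows, samples
    )
    cls = toy_cls(
        table,
        [
            {"category": "interspecific_fixed"},
            {"category": "interspecific_fixed"},
            {"category": "interspecific_fixed"},
            {"category": "private_asexual"},
            {"category": "private_asexual"},
            {"category": "private_asexual"},
        ],
    )
    return cls


class TestLOH:
    def test_call_loh_hand_counts(self):
        cls = loh_fixture()
        profile = call_loh(cls, HYBRID)
        assert profile.informative_sites == 2
        assert profile.loh_sites == 1
        assert profile.retained == {"E": 1}
        assert profile.proportion == pytest.approx(0.5)

    def test_non_hybrid_rejected(self):
        cls = loh_fixture()
        with pytest.raises(ValueError):
            call_loh(cls, SampleMeta("EE_1", "EE", 2, "sexual"))

    def test_private_proportions(self):
        cls = loh_fixture()
        assert private_snp_proportion(cls, "H1") == pytest.approx(2 / 6)
        assert homozygous_private_fraction(cls, "H1") == pytest.approx(1 / 2)

    def test_heterozygosity(self):
        cls = loh_fixture()
        assert heterozygosity(cls.table, "H1") == pytest.approx(2 / 6)
        assert heterozygosity(cls.table, "EE_1") == 0.0


class TestSFS:
    def test_hand_spectrum(self):
        samples = sexual_panel(2)
        r, het = (0, 0), (0, 1)
        rows = [
            [het, r, r, r, r, r, r],   # derived count 1 of 4 E chromosomes
            [het, het, r, r, r, r, r],  # derived count 2
            [het, r, r, r, r, r, r],   # unpolarized: must be skipped
        ]
        table = build_table(
            [("c1", i, "A", "G") for i in range(len(rows))], rows, samples
        )
        cls = toy_cls(
            table,
            [
                {"category": "intraspecific", "focal_species": "E"},
                {"category": "intraspecific", "focal_species": "E"},
                {"category": "intraspecific", "focal_species": "E",
                 "polarized": False, "derived_idx": -1},
            ],
        )
        spec = site_frequency_spectrum(
            cls, ["EE_1", "EE_2"], focal_species="E", population_label="E"
        )
        assert spec.counts == {1: 1, 2: 1}
        assert spec.n_chromosomes == 4
        assert spec.n_unpolarized_skipped == 1
        assert spec.mean_derived_frequency() == pytest.approx((0.25 + 0.5) / 2)

    def test_category_and_synonymity_stratification(self):
        samples = sexual_panel(1)
        het = (0, 1)
        r = (0, 0)
        table = build_table(
            [("c1", 0, "A", "G"), ("c1", 1, "A", "G")],
            [[het, r, r, r], [het, r, r, r]],
            samples,
        )
        cls = toy_cls(
            table,
            [
                {"category": "intraspecific", "focal_species": "E",
                 "synonymity": "synonymous"},
                {"category": "intraspecific", "focal_species": "E",
                 "synonymity": "nonsynonymous"},
            ],
        )
        syn = site_frequency_spectrum(cls, ["EE_1"], synonymity="synonymous")
        nonsyn = site_frequency_spectrum(cls, ["EE_1"], synonymity="nonsynonymous")
        assert syn.n_sites == 1 and nonsyn.n_sites == 1


class TestSharing:
    def test_sharing_counts(self):
        h1 = SampleMeta("H1", "ET", 2, "old_clone", "c1")
        h2 = SampleMeta("H2", "ET", 2, "old_clone", "c1")
        samples = sexual_panel(1) + [h1, h2]
        r, het = (0, 0), (0, 1)
        rows = [
            [r, r, r, r, het, het],  # trunk-like, shared k=2
            [r, r, r, r, het, r],    # tip, k=1
            [r, r, r, r, r, r],      # not carried by this clone
        ]
        table = build_table(
            [("c1", i, "A", "G") for i in range(len(rows))], rows, samples
        )
        cls = toy_cls(
            table,
            [
                {"category": "private_asexual", "synonymity": "synonymous"},
                {"category": "private_asexual", "synonymity": "nonsynonymous"},
                {"category": "private_asexual", "synonymity": "synonymous"},
            ],
        )
        spec = clone_sharing_spectrum(cls, "c1", ["H1", "H2"])
        assert spec.counts == {"synonymous": {2: 1}, "nonsynonymous": {1: 1}}
        assert len(spec.per_site) == 2


class TestQuadraticFit:
    def test_exact_line(self):
        x = np.linspace(0, 1, 12)
        y = 0.3 + 2.0 * x
        g, f = fit_loh_vs_private(x, y)
        assert abs(g.a2) < 1e-8
        assert f.a0 == pytest.approx(g.a0, abs=1e-8)
        assert f.a1 == pytest.approx(g.a1, abs=1e-8)
        assert f.a2 == pytest.approx(g.a2, abs=1e-8)

    def test_exact_parabola(self):
        x = np.linspace(-1, 1, 15)
        y = 0.5 - 1.5 * x + 1.0 * x**2
        g, f = fit_loh_vs_private(x, y)
        assert g.a2 == pytest.approx(1.0, abs=1e-8)
        assert f.a2 == pytest.approx(1.0, abs=1e-8)
        assert g.p_a2 < 1e-6 or math.isnan(g.p_a2)  # rss == 0 -> nan p allowed

    def test_negative_curvature_clipped(self):
        x = np.linspace(0, 1, 30)
        rng = np.random.default_rng(3)
        y = 1.0 - x**2 + 0.01 * rng.normal(size=x.size)
        g, f = fit_loh_vs_private(x, y)
        assert g.a2 < 0
        assert f.a2 >= 0
        assert f.rss >= g.rss - 1e-10

    def test_rejects_short_input(self):
        with pytest.raises(ValueError):
            fit_loh_vs_private([0, 1, 2], [0, 1, 2])
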