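import numpy as np
import pandas as pd
import pytest

from clonedecay.data import GenotypeTable, SampleMeta, UNUSED, MISSING
from clonedecay.synthetic import CloneSpec, SimConfig, simulate


def build_table(site_defs, call_defs, samples):
    """Toy GenotypeTable: site_defs = [(contig,pos,ref,alt)], call_defs =
    list per site of per-sample allele tuples or None (missing)."""
    sites = pd.DataFrame(site_defs, columns=["contig", "pos", "ref", "alt"])
    calls = np.full((len(site_defs), len(samples), 3), UNUSED, dtype=np.int8)
    for i, row in enumerate(call_defs):
        for j, g in enumerate(row):
            ploidy = samples[j].ploidy
            if g is None:
                calls[i, j, :ploidy] = MISSING
            else:
                assert len(g) == ploidy
                calls[i, j, : len(g)] = g
    return GenotypeTable(sites, calls, samples)


def sexual_panel(n_per_species=2, with_outgroup=True):
    samples = []
    for sp in "ETN":
        for j in range(n_per_species):
            samples.append(SampleMeta(f"{sp}{sp}_{j+1}", sp * 2, 2, "sexual"))
    if with_outgroup:
        samples.append(SampleMeta("LL_1", "LL", 2, "outgroup"))
    return samples


@pytest.fixture(scope="session")
def small_sim():
    """A compact but fully featured simulated complex."""
    cfg = SimConfig(
        n_orfs=60,
        orf_len_codons=60,
        n_ind_per_species=6,
        clones=(
            CloneSpec("F1_ET", "ET", 0.0, 2),
            CloneSpec("C_EN_young", "EN", 5e3, 3),
            CloneSpec("C_EN_old", "EN", 1.5e5, 3),
            CloneSpec("C_EEN_old", "EEN", 1.5e5, 3),
        ),
        seed=11,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_cls(small_sim):
    from clonedecay.classify import classify_dataset

    return classify_dataset(small_sim.dataset())
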