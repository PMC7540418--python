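"""Dataset-level dN/dS: ORF eligibility, within-individual and null estimates.

Bridges the genotype table to the codon-level NG86 machinery.  Because codon
masking guarantees at most one variable site per analyzed codon, a diploid or
triploid individual's two distinct codon variants are phase-free, so the
within-individual estimate needs no haplotype reconstruction.  Between
individuals, heterozygous sites are collapsed into seeded pseudo-haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import SiteClassification
from .codon import DnDsEstimate, dnds_from_codon_variants
from .data import Dataset, UNUSED

__all__ = [
    "codon_variants_for_sample",
    "orf_eligible",
    "eligible_orfs",
    "within_individual_dnds",
    "pseudo_haplotype_codons",
    "pairwise_sample_dnds",
    "simulated_hybrid_null",
]

MIN_INTACT_CODONS = 50


def _orf_record(dataset: Dataset, orf_id: str):
    hit = dataset.orfs.loc[dataset.orfs["orf_id"] == orf_id]
    if hit.empty:
        raise KeyError(f"unknown ORF {orf_id}")
    return hit.iloc[0]


def _orf_sites(cls: SiteClassification, orf_id: str) -> pd.DataFrame:
    f = cls.frame
    return f[(f["orf_id"] == orf_id) & (~f["in_stop_codon"])]


def codon_variants_for_sample(
    dataset: Dataset,
    cls: SiteClassification,
    sample_id: str,
    orf_id: str,
) -> list:
    """Per-codon variant list for one individual over one ORF.

    Entries: codon string (homozygous), pair of distinct codon variants
    (heterozygous at the codon's single variable site), or None for codons
    that are masked or not fully called in this sample.  The ORF's terminal
    stop codon is excluded.
    """
    rec = _orf_record(dataset, orf_id)
    seq = dataset.reference[rec["contig"]][rec["start"] : rec["end"]]
    n_codons = len(seq) // 3 - 1  # exclude the stop codon
    variants: list = [seq[3 * i : 3 * i + 3] for i in range(n_codons)]

    table = cls.table
    j = table.sample_index(sample_id)
    for i, row in _orf_sites(cls, orf_id).iterrows():
        ci = int(row["codon_index"])
        if ci >= n_codons:
            continue
        if row["masked"]:
            variants[ci] = None
            continue
        alleles = table.allele_multisets(i, j)
        if alleles is None:
            variants[ci] = None
            continue
        if variants[ci] is None:
            continue
        cp = int(row["codon_pos"])
        codon = variants[ci]
        bases = {0: row["ref"], 1: row["alt"]}
        distinct = sorted(set(alleles))
        cods = [codon[:cp] + bases[a] + codon[cp + 1 :] for a in distinct]
        variants[ci] = cods[0] if len(cods) == 1 else (cods[0], cods[1])
    return variants


def orf_eligible(
    dataset: Dataset,
    cls: SiteClassification,
    orf_id: str,
    sample_ids: list[str],
    min_codons: int = MIN_INTACT_CODONS,
) -> bool:
    """True iff >= ``min_codons`` codons are unmasked and fully called in
    every listed sample (>= 50 intact codons by default)."""
    ok = None
    for sid in sample_ids:
        v = codon_variants_for_sample(dataset, cls, sid, orf_id)
        resolved = np.array([x is not None for x in v])
        ok = resolved if ok is None else (ok & resolved)
    if ok is None:
        return False
    return int(ok.sum()) >= min_codons


def eligible_orfs(
    dataset: Dataset,
    cls: SiteClassification,
    sample_ids: list[str],
    min_codons: int = MIN_INTACT_CODONS,
) -> list[str]:
    return [
        orf_id
        for orf_id in dataset.orfs["orf_id"]
        if orf_eligible(dataset, cls, orf_id, sample_ids, min_codons)
    ]


def within_individual_dnds(
    dataset: Dataset,
    cls: SiteClassification,
    sample_id: str,
    orf_id: str,
    c: float = 0.01,
) -> DnDsEstimate:
    """dN/dS between the allele variants carried by one (hybrid) individual.

    Codons where the individual carries two distinct alleles contribute one
    pathway difference (dosage in triploids is ignored); homozygous codons
    contribute sites only.  A fully homozygous individual gives ratio 1.0.
    """
    meta = cls.table.samples[cls.table.sample_index(sample_id)]
    if meta.ploidy < 2:
        raise ValueError("within-individual dN/dS requires ploidy >= 2")
    variants = codon_variants_for_sample(dataset, cls, sample_id, orf_id)
    return dnds_from_codon_variants(variants, c=c)


def pseudo_haplotype_codons(
    dataset: Dataset,
    cls: SiteClassification,
    sample_id: str,
    orf_id: str,
    rng: np.random.Generator,
) -> list:
    """Collapse an individual to one codon sequence, sampling one allele at
    each heterozygous codon (seeded)."""
    variants = codon_variants_for_sample(dataset, cls, sample_id, orf_id)
    out = []
    for v in variants:
        if v is None or isinstance(v, str):
            out.append(v)
        else:
            out.append(v[rng.integers(0, 2)])
    return out


def _combine(codons_a: list, codons_b: list) -> list:
    merged = []
    for ca, cb in zip(codons_a, codons_b):
        if ca is None or cb is None:
            merged.append(None)
        elif ca == cb:
            merged.append(ca)
        else:
            merged.append((ca, cb))
    return merged


def pairwise_sample_dnds(
    dataset: Dataset,
    cls: SiteClassification,
    sample_a: str,
    sample_b: str,
    orf_id: str,
    c: float = 0.01,
    seed: int = 0,
) -> DnDsEstimate:
    """Between-individual dN/dS using seeded pseudo-haplotypes."""
    rng = np.random.default_rng(seed)
    ha = pseudo_haplotype_codons(dataset, cls, sample_a, orf_id, rng)
    hb = pseudo_haplotype_codons(dataset, cls, sample_b, orf_id, rng)
    return dnds_from_codon_variants(_combine(ha, hb), c=c)


@dataclass
class NullDistribution:
    """Per-ORF x per-pair dN/dS ratios from simulated interspecific hybrids."""

    frame: pd.DataFrame  # orf_id, pair_id, Nd, Sd, N, S, dN, dS, ratio

    @property
    def ratios(self) -> np.ndarray:
        return self.frame["ratio"].to_numpy()


def simulated_hybrid_null(
    dataset: Dataset,
    cls: SiteClassification,
    species_a: str,
    species_b: str,
    orf_ids: list[str] | None = None,
    c: float = 0.01,
    seed: int = 0,
    min_codons: int = MIN_INTACT_CODONS,
) -> NullDistribution:
    """Null dN/dS distribution from all cross-species sexual sample pairs.

    Every individual of species_a is paired with every individual of
    species_b (simulated interspecific hybrids); each pair contributes one
    estimate per eligible ORF, using per-individual pseudo-haplotypes drawn
    once per ORF under the given seed.
    """
    table = cls.table
    sa = [s.sample_id for s in table.samples
          if s.category == "sexual" and s.species == species_a]
    sb = [s.sample_id for s in table.samples
          if s.category == "sexual" and s.species == species_b]
    if not sa or not sb:
        raise ValueError("need >= 1 sexual sample per species")
    if orf_ids is None:
        orf_ids = eligible_orfs(dataset, cls, sa + sb, min_codons)
    rng = np.random.default_rng(seed)
    rows = []
    for orf_id in orf_ids:
        haps = {
            sid: pseudo_haplotype_codons(dataset, cls, sid, orf_id, rng)
            for sid in sa + sb
        }
        for ida in sa:
            for idb in sb:
                est = dnds_from_codon_variants(_combine(haps[ida], haps[idb]), c=c)
                rows.append(
                    {
                        "orf_id": orf_id, "pair_id": f"{ida}x{idb}",
                        "Nd": est.Nd, "Sd": est.Sd, "N": est.N, "S": est.S,
                        "dN": est.dN, "dS": est.dS, "ratio": est.ratio,
                        "valid": est.valid,
                    }
                )
    return NullDistribution(frame=pd.DataFrame(rows))
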