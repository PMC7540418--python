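"""Frequency spectra, heterozygosity, LOH calling and the LOH-vs-private fit.

Site-frequency spectra (SFS) tally derived-allele counts over the called
chromosomes of a population (a sexual species or a clone), stratified by
synonymity — the comparison of synonymous vs nonsynonymous spectra is the
package's read-out of purifying selection.  Clone-sharing spectra count how
many members of a clone carry each private SNP.  Loss of heterozygosity (LOH)
is called at diagnostic fixed interspecific sites: a hybrid that carries
alleles of only one parental genome at a site where its parental species
differ has lost the other parent's allele.  The relation between the
private-SNP proportion and the LOH proportion across clones is summarised by
quadratic fits, unconstrained and with the quadratic coefficient forced
non-negative (accumulating LOH erases an increasing share of private SNPs,
which predicts convexity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classify import SiteClassification, SEXUAL_SPECIES
from .data import GenotypeTable, SampleMeta, UNUSED

__all__ = [
    "FrequencySpectrum",
    "SharingSpectrum",
    "LOHProfile",
    "QuadraticFit",
    "syn_class",
    "site_frequency_spectrum",
    "clone_sharing_spectrum",
    "heterozygosity",
    "call_loh",
    "private_snp_proportion",
    "homozygous_private_fraction",
    "fit_loh_vs_private",
]


def syn_class(synonymity: pd.Series | np.ndarray) -> np.ndarray:
    """Collapse synonymity to {synonymous, nonsynonymous, other}; stop-gains
    count as nonsynonymous (they are tallied separately elsewhere)."""
    s = np.asarray(synonymity, dtype=object)
    out = np.full(s.shape, "other", dtype=object)
    out[s == "synonymous"] = "synonymous"
    out[(s == "nonsynonymous") | (s == "stop_gain")] = "nonsynonymous"
    return out


@dataclass
class FrequencySpectrum:
    """Derived-allele-count spectrum for one population stratum."""

    population: str
    category: str
    synonymity: str
    n_chromosomes: int
    counts: dict  # derived count -> number of sites
    per_site: pd.DataFrame  # site, derived_count, called_chromosomes
    n_unpolarized_skipped: int

    @property
    def n_sites(self) -> int:
        return int(sum(self.counts.values()))

    def mean_derived_frequency(self) -> float:
        df = self.per_site
        if df.empty:
            return float("nan")
        return float((df["derived_count"] / df["called_chromosomes"]).mean())


def _sample_indices(table: GenotypeTable, sample_ids: list[str]) -> np.ndarray:
    return np.array([table.sample_index(s) for s in sample_ids], dtype=int)


def _derived_counts(table, site_rows, sample_idx):
    """Per-site derived-allele count and called chromosome number."""
    recs = []
    for i, di in site_rows:
        # exclude samples with any missing allele at this site
        g2 = table.calls[i, sample_idx, :]
        ok = ~(g2 == -1).any(axis=1)
        alleles = g2[ok]
        alleles = alleles[alleles != UNUSED]
        recs.append((i, int((alleles == di).sum()), int(alleles.size)))
    return recs


def site_frequency_spectrum(
    cls: SiteClassification,
    population_samples: list[str],
    category: str = "intraspecific",
    synonymity: str = "synonymous",
    focal_species: str | None = None,
    population_label: str = "",
) -> FrequencySpectrum:
    """SFS of polarized sites of one category/synonymity in one population.

    Unpolarized sites are skipped and counted.  For ``intraspecific`` sites,
    ``focal_species`` restricts to SNPs segregating in that species.
    """
    table = cls.table
    f = cls.frame
    sel = (f["category"] == category) & (syn_class(f["synonymity"]) == synonymity)
    if focal_species is not None:
        sel &= f["focal_species"].str.contains(focal_species, na=False)
    n_unpol = int((sel & ~f["polarized"]).sum())
    sel &= f["polarized"]
    idx = _sample_indices(table, population_samples)
    rows = [(i, int(f["derived_idx"].iat[k])) for k, i in
            zip(np.nonzero(sel.to_numpy())[0], f.index[sel])]
    recs = _derived_counts(table, rows, idx)
    # keep sites segregating information: include zero-count sites as bin 0
    counts: dict[int, int] = {}
    for _, dc, _nc in recs:
        counts[dc] = counts.get(dc, 0) + 1
    per_site = pd.DataFrame(recs, columns=["site", "derived_count", "called_chromosomes"])
    ploidies = [table.samples[j].ploidy for j in idx]
    return FrequencySpectrum(
        population=population_label or ",".join(population_samples),
        category=category,
        synonymity=synonymity,
        n_chromosomes=int(sum(ploidies)),
        counts=counts,
        per_site=per_site,
        n_unpolarized_skipped=n_unpol,
    )


@dataclass
class SharingSpectrum:
    """How many same-clone individuals share each private SNP (k = carriers)."""

    clone_id: str
    clone_size: int
    counts: dict  # synonymity -> {k: n_sites}
    per_site: pd.DataFrame  # site, k, synonymity


def clone_sharing_spectrum(
    cls: SiteClassification,
    clone_id: str,
    member_ids: list[str],
) -> SharingSpectrum:
    """Sharing spectrum of one clone's private SNPs, split syn/nonsyn."""
    if len(member_ids) < 2:
        warnings.warn(
            f"clone {clone_id} has fewer than 2 members; spectrum degenerate",
            stacklevel=2,
        )
    table = cls.table
    f = cls.frame
    idx = _sample_indices(table, member_ids)
    sel = (f["category"] == "private_asexual") & f["polarized"]
    rows = []
    sclass = syn_class(f["synonymity"])
    for k in np.nonzero(sel.to_numpy())[0]:
        i = f.index[k]
        di = int(f["derived_idx"].iat[k])
        g = table.calls[i, idx, :]
        carriers = ((g == di).any(axis=1)).sum()
        if carriers == 0:
            continue  # private to a different clone
        rows.append({"site": i, "k": int(carriers), "synonymity": sclass[k]})
    per_site = pd.DataFrame(rows, columns=["site", "k", "synonymity"])
    counts: dict[str, dict[int, int]] = {}
    for _, row in per_site.iterrows():
        counts.setdefault(row["synonymity"], {})
        counts[row["synonymity"]][row["k"]] = (
            counts[row["synonymity"]].get(row["k"], 0) + 1
        )
    return SharingSpectrum(
        clone_id=clone_id,
        clone_size=len(member_ids),
        counts=counts,
        per_site=per_site,
    )


# ---------------------------------------------------------------------------
# Heterozygosity and LOH
# ---------------------------------------------------------------------------

def heterozygosity(table: GenotypeTable, sample_id: str) -> float:
    """Fraction of called biallelic sites where the sample carries >= 2
    distinct alleles."""
    j = table.sample_index(sample_id)
    called = table.called()[:, j]
    if not called.any():
        raise ValueError(f"sample {sample_id} has no called sites")
    het = table.heterozygous()[:, j]
    return float(het.sum() / called.sum())


@dataclass
class LOHProfile:
    """Loss-of-heterozygosity summary for one hybrid individual."""

    sample_id: str
    informative_sites: int
    loh_sites: int
    retained: dict = field(default_factory=dict)  # parental letter(s) -> count

    @property
    def proportion(self) -> float:
        if self.informative_sites == 0:
            return float("nan")
        return self.loh_sites / self.informative_sites


def _species_fixed_alleles(table: GenotypeTable) -> np.ndarray:
    """(n_sites, n_species) fixed allele per sexual species (valid at
    interspecific sites; NaN semantics not needed there)."""
    A = np.zeros((table.n_sites, len(SEXUAL_SPECIES)), dtype=int)
    for k, sp in enumerate(SEXUAL_SPECIES):
        idx = np.array(
            [i for i, s in enumerate(table.samples)
             if s.category == "sexual" and s.species == sp],
            dtype=int,
        )
        c = table.allele_counts_by_samples(idx)
        A[:, k] = np.where(c[:, 1] > 0, 1, 0)
    return A


def call_loh(
    cls: SiteClassification,
    sample: SampleMeta,
) -> LOHProfile:
    """Call LOH for one hybrid at its diagnostic fixed interspecific sites.

    Informative sites are fixed differences between the parental genomes the
    hybrid carries.  Diploids: LOH where the call is homozygous.  Triploids:
    LOH only where all observed alleles derive from a single parental
    species (conservative, since one lost homologue out of three need not
    remove a species' allele).
    """
    letters = sorted(set(sample.genomotype))
    if len(letters) < 2:
        raise ValueError(f"{sample.sample_id} is not a hybrid: {sample.genomotype}")
    table = cls.table
    f = cls.frame
    j = table.sample_index(sample.sample_id)
    A = _species_fixed_alleles(table)
    sp_col = {sp: k for k, sp in enumerate(SEXUAL_SPECIES)}

    inter = (f["category"] == "interspecific_fixed").to_numpy()
    informative = 0
    loh = 0
    retained: dict[str, int] = {}
    calls = table.calls
    called = table.called()
    for k in np.nonzero(inter)[0]:
        i = f.index[k]
        if not called[i, j]:
            continue
        par = {sp: int(A[i, sp_col[sp]]) for sp in letters}
        if len(set(par.values())) < 2:
            continue  # parents agree: not diagnostic for this hybrid
        informative += 1
        g = calls[i, j]
        g = g[g != UNUSED]
        if g.max() != g.min():
            continue  # still heterozygous
        v = int(g[0])
        owners = [sp for sp in letters if par[sp] == v]
        if not owners:
            continue  # carries only the non-parental allele; not a clean LOH
        loh += 1
        tag = "|".join(owners)
        retained[tag] = retained.get(tag, 0) + 1
    return LOHProfile(
        sample_id=sample.sample_id,
        informative_sites=informative,
        loh_sites=loh,
        retained=retained,
    )


def private_snp_proportion(cls: SiteClassification, sample_id: str) -> float:
    """Share of the sample's called SNP sites that are private asexual SNPs
    the sample itself carries."""
    table = cls.table
    f = cls.frame
    j = table.sample_index(sample_id)
    called = table.called()[:, j]
    denom = int(called.sum())
    if denom == 0:
        raise ValueError(f"sample {sample_id} has no called sites")
    sel = (f["category"] == "private_asexual").to_numpy() & f["polarized"].to_numpy()
    num = 0
    for k in np.nonzero(sel)[0]:
        i = f.index[k]
        if not called[i]:
            continue
        di = int(f["derived_idx"].iat[k])
        g = table.calls[i, j]
        if (g[g != UNUSED] == di).any():
            num += 1
    return num / denom


def homozygous_private_fraction(cls: SiteClassification, sample_id: str) -> float:
    """Among private SNPs this sample carries, the fraction carried in a
    homozygous state (all allele copies derived)."""
    table = cls.table
    f = cls.frame
    j = table.sample_index(sample_id)
    sel = (f["category"] == "private_asexual").to_numpy() & f["polarized"].to_numpy()
    carried = hom = 0
    for k in np.nonzero(sel)[0]:
        i = f.index[k]
        di = int(f["derived_idx"].iat[k])
        g = table.calls[i, j]
        g = g[g != UNUSED]
        if (g == -1).any() or not (g == di).any():
            continue
        carried += 1
        if (g == di).all():
            hom += 1
    if carried == 0:
        return float("nan")
    return hom / carried


# ---------------------------------------------------------------------------
# Quadratic LOH-vs-private fit
# ---------------------------------------------------------------------------

@dataclass
class QuadraticFit:
    """y = a0 + a1 x + a2 x^2 least-squares fit."""

    a0: float
    a1: float
    a2: float
    constrained: bool
    rss: float
    p_a2: float  # t-test of a2 = 0 (unconstrained fit only, else nan)

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.a0 + self.a1 * x + self.a2 * x**2


def fit_loh_vs_private(x, y) -> tuple[QuadraticFit, QuadraticFit]:
    """Quadratic fits of LOH proportion on private-SNP proportion.

    Returns ``(g, f)``: g is the ordinary least-squares fit, f constrains the
    quadratic coefficient to be non-negative (boundary permitted).  The
    reported ``p_a2`` of g is the t-test of a vanishing quadratic term, i.e.
    the linearity test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need >= 4 points for a quadratic fit with a test")
    X = np.column_stack([np.ones_like(x), x, x**2])

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = x.size - 3
    p_a2 = float("nan")
    if dof > 0 and rss > 0:
        sigma2 = rss / dof
        try:
            cov = sigma2 * np.linalg.inv(X.T @ X)
            se = np.sqrt(cov[2, 2])
            if se > 0:
                t = beta[2] / se
                p_a2 = float(2 * stats.t.sf(abs(t), dof))
        except np.linalg.LinAlgError:
            pass
    g = QuadraticFit(*map(float, beta), constrained=False, rss=rss, p_a2=p_a2)

    # Single-bound convex problem: the constrained optimum is either the
    # unconstrained solution (if a2 >= 0) or the boundary fit with a2 = 0.
    if beta[2] >= 0:
        beta_c, rss_c = beta, rss
    else:
        bl, *_ = np.linalg.lstsq(X[:, :2], y, rcond=None)
        beta_c = np.array([bl[0], bl[1], 0.0])
        resid_c = y - X[:, :2] @ bl
        rss_c = float(resid_c @ resid_c)
    f = QuadraticFit(
        *map(float, beta_c), constrained=True, rss=rss_c, p_a2=float("nan")
    )
    return g, f
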