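"""Site filtering, paralog flagging, codon masking, SNP classification.

Implements the SNP data model for a hybrid complex of three sexual species
(E, T, N) plus an outgroup (L): biallelic/called-fraction filtering, removal
of contigs with paralog-like shared heterozygosity, masking of codons with
more than one polymorphic site (their translation is phase-dependent),
assignment of each retained SNP to one of three mutually exclusive categories
— intraspecific polymorphism, fixed interspecific difference, private asexual
mutation — synonymity annotation by codon translation, and derived-allele
polarization against the sister taxon.

Hybrid genotypes never influence the intraspecific / interspecific calls:
those depend on the sexual species only.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .codon import translate_codon
from .data import Dataset, GenotypeTable, SEXUAL_SPECIES, OUTGROUP

__all__ = [
    "SiteClassification",
    "filter_sites",
    "flag_paralog_contigs",
    "map_sites_to_orfs",
    "mask_multi_variant_codons",
    "classify_sites",
    "annotate_synonymity",
    "default_sister_map",
    "classify_dataset",
]

CATEGORY_LEVELS = (
    "intraspecific",
    "interspecific_fixed",
    "private_asexual",
    "unclassified",
)


def default_sister_map() -> dict:
    """T and N are mutual sisters; E polarizes against the T/N consensus with
    the outgroup L as fallback."""
    return {"T": ("N",), "N": ("T",), "E": ("T", "N"), "fallback": OUTGROUP}


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_sites(
    table: GenotypeTable,
    min_called_fraction: float = 0.8,
    biallelic_only: bool = True,
    include_outgroup: bool = False,
) -> tuple[GenotypeTable, np.ndarray, dict]:
    """Keep biallelic sites called in >= ``min_called_fraction`` of individuals.

    The called fraction is computed over ingroup samples (hybrids included);
    the outgroup is excluded unless ``include_outgroup``.  Returns the filtered
    table, the boolean keep mask over input sites, and removal counts.
    """
    sites = table.sites
    n = len(sites)
    keep = np.ones(n, dtype=bool)
    log = {"input_sites": n}

    if biallelic_only:
        alt = sites["alt"].astype(str)
        bad = alt.str.contains(",").to_numpy() | (alt == ".").to_numpy()
        log["removed_not_biallelic"] = int(bad.sum())
        keep &= ~bad

    idx = [
        i for i, s in enumerate(table.samples)
        if include_outgroup or s.category != "outgroup"
    ]
    called = table.called()[:, idx]
    frac = called.mean(axis=1) if idx else np.zeros(n)
    under = frac < min_called_fraction
    log["removed_undercalled"] = int((under & keep).sum())
    keep &= ~under

    log["retained"] = int(keep.sum())
    if log["retained"] == 0:
        import warnings

        warnings.warn("no sites retained after filtering", stacklevel=2)
    return table.subset_sites(keep), keep, log


def flag_paralog_contigs(
    table: GenotypeTable,
    min_shared_het_sites: int = 1,
) -> tuple[set, np.ndarray]:
    """Contigs with paralog-like heterozygosity shared across distant species.

    A site is spurious when at least one individual of every ingroup sexual
    species AND the outgroup is heterozygous there.  Returns the flagged
    contig set and the per-site spurious mask.
    """
    samples = table.samples
    out_idx = [i for i, s in enumerate(samples) if s.category == "outgroup"]
    if not out_idx:
        raise ValueError("paralog flagging requires an outgroup")
    het = table.heterozygous()
    spurious = het[:, out_idx].any(axis=1)
    for sp in SEXUAL_SPECIES:
        sp_idx = [
            i for i, s in enumerate(samples)
            if s.category == "sexual" and s.species == sp
        ]
        if not sp_idx:
            continue
        spurious &= het[:, sp_idx].any(axis=1)
    contigs = table.sites["contig"].to_numpy()
    flagged = {
        c
        for c in pd.unique(contigs[spurious])
        if int(spurious[contigs == c].sum()) >= min_shared_het_sites
    }
    return flagged, spurious


# ---------------------------------------------------------------------------
# Codon mapping and masking
# ---------------------------------------------------------------------------

def map_sites_to_orfs(sites: pd.DataFrame, orfs: pd.DataFrame) -> pd.DataFrame:
    """Map sites to (orf_id, codon_index, codon_pos); non-ORF sites get NaN.

    The final codon of each ORF annotation is its stop codon; sites there are
    treated as noncoding for synonymity purposes (flag ``in_stop_codon``).
    """
    out = pd.DataFrame(
        {
            "orf_id": pd.Series([None] * len(sites), dtype=object),
            "codon_index": -1,
            "codon_pos": -1,
            "in_stop_codon": False,
        },
        index=sites.index,
    )
    by_contig = {c: g for c, g in orfs.groupby("contig")}
    contig_arr = sites["contig"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    for i in range(len(sites)):
        g = by_contig.get(contig_arr[i])
        if g is None:
            continue
        hit = g[(g["start"] <= pos_arr[i]) & (pos_arr[i] < g["end"])]
        if hit.empty:
            continue
        rec = hit.iloc[0]
        off = pos_arr[i] - rec["start"]
        n_codons = (rec["end"] - rec["start"]) // 3
        out.iat[i, 0] = rec["orf_id"]
        out.iat[i, 1] = off // 3
        out.iat[i, 2] = off % 3
        out.iat[i, 3] = (off // 3) == n_codons - 1
    return out


def mask_multi_variant_codons(codon_map: pd.DataFrame) -> np.ndarray:
    """Mask codons containing >= 2 retained polymorphic sites.

    Returns a boolean per-site mask (True = site lies in a masked codon).
    After masking, every analyzed codon has at most one variable position.
    """
    coding = codon_map["orf_id"].notna()
    key = pd.MultiIndex.from_arrays(
        [codon_map["orf_id"], codon_map["codon_index"]]
    )
    counts = key[coding].value_counts()
    multi = set(counts[counts >= 2].index)
    masked = np.array(
        [coding.iat[i] and (key[i] in multi) for i in range(len(codon_map))]
    )
    # hard guarantee: unmasked analyzed codons hold exactly one variable site
    remaining = key[coding & ~masked].value_counts()
    assert (remaining <= 1).all(), "masking left a codon with 2+ variable sites"
    return masked


# ---------------------------------------------------------------------------
# Category assignment
# ---------------------------------------------------------------------------

def classify_sites(table: GenotypeTable) -> pd.DataFrame:
    """Assign every site to one mutually exclusive SNP category.

    Priority: intraspecific (any sexual species polymorphic), then
    interspecific_fixed (all species monomorphic, >= 1 pair differing), then
    private_asexual (sexuals invariant, >= 1 hybrid apomorphic), else
    unclassified with a reason.
    """
    samples = table.samples
    sp_counts = {}
    for sp in SEXUAL_SPECIES:
        idx = np.array(
            [i for i, s in enumerate(samples)
             if s.category == "sexual" and s.species == sp],
            dtype=int,
        )
        if idx.size == 0:
            raise ValueError(f"no sexual individuals of species {sp}")
        sp_counts[sp] = table.allele_counts_by_samples(idx)

    n = table.n_sites
    poly = {sp: (c[:, 0] > 0) & (c[:, 1] > 0) for sp, c in sp_counts.items()}
    called = {sp: (c[:, 0] + c[:, 1]) > 0 for sp, c in sp_counts.items()}
    allele = {sp: np.where(c[:, 1] > 0, 1, 0) for sp, c in sp_counts.items()}

    any_poly = np.zeros(n, dtype=bool)
    for sp in SEXUAL_SPECIES:
        any_poly |= poly[sp]
    all_called = np.ones(n, dtype=bool)
    for sp in SEXUAL_SPECIES:
        all_called &= called[sp]

    hyb_idx = np.array(
        [i for i, s in enumerate(samples) if s.is_hybrid], dtype=int
    )
    if hyb_idx.size:
        hyb_counts = table.allele_counts_by_samples(hyb_idx)
    else:
        hyb_counts = np.zeros((n, 2), dtype=int)

    category = np.full(n, "unclassified", dtype=object)
    reason = np.full(n, "", dtype=object)
    focal = np.full(n, "", dtype=object)
    pairs = np.full(n, "", dtype=object)
    derived_idx = np.full(n, -1, dtype=int)

    category[any_poly] = "intraspecific"
    for sp in SEXUAL_SPECIES:
        sel = any_poly & poly[sp]
        focal[sel] = np.where(focal[sel] == "", sp, focal[sel] + "+" + sp)

    undecided = ~any_poly
    missing = undecided & ~all_called
    reason[missing] = "missing_sexual_species"
    undecided &= all_called

    A = np.stack([allele[sp] for sp in SEXUAL_SPECIES], axis=1)
    differs = A.max(axis=1) != A.min(axis=1)
    inter = undecided & differs
    category[inter] = "interspecific_fixed"
    for a, b in combinations(range(len(SEXUAL_SPECIES)), 2):
        sel = inter & (A[:, a] != A[:, b])
        tag = f"{SEXUAL_SPECIES[a]}x{SEXUAL_SPECIES[b]}"
        pairs[sel] = np.where(pairs[sel] == "", tag, pairs[sel] + "," + tag)

    mono = undecided & ~differs
    shared = A[:, 0]  # allele common to all sexual species
    other = 1 - shared
    hyb_has_other = np.where(other == 1, hyb_counts[:, 1] > 0, hyb_counts[:, 0] > 0)
    private = mono & hyb_has_other
    category[private] = "private_asexual"
    derived_idx[private] = other[private]
    reason[mono & ~hyb_has_other] = "invariant_in_ingroup"

    return pd.DataFrame(
        {
            "category": category,
            "focal_species": focal,
            "pairs": pairs,
            "reason": reason,
            "derived_idx": derived_idx,  # filled for private; others polarized later
        }
    )


# ---------------------------------------------------------------------------
# Synonymity
# ---------------------------------------------------------------------------

def annotate_synonymity(
    sites: pd.DataFrame,
    codon_map: pd.DataFrame,
    masked: np.ndarray,
    reference: dict,
    orfs: pd.DataFrame,
) -> pd.DataFrame:
    """Classify each site's allele pair as synonymous / nonsynonymous / stop_gain.

    Valid because masking guarantees <= 1 variable site per analyzed codon, so
    translation in the reference context is phase-free.  Returns columns
    ``synonymity``, ``aa_ref``, ``aa_alt``.
    """
    orf_by_id = orfs.set_index("orf_id")
    syn = np.full(len(sites), "noncoding", dtype=object)
    aa_ref = np.full(len(sites), "", dtype=object)
    aa_alt = np.full(len(sites), "", dtype=object)
    for i in range(len(sites)):
        orf_id = codon_map["orf_id"].iat[i]
        if orf_id is None or codon_map["in_stop_codon"].iat[i]:
            continue
        if masked[i]:
            syn[i] = "masked"
            continue
        ref_allele = sites["ref"].iat[i]
        alt_allele = sites["alt"].iat[i]
        if any(b not in "ACGT" for b in (ref_allele + alt_allele)) or \
                len(ref_allele) != 1 or len(alt_allele) != 1:
            raise ValueError(
                f"non-SNP alleles at {sites['contig'].iat[i]}:{sites['pos'].iat[i]}"
            )
        rec = orf_by_id.loc[orf_id]
        ci = int(codon_map["codon_index"].iat[i])
        cp = int(codon_map["codon_pos"].iat[i])
        start = int(rec["start"]) + 3 * ci
        codon = reference[rec["contig"]][start : start + 3]
        codon_ref = codon[:cp] + ref_allele + codon[cp + 1 :]
        codon_alt = codon[:cp] + alt_allele + codon[cp + 1 :]
        a1, a2 = translate_codon(codon_ref), translate_codon(codon_alt)
        aa_ref[i], aa_alt[i] = a1, a2
        if a1 == a2:
            syn[i] = "synonymous"
        elif "*" in (a1, a2):
            syn[i] = "stop_gain"
        else:
            syn[i] = "nonsynonymous"
    return pd.DataFrame({"synonymity": syn, "aa_ref": aa_ref, "aa_alt": aa_alt})


# ---------------------------------------------------------------------------
# Polarization
# ---------------------------------------------------------------------------

def _species_state(table: GenotypeTable, sp: str, category: str = "sexual"):
    idx = np.array(
        [i for i, s in enumerate(table.samples)
         if s.category == category and s.species == sp],
        dtype=int,
    )
    if idx.size == 0:
        return None, None, None
    c = table.allele_counts_by_samples(idx)
    called = (c[:, 0] + c[:, 1]) > 0
    poly = (c[:, 0] > 0) & (c[:, 1] > 0)
    allele = np.where(c[:, 1] > 0, 1, 0)
    return called, poly, allele


def polarize_derived(
    table: GenotypeTable,
    classes: pd.DataFrame,
    sister_map: dict | None = None,
) -> pd.DataFrame:
    """Polarize intraspecific SNPs against the sister taxon.

    The ancestral allele is the one monomorphic in the configured sister
    species (for E: the agreeing T/N consensus, outgroup fallback); a
    polymorphic or missing sister leaves the site unpolarized.  Private
    asexual SNPs are already polarized: the sexual species carry the
    ancestral state.
    """
    if sister_map is None:
        sister_map = default_sister_map()
    state = {sp: _species_state(table, sp) for sp in SEXUAL_SPECIES}
    out_state = _species_state(table, OUTGROUP, category="outgroup")
    fallback = sister_map.get("fallback")

    derived_idx = classes["derived_idx"].to_numpy().copy()
    intra = classes["category"].to_numpy() == "intraspecific"
    for i in np.nonzero(intra)[0]:
        focal = classes["focal_species"].iat[i].split("+")[0]
        sisters = sister_map.get(focal)
        if sisters is None:
            raise KeyError(f"sister_map lacks focal taxon {focal!r}")
        anc = _consensus_allele(i, sisters, state)
        if anc is None and fallback is not None and out_state[0] is not None:
            called, poly, allele = out_state
            if called[i] and not poly[i]:
                anc = int(allele[i])
        if anc is not None:
            derived_idx[i] = 1 - anc
    polarized = derived_idx >= 0
    return pd.DataFrame({"derived_idx": derived_idx, "polarized": polarized})


def _consensus_allele(i, sisters, state):
    """Allele shared by all sister species at site i, or None."""
    alleles = set()
    for sp in sisters:
        called, poly, allele = state[sp]
        if called is None or not called[i] or poly[i]:
            return None
        alleles.add(int(allele[i]))
    return alleles.pop() if len(alleles) == 1 else None


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

@dataclass
class SiteClassification:
    """Filtered genotype table plus one annotation row per retained site."""

    table: GenotypeTable
    frame: pd.DataFrame
    log: dict

    def sites_of(self, category: str, synonymity: str | None = None) -> pd.DataFrame:
        sel = self.frame["category"] == category
        if synonymity is not None:
            sel &= self.frame["synonymity"] == synonymity
        return self.frame[sel]


def classify_dataset(
    dataset: Dataset,
    min_called_fraction: float = 0.8,
    biallelic_only: bool = True,
    drop_paralog_contigs: bool = True,
    min_shared_het_sites: int = 1,
    sister_map: dict | None = None,
) -> SiteClassification:
    """Run the full site-level pipeline: filter, flag, mask, classify, annotate."""
    table = dataset.genotypes
    orig_index = np.arange(table.n_sites)

    filtered, keep, log = filter_sites(
        table, min_called_fraction=min_called_fraction, biallelic_only=biallelic_only
    )
    orig_index = orig_index[keep]

    if drop_paralog_contigs:
        has_outgroup = any(s.category == "outgroup" for s in filtered.samples)
        if has_outgroup:
            flagged, _ = flag_paralog_contigs(
                filtered, min_shared_het_sites=min_shared_het_sites
            )
            if flagged:
                keep2 = ~filtered.sites["contig"].isin(flagged).to_numpy()
                log["removed_paralog_contig_sites"] = int((~keep2).sum())
                filtered = filtered.subset_sites(keep2)
                orig_index = orig_index[keep2]
            log["paralog_contigs"] = sorted(flagged)

    codon_map = map_sites_to_orfs(filtered.sites, dataset.orfs)
    masked = mask_multi_variant_codons(codon_map)
    log["masked_sites"] = int(masked.sum())

    classes = classify_sites(filtered)
    synonymity = annotate_synonymity(
        filtered.sites, codon_map, masked, dataset.reference, dataset.orfs
    )
    polar = polarize_derived(filtered, classes, sister_map=sister_map)

    idx2base = np.stack(
        [filtered.sites["ref"].to_numpy(), filtered.sites["alt"].to_numpy()], axis=1
    )
    di = polar["derived_idx"].to_numpy()
    derived_base = np.where(
        di >= 0, idx2base[np.arange(len(di)), np.clip(di, 0, 1)], ""
    )

    frame = pd.concat(
        [
            pd.DataFrame(
                {
                    "orig_site": orig_index,
                    "contig": filtered.sites["contig"],
                    "pos": filtered.sites["pos"],
                    "ref": filtered.sites["ref"],
                    "alt": filtered.sites["alt"],
                }
            ),
            classes.drop(columns=["derived_idx"]),
            codon_map,
            pd.DataFrame({"masked": masked}),
            synonymity,
            polar,
            pd.DataFrame({"derived_allele": derived_base}),
        ],
        axis=1,
    )
    return SiteClassification(table=filtered, frame=frame, log=log)
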