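"""Forward-time generator of a loach-like sexual–asexual hybrid complex.

Generates, with fully recorded ground truth, the data the analysis modules
consume: reference contigs with single-ORF annotations, three sexual species
(E, T, N) plus a divergent outgroup (L) carrying fixed interspecific
differences and segregating polymorphisms, and gynogenetic hybrid clones
(diploid or triploid combinations of parental haploid genomes) that accumulate
heterozygous private mutations and lose heterozygosity over time.  mtDNA
haplotypes diverge clock-like from the maternal donor species, so K2P distance
to the nearest sexual haplotype is an age proxy, as in the real complex.

Model summary
-------------
* Fixed interspecific differences: each coding site independently becomes
  derived in a species with probability ``d_fix / 2`` (outgroup: ``d_fix``),
  all derived species sharing one alternative allele, so a pair of species
  differs at a site with probability ~ ``d_fix``.  A fraction
  ``f_inter_nonsyn`` of these changes is forced nonsynonymous.
* Intraspecific polymorphism: per-site density ``theta`` per species; derived
  allele frequency classes i in 1..2n-1 are drawn with weight i^(-1-a) where
  a = ``sel_shift`` for nonsynonymous variants and 0 for synonymous ones, a
  stylised picture of purifying selection keeping amino-acid variants rare.
* Clones: a founder draws one haplotype per genomotype letter; private
  mutations arrive as Poisson(mu x coding_nt x tau) per lineage member, split
  into lineage-trunk events (shared by the clone) and tip events (individual
  specific) by ``trunk_fraction``; each is placed heterozygously on one
  haplotype.  Every heterozygous site of a hybrid is independently driven to
  homozygosity with probability 1 - exp(-lambda_loh x tau), the retained
  allele chosen uniformly — so LOH both erases and fixes private mutations.

Site classes never collide: fixed, segregating and private variants occupy
disjoint coding positions (start codon, final sense codon and the stop codon
are never mutated), so every emitted alternative allele has exactly one truth
record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .codon import BASES, SENSE_CODONS, STOP_CODONS, translate_codon
from .data import (
    MISSING,
    UNUSED,
    Dataset,
    GenotypeTable,
    SampleMeta,
    write_bed,
    write_fasta,
    write_sample_tsv,
    write_truth_json,
    write_vcf,
)

__all__ = [
    "SimConfig",
    "CloneSpec",
    "SimResult",
    "simulate",
    "simulate_reference",
    "write_outputs",
    "haplotype_sequence",
    "sample_frequency_classes",
    "simulate_phenotypes",
]


@dataclass(frozen=True)
class CloneSpec:
    """One clonal lineage: genomotype (e.g. 'EEN'), age in generations, size."""

    clone_id: str
    genomotype: str
    age_tau: float
    n_individuals: int
    category: str | None = None  # F1 / young_clone / old_clone; inferred if None

    def __post_init__(self):
        if len(self.genomotype) not in (2, 3):
            raise ValueError("genomotype length must be 2 or 3")
        if self.age_tau < 0:
            raise ValueError("age_tau must be >= 0")

    def inferred_category(self) -> str:
        if self.category:
            return self.category
        if self.age_tau == 0:
            return "F1"
        return "young_clone" if self.age_tau < 5e4 else "old_clone"


def _default_clones() -> tuple:
    # Ages in generations: F1, Holocene-young (~10 ky at ~2 y/generation) and
    # pre-glacial old (~300 ky) lineages, mirroring the age span of the study
    # system.
    return (
        CloneSpec("F1_ET", "ET", 0.0, 2),
        CloneSpec("C_EN_young", "EN", 5e3, 4),
        CloneSpec("C_EN_old", "EN", 1.5e5, 4),
        CloneSpec("C_EEN_old", "EEN", 1.5e5, 4),
    )


@dataclass
class SimConfig:
    """Parameters of the synthetic hybrid complex (rates per site/generation)."""

    n_orfs: int = 200
    orf_len_codons: int = 60
    species_labels: tuple = ("E", "T", "N")
    outgroup_label: str = "L"
    n_ind_per_species: int = 8
    n_ind_outgroup: int = 1
    d_fix: float = 0.01
    f_inter_nonsyn: float = 0.3
    theta: float = 0.004
    f_intra_nonsyn: float = 0.55
    sel_shift: float = 2.0
    clones: tuple = field(default_factory=_default_clones)
    mu: float = 2e-8
    f_priv_nonsyn: float = 0.6
    p_stop: float = 0.05
    lambda_loh: float = 7e-7
    trunk_fraction: float = 0.5
    mt_len: int = 1000
    mt_mu: float = 1e-7
    mt_species_div: float = 0.05
    missing_rate: float = 0.0
    flank_nt: int = 12
    seed: int = 0

    def __post_init__(self):
        for name in ("d_fix", "f_inter_nonsyn", "theta", "f_intra_nonsyn",
                     "f_priv_nonsyn", "p_stop", "trunk_fraction",
                     "mt_species_div", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.orf_len_codons < 1:
            raise ValueError("orf_len_codons must be >= 1")
        if self.sel_shift < 0:
            raise ValueError("sel_shift must be >= 0")
        for r in ("mu", "lambda_loh", "mt_mu"):
            if getattr(self, r) < 0:
                raise ValueError(f"{r} must be >= 0")

    @property
    def coding_nt(self) -> int:
        return 3 * self.orf_len_codons * self.n_orfs


@dataclass
class SimResult:
    """A simulated complex: data containers plus full planted truth."""

    config: SimConfig
    reference: dict
    orfs: pd.DataFrame
    genotypes: GenotypeTable
    mtdna: dict
    truth: dict
    species_pools: dict  # species -> {"site_idx": array, "hap": (n_sites, 2n) 0/1}
    founder_haps: dict  # hybrid sample_id -> list[(species, hap_index)]

    def dataset(self) -> Dataset:
        return Dataset(
            reference=self.reference,
            orfs=self.orfs,
            genotypes=self.genotypes,
            mtdna=self.mtdna,
        )


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

_NONSTOP = [c for c in SENSE_CODONS]


def simulate_reference(config: SimConfig, rng: np.random.Generator | None = None):
    """Random single-ORF contigs: flank + ATG + sense codons + stop + flank."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    stops = sorted(STOP_CODONS)
    reference = {}
    rows = []
    for i in range(config.n_orfs):
        contig = f"contig{i + 1:05d}"
        orf_id = f"orf{i + 1:05d}"
        body = ["ATG"]
        idx = rng.integers(0, len(_NONSTOP), size=config.orf_len_codons - 1)
        body.extend(_NONSTOP[k] for k in idx)
        stop = stops[rng.integers(0, len(stops))]
        flank5 = "".join(BASES[b] for b in rng.integers(0, 4, size=config.flank_nt))
        flank3 = "".join(BASES[b] for b in rng.integers(0, 4, size=config.flank_nt))
        seq = flank5 + "".join(body) + stop + flank3
        reference[contig] = seq
        start = config.flank_nt
        end = start + 3 * config.orf_len_codons + 3  # includes the stop codon
        rows.append({"orf_id": orf_id, "contig": contig, "start": start, "end": end})
    return reference, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mutation-effect bookkeeping
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _alt_classes(codon: str, pos: int):
    """Alternative bases at a codon position grouped by amino-acid effect."""
    aa = translate_codon(codon)
    syn, nonsyn, stop = [], [], []
    for b in BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if alt in STOP_CODONS:
            stop.append(b)
        elif translate_codon(alt) == aa:
            syn.append(b)
        else:
            nonsyn.append(b)
    return tuple(syn), tuple(nonsyn), tuple(stop)


def _choose_alt(codon, pos, want, rng):
    """Pick an alternative base of the wanted class, falling back gracefully.

    ``want`` is 'synonymous', 'nonsynonymous' or 'stop_gain'.  Returns
    (alt_base, realised_class).
    """
    syn, nonsyn, stop = _alt_classes(codon, pos)
    order = {
        "synonymous": [("synonymous", syn), ("nonsynonymous", nonsyn)],
        "nonsynonymous": [("nonsynonymous", nonsyn), ("synonymous", syn)],
        "stop_gain": [("stop_gain", stop), ("nonsynonymous", nonsyn), ("synonymous", syn)],
    }[want]
    for cls, opts in order:
        if opts:
            return opts[rng.integers(0, len(opts))], cls
    raise RuntimeError(f"no alternative base at {codon}[{pos}]")  # unreachable


def sample_frequency_classes(n_variants, n_chrom, a, rng):
    """Derived-allele counts i in 1..n_chrom-1 with weights i^(-1-a).

    a = 0 gives the neutral 1/i spectrum; a > 0 shifts mass toward singletons,
    emulating purifying selection on the derived class.
    """
    i = np.arange(1, n_chrom)
    w = i.astype(float) ** (-1.0 - a)
    w /= w.sum()
    return rng.choice(i, size=n_variants, p=w)


# ---------------------------------------------------------------------------
# Main simulation
# ---------------------------------------------------------------------------

class _SiteRegistry:
    """Global registry of variant sites with truth records."""

    def __init__(self):
        self.rows = []  # contig, pos, ref, alt
        self.truth = []

    def add(self, contig, pos, ref, alt, **truth) -> int:
        idx = len(self.rows)
        self.rows.append((contig, pos, ref, alt))
        self.truth.append({"site": idx, "contig": contig, "pos": int(pos),
                           "ref": ref, "alt": alt, **truth})
        return idx


def simulate(config: SimConfig) -> SimResult:
    """Run the full forward simulation and return data plus planted truth."""
    rng = np.random.default_rng(config.seed)
    reference, orfs = simulate_reference(config, rng)

    L = config.orf_len_codons
    # Candidate coding positions: codons 1 .. L-2 (start codon, final sense
    # codon and stop codon are never mutated).
    n_mut_codons = max(L - 2, 0)
    cand_orf = np.repeat(np.arange(config.n_orfs), n_mut_codons * 3)
    codon_in_orf = np.tile(np.repeat(np.arange(1, L - 1), 3), config.n_orfs)
    codon_pos = np.tile(np.arange(3), n_mut_codons * config.n_orfs)
    n_cand = cand_orf.size

    orf_list = orfs.to_dict("records")
    ref_codon_cache = {}

    def ref_codon(orf_i, codon_i):
        key = (orf_i, codon_i)
        if key not in ref_codon_cache:
            rec = orf_list[orf_i]
            s = rec["start"] + 3 * codon_i
            ref_codon_cache[key] = reference[rec["contig"]][s : s + 3]
        return ref_codon_cache[key]

    def site_location(k):
        orf_i = int(cand_orf[k])
        ci = int(codon_in_orf[k])
        cp = int(codon_pos[k])
        rec = orf_list[orf_i]
        pos = rec["start"] + 3 * ci + cp
        return rec["contig"], pos, ref_codon(orf_i, ci), orf_i, ci, cp

    registry = _SiteRegistry()
    used = np.zeros(n_cand, dtype=bool)
    ingroup = list(config.species_labels)
    all_species = ingroup + [config.outgroup_label]
    n2 = 2 * config.n_ind_per_species  # chromosomes per ingroup species

    # ---- fixed interspecific differences -------------------------------
    p_fix = np.array([config.d_fix / 2.0] * len(ingroup) + [config.d_fix])
    derived_mat = rng.random((n_cand, len(all_species))) < p_fix
    # drop sites where all ingroup species are derived (invariant in-group)
    all_in = derived_mat[:, : len(ingroup)].all(axis=1)
    derived_mat[all_in] = False
    fixed_idx = np.nonzero(derived_mat.any(axis=1))[0]

    species_site_alleles = {sp: {} for sp in all_species}  # sp -> {site: hap array or 'fixed'}
    fixed_sites_by_species = {sp: [] for sp in all_species}

    for k in fixed_idx:
        contig, pos, codon, orf_i, ci, cp = site_location(k)
        want = "nonsynonymous" if rng.random() < config.f_inter_nonsyn else "synonymous"
        alt, realised = _choose_alt(codon, cp, want, rng)
        derived_sp = [sp for j, sp in enumerate(all_species) if derived_mat[k, j]]
        in_derived = [sp for sp in derived_sp if sp in ingroup]
        if in_derived:
            cls = "interspecific_fixed"
        else:
            cls = "outgroup_only"
        site = registry.add(
            contig, pos, codon[cp], alt,
            cls=cls, synonymity=realised, derived=alt,
            derived_species=derived_sp, orf=orf_list[orf_i]["orf_id"],
            codon_index=ci, codon_pos=cp,
        )
        used[k] = True
        for sp in derived_sp:
            fixed_sites_by_species[sp].append(site)

    # ---- intraspecific segregating polymorphisms -----------------------
    seg_hap = {sp: {} for sp in ingroup}  # sp -> {site: bool array over 2n haplotypes}
    for sp in ingroup:
        avail = np.nonzero(~used)[0]
        n_seg = rng.binomial(avail.size, config.theta)
        chosen = rng.choice(avail, size=n_seg, replace=False)
        for k in chosen:
            contig, pos, codon, orf_i, ci, cp = site_location(k)
            want = "nonsynonymous" if rng.random() < config.f_intra_nonsyn else "synonymous"
            alt, realised = _choose_alt(codon, cp, want, rng)
            a_eff = config.sel_shift if realised != "synonymous" else 0.0
            count = int(sample_frequency_classes(1, n2, a_eff, rng)[0])
            carriers = rng.choice(n2, size=count, replace=False)
            hap = np.zeros(n2, dtype=bool)
            hap[carriers] = True
            site = registry.add(
                contig, pos, codon[cp], alt,
                cls="intraspecific", synonymity=realised, derived=alt,
                focal_species=sp, derived_count=count,
                orf=orf_list[orf_i]["orf_id"], codon_index=ci, codon_pos=cp,
            )
            used[k] = True
            seg_hap[sp][site] = hap

    # ---- samples -------------------------------------------------------
    samples: list[SampleMeta] = []
    for sp in ingroup:
        for j in range(config.n_ind_per_species):
            samples.append(SampleMeta(f"{sp}{sp}_{j + 1}", sp * 2, 2, "sexual"))
    for j in range(config.n_ind_outgroup):
        og = config.outgroup_label
        samples.append(SampleMeta(f"{og}{og}_{j + 1}", og * 2, 2, "outgroup"))

    founder_haps = {}
    clone_members = {}
    for spec in config.clones:
        cat = spec.inferred_category()
        members = []
        for j in range(spec.n_individuals):
            sid = f"{spec.clone_id}_{j + 1}"
            samples.append(
                SampleMeta(sid, spec.genomotype, len(spec.genomotype), cat, spec.clone_id)
            )
            members.append(sid)
        clone_members[spec.clone_id] = members

    # ---- clone private mutations and LOH -------------------------------
    priv_events = {}  # sample_id -> list of (site, slot)
    truth_clones = {}
    coding_nt = config.coding_nt

    def draw_private(n_events):
        events = []
        avail = np.nonzero(~used)[0]
        if n_events > avail.size:
            raise RuntimeError("candidate site pool exhausted; lower mu or tau")
        chosen = rng.choice(avail, size=n_events, replace=False)
        for k in chosen:
            contig, pos, codon, orf_i, ci, cp = site_location(k)
            if rng.random() < config.f_priv_nonsyn:
                want = "stop_gain" if rng.random() < config.p_stop else "nonsynonymous"
            else:
                want = "synonymous"
            alt, realised = _choose_alt(codon, cp, want, rng)
            events.append((k, contig, pos, codon[cp], alt, realised,
                           orf_list[orf_i]["orf_id"], ci, cp))
            used[k] = True
        return events

    for spec in config.clones:
        mean_total = config.mu * coding_nt * spec.age_tau
        trunk_n = rng.poisson(config.trunk_fraction * mean_total)
        trunk_raw = draw_private(trunk_n)
        trunk_records = []
        for (k, contig, pos, ref_b, alt, realised, orf_id, ci, cp) in trunk_raw:
            slot = int(rng.integers(0, len(spec.genomotype)))
            site = registry.add(
                contig, pos, ref_b, alt,
                cls="private_asexual", synonymity=realised, derived=alt,
                clone=spec.clone_id, shared="trunk",
                orf=orf_id, codon_index=ci, codon_pos=cp,
            )
            trunk_records.append({"site": site, "slot": slot, "synonymity": realised})
        tip_records = {}
        for sid in clone_members[spec.clone_id]:
            tip_n = rng.poisson((1.0 - config.trunk_fraction) * mean_total)
            tips = []
            for (k, contig, pos, ref_b, alt, realised, orf_id, ci, cp) in draw_private(tip_n):
                slot = int(rng.integers(0, len(spec.genomotype)))
                site = registry.add(
                    contig, pos, ref_b, alt,
                    cls="private_asexual", synonymity=realised, derived=alt,
                    clone=spec.clone_id, shared="tip", carrier=sid,
                    orf=orf_id, codon_index=ci, codon_pos=cp,
                )
                tips.append({"site": site, "slot": slot, "synonymity": realised})
            tip_records[sid] = tips
            priv_events[sid] = [(r["site"], r["slot"]) for r in trunk_records] + [
                (r["site"], r["slot"]) for r in tips
            ]
        truth_clones[spec.clone_id] = {
            "genomotype": spec.genomotype,
            "age_tau": spec.age_tau,
            "members": clone_members[spec.clone_id],
            "trunk": trunk_records,
            "tips": tip_records,
            "n_private_per_individual": {
                sid: len(trunk_records) + len(tip_records[sid])
                for sid in clone_members[spec.clone_id]
            },
            "p_loh": 1.0 - math.exp(-config.lambda_loh * spec.age_tau),
        }

    # ---- assemble the genotype matrix ----------------------------------
    sites_df = pd.DataFrame(registry.rows, columns=["contig", "pos", "ref", "alt"])
    n_sites = len(sites_df)
    n_samp = len(samples)
    calls = np.zeros((n_sites, n_samp, 3), dtype=np.int8)

    species_pools = {}
    for sp in all_species:
        n_h = n2 if sp in ingroup else 2 * config.n_ind_outgroup
        site_list = sorted(
            set(fixed_sites_by_species[sp]) | set(seg_hap.get(sp, {}).keys())
        )
        hap = np.zeros((len(site_list), n_h), dtype=np.int8)
        for r, site in enumerate(site_list):
            if site in seg_hap.get(sp, {}):
                hap[r] = seg_hap[sp][site].astype(np.int8)
            else:
                hap[r] = 1  # fixed derived
        species_pools[sp] = {"site_idx": np.array(site_list, dtype=int), "hap": hap}

    sample_idx = {s.sample_id: i for i, s in enumerate(samples)}
    # sexual and outgroup individuals
    counters = {sp: 0 for sp in all_species}
    for s in samples:
        if s.category not in ("sexual", "outgroup"):
            continue
        sp = s.species
        j = counters[sp]
        counters[sp] += 1
        pool = species_pools[sp]
        i = sample_idx[s.sample_id]
        calls[:, i, 2] = UNUSED
        if pool["site_idx"].size:
            calls[pool["site_idx"], i, 0] = pool["hap"][:, 2 * j]
            calls[pool["site_idx"], i, 1] = pool["hap"][:, 2 * j + 1]

    # hybrids
    truth_loh = {}
    for spec in config.clones:
        p_loh = truth_clones[spec.clone_id]["p_loh"]
        for sid in clone_members[spec.clone_id]:
            i = sample_idx[sid]
            ploidy = len(spec.genomotype)
            if ploidy == 2:
                calls[:, i, 2] = UNUSED
            chosen = []
            for slot, letter in enumerate(spec.genomotype):
                pool = species_pools[letter]
                h = int(rng.integers(0, pool["hap"].shape[1]))
                chosen.append((letter, h))
                if pool["site_idx"].size:
                    calls[pool["site_idx"], i, slot] = pool["hap"][:, h]
            founder_haps[sid] = chosen
            for site, slot in priv_events.get(sid, []):
                calls[site, i, slot] = 1
            # LOH: every heterozygous site independently, prob 1 - exp(-lambda tau)
            g = calls[:, i, :ploidy]
            het_sites = np.nonzero(g.max(axis=1) != g.min(axis=1))[0]
            if p_loh > 0 and het_sites.size:
                hit = het_sites[rng.random(het_sites.size) < p_loh]
                retained = rng.integers(0, 2, size=hit.size)
                # retained allele chosen uniformly among the two present alleles
                events = []
                for site, keep01 in zip(hit, retained):
                    alleles = np.unique(g[site])
                    keep = int(alleles[keep01 % alleles.size])
                    calls[site, i, :ploidy] = keep
                    events.append({"site": int(site), "retained_allele": keep})
                truth_loh[sid] = events
            else:
                truth_loh[sid] = []

    # record whether each planted derived allele is still present anywhere
    # (LOH can erase a private mutation from its only carrier)
    emitted = (calls == 1).any(axis=(1, 2))
    for rec in registry.truth:
        rec["emitted"] = bool(emitted[rec["site"]])

    # optional missingness
    if config.missing_rate > 0:
        drop = rng.random((n_sites, n_samp)) < config.missing_rate
        for i in range(n_samp):
            idx = np.nonzero(drop[:, i])[0]
            sl = calls[idx, i, :]
            sl[sl != UNUSED] = MISSING
            calls[idx, i, :] = sl

    # ---- mtDNA ---------------------------------------------------------
    mt_anc = "".join(BASES[b] for b in rng.integers(0, 4, size=config.mt_len))
    mt_species = {}
    for sp in all_species:
        div = config.mt_species_div * (2.0 if sp == config.outgroup_label else 1.0)
        seq = np.frombuffer(mt_anc.encode(), dtype="S1").astype("U1")
        hit = np.nonzero(rng.random(config.mt_len) < div)[0]
        for p in hit:
            choices = [b for b in BASES if b != seq[p]]
            seq[p] = choices[rng.integers(0, 3)]
        mt_species[sp] = "".join(seq)
    mtdna = {}
    for s in samples:
        if s.category in ("sexual", "outgroup"):
            mtdna[s.sample_id] = mt_species[s.species]
    for spec in config.clones:
        donor = spec.genomotype[0]  # maternal ancestor: first letter
        n_sub = rng.poisson(config.mt_mu * config.mt_len * spec.age_tau)
        seq = np.frombuffer(mt_species[donor].encode(), dtype="S1").astype("U1")
        hit = rng.choice(config.mt_len, size=min(n_sub, config.mt_len), replace=False)
        for p in hit:
            choices = [b for b in BASES if b != seq[p]]
            seq[p] = choices[rng.integers(0, 3)]
        clone_mt = "".join(seq)
        for sid in clone_members[spec.clone_id]:
            mtdna[sid] = clone_mt

    # sort sites by genomic coordinate, remapping all site indices
    order = np.lexsort((sites_df["pos"].to_numpy(), sites_df["contig"].to_numpy()))
    remap = np.empty(n_sites, dtype=int)
    remap[order] = np.arange(n_sites)
    sites_df = sites_df.iloc[order].reset_index(drop=True)
    calls = calls[order]
    for rec in registry.truth:
        rec["site"] = int(remap[rec["site"]])
    for cl in truth_clones.values():
        for r in cl["trunk"]:
            r["site"] = int(remap[r["site"]])
        for tips in cl["tips"].values():
            for r in tips:
                r["site"] = int(remap[r["site"]])
    for events in truth_loh.values():
        for e in events:
            e["site"] = int(remap[e["site"]])
    for sp in species_pools:
        pool = species_pools[sp]
        if pool["site_idx"].size:
            srt = np.argsort(remap[pool["site_idx"]])
            pool["hap"] = pool["hap"][srt]
            pool["site_idx"] = remap[pool["site_idx"]][srt]

    registry.truth.sort(key=lambda r: r["site"])
    truth = {
        "sites": registry.truth,
        "clones": truth_clones,
        "loh": truth_loh,
        "founder_haplotypes": {
            sid: [[sp, h] for sp, h in v] for sid, v in founder_haps.items()
        },
        "config": {
            k: (list(v) if isinstance(v, tuple) and k != "clones" else v)
            for k, v in asdict(config).items()
        },
        "coding_nt": coding_nt,
    }

    table = GenotypeTable(sites_df, calls, samples)
    return SimResult(
        config=config,
        reference=reference,
        orfs=orfs,
        genotypes=table,
        mtdna=mtdna,
        truth=truth,
        species_pools=species_pools,
        founder_haps=founder_haps,
    )


def haplotype_sequence(sim: SimResult, species: str, hap_index: int, orf_id: str) -> str:
    """Nucleotide sequence of one parental haplotype over one ORF (incl. stop)."""
    rec = sim.orfs.loc[sim.orfs["orf_id"] == orf_id].iloc[0]
    seq = list(sim.reference[rec["contig"]][rec["start"] : rec["end"]])
    pool = sim.species_pools[species]
    sites = sim.genotypes.sites
    for r, site in enumerate(pool["site_idx"]):
        if pool["hap"][r, hap_index]:
            row = sites.iloc[site]
            if row["contig"] == rec["contig"] and rec["start"] <= row["pos"] < rec["end"]:
                seq[row["pos"] - rec["start"]] = row["alt"]
    return "".join(seq)


def write_outputs(sim: SimResult, out_dir) -> dict:
    """Write VCF + FASTA + BED + sample TSV + mtDNA FASTA + truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "fasta": out / "reference.fasta",
        "bed": out / "orfs.bed",
        "samples": out / "samples.tsv",
        "mtdna": out / "mtdna.fasta",
        "truth": out / "truth.json",
    }
    write_vcf(sim.genotypes, paths["vcf"], reference=sim.reference)
    write_fasta(sim.reference, paths["fasta"])
    write_bed(sim.orfs, paths["bed"])
    write_sample_tsv(sim.genotypes.samples, paths["samples"])
    write_fasta(sim.mtdna, paths["mtdna"])
    write_truth_json(sim.truth, paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def validate_truth_coverage(sim: SimResult) -> None:
    """Assert every emitted alternative allele has exactly one truth record."""
    truth_sites = [rec["site"] for rec in sim.truth["sites"]]
    if len(truth_sites) != len(set(truth_sites)):
        raise AssertionError("duplicate truth records")
    emitted = set(np.nonzero((sim.genotypes.calls == 1).any(axis=(1, 2)))[0].tolist())
    missing = emitted - set(truth_sites)
    if missing:
        raise AssertionError(f"{len(missing)} emitted alt alleles lack truth records")


# ---------------------------------------------------------------------------
# Phenotype simulator
# ---------------------------------------------------------------------------

_BASE_TRAITS = {
    # trait: (mean, lognormal sigma).  Sizes in mm, masses in g — a plausible
    # adult spined-loach female.
    "SL": (90.0, 0.08),
    "Wt_factor": (7e-6, 0.10),  # Wt = Wt_factor * SL^3
    "We_frac": (0.85, 0.04),    # eviscerated fraction of Wt
    "heart_g_frac": (0.008, 0.20),
    "gonad_g_frac": (0.080, 0.25),
    "liver_g_frac": (0.015, 0.20),
    "spleen_g_frac": (0.003, 0.25),
    "vertebra_frac": (0.012, 0.05),  # vertebra size relative to SL
    "oocyte_per_g": (300.0, 0.30),
    "oocyte_diam": (0.80, 0.15),
    "clutch_mean": (300.0, 0.0),
    "survival_p": (0.5, 0.0),
}


def simulate_phenotypes(
    group_specs: dict | None = None,
    n_per_group: int = 40,
    seed: int = 0,
    n_oocytes: int = 60,
    n_clutches: int = 2,
):
    """Simulate a grouped phenotype table with lognormal noise.

    ``group_specs`` maps group label -> {trait: multiplier}; omitted traits get
    multiplier 1.  Returns ``(traits_df, oocytes_df, annuli_df, truth)`` where
    truth records the planted multipliers.
    """
    if group_specs is None:
        group_specs = {"old_clone": {}, "young_clone": {}}
    for label, spec in group_specs.items():
        unknown = set(spec) - set(_BASE_TRAITS)
        if unknown:
            raise ValueError(f"unknown traits in group {label!r}: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows, oocyte_rows, annuli_rows = [], [], []
    for label, spec in group_specs.items():
        for j in range(n_per_group):
            fid = f"{label}_{j + 1}"
            site = "siteA" if j % 2 == 0 else "siteB"
            season = "spring" if j < n_per_group / 2 else "autumn"

            def draw(trait):
                mean, sig = _BASE_TRAITS[trait]
                if sig <= 0:
                    val = mean
                else:
                    val = mean * rng.lognormal(-0.5 * sig**2, sig)
                return val * spec.get(trait, 1.0)

            SL = draw("SL")
            Wt = draw("Wt_factor") * SL**3
            We = draw("We_frac") * Wt
            heart = draw("heart_g_frac") * Wt
            gonad = draw("gonad_g_frac") * Wt
            liver = draw("liver_g_frac") * Wt
            spleen = draw("spleen_g_frac") * Wt
            vert = draw("vertebra_frac") * SL
            n_ann = int(rng.integers(2, 6))
            R = 0.015 * SL
            k_growth = 0.45
            radii = R * (1.0 - np.exp(-k_growth * np.arange(1, n_ann + 1))) / (
                1.0 - np.exp(-k_growth * (n_ann + 0.5))
            )
            count = max(int(round(draw("oocyte_per_g") * Wt)), 1)
            mean_d, sig_d = _BASE_TRAITS["oocyte_diam"]
            diam = (
                mean_d
                * spec.get("oocyte_diam", 1.0)
                * rng.lognormal(-0.5 * sig_d**2, sig_d, size=n_oocytes)
            )
            clutch_mu = draw("clutch_mean")
            surv_p = min(draw("survival_p"), 1.0)
            clutches = rng.poisson(clutch_mu, size=n_clutches)
            clutches = np.maximum(clutches, 1)
            survived = rng.binomial(clutches, surv_p)

            rows.append(
                {
                    "fish_id": fid, "group": label, "site": site, "season": season,
                    "SL": SL, "Wt": Wt, "We": We,
                    "heart_g": heart, "gonad_g": gonad,
                    "liver_g": liver, "spleen_g": spleen,
                    "vertebra_mm": vert, "vertebra_radius": R,
                    "n_annuli": n_ann, "oocyte_count": count,
                    "clutch_sizes": ";".join(str(int(c)) for c in clutches),
                    "survived": ";".join(str(int(s)) for s in survived),
                }
            )
            oocyte_rows.extend(
                {"fish_id": fid, "group": label, "season": season, "diameter": d}
                for d in diam
            )
            annuli_rows.extend(
                {"fish_id": fid, "group": label, "annulus": i + 1, "radius": r}
                for i, r in enumerate(radii)
            )
    truth = {"group_specs": group_specs, "n_per_group": n_per_group, "seed": seed}
    return (
        pd.DataFrame(rows),
        pd.DataFrame(oocyte_rows),
        pd.DataFrame(annuli_rows),
        truth,
    )
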