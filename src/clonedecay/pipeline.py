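"""End-to-end orchestration: classify -> spectra -> radicality -> dN/dS ->
LOH -> group tests, with a machine-readable JSON report.

``run_full`` is a pure function of its inputs and configuration: one seed
governs every stochastic step (pseudo-haplotype sampling, permutation tests),
so repeated runs produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import SiteClassification, classify_dataset
from .codon import nearest_sexual_distance, radicality_score
from .data import Dataset, read_bed, read_fasta, read_sample_tsv, read_vcf
from .dnds import eligible_orfs, simulated_hybrid_null, within_individual_dnds
from .spectra import (
    call_loh,
    fit_loh_vs_private,
    heterozygosity,
    homozygous_private_fraction,
    private_snp_proportion,
    site_frequency_spectrum,
    syn_class,
)
from .stats import binomial_lrt, pearson_ci, permutation_test, welch_t

__all__ = ["RunConfig", "load_dataset", "run_full"]


@dataclass
class RunConfig:
    """Inputs and knobs of a full analysis run."""

    vcf: str
    reference_fasta: str
    orf_bed: str
    sample_tsv: str
    mtdna_fasta: str | None = None
    out_dir: str = "clonedecay_out"
    min_called_fraction: float = 0.8
    min_codons: int = 50
    dnds_constant: float = 0.01
    max_null_orfs: int = 20
    n_perm: int = 999
    seed: int = 0

    def validate(self) -> None:
        for name in ("vcf", "reference_fasta", "orf_bed", "sample_tsv"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        if self.mtdna_fasta and not Path(self.mtdna_fasta).exists():
            raise FileNotFoundError(f"mtdna_fasta: {self.mtdna_fasta}")


def load_dataset(config: RunConfig) -> Dataset:
    config.validate()
    samples = read_sample_tsv(config.sample_tsv)
    return Dataset(
        reference=read_fasta(config.reference_fasta),
        orfs=read_bed(config.orf_bed),
        genotypes=read_vcf(config.vcf, samples),
        mtdna=read_fasta(config.mtdna_fasta) if config.mtdna_fasta else None,
    )


def _category_counts(cls: SiteClassification) -> dict:
    f = cls.frame
    out = {}
    for cat in ("intraspecific", "interspecific_fixed", "private_asexual", "unclassified"):
        sub = f[f["category"] == cat]
        sc = syn_class(sub["synonymity"])
        out[cat] = {
            "n_sites": int(len(sub)),
            "synonymous": int((sc == "synonymous").sum()),
            "nonsynonymous": int((sc == "nonsynonymous").sum()),
            "stop_gain": int((sub["synonymity"] == "stop_gain").sum()),
            "masked": int((sub["synonymity"] == "masked").sum()),
        }
    return out


def _radicality(cls: SiteClassification, matrix: str) -> dict:
    f = cls.frame
    out = {}
    for cat in ("intraspecific", "interspecific_fixed", "private_asexual"):
        sub = f[(f["category"] == cat) & (f["synonymity"] == "nonsynonymous")]
        scores = [
            radicality_score(r["aa_ref"], r["aa_alt"], matrix)
            for _, r in sub.iterrows()
            if r["aa_ref"] and r["aa_alt"] and r["aa_ref"] != r["aa_alt"]
        ]
        out[cat] = {
            "n": len(scores),
            "mean_score": float(np.mean(scores)) if scores else None,
            "scores": scores,
        }
    return out


def run_full(config: RunConfig, dataset: Dataset | None = None) -> dict:
    """Execute the full analysis and write ``report.json`` to the output dir."""
    if dataset is None:
        dataset = load_dataset(config)
    rng = np.random.default_rng(config.seed)
    report: dict = {
        "provenance": {
            "package": "clonedecay",
            "version": __version__,
            "seed": config.seed,
            "config": asdict(config),
        }
    }

    cls = classify_dataset(dataset, min_called_fraction=config.min_called_fraction)
    report["filtering"] = cls.log
    report["categories"] = _category_counts(cls)

    samples = cls.table.samples
    sexual = {sp: [s.sample_id for s in samples
                   if s.category == "sexual" and s.species == sp]
              for sp in ("E", "T", "N")}
    hybrids = [s for s in samples if s.is_hybrid]

    # --- site frequency spectra per species, syn vs nonsyn ---------------
    sfs = {}
    for sp, ids in sexual.items():
        entry = {}
        freqs = {}
        for syn in ("synonymous", "nonsynonymous"):
            spec = site_frequency_spectrum(
                cls, ids, category="intraspecific", synonymity=syn,
                focal_species=sp, population_label=sp,
            )
            entry[syn] = {
                "counts": {str(k): v for k, v in sorted(spec.counts.items())},
                "n_sites": spec.n_sites,
                "mean_derived_frequency": spec.mean_derived_frequency(),
            }
            ps = spec.per_site
            freqs[syn] = (ps["derived_count"] / ps["called_chromosomes"]).to_numpy()
        if freqs["synonymous"].size and freqs["nonsynonymous"].size:
            vals = np.concatenate([freqs["nonsynonymous"], freqs["synonymous"]])
            labs = np.array(
                ["nonsyn"] * freqs["nonsynonymous"].size
                + ["syn"] * freqs["synonymous"].size
            )
            test = permutation_test(
                vals, labs,
                statistic_fn=lambda a, b: float(np.mean(b) - np.mean(a)),
                n_perm=config.n_perm, seed=int(rng.integers(2**31)),
            )
            entry["nonsyn_rarer_p"] = test.p_value
        sfs[sp] = entry
    report["sfs"] = sfs

    # --- N/S contrast between SNP categories -----------------------------
    f = cls.frame
    sc = syn_class(f["synonymity"])
    cats, ks, ns = [], [], []
    for cat in ("intraspecific", "interspecific_fixed", "private_asexual"):
        sel = (f["category"] == cat).to_numpy()
        nonsyn = int(((sc == "nonsynonymous") & sel).sum())
        total = int((((sc == "nonsynonymous") | (sc == "synonymous")) & sel).sum())
        if total:
            cats.append(cat)
            ks.append(nonsyn)
            ns.append(total)
    if len(cats) >= 2:
        lrt = binomial_lrt(ks, ns, cats)
        report["ns_ratio_lrt"] = {"statistic": lrt.statistic, "df": lrt.df,
                                  "p_value": lrt.p_value, "proportions": lrt.extra}

    # --- radicality -------------------------------------------------------
    report["radicality"] = {m: _radicality(cls, m) for m in ("PAM100", "BLOSUM90")}

    # --- dN/dS ------------------------------------------------------------
    hybrid_ids = [s.sample_id for s in hybrids]
    dnds_report: dict = {}
    if hybrid_ids:
        orfs_ok = eligible_orfs(dataset, cls, hybrid_ids, config.min_codons)
        per_hybrid = {}
        for s in hybrids:
            ratios = []
            for orf_id in orfs_ok:
                est = within_individual_dnds(
                    dataset, cls, s.sample_id, orf_id, c=config.dnds_constant
                )
                if est.valid:
                    ratios.append(est.ratio)
            per_hybrid[s.sample_id] = {
                "n_orfs": len(ratios),
                "mean_ratio": float(np.mean(ratios)) if ratios else None,
            }
        dnds_report["within_hybrids"] = per_hybrid
        dnds_report["n_eligible_orfs"] = len(orfs_ok)
        for pair in (("E", "T"), ("E", "N")):
            if sexual[pair[0]] and sexual[pair[1]]:
                null = simulated_hybrid_null(
                    dataset, cls, pair[0], pair[1],
                    orf_ids=orfs_ok[: config.max_null_orfs],
                    c=config.dnds_constant, seed=int(rng.integers(2**31)),
                )
                ok = null.frame[null.frame["valid"]]
                dnds_report[f"null_{pair[0]}x{pair[1]}"] = {
                    "n": int(len(ok)),
                    "mean_ratio": float(ok["ratio"].mean()) if len(ok) else None,
                }
    report["dnds"] = dnds_report

    # --- heterozygosity, LOH, private SNPs, age correlations -------------
    het = {s.sample_id: heterozygosity(cls.table, s.sample_id) for s in samples}
    report["heterozygosity"] = het
    sex_het = [het[s.sample_id] for s in samples if s.category == "sexual"]
    hyb_het = [het[s.sample_id] for s in hybrids]
    if sex_het and hyb_het:
        report["het_hybrid_vs_sexual"] = asdict(welch_t(hyb_het, sex_het))

    loh_rows = []
    sexual_mts = {}
    if dataset.mtdna:
        sexual_mts = {
            s.sample_id: dataset.mtdna[s.sample_id]
            for s in samples
            if s.category == "sexual" and s.sample_id in dataset.mtdna
        }
    for s in hybrids:
        profile = call_loh(cls, s)
        row = {
            "sample_id": s.sample_id,
            "clone_id": s.clone_id,
            "ploidy": s.ploidy,
            "informative_sites": profile.informative_sites,
            "loh_sites": profile.loh_sites,
            "loh_proportion": profile.proportion,
            "retained": profile.retained,
            "private_proportion": private_snp_proportion(cls, s.sample_id),
            "homozygous_private_fraction": homozygous_private_fraction(
                cls, s.sample_id
            ),
        }
        if sexual_mts and dataset.mtdna and s.sample_id in dataset.mtdna:
            _, d = nearest_sexual_distance(dataset.mtdna[s.sample_id], sexual_mts)
            row["mt_k2p_nearest_sexual"] = d
        loh_rows.append(row)
    report["loh"] = loh_rows

    lf = pd.DataFrame(loh_rows)
    if len(lf) >= 3:
        try:
            if "mt_k2p_nearest_sexual" in lf:
                r = pearson_ci(lf["mt_k2p_nearest_sexual"], lf["loh_proportion"])
                report["loh_vs_mtdist"] = {"r": r.estimate, "ci": [r.ci_low, r.ci_high],
                                           "p_value": r.p_value}
            r2 = pearson_ci(lf["private_proportion"], lf["loh_proportion"])
            report["loh_vs_private"] = {"r": r2.estimate, "ci": [r2.ci_low, r2.ci_high],
                                        "p_value": r2.p_value}
        except ValueError:
            pass
    dip = lf[lf["ploidy"] == 2] if len(lf) else lf
    if len(dip) >= 4:
        g, fq = fit_loh_vs_private(
            dip["private_proportion"], dip["loh_proportion"]
        )
        report["loh_quadratic"] = {"unconstrained": asdict(g), "constrained": asdict(fq)}

    report["provenance"]["config_hash"] = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]
    report = _sanitize(report)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = json.dumps(report, sort_keys=True, indent=1, allow_nan=False)
    (out / "report.json").write_text(payload)
    return report


def _sanitize(obj):
    """Make the report strictly JSON: numpy scalars to Python, NaN to null."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_sanitize(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer, int)) and not isinstance(obj, bool):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if (v != v or v in (float("inf"), float("-inf"))) else v
    return obj
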