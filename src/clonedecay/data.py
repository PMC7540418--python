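"""In-memory containers and file I/O for the hybrid-complex data model.

The central object is :class:`GenotypeTable`: a site table (contig, 0-based
position, ref, alt) plus a ploidy-aware call array of shape
``(n_sites, n_samples, 3)`` holding allele indices (0 = ref, 1 = alt),
``MISSING`` (-1) for uncalled genotypes and ``UNUSED`` (-9) for the third slot
of diploid samples.  Coordinates are 0-based half-open internally and 1-based
in VCF, the standard dialects of each format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = -1
UNUSED = -9

SEXUAL_SPECIES = ("E", "T", "N")
OUTGROUP = "L"

CATEGORIES = ("sexual", "outgroup", "F1", "young_clone", "old_clone")


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: genomotype string over {E,T,N,L}, ploidy, role."""

    sample_id: str
    genomotype: str
    ploidy: int
    category: str
    clone_id: str | None = None

    def __post_init__(self):
        if self.ploidy not in (2, 3):
            raise ValueError(f"ploidy must be 2 or 3, got {self.ploidy}")
        if len(self.genomotype) != self.ploidy:
            raise ValueError(
                f"genomotype {self.genomotype!r} inconsistent with ploidy {self.ploidy}"
            )
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        letters = set(self.genomotype)
        if self.category in ("sexual", "outgroup") and len(letters) != 1:
            raise ValueError("sexual/outgroup samples must be homotypic")
        if self.category in ("F1", "young_clone", "old_clone") and len(letters) < 2:
            raise ValueError("hybrid samples must be heterotypic")

    @property
    def is_hybrid(self) -> bool:
        return self.category in ("F1", "young_clone", "old_clone")

    @property
    def species(self) -> str | None:
        """Species letter for homotypic (sexual/outgroup) samples, else None."""
        letters = set(self.genomotype)
        return next(iter(letters)) if len(letters) == 1 else None


class GenotypeTable:
    """Biallelic SNP calls for a cohort, ploidy-aware with missing markers."""

    def __init__(self, sites: pd.DataFrame, calls: np.ndarray, samples: list[SampleMeta]):
        sites = sites.reset_index(drop=True)
        required = {"contig", "pos", "ref", "alt"}
        if not required.issubset(sites.columns):
            raise ValueError(f"sites must have columns {sorted(required)}")
        if calls.shape != (len(sites), len(samples), 3):
            raise ValueError(
                f"calls shape {calls.shape} != ({len(sites)}, {len(samples)}, 3)"
            )
        self.sites = sites
        self.calls = np.asarray(calls, dtype=np.int8)
        self.samples = list(samples)
        self.sample_ids = [s.sample_id for s in samples]
        self._sample_index = {s.sample_id: i for i, s in enumerate(samples)}

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def subset_sites(self, mask: np.ndarray) -> "GenotypeTable":
        mask = np.asarray(mask)
        return GenotypeTable(self.sites.loc[mask], self.calls[mask], self.samples)

    def called(self) -> np.ndarray:
        """Boolean (n_sites, n_samples): genotype fully called."""
        c = self.calls
        slot_ok = (c >= 0) | (c == UNUSED)
        any_missing = (c == MISSING).any(axis=2)
        return slot_ok.all(axis=2) & ~any_missing

    def allele_multisets(self, site_idx: int, sample_idx: int) -> tuple | None:
        """Sorted allele tuple for one genotype, or None if missing."""
        g = self.calls[site_idx, sample_idx]
        g = g[g != UNUSED]
        if (g == MISSING).any():
            return None
        return tuple(sorted(int(a) for a in g))

    def heterozygous(self) -> np.ndarray:
        """Boolean (n_sites, n_samples): called and carrying >= 2 distinct alleles."""
        c = self.calls
        valid = self.called()
        a = np.where(c == UNUSED, c[:, :, :1], c)  # fill unused slot with first allele
        het = (a.max(axis=2) != a.min(axis=2))
        return valid & het

    def allele_counts_by_samples(self, sample_idx: np.ndarray) -> np.ndarray:
        """(n_sites, 2) counts of ref/alt alleles over the given samples."""
        c = self.calls[:, sample_idx, :]
        n0 = (c == 0).sum(axis=(1, 2))
        n1 = (c == 1).sum(axis=(1, 2))
        return np.stack([n0, n1], axis=1)


@dataclass
class Dataset:
    """Reference sequences, ORF annotations, genotypes and optional mtDNA."""

    reference: dict[str, str]
    orfs: pd.DataFrame  # orf_id, contig, start, end (0-based half-open, incl. stop codon)
    genotypes: GenotypeTable
    mtdna: dict[str, str] | None = None

    @property
    def samples(self) -> list[SampleMeta]:
        return self.genotypes.samples


# ---------------------------------------------------------------------------
# Writers (plain-text standard formats)
# ---------------------------------------------------------------------------

def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(orfs: pd.DataFrame, path) -> None:
    """BED6 with ORF coordinates (0-based half-open, forward strand)."""
    out = pd.DataFrame(
        {
            "chrom": orfs["contig"],
            "start": orfs["start"].astype(int),
            "end": orfs["end"].astype(int),
            "name": orfs["orf_id"],
            "score": 0,
            "strand": "+",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["contig", "start", "end", "orf_id", "score", "strand"],
        usecols=range(6),
    )
    return bed[["orf_id", "contig", "start", "end"]]


def write_sample_tsv(samples: list[SampleMeta], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "genomotype": [s.genomotype for s in samples],
            "ploidy": [s.ploidy for s in samples],
            "category": [s.category for s in samples],
            "clone_id": [s.clone_id if s.clone_id else "NA" for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_sample_tsv(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        clone = row["clone_id"]
        out.append(
            SampleMeta(
                sample_id=row["sample_id"],
                genomotype=row["genomotype"],
                ploidy=int(row["ploidy"]),
                category=row["category"],
                clone_id=None if (pd.isna(clone) or clone == "NA") else clone,
            )
        )
    return out


def write_vcf(table: GenotypeTable, path, reference: dict[str, str] | None = None) -> None:
    """Write a minimal VCF 4.2 (GT only), 1-based positions, ploidy-aware GT."""
    lines = ["##fileformat=VCFv4.2", "##source=clonedecay"]
    contigs = pd.unique(table.sites["contig"])
    for contig in contigs:
        if reference is not None and contig in reference:
            lines.append(f"##contig=<ID={contig},length={len(reference[contig])}>")
        else:
            lines.append(f"##contig=<ID={contig}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += table.sample_ids
    lines.append("\t".join(header))

    calls = table.calls
    for i, row in enumerate(table.sites.itertuples(index=False)):
        fields = [row.contig, str(int(row.pos) + 1), ".", row.ref, row.alt,
                  ".", ".", ".", "GT"]
        for j in range(table.n_samples):
            g = calls[i, j]
            g = g[g != UNUSED]
            if (g == MISSING).any():
                gt = "/".join(["."] * len(g))
            else:
                gt = "/".join(str(int(a)) for a in g)
            fields.append(gt)
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path, samples: list[SampleMeta]) -> GenotypeTable:
    """Read a GT-only VCF into a :class:`GenotypeTable` via pysam.

    Multi-allelic records are kept (alt as comma string) so that the biallelic
    filter downstream can count and remove them.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    vcf_samples = list(vf.header.samples)
    meta_by_id = {s.sample_id: s for s in samples}
    ordered = [meta_by_id[sid] for sid in vcf_samples]

    site_rows = []
    call_rows = []
    for rec in vf:
        alts = rec.alts or ()
        site_rows.append(
            {
                "contig": rec.chrom,
                "pos": rec.pos - 1,
                "ref": rec.ref,
                "alt": ",".join(alts) if alts else ".",
                "n_alt": len(alts),
            }
        )
        row = np.full((len(ordered), 3), UNUSED, dtype=np.int8)
        for j, sid in enumerate(vcf_samples):
            gt = rec.samples[sid]["GT"]
            for k, a in enumerate(gt):
                row[j, k] = MISSING if a is None else a
        call_rows.append(row)
    vf.close()

    sites = pd.DataFrame(site_rows)
    calls = (
        np.stack(call_rows)
        if call_rows
        else np.empty((0, len(ordered), 3), dtype=np.int8)
    )
    return GenotypeTable(sites, calls, ordered)


def write_truth_json(truth, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
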