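"""Codon-level molecular evolution metrics.

Implements the Nei–Gojobori (1986) pathway method for counting synonymous and
nonsynonymous sites and differences, the Jukes–Cantor multiple-hit correction,
pairwise dN/dS with a small-constant-stabilised ratio, the Kimura two-parameter
(K2P) nucleotide distance, and amino-acid "radicality" scoring against the
canonical PAM100 / BLOSUM90 substitution matrices.

Conventions
-----------
* Site counts: at each codon position the three possible single-nucleotide
  changes are classified as synonymous or nonsynonymous; changes that create a
  stop codon count as nonsynonymous (the classic NG86 treatment, as in the
  bioperl/Biopython implementations), so every sense codon contributes
  n + s = 3 sites.
* Pathway differences: between two codons differing at d positions, all d!
  orderings of the single-step changes are enumerated; pathways passing through
  a stop codon are discarded and the synonymous / nonsynonymous step counts are
  averaged over the remaining pathways.  If every pathway is blocked, the
  average is taken over all pathways (steps into/out of stops counted as
  nonsynonymous) so that Nd + Sd always equals the positional Hamming distance.
* dN/dS ratio: a pseudo-constant c (default 0.01) is added to both dN and dS
  before forming the ratio, so identical sequences give exactly 1.0 and ratios
  stay finite when either class of change is absent.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "BASES",
    "SENSE_CODONS",
    "STOP_CODONS",
    "translate_codon",
    "SaturationError",
    "SiteCounts",
    "DnDsEstimate",
    "K2PDistance",
    "ng86_site_counts",
    "ng86_pathway_counts",
    "jukes_cantor",
    "pairwise_dnds",
    "dnds_from_codon_variants",
    "k2p_distance",
    "nearest_sexual_distance",
    "radicality_score",
]

BASES = "ACGT"

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS = tuple(sorted(_STANDARD.forward_table))
_AA = dict(_STANDARD.forward_table)
for _c in STOP_CODONS:
    _AA[_c] = "*"

_PURINES = frozenset("AG")


def translate_codon(codon: str) -> str:
    """Translate a codon with the standard genetic code; stops give ``'*'``."""
    try:
        return _AA[codon.upper()]
    except KeyError:
        raise ValueError(f"not an unambiguous codon: {codon!r}") from None


class SaturationError(ValueError):
    """Raised when an observed difference proportion exceeds the model's domain."""


@dataclass(frozen=True)
class SiteCounts:
    """Synonymous (S) and nonsynonymous (N) site counts for a codon sequence."""

    N: float
    S: float


@dataclass
class DnDsEstimate:
    """Pairwise dN/dS under NG86 counting with Jukes–Cantor correction."""

    Nd: float
    Sd: float
    N: float
    S: float
    pN: float
    pS: float
    dN: float
    dS: float
    c: float
    ratio: float
    n_codons: int
    valid: bool = True


@dataclass(frozen=True)
class K2PDistance:
    """Kimura two-parameter distance with its transition/transversion parts."""

    P: float
    Q: float
    d: float
    n_sites: int


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Return (n, s): nonsynonymous and synonymous site counts of one codon.

    Each of the nine single-nucleotide neighbours contributes 1/3 of a site to
    the class of its amino-acid effect.  Changes creating stop codons count as
    nonsynonymous, the classic NG86 treatment shared by the bioperl and
    Biopython implementations, so n + s = 3 for every sense codon.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon has no site counts: {codon}")
    aa = translate_codon(codon)
    n = s = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in STOP_CODONS and translate_codon(alt) == aa:
                s += 1.0 / 3.0
            else:
                n += 1.0 / 3.0
    return n, s


def _step_is_synonymous(codon_a: str, codon_b: str) -> bool:
    return translate_codon(codon_a) == translate_codon(codon_b)


@lru_cache(maxsize=None)
def ng86_pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (Nd, Sd) between two sense codons.

    Averages synonymous / nonsynonymous step counts over all orderings of the
    differing positions, skipping pathways that pass through a stop codon.
    Nd + Sd always equals the number of differing positions.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    if codon_a in STOP_CODONS or codon_b in STOP_CODONS:
        raise ValueError("pathway counts are defined for sense codons only")
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0

    open_paths: list[tuple[float, float]] = []
    all_paths: list[tuple[float, float]] = []
    for order in itertools.permutations(diff):
        cur = codon_a
        nd = sd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != codon_b:
                blocked = True
            if _step_is_synonymous(cur, nxt):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        all_paths.append((nd, sd))
        if not blocked:
            open_paths.append((nd, sd))

    paths = open_paths if open_paths else all_paths
    nd = sum(p[0] for p in paths) / len(paths)
    sd = sum(p[1] for p in paths) / len(paths)
    return nd, sd


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor distance d = -(3/4) ln(1 - (4/3) p).

    Raises :class:`SaturationError` for p >= 3/4 where the correction diverges.
    """
    if p < 0:
        raise ValueError(f"proportion must be non-negative, got {p}")
    if p >= 0.75:
        raise SaturationError(f"p = {p} >= 3/4: Jukes–Cantor correction saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _codon_usable(codon: str) -> bool:
    return (
        len(codon) == 3
        and all(b in BASES for b in codon)
        and codon not in STOP_CODONS
    )


def dnds_from_codon_variants(
    variants: list,
    c: float = 0.01,
) -> DnDsEstimate:
    """dN/dS from a per-codon list of variants.

    Each element of ``variants`` is either a single codon string (homozygous,
    contributes sites only), a pair ``(codon_a, codon_b)`` of distinct codon
    variants (contributes pathway differences plus the average of the two
    variants' sites), or ``None`` (masked/missing, skipped).  This is the
    common core of both between-sequence and within-individual estimates.
    """
    N_a = S_a = N_b = S_b = 0.0
    Nd = Sd = 0.0
    used = 0
    for item in variants:
        if item is None:
            continue
        if isinstance(item, str):
            ca = cb = item
        else:
            ca, cb = item
        if not (_codon_usable(ca) and _codon_usable(cb)):
            continue
        na, sa = ng86_site_counts(ca)
        nb, sb = ng86_site_counts(cb)
        N_a += na
        S_a += sa
        N_b += nb
        S_b += sb
        if ca != cb:
            nd, sd = ng86_pathway_counts(ca, cb)
            Nd += nd
            Sd += sd
        used += 1

    if used == 0:
        return DnDsEstimate(
            Nd=math.nan, Sd=math.nan, N=math.nan, S=math.nan,
            pN=math.nan, pS=math.nan, dN=math.nan, dS=math.nan,
            c=c, ratio=math.nan, n_codons=0, valid=False,
        )

    N = 0.5 * (N_a + N_b)
    S = 0.5 * (S_a + S_b)
    pN = Nd / N if N > 0 else 0.0
    pS = Sd / S if S > 0 else 0.0
    dN = jukes_cantor(pN)
    dS = jukes_cantor(pS)
    ratio = (dN + c) / (dS + c)
    return DnDsEstimate(
        Nd=Nd, Sd=Sd, N=N, S=S, pN=pN, pS=pS, dN=dN, dS=dS,
        c=c, ratio=ratio, n_codons=used, valid=True,
    )


def pairwise_dnds(
    seq_a: str,
    seq_b: str,
    c: float = 0.01,
    skip_codons=(),
) -> DnDsEstimate:
    """NG86 + Jukes–Cantor dN/dS between two aligned coding sequences.

    Sequences must have equal length divisible by 3.  Codons listed in
    ``skip_codons`` (0-based codon indices) or containing ambiguous bases or
    stops in either sequence are skipped in both.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    if len(seq_a) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    skip = set(skip_codons)
    variants = []
    for i in range(len(seq_a) // 3):
        if i in skip:
            variants.append(None)
            continue
        ca = seq_a[3 * i : 3 * i + 3]
        cb = seq_b[3 * i : 3 * i + 3]
        if not (_codon_usable(ca) and _codon_usable(cb)):
            variants.append(None)
            continue
        variants.append(ca if ca == cb else (ca, cb))
    return dnds_from_codon_variants(variants, c=c)


def k2p_distance(seq_a: str, seq_b: str) -> K2PDistance:
    """Kimura two-parameter distance between two aligned sequences.

    Sites where either sequence carries a non-ACGT symbol are skipped pairwise.
    Raises :class:`SaturationError` when the log arguments are non-positive.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    n = ts = tv = 0
    for a, b in zip(seq_a, seq_b):
        if a not in BASES or b not in BASES:
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable sites")
    P = ts / n
    Q = tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P saturated: P={P:.4f}, Q={Q:.4f}")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PDistance(P=P, Q=Q, d=d, n_sites=n)


def nearest_sexual_distance(hybrid_mt: str, sexual_mts: dict) -> tuple[str, float]:
    """Minimum K2P distance from a hybrid mtDNA haplotype to any sexual one.

    Returns ``(sexual_id, distance)`` for the closest sexual haplotype.
    """
    if not sexual_mts:
        raise ValueError("no sexual haplotypes supplied")
    best_id, best_d = None, math.inf
    for sid, seq in sexual_mts.items():
        d = k2p_distance(hybrid_mt, seq).d
        if d < best_d:
            best_id, best_d = sid, d
    return best_id, best_d


# ---------------------------------------------------------------------------
# Radicality scoring
# ---------------------------------------------------------------------------

_MATRICES: dict[str, object] = {}


def _load_matrix(name: str):
    """Load a canonical amino-acid substitution matrix (PAM100 or BLOSUM90)."""
    key = name.upper()
    if key not in _MATRICES:
        from biotite.sequence.align import SubstitutionMatrix
        from biotite.sequence import ProteinSequence

        alph = ProteinSequence.alphabet
        _MATRICES[key] = SubstitutionMatrix(alph, alph, key)
    return _MATRICES[key]


def radicality_score(aa_from: str, aa_to: str, matrix: str = "PAM100") -> int:
    """Substitution-matrix score of an amino-acid replacement.

    Lower scores mean more radical (biochemically dissimilar) changes.  The
    lookup is symmetric.  Stop symbols are rejected: premature stop codons are
    tallied separately from radicality.
    """
    aa_from, aa_to = aa_from.upper(), aa_to.upper()
    standard = set("ACDEFGHIKLMNPQRSTVWY")
    if aa_from not in standard or aa_to not in standard:
        raise ValueError(
            f"radicality is defined for standard amino acids, got {aa_from}->{aa_to}"
        )
    if aa_from == aa_to:
        raise ValueError("radicality requires a replacement (aa_from != aa_to)")
    mat = _load_matrix(matrix)
    return int(mat.get_score(aa_from, aa_to))
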