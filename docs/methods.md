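# Methods

This document records the model behind the synthetic generator, the
conventions used by the estimators, and the numerical choices that are not
obvious from the code.

## 1. Synthetic hybrid complex (`clonedecay.synthetic`)

The generator produces a stylised sexual–asexual complex: three sexual
species (E, T, N), a divergent outgroup (L) and gynogenetic hybrid clones
whose genomes are diploid or triploid combinations of parental haploid
genomes (genomotypes such as `ET`, `EN`, `EEN`). Every emitted variant site
carries a truth record (class, synonymity, derived allele, whether it
survived LOH and missingness), so recovery can be checked exactly.

**Reference and ORFs.** Each of `n_orfs` contigs holds one forward-strand ORF
of `orf_len_codons` codons (ATG … sense codons … stop) with `flank_nt`
noncoding flanks. The start codon, the final sense codon and the stop codon
are never mutated, so all planted variants are in unambiguous coding context.

**Site classes are disjoint by construction.** Fixed interspecific
differences, intraspecific polymorphisms and clone-private mutations occupy
distinct coding positions. This is a deliberate simplification: it gives each
alternative allele exactly one truth record and makes classification recovery
a clean measurement rather than an exercise in tie-breaking.

* *Fixed differences*: each eligible site becomes derived in a given sexual
  species with probability `d_fix / 2` (outgroup: `d_fix`), all derived
  species sharing one alternative allele; a pair of species then differs at a
  site with probability ≈ `d_fix`. A fraction `f_inter_nonsyn` is forced
  nonsynonymous.
* *Intraspecific polymorphism*: density `theta` per site per species. Derived
  allele counts i ∈ {1, …, 2n−1} are drawn with weight i^(−1−a), where
  a = `sel_shift` for nonsynonymous sites and a = 0 for synonymous ones — a
  stylised rendering of purifying selection keeping amino-acid variants rare.
  `sample_frequency_classes` exposes this sampler directly; the SFS-rarity
  permutation test must detect a = 2 and stay calibrated at a = 0.
* *Private mutations*: each clone lineage member receives
  Poisson(`mu` × coding_nt × `age_tau`) heterozygous mutations, split into
  clone-shared trunk events and individual tip events by `trunk_fraction`.
* *LOH*: every heterozygous site of a hybrid is driven to homozygosity
  independently with probability 1 − exp(−`lambda_loh` × `age_tau`), the
  retained haplotype chosen uniformly. LOH therefore both erases and fixes
  private mutations, and the truth records mark which private mutations were
  actually *emitted* into the genotype table.
* *mtDNA*: clock-like divergence from the maternal donor species at rate
  `mt_mu`, so the K2P distance to the nearest sexual haplotype is an age
  proxy.

Default rates (`SimConfig`): `d_fix` = 0.01, `theta` = 0.004,
`mu` = 2·10⁻⁸ /site/generation, `lambda_loh` = 7·10⁻⁷ /site/generation,
`sel_shift` = 2.0, `f_inter_nonsyn` = 0.3, `f_intra_nonsyn` = 0.55,
`f_priv_nonsyn` = 0.6, `p_stop` = 0.05, `mt_mu` = 1·10⁻⁷,
`mt_species_div` = 0.05. Clone ages are expressed in generations; the default
complex spans an F1 (τ = 0), a Holocene-young clone (τ = 5·10³) and
pre-glacial old clones (τ = 1.5·10⁵).

**Phenotypes.** `simulate_phenotypes` draws standard length from a normal
distribution, total mass from a length–weight power law (slope ≈ 3.1) with
lognormal noise, organ masses as noisy fractions of body mass, oocyte counts
and scale annuli; group-level multipliers (e.g. `gonad_g_frac: 2.0`) plant
effects for the comparison harness to detect.

## 2. SNP classification (`clonedecay.classify`)

1. **Filtering**: a site is kept if at least 80 % of ingroup samples have
   calls (the outgroup is excluded from the denominator by default) and the
   site is biallelic. Removal counts are reported.
2. **Paralog flagging**: a site heterozygous in *every* sexual species *and*
   the outgroup is flagged as a likely collapsed paralog and excluded.
3. **Category** (priority order, hybrids never influence the first two):
   *intraspecific* (segregating within ≥ 1 sexual species) →
   *interspecific_fixed* (alternative alleles fixed between sexual species)
   → *private_asexual* (variant seen only in hybrid samples) →
   *unclassified*.
4. **Codon masking**: a codon containing ≥ 2 variable sites is masked for
   all synonymity and dN/dS purposes. This is enforced as a hard invariant.
5. **Polarization** of fixed E×T and E×N differences against the sister
   species and outgroup: for an E×T difference, the allele carried by N
   decides the ancestral state; where the consensus of sister species is
   ambiguous, the outgroup L decides; otherwise the site stays unpolarized.

## 3. Codon metrics (`clonedecay.codon`)

**NG86 site counting.** Each codon position contributes synonymous fraction
s = (# synonymous single-nucleotide changes)/3, with changes *into stop
codons counted as nonsynonymous* (so n + s = 3 exactly for every sense
codon). This matches the widespread Biopython/bioperl convention and keeps
N + S equal to the sequence length in sites.

**NG86 pathway counting.** For a codon pair differing at k ≤ 3 positions,
Nd and Sd are averaged over the k! orderings of the changes. Orderings that
pass through a stop codon are excluded; if *every* ordering is blocked, all
orderings are used as a fallback (so Nd + Sd always equals the Hamming
distance in differing positions). The implementation is verified
exhaustively against an independently written brute-force path enumerator
over all 61 × 61 sense-codon pairs.

**Distances and dN/dS.** pN and pS receive the Jukes–Cantor correction;
saturation (p ≥ 3/4, or the K2P logarithm arguments ≤ 0) raises a
`SaturationError` rather than returning NaN. The dN/dS ratio uses a small
pseudo-constant c = 0.01 added to *both* numerator and denominator, so
identical sequences give a ratio of exactly 1.0 and zero-dS comparisons stay
finite without discarding data.

**Radicality.** Amino-acid replacements are scored with PAM100 and BLOSUM90
(via biotite); lower scores mean more radical changes.

## 4. Within-individual dN/dS (`clonedecay.dnds`)

For a hybrid individual, each ORF yields a pair of codon strings from its two
haplotype copies (triploids contribute the two parental-species copies).
Codons overlapping masked or uncalled sites are dropped; an ORF is *eligible*
when ≥ 50 resolved codons remain. In an F1 this within-individual dN/dS
equals the pairwise dN/dS of the two parental founder haplotypes exactly — a
built-in identity used for validation. A null distribution is built from
random pairs of sexual-species haplotypes of the same ORFs.

## 5. Spectra and LOH (`clonedecay.spectra`)

LOH is called per hybrid at diagnostic (fixed interspecific, polarized)
sites: a diploid hybrid shows LOH where it is homozygous at such a site; a
triploid where all allele copies come from one parental species. The
retained-parent tally, heterozygosity, private-SNP proportion and
homozygous-private fraction feed the age analyses.

The LOH-versus-private-load relationship is summarised by a quadratic least
squares fit. The constrained fit (curvature a₂ ≥ 0) uses the exact
single-bound KKT solution: the unconstrained least-squares solution if its
a₂ ≥ 0, otherwise the boundary refit with a₂ = 0. This is exact (no
iterative solver), so a dataset generated from a straight line gives
identical constrained and unconstrained fits to machine precision, and the
constrained residual sum of squares is never below the unconstrained one.

## 6. Statistical tests (`clonedecay.stats`)

* **Binomial LRT** for equality of proportions across groups uses the
  closed-form log-likelihood ratio (equivalent to the deviance difference of
  a binomial GLM with group factor, against which it is cross-checked).
* **Permutation tests** report p = (1 + #{perm ≥ obs}) / (1 + n_perm), never
  returning 0. When observations are clustered (members of one clone),
  cluster labels are permuted as blocks.
* **KS permutation** evaluates the two-sample KS statistic under label
  permutations (vectorised). Note that with *equal* group sizes the KS
  statistic lives on a coarse grid; ties then make the permutation test
  visibly conservative (≈ 2.8 % rejection at nominal 5 % with 30/30). With
  coprime sizes such as 31/37 the empirical level is ≈ 5 %. Calibration
  checks therefore use unequal, coprime sizes; this is a property of the
  statistic's support, not of the implementation.
* Additional tools: Fisher-z confidence interval for Pearson correlation,
  two-sided variance F-test, Welch t-test, Fisher exact and chi-squared
  contingency tests.

## 7. Phenotype analysis (`clonedecay.phenotype`)

Indices: condition (eviscerated mass / SL³), organ somatic indices
(heart/spleen/liver/gonad mass over body mass, with a switchable
denominator), vertebra index, absolute and length-relative fecundity, and
length–weight residuals (LWR) from a log–log regression. Growth is
back-calculated from scale annulus radii by direct proportion
(SLᵢ = SL × rᵢ/R), with monotonicity and range validation.
`compare_groups` runs permutation and Welch tests per index, a KS permutation
test on oocyte-size distributions and contingency tests on clutch size and
embryo survival, all deterministic given a seed and invariant to row order.

## 8. Verification strategy and problem sizes

Tests follow an oracle-first design: every derived quantity is checked either
against an independently coded oracle (brute-force NG86 pathway enumeration,
hand hypergeometric enumeration for Fisher exact, statsmodels GLM for the
binomial LRT, Biopython for single-step dN/dS and BLOSUM90 scores) or against
a planted truth with an explicit statistical envelope (95 % Poisson envelope
for mutation counts, 95 % binomial envelope for LOH, 3–7 % envelopes for
1000-replicate calibration runs). Problem sizes in the verification suite
(e.g. 200 ORFs × 60 codons for classification recovery, 20 replicate clones
per age class, 1000 null replicates per calibration) were chosen so the
checks are sharp yet the whole suite runs in about a minute on one CPU.

## 9. Limitations

The generator is stylised: site classes never collide, mutations are
independent across sites, LOH acts per site rather than in tracts, there is
no linkage, no recombination within sexual species, and no gene conversion
bias. These simplifications are intentional — they make planted truth exact
and recovery unambiguous — but absolute rates and spectra should not be read
as quantitative predictions for any real complex.
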