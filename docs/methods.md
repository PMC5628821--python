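# Methods

This document describes the algorithms and modelling choices in `snpwave`,
in pipeline order, together with the reasoning behind the non-obvious
decisions and the known limitations of the desk-scale generators.

## Synthetic data (`snpwave.simulate`)

**Breed allele frequencies** follow the Balding–Nichols model: an ancestral
alt-allele frequency `p` is drawn from a Beta(0.8, 0.8) spectrum (slightly
favouring extreme frequencies, which yields the rare-variant excess seen in
real folded MAF spectra), optionally sharpened per breed by
`p ← p^shape`, and each breed's frequency is drawn from
`Beta(p(1−F)/F, (1−p)(1−F)/F)` with `F` the breed's fixation index. This
gives `E[p_breed] = p` and `Var[p_breed] = F·p(1−p)`, both verified in
closed form by the tests.

**Genome and sites.** The reference is a uniform random sequence. Base
sites are a Poisson draw thinned to a minimum spacing of 10 bp; planted
defects then overwrite a controlled fraction: clustered partners placed
within 10 bp of a base site (to trip the spacing filter), A/T or G/C allele
pairs (strand-ambiguous), and variant qualities pushed to Q ≤ 10. Every
planted defect is recorded in a `truth` dictionary so filters can be
checked against ground truth exactly rather than statistically.

**Genotypes** are Hardy–Weinberg binomial draws at each breed's
frequencies. For analyses that need genuine relatedness structure,
`simulate_half_sib_genotypes` builds paternal half-sib families: genotyped
sires drawn under Hardy–Weinberg, offspring receiving one Mendelian sire
allele and one population allele (ungenotyped dams). This is the structure
of a dairy population sharing artificial-insemination bulls. It matters for
REML: with unrelated Hardy–Weinberg draws the genomic relationship matrix
is numerically close to the identity at desk scale, so `h²` is nearly
unidentifiable (the likelihood is flat in `h²` when `K ≈ I`); half-sib
families give the kinship eigenvalue spread that makes heritability
estimable with a few hundred animals. Marginal genotype frequencies remain
in Hardy–Weinberg proportions, which the tests verify.

**Phenotypes** are `y = Xβ + Σ_q x_q b_q + a + e` with categorical herd /
year / season / parity fixed effects and an age covariate, optional QTL
with fixed allele-substitution effects, a polygenic term drawn with
covariance proportional to the VanRaden GRM of the simulated genotypes, and
Gaussian noise scaled so the *realized* narrow-sense heritability (QTL
variance counts as genetic) equals the requested `h²` exactly.

## Variant intake (`snpwave.intake`)

VCF reading is delegated to `cyvcf2`; only biallelic SNVs with a numeric
QUAL survive loading (indels, multiallelic records and missing-QUAL records
are tallied in a skip ledger), and duplicate positions keep the higher-QUAL
record. The discovery filters are applied with a fixed reason
precedence so the ledger is deterministic:

1. `not_heterozygous` — no called individual in any breed is heterozygous;
2. `quality` — QUAL not strictly greater than 10;
3. `spacing` — another discovered SNP (pooled across breeds) within 10 bp.

Ambiguous A/T and G/C SNPs are removed separately (`strip_ambiguous`)
because, unlike the filters above, arrays *can* type them at the cost of a
second oligo; callers decide.

**Corrected reference.** Positions where every called individual across
all breeds is homozygous alternate have the alt base substituted into the
reference, producing a species-corrected reference for probe design. The
operation is idempotent by construction: a position already carrying the
alt base is a no-op, while a base matching neither allele is a hard error
(it indicates mismatched inputs, not a re-run).

**Flank pairs.** Each surviving SNP gets a 71-mer window with the target at
position 36 (1-based). The 5' flank is the forward-strand window; the 3'
flank is its reverse complement, i.e. the same locus read from the other
strand, which is how the second probeset of a dual-probe SNP physically
differs from the first. Other discovered SNPs inside the window are
annotated by signed offset from the target; offsets in the terminal 25
bases set per-side terminal flags.

## Probe evaluation (`snpwave.probes`)

Real array vendors score convertibility with a proprietary model; `snpwave`
uses a deterministic surrogate with the same qualitative behaviour:

```
p = 0.9 · f_gc · f_homopolymer · f_unique · f_secondary
```

- `f_gc` decreases linearly with distance of GC content from 0.5;
- `f_homopolymer` penalizes the longest single-base run beyond 4;
- `f_unique` is 1 for flanks whose 16-mers (canonical, i.e. counted
  together with their reverse complements) are all unique in the genome,
  decreasing with multiplicity;
- `f_secondary` penalizes secondary polymorphisms on the probe-arm side of
  the flank — within 20 nt of the target — severely (with the default
  constants an arm-side secondary forces `p ≤ 0.5`, below the hard floor),
  and distal secondaries mildly.

Flanks with `p ≥ 0.6` are *recommended*; `p ≥ 0.56` is the hard floor below
which a flank is never built. Because an arm-side secondary forces `p`
below the floor, the invariant "no built probeset has a secondary SNP
within 20 bases on its arm side" holds by construction and is tested as a
property. A SNP with a recommended flank gets exactly one probeset (the
recommended flank of highest `p`); a SNP retained for genome coverage with
no recommended flank gets one probeset per surviving flank — this is what
produces the single-flank / dual-flank accounting
`total probesets = n_single + 2·n_dual`.

## Panel selection (`snpwave.panel`)

Candidates are partitioned into quality waves by the shipped 70-wave table
(per-breed MAF floors, minimum number of polymorphic breeds, oligo count,
nearest-neighbour spacing, design- and SNP-score tiers, then two catch-all
waves by oligo count). Waves are processed in order; within a wave the
candidate with the highest gap-filling score is selected each round:

```
score_i = Σ_j w_j · MAF_ij · (B_ij − A_ij) · (1 − |(A_ij+B_ij)/2 − P_i| / ((B_ij−A_ij)/2))
```

where `(A_ij, B_ij)` is the gap enclosing position `P_i` among SNPs already
selected *and polymorphic in breed j* (chromosome ends count as gap
boundaries; monomorphic breeds contribute nothing, since `MAF_ij = 0` and
the selected SNP is not inserted into that breed's index). The score is the
product of gap length and centrality, maximal at the gap midpoint and zero
at its edges.

The engine is a lazy max-heap. Every candidate is scored once against the
current gap index; when a candidate is popped, its score is recomputed, and
it is re-pushed if stale. This is exact because scores are monotone
non-increasing as selection proceeds (inserting a point can only split or
leave unchanged every enclosing gap, and the score is monotone in the gap),
so a popped candidate whose fresh score equals its cached score is still
the maximum. Ties break on higher score, then chromosome, then position,
then SNP id, identically in the heap and in the shipped full-rescan oracle
(`select_panel_oracle`), and the two are compared exactly — selection
sequence and scores — over randomized instances in the tests.

## Genotyping QC (`snpwave.qc`)

Per-probeset classification from called genotypes, with call-rate threshold
0.97 and a minimum of 2 minor-allele observations:

- `CallRateBelowThreshold` — call rate below threshold (checked first);
- `PolyHighResolution` — both homozygote classes present and the minor
  allele observed at least twice;
- `NoMinorHom` — polymorphic but one homozygote class absent;
- `MonoHighResolution` — monomorphic with high call rate;
- `Other` — remaining cases (e.g. only heterozygotes, or a single
  minor-allele carrier). A `VINO` category is reserved but never produced:
  the caller model has no variant-intensity channel.

`best_probeset_per_snp` keeps one probeset per SNP by best category, then
call rate, then id. `category_report` tabulates counts as percentages of an
explicit denominator — percentages of different denominators (e.g.
polymorphism rates in a related species measured only on its callable
subset) can then coexist without ambiguity.

## Relationship matrices (`snpwave.kinship`)

The GRM is VanRaden method 1: `G = ZZ' / (2 Σ p_k(1−p_k))` with `Z` the
dosage matrix centred at `2p_k`, sample allele frequencies, monomorphic
sites dropped, missing dosages mean-imputed. Note that with sample (rather
than base-population) frequencies, family structure deflates all entries by
a common offset; comparisons against pedigree expectations should therefore
use differences (e.g. half-sib minus unrelated means ≈ 0.25), which is how
the tests are written. The NRM uses the tabular method over a
parents-before-offspring pedigree, with unknown parents as founders;
standard identities (parent–offspring 0.5, offspring-of-full-sibs diagonal
1.25) are reproduced exactly.

## GRAMMAR GWAS (`snpwave.gwas`)

**QC** removes duplicate samples (pairwise IBS ≥ 0.99, computed on pairwise
complete dosages), then samples and SNPs below 10% call rate and SNPs below
1% MAF, with a removal ledger.

**Structure** is inspected by classical MDS of `1 − IBS` distances
(double-centred, eigendecomposed). Caveat: `1 − IBS` is not generally a
Euclidean metric, so negative eigenvalues can occur and only the requested
top-`k` positive components are returned.

**Step one** fits `y = Xβ + a + e`, `a ~ N(0, σ²_a K)`, by spectral REML:
with `K = USU'`, rotating by `U'` diagonalizes the covariance into weights
`w_i = h² s_i + (1 − h²)`, making the restricted likelihood a smooth scalar
function of `h²` that is maximized by bounded Brent search; the variance
scale, GLS fixed effects, polygenic BLUPs and environmental residuals
`e = y − Xβ̂ − â` then follow in closed form.

**Step two** regresses the residuals on each SNP's mean-imputed dosage; the
squared Wald statistic is referred to χ²(1). Genomic control divides by
`λ = median(χ²)/0.4549`, floored at 1, and significance is called on the
corrected p-values (default α = 1e-4).

**Calibration testing.** The null-calibration test uses unrelated samples
with the identity as the kinship matrix. This isolates the scan machinery:
with `K = I` the GLS step reduces to OLS and BLUP shrinkage is a uniform
scalar that cancels in the χ², so any miscalibration observed is a genuine
defect rather than an artefact of mismatch between simulated and assumed
covariance. (Under family structure, residual-based GRAMMAR statistics are
known to be mildly conservative; that deflation is a property of the
method, not a bug, and is not what the calibration test targets.) Because
the Monte-Carlo standard error of `λ` estimated from 10,000 SNPs is ≈0.023,
the calibration test averages `λ` over five independent replicates and
applies a ≥4-of-5 rule to the per-replicate Kolmogorov–Smirnov uniformity
checks, keeping the false-alarm probability of the test itself below ~10⁻³
without loosening the calibration bands. The GRM-based REML path is
validated separately by heritability recovery on half-sib cohorts and by
planted-QTL power tests.

## Numerical choices and limitations

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; every generator is bit-reproducible.
- Kinship matrices are symmetrized and eigenvalue-clipped at zero before
  REML; matrices with eigenvalues below −1e−6 are rejected as non-PSD
  rather than silently repaired.
- The REML search brackets `h² ∈ [0, 1 − 1e−6]`; `σ²` estimates use the
  REML (n − p) scaling.
- The p-convert surrogate is a stand-in with the right monotonicities, not
  a trained model; absolute values are only meaningful relative to its own
  thresholds.
- The synthetic genome is i.i.d. uniform sequence: there is no repeat
  structure, so 16-mer non-uniqueness is rare unless planted, and no
  linkage disequilibrium, so GWAS hits are single-SNP rather than peaks.
- Pedigrees from the phenotype simulator are random-mating structures used
  to exercise pedigree code; except for the half-sib generator, genotypes
  are frequency draws, not gene drops down those pedigrees.
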