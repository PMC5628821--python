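"""Synthetic reference genomes, multi-breed variant panels, genotypes,
pedigrees and phenotypes with recorded ground truth.

Breed divergence follows the Balding-Nichols model: given an ancestral
allele frequency p, each breed's frequency is drawn from
Beta(p (1-F)/F, (1-p)(1-F)/F), so E[p_breed] = p and
Var[p_breed] = F p (1-p), with F the breed's fixation index. A per-breed
``maf_spectrum_shape`` power applied to the ancestral frequency before the
drift draw skews a breed toward rare variants (a low-MAF excess) with a
single parameter; at shape 1 the Balding-Nichols centring holds exactly.

All generators take an explicit seed and are bit-reproducible; the ``truth``
records carry everything needed to recompute downstream expectations
(planted close-pair positions, ambiguous SNPs, low-quality sites,
monomorphic sites, QTL effects and realized variance components).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from snpwave.genotypes import GenotypeMatrix
from snpwave.kinship import build_grm

BASES = np.array(list("ACGT"))
COMPLEMENT = str.maketrans("ACGT", "TGCA")
AMBIGUOUS_PAIRS = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]

# Unambiguous substitutions available for each reference base.
_UNAMBIGUOUS_ALT = {
    "A": ["C", "G"],
    "T": ["C", "G"],
    "C": ["A", "T"],
    "G": ["A", "T"],
}
_AMBIGUOUS_ALT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class BreedModel:
    """One breed's drift and sampling parameters."""

    name: str
    fst: float
    maf_spectrum_shape: float = 1.0
    n_samples: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.maf_spectrum_shape <= 0:
            raise ValueError("maf_spectrum_shape must be positive")


@dataclass
class PanelSite:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float = 50.0


@dataclass
class SimulatedPanel:
    reference: dict[str, str]
    sites: list[PanelSite]
    breed_frequencies: np.ndarray | None = None  # (n_sites, n_breeds)
    breed_names: list[str] = field(default_factory=list)
    truth: dict = field(default_factory=dict)

    def validate(self) -> None:
        for s in self.sites:
            seq = self.reference[s.chrom]
            if not 1 <= s.pos <= len(seq):
                raise ValueError(f"site {s.chrom}:{s.pos} outside chromosome")
            if seq[s.pos - 1] != s.ref:
                raise ValueError(f"ref mismatch at {s.chrom}:{s.pos}")
        if self.breed_frequencies is not None:
            f = self.breed_frequencies
            if f.min() < 0 or f.max() > 1:
                raise ValueError("breed frequencies outside [0, 1]")


@dataclass
class SimulatedStudy:
    genotypes: GenotypeMatrix
    pedigree: list[tuple[str, str, str]]
    phenotypes: pd.DataFrame
    qtl_truth: list[tuple[str, float]]
    h2_true: float
    truth: dict = field(default_factory=dict)


def simulate_breed_frequencies(
    n_sites: int,
    breeds: list[BreedModel],
    ancestral_spectrum: tuple[float, float] = (0.8, 0.8),
    seed: int = 0,
) -> np.ndarray:
    """Draw a site x breed alt-allele frequency matrix under Balding-Nichols.

    ``ancestral_spectrum`` is the (a, b) of the Beta law for the ancestral
    alt-allele frequency; the default slightly favours extreme frequencies,
    producing realistic folded MAF spectra with a rare-variant excess.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    a, b = ancestral_spectrum
    p_anc = rng.beta(a, b, size=n_sites)
    out = np.empty((n_sites, len(breeds)))
    for j, breed in enumerate(breeds):
        p = np.clip(p_anc**breed.maf_spectrum_shape, 1e-12, 1 - 1e-12)
        if breed.fst == 0.0:
            out[:, j] = p
        else:
            f = breed.fst
            out[:, j] = rng.beta(p * (1 - f) / f, (1 - p) * (1 - f) / f)
    return out


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def simulate_genome_and_sites(
    n_chrom: int = 2,
    chrom_length: int = 1_000_000,
    site_density: float = 1e-3,
    cluster_fraction: float = 0.0,
    ambiguous_fraction: float = 0.0,
    seed: int = 0,
    low_quality_fraction: float = 0.0,
    min_spacing: int = 10,
) -> SimulatedPanel:
    """Random reference plus a panel of SNV sites.

    Base sites are a Poisson draw thinned so no two lie within
    ``min_spacing`` bases; ``cluster_fraction`` of them then receive a
    planted partner closer than ``min_spacing`` (to exercise the spacing
    filter), ``ambiguous_fraction`` get an A/T or G/C allele pair, and
    ``low_quality_fraction`` get a variant quality drawn below the Q>10
    discovery threshold. Every planted feature is recorded in ``truth``.
    """
    for name, frac in [("cluster_fraction", cluster_fraction),
                       ("ambiguous_fraction", ambiguous_fraction),
                       ("low_quality_fraction", low_quality_fraction)]:
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    expected = chrom_length * site_density
    if chrom_length < 80 or expected * (min_spacing + 1) > chrom_length:
        raise ValueError("chromosome too short for the requested site density")

    rng = np.random.default_rng(seed)
    reference: dict[str, str] = {}
    sites: list[PanelSite] = []
    truth: dict = {
        "seed": seed,
        "params": dict(n_chrom=n_chrom, chrom_length=chrom_length,
                       site_density=site_density,
                       cluster_fraction=cluster_fraction,
                       ambiguous_fraction=ambiguous_fraction,
                       low_quality_fraction=low_quality_fraction),
        "clustered_pairs": [],   # [(chrom, base_pos, partner_pos)]
        "ambiguous_sites": [],   # [(chrom, pos)]
        "low_quality_sites": [],  # [(chrom, pos, qual)]
    }

    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        seq = list(_random_sequence(rng, chrom_length))
        n_sites = rng.poisson(expected)
        # thin a uniform draw so base sites respect the spacing floor
        positions: list[int] = []
        candidates = np.sort(rng.integers(36, chrom_length - 35, size=4 * n_sites))
        for p in candidates:
            if len(positions) >= n_sites:
                break
            if not positions or p - positions[-1] > min_spacing:
                positions.append(int(p))
        pos_arr = np.array(positions)

        n_cluster = int(round(cluster_fraction * len(positions)))
        cluster_base = rng.choice(len(positions), size=n_cluster, replace=False) \
            if n_cluster else np.array([], dtype=int)
        partner_pos: list[tuple[int, int]] = []  # (base index, partner position)
        taken = set(positions)
        for bi in cluster_base:
            base = positions[bi]
            for delta in rng.permutation(np.arange(1, min_spacing)):
                cand = base + int(delta)
                if cand not in taken and 36 <= cand <= chrom_length - 35:
                    partner_pos.append((bi, cand))
                    taken.add(cand)
                    break

        n_total = len(positions)
        ambiguous_idx = set(
            rng.choice(n_total, size=int(round(ambiguous_fraction * n_total)),
                       replace=False).tolist()) if n_total else set()
        lowq_idx = set(
            rng.choice(n_total, size=int(round(low_quality_fraction * n_total)),
                       replace=False).tolist()) if n_total else set()

        def make_site(pos: int, ambiguous: bool, low_q: bool) -> PanelSite:
            ref = seq[pos - 1]
            if ambiguous:
                alt = _AMBIGUOUS_ALT[ref]
            else:
                alt = _UNAMBIGUOUS_ALT[ref][rng.integers(0, 2)]
            qual = float(rng.uniform(1.0, 10.0)) if low_q \
                else float(rng.gamma(4.0, 40.0) + 11.0)
            return PanelSite(chrom, pos, ref, alt, qual)

        chrom_sites = []
        for i, pos in enumerate(positions):
            s = make_site(pos, i in ambiguous_idx, i in lowq_idx)
            chrom_sites.append(s)
            if i in ambiguous_idx:
                truth["ambiguous_sites"].append((chrom, pos))
            if i in lowq_idx:
                truth["low_quality_sites"].append((chrom, pos, s.qual))
        for bi, ppos in partner_pos:
            s = make_site(ppos, False, False)
            chrom_sites.append(s)
            truth["clustered_pairs"].append((chrom, positions[bi], ppos))

        chrom_sites.sort(key=lambda s: s.pos)
        reference[chrom] = "".join(seq)
        sites.extend(chrom_sites)

    panel = SimulatedPanel(reference=reference, sites=sites, truth=truth)
    panel.validate()
    return panel


def simulate_genotypes(
    panel: SimulatedPanel,
    breeds: list[BreedModel],
    seed: int = 0,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes at each breed's site frequencies."""
    if panel.breed_frequencies is None:
        raise ValueError("panel has no breed frequencies; run "
                         "simulate_breed_frequencies first")
    freqs = panel.breed_frequencies
    if freqs.shape != (len(panel.sites), len(breeds)):
        raise ValueError("frequency matrix shape does not match sites x breeds")
    rng = np.random.default_rng(seed)
    blocks, sample_ids, breed_map = [], [], {}
    for j, breed in enumerate(breeds):
        calls = rng.binomial(2, freqs[:, j], size=(breed.n_samples, len(panel.sites)))
        blocks.append(calls.astype(np.int8))
        ids = [f"{breed.name}_{i + 1}" for i in range(breed.n_samples)]
        sample_ids.extend(ids)
        breed_map.update({s: breed.name for s in ids})
    calls = np.vstack(blocks)
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = -1
    snp_ids = [f"{s.chrom}_{s.pos}" for s in panel.sites]
    return GenotypeMatrix(sample_ids, snp_ids, calls, sample_breed=breed_map)


def simulate_half_sib_genotypes(
    site_frequencies: np.ndarray,
    breed_name: str,
    n_sires: int,
    n_offspring: int,
    seed: int = 0,
    site_ids: list[str] | None = None,
) -> tuple[GenotypeMatrix, list[tuple[str, str, str]]]:
    """Paternal half-sib families: genotyped sires drawn under Hardy-Weinberg
    at the site frequencies, offspring receiving one sire allele and one
    population allele (ungenotyped dams).

    This is the relatedness structure of a dairy population sharing
    artificial-insemination bulls; it gives the genomic relationship matrix
    the eigenvalue spread that makes heritability identifiable at desk
    scale, which unrelated Hardy-Weinberg draws do not. Marginal genotype
    frequencies remain in Hardy-Weinberg proportions.
    """
    p = np.asarray(site_frequencies, dtype=float)
    if n_sires < 1 or n_offspring < 0:
        raise ValueError("need at least one sire and non-negative offspring")
    rng = np.random.default_rng(seed)
    m = len(p)
    sires = rng.binomial(2, p, size=(n_sires, m)).astype(np.int8)
    sire_of = rng.integers(0, n_sires, size=n_offspring)
    sire_geno = sires[sire_of]
    transmit = np.where(sire_geno == 1,
                        rng.integers(0, 2, size=sire_geno.shape),
                        sire_geno // 2)
    dam_allele = rng.binomial(1, p, size=(n_offspring, m))
    offspring = (transmit + dam_allele).astype(np.int8)

    sire_ids = [f"{breed_name}_sire{i + 1}" for i in range(n_sires)]
    off_ids = [f"{breed_name}_{i + 1}" for i in range(n_offspring)]
    calls = np.vstack([sires, offspring]) if n_offspring else sires
    ids = sire_ids + off_ids
    snp_ids = site_ids if site_ids is not None else [f"snp{i+1}" for i in range(m)]
    gm = GenotypeMatrix(ids, list(snp_ids), calls,
                        sample_breed={s: breed_name for s in ids})
    pedigree = [(s, "0", "0") for s in sire_ids] + [
        (off_ids[i], sire_ids[sire_of[i]], "0") for i in range(n_offspring)]
    return gm, pedigree


def _simulate_pedigree(sample_ids: list[str], n_generations: int,
                       rng: np.random.Generator) -> list[tuple[str, str, str]]:
    """Random-mating pedigree over the samples; parents precede offspring."""
    n = len(sample_ids)
    n_generations = max(1, n_generations)
    bounds = np.linspace(0, n, n_generations + 1).astype(int)
    pedigree: list[tuple[str, str, str]] = []
    for g in range(n_generations):
        start, stop = bounds[g], bounds[g + 1]
        prev = sample_ids[:start]
        for i in range(start, stop):
            if g == 0 or len(prev) < 2:
                pedigree.append((sample_ids[i], "0", "0"))
            else:
                sire, dam = rng.choice(len(prev), size=2, replace=False)
                pedigree.append((sample_ids[i], prev[sire], prev[dam]))
    return pedigree


DEFAULT_FIXED_EFFECTS = {
    # 270-day lactation records from commercial herds: farm, calving-year
    # class (pre/post 2010), calving season, parity class, age in months.
    "mean": 2200.0,          # kg, typical Mediterranean buffalo 270-d yield
    "farm": [0.0, 150.0, -120.0, 80.0],
    "calv_year": [0.0, 60.0],
    "calv_season": [0.0, 40.0, -30.0, 20.0],
    "calvings": [0.0, 180.0],
    "age_slope": 2.0,        # kg per month
    "sigma_p": 450.0,        # phenotypic SD of the random (genetic+residual) part
}


def simulate_phenotypes_and_pedigree(
    genotypes: GenotypeMatrix,
    qtl: list[tuple[str, float]],
    h2: float,
    fixed_effect_design: pd.DataFrame | None = None,
    n_generations: int = 3,
    seed: int = 0,
    effects: dict | None = None,
    pedigree: list[tuple[str, str, str]] | None = None,
) -> SimulatedStudy:
    """Quantitative trait with fixed effects, QTL, GRM-structured polygenic
    values and residual noise scaled so the realized narrow-sense
    heritability equals ``h2``.

    The polygenic term is drawn with covariance proportional to the VanRaden
    genomic relationship built from the simulated genotypes; QTL effects (in
    trait units per alt allele) count toward the genetic variance. The
    pedigree is a random-mating structure over the same samples used to
    exercise pedigree-relationship code; the genotypes themselves are
    frequency draws, not gene drops.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must be in [0, 1]")
    if h2 > 0 and genotypes.n_probesets == 0:
        raise ValueError("nonzero heritability requires markers")
    eff = dict(DEFAULT_FIXED_EFFECTS)
    if effects:
        eff.update(effects)
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    ids = genotypes.sample_ids

    if fixed_effect_design is None:
        fixed_effect_design = pd.DataFrame({
            "farm": rng.integers(1, 5, size=n),
            "calv_year": rng.integers(1, 3, size=n),
            "calv_season": rng.integers(1, 5, size=n),
            "calvings": rng.integers(1, 3, size=n),
            "age_months": rng.uniform(30, 140, size=n),
        }, index=ids)
    cov = fixed_effect_design

    fixed = (eff["mean"]
             + np.asarray(eff["farm"])[cov["farm"].to_numpy() - 1]
             + np.asarray(eff["calv_year"])[cov["calv_year"].to_numpy() - 1]
             + np.asarray(eff["calv_season"])[cov["calv_season"].to_numpy() - 1]
             + np.asarray(eff["calvings"])[cov["calvings"].to_numpy() - 1]
             + eff["age_slope"] * cov["age_months"].to_numpy())

    sigma_p2 = eff["sigma_p"] ** 2
    dosage = genotypes.dosage(impute_mean=True)

    qtl_vals = np.zeros(n)
    for snp_id, beta in qtl:
        if snp_id not in genotypes.probeset_ids:
            raise ValueError(f"QTL site {snp_id!r} not in genotypes")
        qtl_vals += beta * dosage[:, genotypes.probeset_ids.index(snp_id)]
    qtl_vals -= qtl_vals.mean()

    genetic = qtl_vals.copy()
    if h2 > 0:
        grm = build_grm(genotypes).matrix
        # small jitter keeps the Cholesky stable for near-singular GRMs
        chol = np.linalg.cholesky(grm + 1e-6 * np.eye(n))
        poly = chol @ rng.standard_normal(n)
        poly -= poly.mean()
        target_poly_var = max(h2 * sigma_p2 - qtl_vals.var(), 0.0)
        if poly.std() > 0:
            poly *= np.sqrt(target_poly_var) / poly.std()
        genetic = qtl_vals + poly
        # final trim so realized genetic variance hits the target exactly
        if genetic.std() > 0 and h2 > 0:
            genetic *= np.sqrt(h2 * sigma_p2) / genetic.std()
    resid = rng.standard_normal(n)
    resid -= resid.mean()
    resid *= np.sqrt((1.0 - h2) * sigma_p2) / resid.std() if resid.std() > 0 else 1.0

    trait = fixed + genetic + resid
    phenotypes = cov.copy()
    phenotypes.insert(0, "lact_record", trait)
    phenotypes.index.name = "sample_id"

    if pedigree is None:
        pedigree = _simulate_pedigree(ids, n_generations, rng)
    var_g, var_e = float(np.var(genetic)), float(np.var(resid))
    truth = {
        "seed": seed,
        "h2_target": h2,
        "realized_var_genetic": var_g,
        "realized_var_residual": var_e,
        "realized_h2": var_g / (var_g + var_e) if var_g + var_e > 0 else 0.0,
        "fixed_effects": eff,
        "genetic_values": genetic,
        "residuals": resid,
    }
    return SimulatedStudy(genotypes=genotypes, pedigree=pedigree,
                          phenotypes=phenotypes, qtl_truth=list(qtl),
                          h2_true=h2, truth=truth)


# ---------------------------------------------------------------------------
# Writers: plain-text VCF v4.2 (one file per breed), FASTA and TSV outputs.

def write_fasta(reference: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(panel: SimulatedPanel, genotypes: GenotypeMatrix,
              breed: str, path) -> None:
    """VCFv4.2 for one breed's samples at the panel's sites."""
    samples = [s for s in genotypes.sample_ids
               if genotypes.sample_breed and genotypes.sample_breed[s] == breed]
    if not samples:
        raise ValueError(f"no samples for breed {breed!r}")
    rows = [genotypes.sample_ids.index(s) for s in samples]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=snpwave-simulate\n")
        for chrom, seq in panel.reference.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for k, site in enumerate(panel.sites):
            gts = "\t".join(_GT_STRING[int(genotypes.calls[r, k])] for r in rows)
            fh.write(f"{site.chrom}\t{site.pos}\t{site.chrom}_{site.pos}\t"
                     f"{site.ref}\t{site.alt}\t{site.qual:.2f}\t.\t.\tGT\t{gts}\n")


def write_pedigree(pedigree: list[tuple[str, str, str]], path) -> None:
    pd.DataFrame(pedigree, columns=["id", "sire", "dam"]).to_csv(
        path, sep="\t", index=False)


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, sep="\t")
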