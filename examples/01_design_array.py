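"""Design a small multi-breed genotyping panel end to end.

The script walks the whole array-design half of the pipeline on synthetic
data with known ground truth:

1. simulate a reference genome, a discovered-SNV panel with planted
   spacing/quality/ambiguity defects, and per-breed genotypes for four
   river-buffalo breeds;
2. round-trip the discovery call set through per-breed VCFs;
3. apply the discovery filters (heterozygous in at least one individual,
   Q > 10, no neighbour within 10 bp) and drop strand-ambiguous SNPs;
4. build the species-corrected reference and extract 71-mer flank pairs;
5. score both flanks of every candidate with the p-convert surrogate and
   build probesets;
6. run the wave-based greedy gap-minimizing selection with the shipped
   70-wave quality-tier table and report the gap statistics.

Everything is written to a temporary directory; nothing in the repository
is modified.
"""

import tempfile
from pathlib import Path

from snpwave import (
    BreedModel,
    simulate_breed_frequencies,
    simulate_genome_and_sites,
    simulate_genotypes,
)
from snpwave.intake import (
    PositionIndex,
    build_corrected_reference,
    compute_breed_maf,
    extract_flanks,
    filter_sites,
    load_sites,
    merge_breed_sites,
    strip_ambiguous,
)
from snpwave.panel import (
    CandidateSNP,
    gap_statistics,
    load_wave_table,
    select_panel,
)
from snpwave.probes import (
    KmerIndex,
    assemble_design,
    build_probesets,
    evaluate_flank_pair,
)
from snpwave.simulate import write_vcf

BREEDS = [
    BreedModel("Mediterranean", fst=0.05, n_samples=8),
    BreedModel("Murrah", fst=0.08, n_samples=8),
    BreedModel("Jaffarabadi", fst=0.12, maf_spectrum_shape=1.6, n_samples=6),
    BreedModel("Nili-Ravi", fst=0.08, n_samples=6),
]

workdir = Path(tempfile.mkdtemp(prefix="snpwave_design_"))
print(f"working in {workdir}\n")

# -- 1. synthetic discovery data --------------------------------------------
panel = simulate_genome_and_sites(
    n_chrom=2, chrom_length=500_000, site_density=1e-3,
    cluster_fraction=0.06, ambiguous_fraction=0.10,
    low_quality_fraction=0.05, seed=11)
panel.breed_frequencies = simulate_breed_frequencies(
    len(panel.sites), BREEDS, seed=12)
panel.breed_names = [b.name for b in BREEDS]
genotypes = simulate_genotypes(panel, BREEDS, seed=13)
print(f"simulated {len(panel.sites)} SNVs on {len(panel.reference)} "
      f"chromosomes for {genotypes.n_samples} animals in {len(BREEDS)} breeds")
print(f"planted defects: {len(panel.truth['clustered_pairs'])} clustered "
      f"pairs, {len(panel.truth['ambiguous_sites'])} ambiguous, "
      f"{len(panel.truth['low_quality_sites'])} low-quality sites\n")

# -- 2. VCF round trip -------------------------------------------------------
per_breed = {}
for breed in BREEDS:
    vcf = workdir / f"{breed.name}.vcf"
    write_vcf(panel, genotypes, breed.name, vcf)
    sites, ledger = load_sites(vcf, breed.name)
    per_breed[breed.name] = sites
    print(f"{breed.name}: loaded {len(sites)} SNVs from {vcf.name} "
          f"({dict(ledger)})")
merged = merge_breed_sites(per_breed)

# -- 3. discovery filters ----------------------------------------------------
pooled = PositionIndex.from_sites(merged)
retained, rejected = filter_sites(merged, pooled)
reasons = {}
for _, reason in rejected:
    reasons[reason] = reasons.get(reason, 0) + 1
print(f"\ndiscovery filters: {len(retained)} retained, "
      f"{len(rejected)} rejected {reasons}")
candidates_sites = strip_ambiguous(retained)
print(f"after dropping A/T and G/C SNPs: {len(candidates_sites)} candidates")

# -- 4. corrected reference and flanks --------------------------------------
corrected = build_corrected_reference(panel.reference, merged)
n_subst = sum(a != b for c in panel.reference
              for a, b in zip(panel.reference[c], corrected[c]))
print(f"species-corrected reference: {n_subst} bases substituted")

# -- 5. probe design ---------------------------------------------------------
index = KmerIndex(corrected, k=16)
mafs = compute_breed_maf(candidates_sites)
per_snp, drop_reasons, cands = {}, {}, []
for site, site_maf in zip(candidates_sites, mafs):
    try:
        flanks = extract_flanks(corrected, site, pooled)
    except ValueError:
        drop_reasons["edge_locus"] = drop_reasons.get("edge_locus", 0) + 1
        continue
    evals = evaluate_flank_pair(flanks, index)
    probesets, reason = build_probesets(flanks.snp_id, flanks, evals)
    if reason:
        drop_reasons[reason] = drop_reasons.get(reason, 0) + 1
        continue
    per_snp[flanks.snp_id] = probesets
    near = pooled.nearest_other_distance(site.chrom, site.pos)
    cands.append(CandidateSNP(
        snp_id=flanks.snp_id, chrom=site.chrom, pos=site.pos,
        maf={b: (site_maf[b].maf or 0.0) for b in per_breed},
        design_score=max(p.p_convert for p in probesets),
        snp_score=site.qual,
        oligo_count=max(p.oligo_count for p in probesets),
        nearest_snp_bp=float(near) if near is not None else float("inf")))

design = assemble_design(per_snp)
print(f"probe design: {design.n_single_flank_snps} single-flank + "
      f"{design.n_dual_flank_snps} dual-flank SNPs = "
      f"{design.total_probesets} probesets for {design.total_snps} SNPs "
      f"(dropped: {drop_reasons})")

# -- 6. wave-based greedy selection ------------------------------------------
waves, weights = load_wave_table()
lengths = {c: len(seq) for c, seq in corrected.items()}
result = select_panel(cands, waves, weights, target_n=100,
                      chrom_lengths=lengths)
print(f"\nselected {len(result.selected)} SNPs; per-wave counts "
      f"{dict(sorted(result.per_wave_counts.items()))}")

pos_by_chrom = {}
by_id = {c.snp_id: c for c in cands}
for sid in result.selected:
    c = by_id[sid]
    pos_by_chrom.setdefault(c.chrom, []).append(c.pos)
stats = gap_statistics(pos_by_chrom, lengths)
print("gap statistics (bp): " +
      ", ".join(f"{k}={v:.0f}" for k, v in stats.items()))
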